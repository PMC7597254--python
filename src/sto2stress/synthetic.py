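"""Ground-truth generators for every pipeline stage.

Three simulators close the loop on the analysis chain, each storing the
truth it injected so downstream estimates can be scored exactly:

* :func:`generate_cube` — forward Beer–Lambert imaging: given true StO2,
  total-hemoglobin and melanin maps it exponentiates the chromophore
  mixture into a reflectance cube (plus optional sensor noise), the exact
  inverse of the unmixing in :mod:`sto2stress.sto2`.
* :func:`generate_landmarks` — a random quartic-consistent facial
  deformation with matched landmark pairs and a deformed map, the exact
  model class of :mod:`sto2stress.registration`.
* :func:`generate_cohort` — a stress-study cohort in the published
  database layout: 42 participants x 5 conditions (ES_baseline, ES,
  PS_baseline, PS1, PS2) of registered StO2 maps on the standard canvas,
  210 maps total.

Cohort effect structure (defaults, saturation units):

* Emotional stress raises StO2 in the forehead, both cheeks and the
  meixin; the nose barely changes; chin and philtrum are mixed-sign with
  a negative minority.
* Physical stress is participant-global in sign: with probability
  ``p_down`` (= 0.6) the whole face drops below baseline; otherwise it
  rises.  Two minutes later (PS2) each participant has recovered a
  fraction ``recovery`` of the way back toward baseline, so PS2 deltas
  shrink toward zero without vanishing.
* The class-discriminative structure is placed in {ROI4, ROI5, ROI7} by
  construction (see the effect tables below), making that triple the
  simulator's known best subset for the exhaustive search.  This is a
  simulator convention, not an empirical claim.

Every generator is a pure function of (config, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .hsi_core import HSICube, Map2D, WavelengthGrid
from .registration import (
    LandmarkSet,
    N_LANDMARKS,
    _design_matrix,
    standard_landmarks,
)
from .roi_features import ROIGeometry, default_geometry
from .sto2 import ChromophoreBasis, default_basis

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cube",
    "generate_cohort",
    "generate_landmarks",
    "smooth_field",
]


def smooth_field(shape: tuple[int, int], sigma_px: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero-mean low-frequency Gaussian random surface with pixel SD ``sd``.

    Correlation length is ~``sigma_px``.  Synthesised on a coarse grid
    (white noise smoothed at 2 coarse-pixels) and bilinearly upsampled, so
    the cost is independent of the correlation length.
    """
    factor = max(1.0, sigma_px / 2.0)
    coarse = (int(np.ceil(shape[0] / factor)) + 3,
              int(np.ceil(shape[1] / factor)) + 3)
    f = ndimage.gaussian_filter(rng.standard_normal(coarse), 2.0)
    if factor > 1.0:
        f = ndimage.zoom(f, factor, order=1)
    f = f[:shape[0], :shape[1]]
    f = f - f.mean()
    s = f.std()
    return f * (sd / s) if s > 0 else f


# ---------------------------------------------------------------------------
# Forward Beer-Lambert cube generation

def generate_cube(
    sto2_map: np.ndarray,
    thb_map: np.ndarray | float = 1.0,
    mel_map: np.ndarray | float = 0.1,
    offset: np.ndarray | float = 0.05,
    basis: ChromophoreBasis | None = None,
    reference: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[HSICube, dict]:
    """Forward-simulate a reflectance cube from chromophore truth maps.

    Per pixel, ``c_HbO2 = StO2 * THb`` and ``c_Hb = (1 - StO2) * THb``;
    the linear predictor ``L = eps @ c + offset`` is exponentiated into
    reflectance ``R = R_ref * 10**(-L)``, then i.i.d. Gaussian reflectance
    noise of standard deviation ``noise_sigma`` (absolute reflectance
    units; 0.005 = 0.5%) is added.

    Returns the cube and a truth dict holding the injected maps and the
    noiseless linear predictor (for exact oracle comparisons).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    sto2 = np.asarray(sto2_map, dtype=float)
    if sto2.ndim != 2:
        raise ValueError("sto2_map must be 2D")
    if np.any((sto2 < 0) | (sto2 > 1)):
        raise ValueError("true StO2 must lie in [0, 1]")
    thb = np.broadcast_to(np.asarray(thb_map, float), sto2.shape)
    mel = np.broadcast_to(np.asarray(mel_map, float), sto2.shape)
    off = np.broadcast_to(np.asarray(offset, float), sto2.shape)
    if basis is None:
        basis = default_basis()
    if reference is None:
        reference = np.ones(len(basis))
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (len(basis),):
        raise ValueError("reference length must match basis grid")

    c = np.stack([sto2 * thb, (1.0 - sto2) * thb, mel], axis=-1)  # (h, w, 3)
    eps = np.stack([basis.eps_hbo2, basis.eps_hb, basis.eps_mel])  # (3, n_bands)
    predictor = c @ eps + off[..., None]  # (h, w, n_bands)
    refl = reference * 10.0 ** (-predictor)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, noise_sigma, refl.shape)
    cube = HSICube(refl, WavelengthGrid(basis.wavelengths_nm))
    truth = {
        "sto2": sto2, "thb": np.array(thb), "mel": np.array(mel),
        "offset": np.array(off), "linear_predictor": predictor,
    }
    return cube, truth


# ---------------------------------------------------------------------------
# Cohort generation

# Per-ROI (mean, sd) of the ES - ES_baseline delta, saturation units.
_ES_EFFECTS = {
    "ROI1": (0.040, 0.022),
    "ROI2": (0.030, 0.022),
    "ROI3": (0.000, 0.022),
    "ROI4": (0.040, 0.008),
    "ROI5": (0.004, 0.008),
    "ROI6": (0.006, 0.022),
    "ROI7": (0.050, 0.008),
}

# Per-ROI (mean, sd) of the unsigned PS1 magnitude for participants whose
# PS1 dropped below baseline (deltas are the negated draws): these differ
# from ES by sign in every region.
_PS_DOWN_MAGNITUDES = {
    "ROI1": (0.035, 0.022),
    "ROI2": (0.030, 0.022),
    "ROI3": (0.030, 0.022),
    "ROI4": (0.030, 0.008),
    "ROI5": (0.030, 0.008),
    "ROI6": (0.030, 0.022),
    "ROI7": (0.030, 0.008),
}

# Participants whose PS1 *rose* are the hard class boundary, and they are a
# mixture of three variants.  Each variant reproduces the ES facial
# pattern except in exactly one of ROI4 / ROI5 / ROI7, where the mean is
# displaced by several within-class SDs (left cheek flat-to-down, chin
# strongly up, meixin flat-to-down).  Consequences, by construction: any
# subset omitting one of the three regions overlaps an entire PS-up
# subpopulation with the ES cluster, while {ROI4, ROI5, ROI7} separates
# every variant with a large margin — the triple is the unique best
# subset.  ROI1/2/3/6 match ES in the mean and carry twice the
# variability, adding noise rather than signal.  This is a simulator
# convention that gives the exhaustive search a verifiable right answer,
# not an empirical claim about faces.
_PS_UP_BASE = {
    "ROI1": (0.035, 0.022),
    "ROI2": (0.030, 0.022),
    "ROI3": (0.005, 0.022),
    "ROI4": (0.040, 0.008),
    "ROI5": (0.004, 0.008),
    "ROI6": (0.010, 0.022),
    "ROI7": (0.050, 0.008),
}

#: variant coordinate -> replacement mean for that ROI's PS-up delta
_PS_UP_VARIANT_MEANS = {
    "ROI4": -0.025,
    "ROI5": 0.075,
    "ROI7": -0.025,
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic stress cohort."""

    n_participants: int = 42
    canvas_shape: tuple[int, int] = (513, 911)
    es_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_ES_EFFECTS))
    ps_down_magnitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_PS_DOWN_MAGNITUDES))
    ps_up_base: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_PS_UP_BASE))
    ps_up_variant_means: dict[str, float] = field(
        default_factory=lambda: dict(_PS_UP_VARIANT_MEANS))
    #: probability of a globally *lower* PS1 than baseline
    p_down: float = 0.6
    #: fraction of the PS1 excursion recovered by PS2
    recovery: float = 0.5
    #: participant baseline StO2 level: mean, sd
    baseline_level: tuple[float, float] = (0.65, 0.03)
    #: SD of the per-participant smooth anatomical field
    anatomy_sd: float = 0.02
    #: SD of the per-condition smooth noise field
    spatial_noise_sd: float = 0.002
    #: SD of per-pixel white noise
    pixel_noise_sd: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 <= self.p_down <= 1.0:
            raise ValueError("p_down must be in [0, 1]")
        if not 0.0 <= self.recovery <= 1.0:
            raise ValueError("recovery must be in [0, 1]")
        for name in ("anatomy_sd", "spatial_noise_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for d in (self.es_effects, self.ps_down_magnitudes, self.ps_up_base):
            for roi, (_, sd) in d.items():
                if sd < 0:
                    raise ValueError(f"{roi}: SD must be >= 0")
        unknown = set(self.ps_up_variant_means) - set(self.ps_up_base)
        if unknown:
            raise ValueError(f"variant coordinates not in ps_up_base: {unknown}")


@dataclass
class ParticipantTruth:
    """Injected truth for one participant."""

    base_level: float
    ps_down: bool
    es_deltas: dict[str, float]
    ps1_deltas: dict[str, float]
    ps2_deltas: dict[str, float]


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates of a cohort."""

    config: CohortConfig
    participants: dict[str, ParticipantTruth]

    def to_dict(self) -> dict:
        return {
            "config": {**asdict(self.config),
                       "canvas_shape": list(self.config.canvas_shape)},
            "participants": {k: asdict(v) for k, v in self.participants.items()},
        }


def _delta_surface(deltas: dict[str, float], global_term: float,
                   roi_masks: dict[str, np.ndarray],
                   outside: np.ndarray) -> np.ndarray:
    surf = global_term * outside
    for roi, d in deltas.items():
        surf = surf + d * roi_masks[roi]
    return surf


def generate_cohort(
    config: CohortConfig | None = None,
    geometry: ROIGeometry | None = None,
) -> tuple[dict[str, dict[str, Map2D]], GroundTruth]:
    """Simulate registered StO2 maps for a full stress cohort.

    Returns ``(cohort, truth)`` where ``cohort[participant][condition]``
    is a :class:`Map2D` on the standard canvas, for the five conditions
    ES_baseline, ES, PS_baseline, PS1, PS2 (``n_participants x 5`` maps),
    and ``truth`` records every drawn delta.

    Per participant: a baseline level plus a smooth anatomical field is
    shared by all five conditions (so baseline subtraction removes it);
    condition surfaces add the drawn per-ROI deltas inside the ROI rasters
    and a global term elsewhere; each acquisition gets its own smooth
    noise field and white pixel noise.  Values are clipped to [0, 1].
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    if geometry is None:
        geometry = default_geometry(config.canvas_shape)
    elif geometry.canvas_shape != tuple(config.canvas_shape):
        raise ValueError("geometry canvas does not match config canvas")

    shape = tuple(config.canvas_shape)
    rng = np.random.default_rng(config.seed)
    roi_masks = {r: geometry.mask(r).astype(float) for r in geometry.names}
    outside = 1.0 - sum(roi_masks.values())
    sigma_anat = min(shape) / 8.0
    sigma_cond = min(shape) / 16.0

    cohort: dict[str, dict[str, Map2D]] = {}
    participants: dict[str, ParticipantTruth] = {}
    full_mask = np.ones(shape, dtype=bool)

    variants = sorted(config.ps_up_variant_means)
    n_up_seen = 0  # PS-up variants are assigned round-robin (balanced)

    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        base_level = rng.normal(*config.baseline_level)
        anatomy = smooth_field(shape, sigma_anat, config.anatomy_sd, rng)

        es_deltas = {r: rng.normal(m, s) for r, (m, s) in config.es_effects.items()}
        ps_down = bool(rng.random() < config.p_down)
        if ps_down:
            sign = -1.0
            ps1_deltas = {r: -abs(rng.normal(m, s))
                          for r, (m, s) in config.ps_down_magnitudes.items()}
        else:
            sign = 1.0
            variant = variants[n_up_seen % len(variants)] if variants else None
            n_up_seen += 1
            ps1_deltas = {}
            for r, (m, s) in config.ps_up_base.items():
                mean = config.ps_up_variant_means[r] if r == variant else m
                ps1_deltas[r] = rng.normal(mean, s)
        ps2_deltas = {r: (1.0 - config.recovery) * d for r, d in ps1_deltas.items()}

        surfaces = {
            "ES_baseline": np.zeros(shape),
            "ES": _delta_surface(es_deltas, 0.01, roi_masks, outside),
            "PS_baseline": np.zeros(shape),
            "PS1": _delta_surface(ps1_deltas, sign * 0.03, roi_masks, outside),
            "PS2": _delta_surface(ps2_deltas, (1.0 - config.recovery) * sign * 0.03,
                                  roi_masks, outside),
        }
        maps = {}
        for cond, surf in surfaces.items():
            vals = base_level + anatomy + surf
            if config.spatial_noise_sd > 0:
                vals = vals + smooth_field(shape, sigma_cond,
                                           config.spatial_noise_sd, rng)
            if config.pixel_noise_sd > 0:
                vals = vals + rng.normal(0.0, config.pixel_noise_sd, shape)
            maps[cond] = Map2D(np.clip(vals, 0.0, 1.0), full_mask.copy())
        cohort[pid] = maps
        participants[pid] = ParticipantTruth(
            base_level=float(base_level), ps_down=ps_down,
            es_deltas={k: float(v) for k, v in es_deltas.items()},
            ps1_deltas={k: float(v) for k, v in ps1_deltas.items()},
            ps2_deltas={k: float(v) for k, v in ps2_deltas.items()},
        )
    return cohort, GroundTruth(config=config, participants=participants)


# ---------------------------------------------------------------------------
# Quartic-consistent deformations for the registration harness

def generate_landmarks(
    canvas_shape: tuple[int, int] = (513, 911),
    deformation_scale: float = 5.0,
    seed: int = 0,
    truth_map: Map2D | None = None,
    landmark_jitter: float = 0.0,
) -> tuple[LandmarkSet, LandmarkSet, Map2D, dict]:
    """Random quartic deformation with matched landmarks and deformed map.

    A true canvas→source transform ``T`` is built as identity plus a
    random quartic perturbation whose RMS landmark displacement equals
    ``deformation_scale`` pixels (0 gives the identity).  Source landmarks
    are ``T(reference landmarks)`` plus optional i.i.d. jitter; the
    deformed map satisfies ``deformed(T(p)) ≈ truth_map(p)`` (constructed
    by numerically inverting the near-identity ``T``).  Because ``T`` is
    itself quartic, a fitted quartic warp can recover it exactly at the
    landmarks.

    Returns ``(source_landmarks, target_landmarks, deformed_map, truth)``
    with the truth dict holding the transform callable and the truth map.
    """
    if deformation_scale < 0:
        raise ValueError("deformation scale must be >= 0")
    h, w = canvas_shape
    rng = np.random.default_rng(seed)
    target = standard_landmarks(canvas_shape)
    if truth_map is None:
        vals = 0.65 + smooth_field(canvas_shape, min(canvas_shape) / 10.0, 0.05, rng)
        truth_map = Map2D(np.clip(vals, 0.0, 1.0), np.ones(canvas_shape, bool))

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    hx, hy = w / 2.0, h / 2.0

    def _normalise(x, y):
        return (x - cx) / hx, (y - cy) / hy

    # identity in monomial coordinates: x = cx + hx * xn, y = cy + hy * yn
    coef_x = np.zeros(15)
    coef_y = np.zeros(15)
    # exponent order matches registration._design_matrix: (0,0), (0,1), (1,0), ...
    coef_x[0], coef_x[2] = cx, hx
    coef_y[0], coef_y[1] = cy, hy

    if deformation_scale > 0:
        pert_x = rng.standard_normal(15)
        pert_y = rng.standard_normal(15)
        xn, yn = _normalise(target.x, target.y)
        M = _design_matrix(xn, yn)
        disp = np.column_stack([M @ pert_x, M @ pert_y])
        rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
        scale = deformation_scale / rms
        coef_x = coef_x + pert_x * scale
        coef_y = coef_y + pert_y * scale

    def transform(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xn, yn = _normalise(np.asarray(x, float), np.asarray(y, float))
        M = _design_matrix(xn.ravel(), yn.ravel())
        return ((M @ coef_x).reshape(np.shape(x)),
                (M @ coef_y).reshape(np.shape(y)))

    src_pts = np.column_stack(transform(target.x, target.y))
    if landmark_jitter > 0:
        src_pts = src_pts + rng.normal(0.0, landmark_jitter, src_pts.shape)
    source = LandmarkSet(src_pts, frame_id="deformed")

    # deformed image D on the source grid: D(q) = truth(T^{-1}(q)),
    # T inverted by fixed-point iteration (T is near identity)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    px, py = xx.copy(), yy.copy()
    for _ in range(8):
        tx, ty = transform(px, py)
        px = px - (tx - xx)
        py = py - (ty - yy)
    vals = ndimage.map_coordinates(truth_map.values, [py.ravel(), px.ravel()],
                                   order=1, mode="nearest").reshape(h, w)
    inside = (px >= 0) & (px <= w - 1) & (py >= 0) & (py <= h - 1)
    deformed = Map2D(vals, inside)

    truth = {"transform": transform, "truth_map": truth_map,
             "coef_x": coef_x, "coef_y": coef_y}
    return source, target, deformed, truth
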