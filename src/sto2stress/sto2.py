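"""Three-chromophore unmixing of attenuation spectra and StO2 mapping.

In the green–yellow analysis window (518–580 nm) the dominant skin
chromophores are oxyhemoglobin (HbO2), deoxyhemoglobin (Hb) and melanin.
Per pixel, the optical density is modelled as a modified Beer–Lambert
mixture

    A(lambda) = eps_HbO2(lambda) c1 + eps_Hb(lambda) c2
                + eps_mel(lambda) c3 + b,

where c1..c3 are non-negative effective concentration x pathlength
products and the wavelength-flat offset ``b`` absorbs scattering and
baseline losses (the "modified" element).  The fit is a non-negative least
squares problem (offset unconstrained).  Tissue oxygen saturation is then

    StO2 = c1 / (c1 + c2),

masked invalid where the total hemoglobin signal falls below a floor
(avoiding 0/0 on hemoglobin-free or failed pixels).  Facial microcirculation
StO2 spans roughly 0.60 (venous) to 0.98 (arterial).

The packaged default extinction basis is a smooth analytic approximation
of the published band shapes — HbO2 beta/alpha bands near 542/577 nm, the
single broad Hb band near 556 nm, melanin as a power-law decay — in
arbitrary consistent units; it is synthetic, not a literature table, and
can be swapped for any CSV basis (columns ``wavelength_nm, eps_hbo2,
eps_hb, eps_mel``).  Saturation is a ratio of coefficients fitted against
the same basis, so a consistent rescaling of the basis leaves StO2
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import lsq_linear

from .hsi_core import HSICube, Map2D, WavelengthGrid, attenuation, select_band_window

__all__ = [
    "ChromophoreBasis",
    "ChromophoreFit",
    "default_basis",
    "load_basis_csv",
    "fit_chromophores",
    "sto2_from_fit",
    "sto2_map",
    "smooth_masked",
]

#: default spectral fit window, nm
DEFAULT_WINDOW_NM = (518.0, 580.0)
#: default hemoglobin-sum floor (basis units) below which StO2 is invalid
DEFAULT_HB_FLOOR = 1e-6
#: default moving-average smoothing kernel (pixels, square)
DEFAULT_SMOOTH_PX = 5


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def hbo2_extinction(wl_nm: np.ndarray) -> np.ndarray:
    """Synthetic HbO2 extinction: beta (542 nm) + alpha (577 nm) bands."""
    wl = np.asarray(wl_nm, dtype=float)
    return (
        1.00 * _gauss(wl, 542.0, 10.0)
        + 0.85 * _gauss(wl, 577.0, 8.0)
        + 0.08 * np.exp(-(wl - 500.0) / 80.0)
    )


def hb_extinction(wl_nm: np.ndarray) -> np.ndarray:
    """Synthetic Hb extinction: single broad band at 556 nm."""
    wl = np.asarray(wl_nm, dtype=float)
    return 1.05 * _gauss(wl, 556.0, 16.0) + 0.10 * np.exp(-(wl - 500.0) / 80.0)


def melanin_extinction(wl_nm: np.ndarray) -> np.ndarray:
    """Melanin as a smooth power-law decay in wavelength."""
    wl = np.asarray(wl_nm, dtype=float)
    return 0.5 * (wl / 550.0) ** -3.0


@dataclass(frozen=True)
class ChromophoreBasis:
    """Extinction spectra for HbO2, Hb and melanin on a wavelength grid."""

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    eps_mel: np.ndarray
    basis_id: str = "unnamed"

    def __post_init__(self) -> None:
        for name in ("wavelengths_nm", "eps_hbo2", "eps_hb", "eps_mel"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.wavelengths_nm.size
        if any(getattr(self, a).shape != (n,) for a in ("eps_hbo2", "eps_hb", "eps_mel")):
            raise ValueError("extinction columns must match wavelength grid length")
        if any(np.any(getattr(self, a) < 0) for a in ("eps_hbo2", "eps_hb", "eps_mel")):
            raise ValueError("extinction values must be non-negative")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix: columns (eps_hbo2, eps_hb, eps_mel, 1)."""
        return np.column_stack(
            [self.eps_hbo2, self.eps_hb, self.eps_mel, np.ones(len(self))]
        )

    def resample(self, wl_nm: np.ndarray) -> "ChromophoreBasis":
        """Linear-interpolate the basis onto a new wavelength grid."""
        wl = np.asarray(wl_nm, dtype=float)
        if wl.min() < self.wavelengths_nm.min() or wl.max() > self.wavelengths_nm.max():
            raise ValueError("requested grid extends outside the basis support")
        interp = lambda col: np.interp(wl, self.wavelengths_nm, col)
        return ChromophoreBasis(
            wl, interp(self.eps_hbo2), interp(self.eps_hb), interp(self.eps_mel),
            basis_id=self.basis_id,
        )


def default_basis(wl_nm: np.ndarray | None = None) -> ChromophoreBasis:
    """The packaged synthetic three-chromophore basis.

    Evaluated analytically on ``wl_nm`` (default: 500–600 nm, 2 nm step,
    covering the 518–580 nm fit window).
    """
    if wl_nm is None:
        wl_nm = np.arange(500.0, 600.0 + 1e-9, 2.0)
    wl = np.asarray(wl_nm, dtype=float)
    return ChromophoreBasis(
        wl, hbo2_extinction(wl), hb_extinction(wl), melanin_extinction(wl),
        basis_id="synthetic-analytic-v1",
    )


def load_basis_csv(path: str | Path) -> ChromophoreBasis:
    """Load a basis from CSV (columns wavelength_nm, eps_hbo2, eps_hb, eps_mel)."""
    df = pd.read_csv(path, comment="#")
    required = {"wavelength_nm", "eps_hbo2", "eps_hb", "eps_mel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"basis CSV missing columns: {sorted(missing)}")
    df = df.sort_values("wavelength_nm")
    return ChromophoreBasis(
        df["wavelength_nm"].to_numpy(), df["eps_hbo2"].to_numpy(),
        df["eps_hb"].to_numpy(), df["eps_mel"].to_numpy(),
        basis_id=str(Path(path).name),
    )


@dataclass(frozen=True)
class ChromophoreFit:
    """Result of one per-pixel spectral fit."""

    c_hbo2: float
    c_hb: float
    c_mel: float
    offset: float
    residual_norm: float
    valid: bool = True

    INVALID: "ChromophoreFit" = None  # type: ignore[assignment]


ChromophoreFit.INVALID = ChromophoreFit(
    np.nan, np.nan, np.nan, np.nan, np.nan, valid=False
)


def fit_chromophores(
    spectrum: np.ndarray, basis: ChromophoreBasis
) -> ChromophoreFit:
    """Fit one attenuation spectrum as a non-negative chromophore mixture.

    Concentrations are constrained >= 0 (physical); the flat offset is
    unconstrained.  Spectrum and basis must share the same (windowed)
    wavelength grid.  An all-invalid spectrum yields
    ``ChromophoreFit.INVALID`` rather than raising.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.shape != (len(basis),):
        raise ValueError(
            f"spectrum has {y.shape} entries, basis has {len(basis)} wavelengths"
        )
    good = np.isfinite(y)
    if good.sum() < 4:
        return ChromophoreFit.INVALID
    E = basis.matrix[good]
    res = lsq_linear(
        E, y[good],
        bounds=([0.0, 0.0, 0.0, -np.inf], np.inf),
        method="bvls",
    )
    c1, c2, c3, b = res.x
    rnorm = float(np.linalg.norm(E @ res.x - y[good]))
    return ChromophoreFit(float(c1), float(c2), float(c3), float(b), rnorm)


def sto2_from_fit(fit: ChromophoreFit, floor: float = DEFAULT_HB_FLOOR) -> float:
    """Saturation ``c_HbO2 / (c_Hb + c_HbO2)``; NaN when the total
    hemoglobin signal is below ``floor`` or the fit is invalid."""
    if not fit.valid:
        return float("nan")
    total = fit.c_hbo2 + fit.c_hb
    if total < floor:
        return float("nan")
    return float(fit.c_hbo2 / total)


def smooth_masked(map2d: Map2D, size: int = DEFAULT_SMOOTH_PX) -> Map2D:
    """Mask-aware square moving average.

    Each valid output pixel averages the valid pixels inside its
    ``size x size`` neighbourhood (renormalised by the valid count), so
    invalid pixels neither contribute values nor shrink their neighbours'
    averages.  A constant map is unchanged.
    """
    if size <= 1:
        return Map2D(map2d.values.copy(), map2d.mask.copy())
    vals = np.where(map2d.mask, map2d.values, 0.0)
    num = ndimage.uniform_filter(vals, size=size, mode="constant")
    den = ndimage.uniform_filter(map2d.mask.astype(float), size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return Map2D(out, map2d.mask & (den > 0))


def _batched_fit(A: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-pixel mixture fit.

    ``A`` is (n_pixels, n_bands); ``E`` the (n_bands, 4) design matrix.
    Solves unconstrained least squares for every pixel at once, then
    re-solves only pixels with negative concentrations under the bound
    constraint.  Returns (coefficients (n_pixels, 4), residual norms).
    """
    coef, *_ = np.linalg.lstsq(E, A.T, rcond=None)
    coef = coef.T
    neg = np.any(coef[:, :3] < 0, axis=1)
    for i in np.nonzero(neg)[0]:
        res = lsq_linear(
            E, A[i], bounds=([0.0, 0.0, 0.0, -np.inf], np.inf), method="bvls"
        )
        coef[i] = res.x
    resid = np.linalg.norm(A - coef @ E.T, axis=1)
    return coef, resid


def sto2_map(
    cube: HSICube,
    basis: ChromophoreBasis | None = None,
    reference: np.ndarray | None = None,
    window_nm: tuple[float, float] = DEFAULT_WINDOW_NM,
    smooth_px: int = DEFAULT_SMOOTH_PX,
    hb_floor: float = DEFAULT_HB_FLOOR,
) -> Map2D:
    """Per-pixel StO2 map from a reflectance cube.

    Pipeline: attenuation against ``reference`` (default: unit reference,
    i.e. the cube already holds reflectance relative to the white
    standard) → restriction to the fit window → non-negative mixture fit
    per pixel → saturation ratio → mask-aware moving-average smoothing of
    the raw saturation image.

    The fit always uses only bands inside ``window_nm`` even when the cube
    carries a wider grid.  Raises if the window misses the grid entirely.
    """
    if reference is None:
        reference = np.ones(cube.n_bands)
    att = attenuation(cube, reference)
    att_win, sub_grid = select_band_window(att, cube.grid, *window_nm)
    if basis is None:
        basis = default_basis(sub_grid.wavelengths_nm)
    elif not np.array_equal(basis.wavelengths_nm, sub_grid.wavelengths_nm):
        basis = basis.resample(sub_grid.wavelengths_nm)

    h, w = cube.height, cube.width
    flat = att_win.reshape(h * w, -1)
    valid = cube.mask.ravel() & np.all(np.isfinite(flat), axis=1)

    sat = np.full(h * w, np.nan)
    if valid.any():
        coef, _ = _batched_fit(flat[valid], basis.matrix)
        total = coef[:, 0] + coef[:, 1]
        ok = total >= hb_floor
        s = np.full(valid.sum(), np.nan)
        s[ok] = coef[ok, 0] / total[ok]
        sat[valid] = s

    raw = Map2D(sat.reshape(h, w), np.isfinite(sat.reshape(h, w)))
    out = smooth_masked(raw, smooth_px)
    # saturation is a ratio of non-negative quantities: clamp numerical spill
    out.values[out.mask] = np.clip(out.values[out.mask], 0.0, 1.0)
    return out
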