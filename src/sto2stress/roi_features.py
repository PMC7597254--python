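"""Seven-ROI geometry, mean-StO2 summaries and delta features.

Seven regions of interest on the standard face carry the regional StO2
signal: ROI1 forehead, ROI2 right cheek, ROI3 nose, ROI4 left cheek,
ROI5 chin, ROI6 philtrum, ROI7 meixin (the inter-eyebrow / glabella
region).  Because every map is registered to the same canvas, each ROI
covers the identical pixel set — hence the identical area — for every
participant.

The classification feature is the per-ROI *delta* mean StO2: the mean over
the ROI under a stress condition minus the mean under that condition's own
baseline (removing individual differences).  The emotional-stress feature
row is ES − ES_baseline; the physical-stress row is PS1 − PS_baseline.
Delta scores for the recovery contrasts PS2 − PS1 and PS2 − PS_baseline
are provided for trend analysis.

ROI polygon vertices are configuration, not constants: the exact outlines
are not published, so the packaged default geometry is a qualitative
face layout (stored in fractional canvas coordinates so it scales to any
configured canvas) and any YAML polygon file can replace it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as _raster_polygon

from .hsi_core import Map2D

__all__ = [
    "ROI_NAMES",
    "CONDITIONS",
    "ROIGeometry",
    "default_geometry",
    "mean_sto2",
    "build_feature_table",
    "delta_scores",
    "roi_boxplot_stats",
]

logger = logging.getLogger(__name__)

ROI_NAMES = {
    "ROI1": "forehead",
    "ROI2": "right_cheek",
    "ROI3": "nose",
    "ROI4": "left_cheek",
    "ROI5": "chin",
    "ROI6": "philtrum",
    "ROI7": "meixin",
}

#: acquisition conditions per participant
CONDITIONS = ("ES_baseline", "ES", "PS_baseline", "PS1", "PS2")

#: contrasts reported by :func:`delta_scores`
CONTRASTS = ("ES-ES_baseline", "PS1-PS_baseline", "PS2-PS1", "PS2-PS_baseline")

#: minimum fraction of valid ROI pixels for a usable mean
VALID_FRACTION = 0.5

# default ROI rectangles in fractional canvas coordinates
# (x_lo, x_hi, y_lo, y_hi), x = fraction of width, y = fraction of height
_DEFAULT_FRACTIONS = {
    "ROI1": (0.300, 0.700, 0.109, 0.215),   # forehead band
    "ROI2": (0.252, 0.388, 0.500, 0.660),   # right cheek (image-left)
    "ROI3": (0.460, 0.540, 0.400, 0.570),   # nose
    "ROI4": (0.612, 0.748, 0.500, 0.660),   # left cheek (image-right)
    "ROI5": (0.428, 0.572, 0.830, 0.925),   # chin
    "ROI6": (0.472, 0.528, 0.615, 0.700),   # philtrum
    "ROI7": (0.452, 0.548, 0.230, 0.320),   # meixin (between eyebrows)
}


@dataclass
class ROIGeometry:
    """Named polygon regions in standard-face pixel coordinates.

    ``polygons`` maps ROI key -> (n, 2) array of (x, y) vertices on the
    ``canvas_shape`` (rows, cols) canvas.  Regions must be non-empty,
    pairwise disjoint and inside the canvas.
    """

    polygons: dict[str, np.ndarray]
    canvas_shape: tuple[int, int]
    _masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.polygons = {
            k: np.asarray(v, dtype=float) for k, v in self.polygons.items()
        }
        occupancy = np.zeros(self.canvas_shape, dtype=np.uint8)
        for name in self.polygons:
            m = self.mask(name)
            if not m.any():
                raise ValueError(f"{name}: empty region")
            occupancy += m
        if occupancy.max() > 1:
            raise ValueError("ROI polygons overlap")

    @property
    def names(self) -> list[str]:
        return list(self.polygons)

    def mask(self, name: str) -> np.ndarray:
        """Boolean raster of one ROI (cached)."""
        if name not in self.polygons:
            raise KeyError(f"unknown ROI {name!r}; have {list(self.polygons)}")
        if name not in self._masks:
            verts = self.polygons[name]
            h, w = self.canvas_shape
            if (verts[:, 0].min() < 0 or verts[:, 0].max() > w
                    or verts[:, 1].min() < 0 or verts[:, 1].max() > h):
                raise ValueError(f"{name}: vertices outside canvas {self.canvas_shape}")
            rr, cc = _raster_polygon(verts[:, 1], verts[:, 0], shape=self.canvas_shape)
            m = np.zeros(self.canvas_shape, dtype=bool)
            m[rr, cc] = True
            self._masks[name] = m
        return self._masks[name]

    def area_px(self, name: str) -> int:
        return int(self.mask(name).sum())

    def scaled_to(self, canvas_shape: tuple[int, int]) -> "ROIGeometry":
        """Same fractional layout on a different canvas."""
        h0, w0 = self.canvas_shape
        h1, w1 = canvas_shape
        scale = np.array([w1 / w0, h1 / h0])
        return ROIGeometry(
            {k: v * scale for k, v in self.polygons.items()}, (h1, w1)
        )

    # -- YAML config interface ------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "canvas_shape": list(self.canvas_shape),
            "rois": {
                k: {
                    "name": ROI_NAMES.get(k, k),
                    "vertices_xy": np.asarray(v).tolist(),
                }
                for k, v in self.polygons.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ROIGeometry":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            {k: np.array(v["vertices_xy"]) for k, v in doc["rois"].items()},
            tuple(doc["canvas_shape"]),
        )


def default_geometry(canvas_shape: tuple[int, int] = (513, 911)) -> ROIGeometry:
    """Packaged seven-ROI layout, scaled to ``canvas_shape``."""
    h, w = canvas_shape
    polys = {}
    for key, (x0, x1, y0, y1) in _DEFAULT_FRACTIONS.items():
        polys[key] = np.array([
            [x0 * w, y0 * h], [x1 * w, y0 * h], [x1 * w, y1 * h], [x0 * w, y1 * h],
        ])
    return ROIGeometry(polys, canvas_shape)


def mean_sto2(map2d: Map2D, geometry: ROIGeometry, roi: str) -> float:
    """Mask-aware mean StO2 over one ROI.

    NaN when fewer than 50% of the ROI's pixels are valid (robustness to
    warp-edge masking: a half-masked region still yields an unbiased mean,
    a mostly-masked one does not).
    """
    m = geometry.mask(roi)
    if map2d.shape != geometry.canvas_shape:
        raise ValueError(
            f"map shape {map2d.shape} != geometry canvas {geometry.canvas_shape}"
        )
    valid = m & map2d.mask
    if valid.sum() < VALID_FRACTION * m.sum():
        return float("nan")
    return float(map2d.values[valid].mean())


def _roi_means(map2d: Map2D, geometry: ROIGeometry) -> dict[str, float]:
    return {roi: mean_sto2(map2d, geometry, roi) for roi in geometry.names}


CohortMaps = dict[str, dict[str, Map2D]]  # participant -> condition -> map


def build_feature_table(cohort: CohortMaps, geometry: ROIGeometry) -> pd.DataFrame:
    """Per-participant delta features for classification.

    Two rows per participant: the ES row holds (ES − ES_baseline) per-ROI
    delta means, the PS row (PS1 − PS_baseline).  Participants missing any
    of the five conditions are excluded with a logged warning, keeping the
    table balanced.

    Returns a DataFrame with columns ``participant, stress`` plus one
    column per ROI key.
    """
    rows = []
    for pid in sorted(cohort):
        maps = cohort[pid]
        missing = [c for c in CONDITIONS if c not in maps]
        if missing:
            logger.warning("participant %s missing conditions %s; excluded",
                           pid, missing)
            continue
        means = {c: _roi_means(maps[c], geometry) for c in CONDITIONS}
        for label, stress_cond, base_cond in (
            ("ES", "ES", "ES_baseline"), ("PS", "PS1", "PS_baseline"),
        ):
            row = {"participant": pid, "stress": label}
            for roi in geometry.names:
                row[roi] = means[stress_cond][roi] - means[base_cond][roi]
            rows.append(row)
    return pd.DataFrame(rows, columns=["participant", "stress", *geometry.names])


def delta_scores(cohort: CohortMaps, geometry: ROIGeometry) -> pd.DataFrame:
    """Signed delta scores for all four contrasts per participant x ROI.

    Long-format DataFrame with columns ``participant, roi, contrast,
    delta``.  The recovery contrasts satisfy the algebraic identity
    (PS1 − PS_base) + (PS2 − PS1) = PS2 − PS_base.
    """
    rows = []
    for pid in sorted(cohort):
        maps = cohort[pid]
        if any(c not in maps for c in CONDITIONS):
            logger.warning("participant %s incomplete; excluded from delta scores", pid)
            continue
        means = {c: _roi_means(maps[c], geometry) for c in CONDITIONS}
        pairs = {
            "ES-ES_baseline": ("ES", "ES_baseline"),
            "PS1-PS_baseline": ("PS1", "PS_baseline"),
            "PS2-PS1": ("PS2", "PS1"),
            "PS2-PS_baseline": ("PS2", "PS_baseline"),
        }
        for contrast, (a, b) in pairs.items():
            for roi in geometry.names:
                rows.append({
                    "participant": pid, "roi": roi, "contrast": contrast,
                    "delta": means[a][roi] - means[b][roi],
                })
    return pd.DataFrame(rows, columns=["participant", "roi", "contrast", "delta"])


def fraction_below_zero(scores: pd.DataFrame, contrast: str) -> float:
    """Fraction of participants whose face-average delta is negative.

    The per-participant summary averages the contrast over all ROIs; a
    participant counts as "below baseline" when that average is < 0.
    """
    sub = scores[scores["contrast"] == contrast]
    if sub.empty:
        raise ValueError(f"no rows for contrast {contrast!r}")
    per_part = sub.groupby("participant")["delta"].mean()
    return float((per_part < 0).mean())


def roi_boxplot_stats(values: np.ndarray | pd.Series) -> dict[str, float]:
    """Five-number summary (min, q1, median, q3, max) of a per-ROI vector.

    Quartiles use linear interpolation (the inclusive convention).
    Requires at least 5 values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError(f"need >= 5 values for a boxplot summary, got {v.size}")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "min": float(v.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(v.max()),
    }
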