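"""Landmark-based quartic polynomial registration onto a standard face.

Every raw facial StO2 map is warped onto a fixed "standard face" canvas
(513 rows x 911 columns by default) so that facial regions become
pixel-comparable across participants.  The correspondence is given by 65
facial key points per image; the transform is a full fourth-order bivariate
polynomial (all 15 monomials ``x^i y^j`` with ``i + j <= 4``) fitted per
output coordinate by least squares.

Conventions
-----------
* Points are (x, y) = (column, row), 0-based internally; landmark files may
  be 1-based and are converted at the I/O boundary.
* The warp is fitted as a *backward* mapping (standard canvas -> source
  image) and applied by bilinear resampling, which leaves no holes.
* Monomials are evaluated in coordinates centred and scaled to the canvas
  half-extent: raw quartic terms over hundreds of pixels are severely
  ill-conditioned.
* No mirror flip is applied anywhere: image-left is the participant's
  right side (ROI2 = right cheek, ROI4 = left cheek).
* Ear regions are not covered by the 65 key points; values warped into ear
  areas do not represent real ear StO2 and are excluded from every ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hsi_core import Map2D

__all__ = [
    "N_LANDMARKS",
    "LandmarkSet",
    "PolynomialWarp",
    "StandardFace",
    "fit_warp",
    "apply_warp",
    "read_landmarks",
    "write_landmarks",
    "standard_landmarks",
]

N_LANDMARKS = 65
#: default standard-face canvas (rows, cols)
STANDARD_SHAPE = (513, 911)
POLY_DEGREE = 4
N_MONOMIALS = 15  # monomials x^i y^j with i+j <= 4


@dataclass(frozen=True)
class LandmarkSet:
    """65 ordered facial key points, (x, y) image coordinates, 0-based."""

    points: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"landmark set must be {N_LANDMARKS} x 2, got {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


class ConditioningError(np.linalg.LinAlgError):
    """The landmark configuration cannot support a stable quartic fit."""


def _monomial_exponents() -> list[tuple[int, int]]:
    return [(i, j) for total in range(POLY_DEGREE + 1)
            for i in range(total + 1) for j in (total - i,)]


_EXPONENTS = _monomial_exponents()
assert len(_EXPONENTS) == N_MONOMIALS


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cols = [x ** i * y ** j for i, j in _EXPONENTS]
    return np.column_stack(cols)


@dataclass(frozen=True)
class PolynomialWarp:
    """Fitted quartic backward mapping: canvas (x, y) -> source (x, y).

    ``coef_x`` / ``coef_y`` are the 15 monomial coefficients for each
    output coordinate, in normalised canvas coordinates; per-landmark fit
    residuals (px) are retained for diagnostics, never discarded.
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    center: np.ndarray     # (x0, y0) normalisation centre
    half_extent: np.ndarray  # (hx, hy) normalisation scale
    residuals_px: np.ndarray

    def __post_init__(self) -> None:
        for name in ("coef_x", "coef_y"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (N_MONOMIALS,):
                raise ValueError(f"{name} must have length {N_MONOMIALS}")
            object.__setattr__(self, name, c)

    def _normalise(self, x: np.ndarray, y: np.ndarray):
        return ((x - self.center[0]) / self.half_extent[0],
                (y - self.center[1]) / self.half_extent[1])

    def __call__(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map canvas coordinates to source coordinates."""
        xn, yn = self._normalise(np.asarray(x, float), np.asarray(y, float))
        shape = xn.shape
        M = _design_matrix(xn.ravel(), yn.ravel())
        return (M @ self.coef_x).reshape(shape), (M @ self.coef_y).reshape(shape)

    @property
    def rms_residual_px(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_px ** 2)))


@dataclass(frozen=True)
class StandardFace:
    """Standard-face canvas plus its reference landmark set.

    The published standard face is an average of 100 aligned faces and is
    not reconstructible from printed material; the packaged reference
    (:func:`standard_landmarks`) is a synthetic face-shaped layout on the
    same 513 x 911 canvas.  A user-supplied canvas/landmarks pair is
    accepted anywhere a ``StandardFace`` is.
    """

    shape: tuple[int, int] = STANDARD_SHAPE
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if self.landmarks is None:
            object.__setattr__(self, "landmarks", standard_landmarks(self.shape))
        pts = self.landmarks.points
        h, w = self.shape
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > w - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > h - 1):
            raise ValueError("reference landmarks fall outside the canvas")


def standard_landmarks(shape: tuple[int, int] = STANDARD_SHAPE) -> LandmarkSet:
    """Synthetic 65-point reference layout on the standard canvas.

    Deterministic, parametric face: 17 jaw-contour points, 5 hairline
    points, 2 x 5 eyebrow points, 9 nose points, 2 x 6 eye points, 12
    mouth points — 65 total, ears excluded.  Proportioned to the canvas so the layout scales to any
    configured shape.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    fw, fh = 0.40 * w, 0.46 * h  # face half-extents

    pts: list[tuple[float, float]] = []
    # jaw contour: lower half-ellipse, ear-to-ear (17)
    for t in np.linspace(np.pi, 2 * np.pi, 17):
        pts.append((cx + fw * np.cos(t), cy - fh * np.sin(t)))
    # hairline: upper arc (5)
    for t in np.linspace(0.25 * np.pi, 0.75 * np.pi, 5):
        pts.append((cx + fw * np.cos(t), cy - fh * np.sin(t)))
    # eyebrows: two arcs of 5 (10)
    for side in (-1, 1):
        for u in np.linspace(-1, 1, 5):
            pts.append((cx + side * (0.45 + 0.20 * u) * fw,
                        cy - 0.52 * fh - 0.06 * fh * (1 - u ** 2)))
    # nose: bridge (4) + base (5) (9)
    for v in np.linspace(-0.35, 0.15, 4):
        pts.append((cx, cy + v * fh))
    for u in np.linspace(-1, 1, 5):
        pts.append((cx + 0.16 * u * fw, cy + 0.22 * fh + 0.04 * fh * (1 - u ** 2)))
    # eyes: two hexagons of 6 (12)
    for side in (-1, 1):
        ex, ey = cx + side * 0.42 * fw, cy - 0.30 * fh
        for t in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            pts.append((ex + 0.13 * fw * np.cos(t), ey + 0.06 * fh * np.sin(t)))
    # mouth: outer ellipse of 12 (12)
    for t in np.linspace(0, 2 * np.pi, 12, endpoint=False):
        pts.append((cx + 0.26 * fw * np.cos(t), cy + 0.55 * fh + 0.10 * fh * np.sin(t)))

    pts_arr = np.array(pts)
    assert pts_arr.shape == (N_LANDMARKS, 2)
    pts_arr[:, 0] = np.clip(pts_arr[:, 0], 0, w - 1)
    pts_arr[:, 1] = np.clip(pts_arr[:, 1], 0, h - 1)
    return LandmarkSet(pts_arr, frame_id="standard")


def fit_warp(source: LandmarkSet, target: LandmarkSet) -> PolynomialWarp:
    """Fit the quartic backward mapping target -> source.

    ``source`` are landmarks in the raw image, ``target`` the corresponding
    reference landmarks on the standard canvas, in matching order.  The
    65 x 15 design matrix (per axis) is solved in least squares in centred,
    scaled target coordinates.  Raises :class:`ConditioningError` for
    degenerate (e.g. collinear) configurations.
    """
    tx, ty = target.x, target.y
    center = np.array([tx.mean(), ty.mean()])
    half = np.array([
        max(np.abs(tx - center[0]).max(), 1.0),
        max(np.abs(ty - center[1]).max(), 1.0),
    ])
    M = _design_matrix((tx - center[0]) / half[0], (ty - center[1]) / half[1])
    rank = np.linalg.matrix_rank(M)
    if rank < N_MONOMIALS:
        raise ConditioningError(
            f"degenerate landmark configuration: design rank {rank} < {N_MONOMIALS}"
        )
    coef_x, *_ = np.linalg.lstsq(M, source.x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(M, source.y, rcond=None)
    pred = np.column_stack([M @ coef_x, M @ coef_y])
    residuals = np.linalg.norm(pred - source.points, axis=1)
    return PolynomialWarp(coef_x, coef_y, center, half, residuals)


def apply_warp(
    map2d: Map2D, warp: PolynomialWarp, face: StandardFace | None = None
) -> Map2D:
    """Resample a raw map onto the standard canvas through a fitted warp.

    For every canvas pixel the warp gives a source position; values are
    bilinearly interpolated.  A canvas pixel is valid only if all four
    source neighbours are valid and inside the image (mask conservation:
    no valid output originates from invalid input).
    """
    if face is None:
        face = StandardFace()
    h, w = face.shape
    yy, xx = np.mgrid[0:h, 0:w]
    sx, sy = warp(xx.astype(float), yy.astype(float))

    src_vals = np.where(map2d.mask, map2d.values, 0.0)
    coords = np.stack([sy.ravel(), sx.ravel()])
    vals = ndimage.map_coordinates(
        src_vals, coords, order=1, mode="constant", cval=0.0
    ).reshape(h, w)
    wgt = ndimage.map_coordinates(
        map2d.mask.astype(float), coords, order=1, mode="constant", cval=0.0
    ).reshape(h, w)
    inside = (
        (sx >= 0) & (sx <= map2d.shape[1] - 1)
        & (sy >= 0) & (sy <= map2d.shape[0] - 1)
    )
    out_mask = inside & (wgt >= 1.0 - 1e-12)
    out_vals = np.full((h, w), np.nan)
    out_vals[out_mask] = vals[out_mask]
    return Map2D(out_vals, out_mask)


# ---------------------------------------------------------------------------
# Landmark file I/O (CSV/PTS-style text: 65 rows of x,y)

def read_landmarks(
    path: str | Path, one_based: bool = False, yx_order: bool = False,
    frame_id: str | None = None,
) -> LandmarkSet:
    """Read a 65-row x,y landmark text file.

    ``one_based`` subtracts 1 from both coordinates (files exported from
    1-based tools); ``yx_order`` swaps columns for files stored row,col.
    """
    path = Path(path)
    pts = np.loadtxt(path, delimiter=",", comments="#")
    if pts.shape != (N_LANDMARKS, 2):
        raise ValueError(f"{path}: expected {N_LANDMARKS} x 2 landmarks, got {pts.shape}")
    if yx_order:
        pts = pts[:, ::-1]
    if one_based:
        pts = pts - 1.0
    return LandmarkSet(pts, frame_id=frame_id or path.stem)


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    np.savetxt(path, lm.points, delimiter=",", fmt="%.6f", header="x,y")
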