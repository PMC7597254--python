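"""Hyperspectral cube data model, I/O and attenuation computation.

A hyperspectral reflectance acquisition is a 3D cube indexed
``(row, col, band)`` with a strictly increasing wavelength axis in
nanometres.  Reflectance is dimensionless in ``(0, 1]`` relative to a white
standard; pixels where reflectance is non-positive (shadow, saturation,
dead sensor elements) are carried in an explicit validity mask and
propagate as invalid through every derived map — they are never silently
zeroed, which would bias downstream region statistics.

Attenuation (optical density) is computed as ``A(lambda) =
-log10(R / R_ref)`` against an explicit per-band reference spectrum; base-10
is the optical-density convention and any base change is absorbed into
fitted chromophore coefficients.

Two on-disk formats are supported: a self-describing NumPy ``.npz``
container (native, bit-exact round trip) and ENVI header + band-sequential
raw (interchange with hyperspectral toolboxes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HSICube",
    "Map2D",
    "read_cube",
    "write_cube",
    "attenuation",
    "select_band_window",
]

#: wavelength range (nm) expected of conformant acquisitions
WAVELENGTH_RANGE_NM = (380.0, 800.0)


class FormatError(ValueError):
    """A file is missing required metadata or is structurally malformed."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths, in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1D array")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def window_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of bands with ``lo_nm <= lambda <= hi_nm`` (order kept)."""
        if lo_nm >= hi_nm:
            raise ValueError(f"empty window: lo={lo_nm} >= hi={hi_nm}")
        idx = np.nonzero(
            (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        )[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{lo_nm}, {hi_nm}] nm does not overlap grid "
                f"[{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}] nm"
            )
        return idx


@dataclass
class HSICube:
    """Reflectance cube ``data[row, col, band]`` with wavelength grid.

    ``mask`` flags valid pixels (spatially; a pixel is valid only if its
    whole spectrum is usable).  On construction, pixels with any
    non-positive reflectance are marked invalid.
    """

    data: np.ndarray
    grid: WavelengthGrid
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3D (row, col, band)")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"band count {self.data.shape[2]} != grid length {len(self.grid)}"
            )
        positive = np.all(self.data > 0, axis=2)
        if self.mask is None:
            self.mask = positive
        else:
            self.mask = np.asarray(self.mask, dtype=bool) & positive
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match spatial shape")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class Map2D:
    """Scalar image with a per-pixel validity mask.

    Statistics over a ``Map2D`` must always be taken over ``mask``-valid
    pixels only; values at invalid pixels are unspecified.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Map2D values must be 2D")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_mean(self) -> float:
        if not self.mask.any():
            return float("nan")
        return float(self.values[self.mask].mean())

    def to_csv(self, path: str | Path) -> None:
        """Export values as CSV; invalid pixels written as empty fields."""
        out = self.values.astype(object)
        out[~self.mask] = ""
        np.savetxt(path, out, delimiter=",", fmt="%s")

    def to_png(self, path: str | Path, cmap: str = "jet",
               vmin: float = 0.0, vmax: float = 1.0) -> None:
        """8-bit colour-mapped export; invalid pixels rendered black."""
        import matplotlib as mpl
        import imageio.v3 as iio

        norm = np.clip((self.values - vmin) / (vmax - vmin), 0.0, 1.0)
        rgba = mpl.colormaps[cmap](norm)
        rgba[~self.mask] = (0.0, 0.0, 0.0, 1.0)
        iio.imwrite(Path(path), (rgba[..., :3] * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# I/O

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64,
                12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` lines of an ENVI .hdr."""
    fields: dict[str, str] = {}
    # brace-delimited values may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> HSICube:
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks wavelength metadata")
    wl = np.array(
        [float(x) for x in fields["wavelength"].strip("{} ").split(",") if x.strip()]
    )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"only BSQ interleave supported, got {interleave!r}")
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        raise FormatError(f"ENVI raw file not found: {raw_path}")
    raw = np.fromfile(raw_path, dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != samples * lines * bands:
        raise FormatError("ENVI raw size inconsistent with header dimensions")
    data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    try:
        grid = WavelengthGrid(wl)
    except ValueError as exc:
        raise FormatError(f"invalid wavelength metadata: {exc}") from exc
    return HSICube(data=data, grid=grid)


def _write_envi(cube: HSICube, path: Path, dtype=np.float32) -> None:
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    raw_path = hdr_path.with_suffix(".raw")
    wl = ", ".join(f"{w:.17g}" for w in cube.grid.wavelengths_nm)
    hdr = (
        "ENVI\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    cube.data.transpose(2, 0, 1).astype(dtype).tofile(raw_path)


def read_cube(path: str | Path, format: str | None = None) -> HSICube:
    """Read a hyperspectral cube from disk.

    Parameters
    ----------
    path
        File path (``.npz`` native container, or ENVI ``.hdr``/``.raw``).
    format
        ``"envi"`` or ``"npz"``; inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "envi" if path.suffix in (".hdr", ".raw") else "npz"
    if format == "envi":
        return _read_envi(path)
    if format == "npz":
        with np.load(path) as npz:
            if "wavelengths_nm" not in npz:
                raise FormatError("container lacks wavelength metadata")
            try:
                grid = WavelengthGrid(npz["wavelengths_nm"])
            except ValueError as exc:
                raise FormatError(str(exc)) from exc
            mask = npz["mask"] if "mask" in npz else None
            return HSICube(data=npz["data"], grid=grid, mask=mask)
    raise ValueError(f"unknown format {format!r}")


def write_cube(cube: HSICube, path: str | Path, format: str | None = None) -> None:
    """Write a cube (``.npz`` native, bit-exact; or ENVI float32)."""
    path = Path(path)
    if format is None:
        format = "envi" if path.suffix in (".hdr", ".raw") else "npz"
    if format == "envi":
        _write_envi(cube, path)
    elif format == "npz":
        np.savez_compressed(
            path, data=cube.data, wavelengths_nm=cube.grid.wavelengths_nm,
            mask=cube.mask,
        )
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Spectral computations

def attenuation(cube: HSICube, reference: np.ndarray) -> np.ndarray:
    """Per-pixel optical density against a white-standard spectrum.

    ``A(lambda) = -log10(R(lambda) / R_ref(lambda))``.  Entries where the
    reflectance is non-positive are NaN; the cube's mask already excludes
    such pixels.

    Parameters
    ----------
    cube
        Reflectance cube.
    reference
        Strictly positive per-band reference spectrum, same band count.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (cube.n_bands,):
        raise ValueError(
            f"reference has {reference.shape} entries, cube has {cube.n_bands} bands"
        )
    if np.any(reference <= 0):
        raise ValueError("reference spectrum must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        att = -np.log10(cube.data / reference)
    att[cube.data <= 0] = np.nan
    return att


def select_band_window(
    array: np.ndarray, grid: WavelengthGrid, lo_nm: float, hi_nm: float
) -> tuple[np.ndarray, WavelengthGrid]:
    """Restrict a cube/attenuation array to bands in ``[lo_nm, hi_nm]``.

    The band axis is the last axis.  Bands are selected, never reordered or
    interpolated.  Returns the restricted array and its sub-grid.
    """
    idx = grid.window_indices(lo_nm, hi_nm)
    sub = np.asarray(array)[..., idx]
    return sub, WavelengthGrid(grid.wavelengths_nm[idx])
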