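"""Hypercube containers, reflectance calibration, ROI segmentation.

Calibration follows the standard white/dark normalisation

    R = (R_raw - R_dark) / (R_white - R_dark)

applied element-wise, after which the fruit region is isolated on the
super-red image 2R - G - B (red fruit scores high, the spectrally flat
background scores ~0) and the sample spectrum is the per-band mean over
the masked pixels.  Cubes round-trip through either an ENVI-style
header + BSQ binary pair or a compressed .npz container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import CalibrationError, FormatError, SegmentationError


@dataclass
class Hypercube:
    """rows x cols x bands array with its wavelength vector.

    kind is "raw" (camera counts) or "reflectance" (calibrated).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"bands dimension {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ReferenceFrames:
    """White and dark reference cubes matching the raw cube's shape."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share a shape")


@dataclass
class Mask:
    """Boolean fruit-pixel mask."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


def calibrate(raw: Hypercube, refs: ReferenceFrames) -> Hypercube:
    """White/dark reflectance calibration: (raw - dark)/(white - dark)."""
    if raw.kind != "raw":
        raise ValueError("calibrate expects a raw-counts cube")
    if refs.white.shape != raw.data.shape:
        raise ValueError(
            f"reference shape {refs.white.shape} != cube shape {raw.data.shape}"
        )
    denom = refs.white - refs.dark
    bad = denom == 0
    if bad.any():
        where = tuple(int(v) for v in np.argwhere(bad)[0])
        raise CalibrationError(f"white == dark at element {where}")
    return Hypercube(
        (raw.data - refs.dark) / denom, raw.wavelengths, kind="reflectance"
    )


def crop_bands(cube: Hypercube, lo: float, hi: float) -> Hypercube:
    """Keep bands with lo <= wavelength <= hi (both ends inclusive)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise ValueError(f"no bands inside [{lo}, {hi}] nm")
    return Hypercube(cube.data[:, :, keep], cube.wavelengths[keep], cube.kind)


def nearest_band(wavelengths: np.ndarray, target: float) -> int:
    """Index of the grid band nearest to target nm (ties -> lower band)."""
    return int(np.argmin(np.abs(np.asarray(wavelengths) - target)))


def segment_superred(
    cube: Hypercube,
    rgb_wavelengths: tuple[float, float, float] = (691.0, 531.0, 457.0),
    threshold: float | str = "otsu",
) -> Mask:
    """Fruit mask from the super-red score 2R - G - B.

    R, G, B are the band images nearest the requested wavelengths.  The
    score is thresholded (Otsu by default) and the largest 4-connected
    component is kept, dropping background specks.
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_superred expects a calibrated cube")
    r, g, b = (nearest_band(cube.wavelengths, w) for w in rgb_wavelengths)
    score = 2.0 * cube.data[:, :, r] - cube.data[:, :, g] - cube.data[:, :, b]
    if threshold == "otsu":
        if np.ptp(score) == 0:
            raise SegmentationError("constant super-red score; nothing to segment")
        t = float(threshold_otsu(score))
    else:
        t = float(threshold)
    binary = score > t
    if not binary.any():
        raise SegmentationError(f"no pixel above super-red threshold {t}")
    labels, n = ndimage.label(binary)  # default structure = 4-connectivity
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    return Mask(labels == (1 + int(np.argmax(sizes))))


def mean_spectrum(cube: Hypercube, mask: Mask) -> np.ndarray:
    """Per-band arithmetic mean over the masked pixels."""
    if mask.pixel_count == 0:
        raise ValueError("mask is empty")
    if mask.values.shape != cube.data.shape[:2]:
        raise ValueError("mask shape does not match cube")
    return cube.data[mask.values].mean(axis=0)


# ---------------------------------------------------------------------------
# On-disk formats: ENVI header + BSQ binary, or compressed .npz container.

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_cube(cube: Hypercube, path: str | Path) -> Path:
    """Write a cube; '.npz' -> compressed container, '.hdr' -> ENVI+BSQ
    (binary goes to the same stem with suffix '.img')."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, data=cube.data, wavelengths=cube.wavelengths,
            kind=np.array(cube.kind),
        )
        return path
    if path.suffix != ".hdr":
        raise FormatError(f"unsupported cube extension {path.suffix!r}")
    data = np.ascontiguousarray(cube.data)
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    wl_list = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[data.dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl_list} }}\n"
    )
    # BSQ: band-sequential, each band stored as a full rows x cols plane.
    data.transpose(2, 0, 1).tofile(path.with_suffix(".img"))
    return path


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{"):
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ").strip()
        fields[key.strip().lower()] = value
    return fields


def read_cube(path: str | Path) -> tuple[Hypercube, ReferenceFrames | None]:
    """Read a cube written by write_cube (or a scene container written by
    synthetic.save_scene, in which case the reference frames come back)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            if "raw_cube" in z:  # a synthetic scene container
                cube = Hypercube(z["raw_cube"], z["wavelengths"], kind="raw")
                refs = ReferenceFrames(z["white_frame"], z["dark_frame"])
                return cube, refs
            if "data" not in z or "wavelengths" not in z:
                raise FormatError(f"{path.name}: missing data/wavelengths arrays")
            kind = str(z["kind"]) if "kind" in z else "raw"
            return Hypercube(z["data"], z["wavelengths"], kind=kind), None
    if path.suffix != ".hdr":
        raise FormatError(f"unsupported cube extension {path.suffix!r}")
    fields = _parse_envi_header(path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as e:
        raise FormatError(f"{path.name}: missing header field {e}") from e
    if "wavelength" not in fields:
        raise FormatError(f"{path.name}: header has no wavelength list")
    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].split(",") if v.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"{path.name}: {wavelengths.size} wavelengths for {bands} bands"
        )
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError("only BSQ interleave is supported")
    dtype = _ENVI_DTYPES.get(dtype_code)
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    flat = np.fromfile(path.with_suffix(".img"), dtype=dtype)
    if flat.size != rows * cols * bands:
        raise FormatError(
            f"{path.name}: binary holds {flat.size} values, header implies "
            f"{rows * cols * bands}"
        )
    data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    kind = fields.get("cube kind", "raw")
    return Hypercube(data, wavelengths, kind=kind), None


def write_mask_png(mask: Mask, path: str | Path) -> Path:
    """Save a mask as an 8-bit 0/255 PNG for visual inspection."""
    path = Path(path)
    Image.fromarray((mask.values.astype(np.uint8)) * 255, mode="L").save(path)
    return path


def read_mask_png(path: str | Path) -> Mask:
    return Mask(np.asarray(Image.open(path)) > 127)
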