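"""Color-moment and texture features of the fruit ROI, and feature fusion.

Three feature blocks feed the regression models:

* spectral — the ROI-mean reflectance spectrum (one column per band);
* color — first three moments (mean, population SD, signed cube root of
  the third central moment) of the red/green/blue band images (691, 531,
  457 nm) over the ROI: 9 features;
* texture — for each of two quality-linked wavelengths, 15 gray
  level-gradient co-occurrence matrix (GLGCM) statistics plus 3 Gabor
  statistics: 36 features.

GLGCM statistic definitions (the 15-feature contract, with p(i,j) the
normalised joint histogram of quantised gray level i and gradient level j,
marginals p_i, p_j, means/SDs mu/sigma of the marginals):

 1. small grads dominance   sum p(i,j)/(j+1)^2
 2. big grads dominance     sum p(i,j)*j^2
 3. gray asymmetry          sum_i p_i(i)^2
 4. grads asymmetry         sum_j p_j(j)^2
 5. energy                  sum p(i,j)^2
 6. gray mean               mu_i
 7. grads mean              mu_j
 8. gray variance           sigma_i^2
 9. grads variance          sigma_j^2
10. correlation             sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
                            (0 when either sigma is 0)
11. gray entropy            -sum p_i ln p_i
12. grads entropy           -sum p_j ln p_j
13. entropy                 -sum p ln p
14. inertia                 sum (i-j)^2 p(i,j)
15. homogeneity             sum p(i,j)/(1+(i-j)^2)

with 0*ln 0 = 0 throughout.  Levels are 0-indexed after max-scaling
quantisation x -> round(x*(L-1)/max) (all zero when max == 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gabor_kernel

from .errors import AlignmentError
from .hsi_io import Hypercube, Mask, nearest_band
from .preprocessing import SpectraTable

GLGCM_FEATURE_NAMES = (
    "small_grads_dominance",
    "big_grads_dominance",
    "gray_asymmetry",
    "grads_asymmetry",
    "energy",
    "gray_mean",
    "grads_mean",
    "gray_variance",
    "grads_variance",
    "correlation",
    "gray_entropy",
    "grads_entropy",
    "entropy",
    "inertia",
    "homogeneity",
)
GABOR_FEATURE_NAMES = ("gabor_mean", "gabor_contrast", "gabor_entropy")

RGB_WAVELENGTHS = (691.0, 531.0, 457.0)
# Quality-linked texture wavelength pairs (nm).
TEXTURE_BAND_PAIRS = {"ssc": (676.0, 910.0), "ph": (444.0, 842.0), "vc": (837.0, 891.0)}


@dataclass(frozen=True)
class GLGCMConfig:
    gray_levels: int = 16
    grad_levels: int = 16
    gradient_operator: str = "sobel"

    def __post_init__(self):
        if self.gray_levels < 2 or self.grad_levels < 2:
            raise ValueError("quantisation levels must be >= 2")
        if self.gradient_operator != "sobel":
            raise ValueError(f"unknown gradient operator {self.gradient_operator!r}")


@dataclass
class FeatureTable:
    """samples x features matrix with per-feature names and block tags."""

    F: np.ndarray
    names: list[str]
    blocks: list[str]
    ids: list[str]

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be samples x features")
        if not (self.F.shape[1] == len(self.names) == len(self.blocks)):
            raise ValueError("names/blocks must align with columns")
        if self.F.shape[0] != len(self.ids):
            raise ValueError("row count != id count")

    def block_columns(self, block: str) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.blocks) if b == block])

    def to_csv(self, path) -> None:
        import pandas as pd

        header = pd.MultiIndex.from_arrays([self.blocks, self.names])
        pd.DataFrame(self.F, index=self.ids, columns=header).to_csv(path)


def _masked_moments(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(values.mean())
    centered = values - mean
    sd = float(np.sqrt(np.mean(centered**2)))
    m3 = float(np.mean(centered**3))
    return mean, sd, float(np.cbrt(m3))


def color_moments(
    cube: Hypercube,
    mask: Mask,
    rgb_wavelengths: tuple[float, float, float] = RGB_WAVELENGTHS,
) -> np.ndarray:
    """9 color features: (mean, SD, skew-root) per R/G/B band image."""
    if mask.pixel_count == 0:
        raise ValueError("mask is empty")
    out = []
    for w in rgb_wavelengths:
        channel = cube.data[:, :, nearest_band(cube.wavelengths, w)]
        out.extend(_masked_moments(channel[mask.values]))
    return np.array(out)


def _fill_background_nearest(crop: np.ndarray, mask_crop: np.ndarray) -> np.ndarray:
    """Replace background pixels with the nearest ROI pixel's value so the
    gradient operator sees no artificial fruit/background edge."""
    if mask_crop.all():
        return crop
    _, (ir, ic) = ndimage.distance_transform_edt(
        ~mask_crop, return_distances=True, return_indices=True
    )
    return crop[ir, ic]


def _quantise(values: np.ndarray, levels: int) -> np.ndarray:
    top = values.max()
    if top <= 0:
        return np.zeros(values.shape, dtype=int)
    q = np.rint(values * (levels - 1) / top).astype(int)
    return np.clip(q, 0, levels - 1)


def glgcm_joint_histogram(
    image: np.ndarray, mask: Mask, cfg: GLGCMConfig | None = None
) -> np.ndarray:
    """Normalised joint probability table p(gray i, grad j) over the ROI."""
    cfg = cfg or GLGCMConfig()
    mv = mask.values
    if not mv.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mv.any(axis=1))
    cols = np.flatnonzero(mv.any(axis=0))
    if rows.size < 3 or cols.size < 3:
        raise ValueError("mask bounding box must be at least 3x3")
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    crop = _fill_background_nearest(
        np.asarray(image, dtype=float)[sl], mv[sl]
    )
    gx = ndimage.sobel(crop, axis=0, mode="nearest")
    gy = ndimage.sobel(crop, axis=1, mode="nearest")
    grad = np.hypot(gx, gy)
    inside = mv[sl]
    qg = _quantise(crop, cfg.gray_levels)[inside]
    qs = _quantise(grad, cfg.grad_levels)[inside]
    hist = np.zeros((cfg.gray_levels, cfg.grad_levels))
    np.add.at(hist, (qg, qs), 1.0)
    return hist / hist.sum()


def glgcm_statistics(p: np.ndarray) -> np.ndarray:
    """The 15 GLGCM statistics (module docstring order) of a joint table."""
    i = np.arange(p.shape[0])[:, None]
    j = np.arange(p.shape[1])[None, :]
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((np.arange(p.shape[0]) * p_i).sum())
    mu_j = float((np.arange(p.shape[1]) * p_j).sum())
    var_i = float(((np.arange(p.shape[0]) - mu_i) ** 2 * p_i).sum())
    var_j = float(((np.arange(p.shape[1]) - mu_j) ** 2 * p_j).sum())
    sd_i, sd_j = math.sqrt(var_i), math.sqrt(var_j)
    if sd_i > 0 and sd_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j))
    else:
        corr = 0.0

    def _entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    return np.array(
        [
            float((p / (j + 1.0) ** 2).sum()),
            float((p * j**2).sum()),
            float((p_i**2).sum()),
            float((p_j**2).sum()),
            float((p**2).sum()),
            mu_i,
            mu_j,
            var_i,
            var_j,
            corr,
            _entropy(p_i),
            _entropy(p_j),
            _entropy(p),
            float(((i - j) ** 2 * p).sum()),
            float((p / (1.0 + (i - j) ** 2)).sum()),
        ]
    )


def glgcm_features(
    image: np.ndarray, mask: Mask, cfg: GLGCMConfig | None = None
) -> np.ndarray:
    """15 GLGCM texture statistics of one band image over the ROI."""
    return glgcm_statistics(glgcm_joint_histogram(image, mask, cfg))


def build_gabor_kernel(
    sigma_pair: tuple[float, float] = (2.0, 4.0),
    theta_deg: float = 60.0,
    frequency: float = 0.25,
) -> np.ndarray:
    """Complex Gabor kernel (envelope sigma_x=2, sigma_y=4 px, 60 deg,
    0.25 cycles/px by default), mean-subtracted so the DC gain is zero and
    flat regions produce no response."""
    k = gabor_kernel(
        frequency=frequency,
        theta=math.radians(theta_deg),
        sigma_x=sigma_pair[0],
        sigma_y=sigma_pair[1],
    )
    return k - k.mean()


def gabor_features(
    image: np.ndarray,
    mask: Mask,
    sigma_pair: tuple[float, float] = (2.0, 4.0),
    theta_deg: float = 60.0,
    frequency: float = 0.25,
    histogram_bins: int = 64,
) -> np.ndarray:
    """(mean, contrast, entropy) of the Gabor response magnitude over the ROI.

    Contrast is the population SD; entropy is Shannon entropy (nats) of the
    64-bin magnitude histogram.
    """
    image = np.asarray(image, dtype=float)
    kernel = build_gabor_kernel(sigma_pair, theta_deg, frequency)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"Gabor kernel {kernel.shape} larger than image {image.shape}"
        )
    if mask.pixel_count == 0:
        raise ValueError("mask is empty")
    real = ndimage.convolve(image, np.real(kernel), mode="nearest")
    imag = ndimage.convolve(image, np.imag(kernel), mode="nearest")
    magnitude = np.hypot(real, imag)[mask.values]
    mean = float(magnitude.mean())
    contrast = float(np.sqrt(np.mean((magnitude - mean) ** 2)))
    if magnitude.max() == magnitude.min():
        entropy = 0.0
    else:
        counts, _ = np.histogram(magnitude, bins=histogram_bins)
        q = counts[counts > 0] / counts.sum()
        entropy = float(-(q * np.log(q)).sum())
    return np.array([mean, contrast, entropy])


def texture_block(
    cube: Hypercube,
    mask: Mask,
    band_pair: tuple[float, float],
    cfg: GLGCMConfig | None = None,
    **gabor_kwargs,
) -> np.ndarray:
    """36 texture features: [GLGCM(l1) 15, Gabor(l1) 3, GLGCM(l2) 15,
    Gabor(l2) 3] at the two quality-linked wavelengths."""
    out = []
    for w in band_pair:
        band = cube.data[:, :, nearest_band(cube.wavelengths, w)]
        out.append(glgcm_features(band, mask, cfg))
        out.append(gabor_features(band, mask, **gabor_kwargs))
    return np.concatenate(out)


def texture_feature_names(band_pair: tuple[float, float]) -> list[str]:
    names = []
    for w in band_pair:
        names.extend(f"{n}_{w:g}nm" for n in GLGCM_FEATURE_NAMES)
        names.extend(f"{n}_{w:g}nm" for n in GABOR_FEATURE_NAMES)
    return names


def assemble_features(
    spectra: SpectraTable,
    color: "np.ndarray | FeatureTable | None" = None,
    texture: "np.ndarray | FeatureTable | None" = None,
    include: set[str] | tuple[str, ...] = ("spectral",),
    texture_band_pair: tuple[float, float] | None = None,
) -> FeatureTable:
    """Horizontally fuse the requested blocks (spectral, color, texture).

    color/texture may be plain arrays (rows aligned with spectra.ids) or
    FeatureTables, whose ids must then match exactly.
    """
    include = set(include)
    unknown = include - {"spectral", "color", "texture"}
    if unknown:
        raise ValueError(f"unknown blocks {sorted(unknown)}")
    mats: list[np.ndarray] = []
    names: list[str] = []
    blocks: list[str] = []

    def _coerce(block, label: str, expected_width: int | None) -> np.ndarray:
        if block is None:
            raise AlignmentError(f"{label} block requested but not supplied")
        if isinstance(block, FeatureTable):
            if block.ids != spectra.ids:
                raise AlignmentError(f"{label} block ids do not match spectra ids")
            arr = block.F
        else:
            arr = np.asarray(block, dtype=float)
        if arr.shape[0] != spectra.n_samples:
            raise AlignmentError(
                f"{label} block has {arr.shape[0]} rows, spectra {spectra.n_samples}"
            )
        if expected_width is not None and arr.shape[1] != expected_width:
            raise ValueError(
                f"{label} block must have {expected_width} columns, got {arr.shape[1]}"
            )
        return arr

    if "spectral" in include:
        mats.append(spectra.X)
        names.extend(f"{w:g}nm" for w in spectra.wavelengths)
        blocks.extend(["spectral"] * spectra.n_bands)
    if "color" in include:
        arr = _coerce(color, "color", 9)
        mats.append(arr)
        channel_names = [
            f"{ch}_{m}" for ch in "rgb" for m in ("mean", "sd", "skew")
        ]
        names.extend(channel_names)
        blocks.extend(["color"] * 9)
    if "texture" in include:
        arr = _coerce(texture, "texture", 36)
        mats.append(arr)
        if texture_band_pair is not None:
            names.extend(texture_feature_names(texture_band_pair))
        else:
            names.extend(f"texture_{k}" for k in range(36))
        blocks.extend(["texture"] * 36)
    if not mats:
        raise ValueError("no blocks requested")
    return FeatureTable(np.hstack(mats), names, blocks, list(spectra.ids))
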