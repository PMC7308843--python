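"""Synthetic hyperspectral strawberry scenes with known ground truth.

The real study material — hyperspectral reflectance images of 120
strawberries measured over five storage times, together with destructively
assayed soluble solid content (SSC, %), pH, and vitamin C (VC, g/kg) — is
not publicly deposited.  This module generates stand-in scenes with the
statistical structure the downstream analysis assumes, so that every stage
(reflectance calibration, ROI segmentation, pretreatment, feature
extraction, variable selection, regression, distribution maps) is testable
end to end with known truth.

The forward model is deliberately simple and *linear in the normalised
latent qualities*: reflectance is a fixed smooth baseline (low below
500 nm, high plateau at 750-950 nm) plus compactly supported absorption
dips near 680 nm (chlorophyll), 750 nm and 960 nm (water overtones) whose
depths, together with the NIR plateau height, move monotonically with
SSC/pH/VC.  SSC raises the 750-950 nm plateau; pH and VC lower it — the
trends reported for real strawberries.  A raw scene is then

    raw = dark + (white - dark) * (a + b * reflectance) + noise

inside the fruit mask, i.e. exactly the distortion that white/dark
calibration and multiplicative scatter correction are designed to undo.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BerrySpecError

# Observed ranges of the 120-fruit reference assays (calibration+prediction
# pooled); the generator never leaves them.
SSC_RANGE = (3.4, 8.4)
PH_RANGE = (2.68, 3.33)
VC_RANGE = (0.4745, 0.8421)

# Spectrograph grid: 374-1020 nm at 2.31 nm, 280 bands.
WL_START = 374.0
WL_STEP = 2.31
N_BANDS = 280


def default_wavelengths() -> np.ndarray:
    """The instrument wavelength grid in nm (280 bands, 374-1020 nm)."""
    return WL_START + WL_STEP * np.arange(N_BANDS)


@dataclass(frozen=True)
class LatentQuality:
    """Ground-truth quality of one fruit.

    ssc in percent, ph unitless, vc in g/kg; storage_group indexes the
    storage-time cohort (0..groups-1).
    """

    ssc: float
    ph: float
    vc: float
    storage_group: int = 0

    def __post_init__(self):
        for name, value, (lo, hi) in (
            ("ssc", self.ssc, SSC_RANGE),
            ("ph", self.ph, PH_RANGE),
            ("vc", self.vc, VC_RANGE),
        ):
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value} outside observed range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class VCAssay:
    """Spectrophotometric vitamin-C assay inputs.

    C: VC concentration of the juice (g/mL, from the calibration curve);
    V: juice volume (mL); M: fruit mass (g).
    """

    C: float
    V: float
    M: float

    def __post_init__(self):
        if self.C < 0:
            raise ValueError("concentration C must be >= 0")
        if self.V <= 0 or self.M <= 0:
            raise ValueError("volume V and mass M must be > 0")


def vc_content(assay: VCAssay) -> float:
    """VC content in g/kg from the juice assay: C * V / M * 1000."""
    return assay.C * assay.V / assay.M * 1000.0


def _normalise(value, lo: float, hi: float):
    """Map a latent from its observed range to [-1, 1]."""
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return (np.asarray(value, dtype=float) - mid) / half


def _bump(wl: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Smooth bump with compact support on [center-hw, center+hw].

    exp(1 - 1/(1-u^2)) for |u|<1, exactly 0 outside; peak value 1.
    Compact support keeps each latent's spectral footprint to a declared
    window, so 'unlinked' bands are bit-identical across latent changes.
    """
    u = (wl - center) / halfwidth
    out = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    ui = u[inside]
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - ui * ui))
    return out


@dataclass(frozen=True)
class SpectralEffects:
    """Effect sizes (reflectance units per unit normalised latent).

    Positive dip terms deepen the absorber as the latent rises; plateau
    terms move the 750-950 nm shoulder (SSC up, pH/VC down).
    """

    ssc_plateau: float = 0.05
    ssc_dip680: float = 0.06
    ph_plateau: float = 0.04
    ph_dip750: float = 0.04
    vc_plateau: float = 0.03
    vc_dip960: float = 0.07

    @classmethod
    def zero(cls) -> "SpectralEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# Windows (nm) over which each latent is allowed to change the spectrum.
SSC_WINDOWS = ((640.0, 720.0), (740.0, 960.0))
PH_WINDOWS = ((715.0, 785.0), (740.0, 960.0))
VC_WINDOWS = ((905.0, 1015.0), (740.0, 960.0))

_PLATEAU_CENTER, _PLATEAU_HW = 850.0, 110.0
_DIP680_CENTER, _DIP680_HW = 680.0, 40.0
_DIP750_CENTER, _DIP750_HW = 750.0, 35.0
_DIP960_CENTER, _DIP960_HW = 960.0, 55.0
_BASE_DIP680 = 0.10
_BASE_DIP750 = 0.06
_BASE_DIP960 = 0.12


def baseline_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Fixed fruit reflectance at all-midpoint latents: logistic ramp from
    ~0.12 (blue) to ~0.62 (NIR) with the three baseline absorption dips."""
    wl = np.asarray(wavelengths, dtype=float)
    base = 0.12 + 0.50 / (1.0 + np.exp(-(wl - 600.0) / 40.0))
    base -= _BASE_DIP680 * _bump(wl, _DIP680_CENTER, _DIP680_HW)
    base -= _BASE_DIP750 * _bump(wl, _DIP750_CENTER, _DIP750_HW)
    base -= _BASE_DIP960 * _bump(wl, _DIP960_CENTER, _DIP960_HW)
    return base


def latent_response_vectors(
    wavelengths: np.ndarray, effects: SpectralEffects | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(baseline, f_ssc, f_ph, f_vc) band vectors.

    Reflectance is baseline + z_ssc*f_ssc + z_ph*f_ph + z_vc*f_vc with
    z the [-1, 1]-normalised latents.
    """
    if effects is None:
        effects = SpectralEffects()
    wl = np.asarray(wavelengths, dtype=float)
    plateau = _bump(wl, _PLATEAU_CENTER, _PLATEAU_HW)
    f_ssc = effects.ssc_plateau * plateau - effects.ssc_dip680 * _bump(
        wl, _DIP680_CENTER, _DIP680_HW
    )
    f_ph = -effects.ph_plateau * plateau - effects.ph_dip750 * _bump(
        wl, _DIP750_CENTER, _DIP750_HW
    )
    f_vc = -effects.vc_plateau * plateau - effects.vc_dip960 * _bump(
        wl, _DIP960_CENTER, _DIP960_HW
    )
    return baseline_spectrum(wl), f_ssc, f_ph, f_vc


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelengths must be a nonempty 1-D vector")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if wl[0] < WL_START or wl[-1] > 1020.0:
        raise ValueError(
            f"wavelengths must lie within [{WL_START}, 1020] nm, "
            f"got [{wl[0]}, {wl[-1]}]"
        )
    return wl


def spectral_forward_model(
    q: LatentQuality,
    wavelengths: np.ndarray,
    effects: SpectralEffects | None = None,
) -> np.ndarray:
    """Deterministic fruit reflectance spectrum in (0, 1) for latents q."""
    wl = _check_wavelengths(wavelengths)
    base, f_ssc, f_ph, f_vc = latent_response_vectors(wl, effects)
    z_ssc = _normalise(q.ssc, *SSC_RANGE)
    z_ph = _normalise(q.ph, *PH_RANGE)
    z_vc = _normalise(q.vc, *VC_RANGE)
    return base + z_ssc * f_ssc + z_ph * f_ph + z_vc * f_vc


@dataclass(frozen=True)
class NoiseConfig:
    """Scene geometry, scatter and noise settings.

    scatter_offset_sd / scatter_slope_sd: per-ROI-pixel multiplicative
    scatter, reflectance' = a + b*reflectance with a~N(0, offset_sd),
    b~N(1, slope_sd) — the distortion MSC removes.
    additive_sd: additive camera-count noise inside the mask.
    gradient_*: amplitude of the planted within-fruit linear latent
    gradients (truth-map units) used by the distribution-map checks.
    """

    rows: int = 64
    cols: int = 64
    ellipse_semiaxes: tuple[float, float] = (18.0, 22.0)  # (row, col)
    scatter_offset_sd: float = 0.02
    scatter_slope_sd: float = 0.05
    additive_sd: float = 15.0  # counts
    background_reflectance: float = 0.2
    white_level: float = 4000.0
    dark_level: float = 100.0
    gradient_ssc: float = 0.5   # % across the fruit semi-axis
    gradient_ph: float = 0.02
    gradient_vc: float = 0.01

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(scatter_offset_sd=0.0, scatter_slope_sd=0.0, additive_sd=0.0)


@dataclass
class SyntheticScene:
    """One generated fruit image with full ground truth."""

    raw_cube: np.ndarray          # rows x cols x bands, counts
    white_frame: np.ndarray       # same shape, counts
    dark_frame: np.ndarray        # same shape, counts
    truth_mask: np.ndarray        # rows x cols bool
    truth: LatentQuality
    truth_maps: dict[str, np.ndarray]  # per-pixel ssc/ph/vc
    wavelengths: np.ndarray

    def __post_init__(self):
        if not np.all(self.dark_frame < self.white_frame):
            raise BerrySpecError("dark_frame must be < white_frame everywhere")
        if not self.truth_mask.any():
            raise BerrySpecError("truth_mask must contain at least one pixel")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise BerrySpecError("wavelengths must be strictly increasing")


def _ellipse_mask(rows: int, cols: int, semiaxes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ry, rx = semiaxes
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def generate_scene(
    q: LatentQuality,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    effects: SpectralEffects | None = None,
) -> SyntheticScene:
    """Generate one raw scene (counts) plus white/dark frames and truth.

    Reproducible: the same (q, noise, seed) yields bit-identical output.
    """
    noise = noise or NoiseConfig()
    wl = _check_wavelengths(
        default_wavelengths() if wavelengths is None else wavelengths
    )
    rng = np.random.default_rng(seed)
    rows, cols, bands = noise.rows, noise.cols, wl.size
    mask = _ellipse_mask(rows, cols, noise.ellipse_semiaxes)

    # Per-pixel latent maps: scene truth plus planted linear gradients
    # (zero-mean over the symmetric ellipse, so the ROI mean stays at q).
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ry, rx = noise.ellipse_semiaxes
    gx = (cc - cx) / rx  # in [-1, 1] on the fruit
    gy = (rr - cy) / ry
    ssc_map = q.ssc + noise.gradient_ssc * gx
    ph_map = q.ph + noise.gradient_ph * gy
    vc_map = q.vc - noise.gradient_vc * gx

    base, f_ssc, f_ph, f_vc = latent_response_vectors(wl, effects)
    refl = (
        base[None, None, :]
        + _normalise(ssc_map, *SSC_RANGE)[:, :, None] * f_ssc[None, None, :]
        + _normalise(ph_map, *PH_RANGE)[:, :, None] * f_ph[None, None, :]
        + _normalise(vc_map, *VC_RANGE)[:, :, None] * f_vc[None, None, :]
    )
    refl[~mask] = noise.background_reflectance  # spectrally flat background

    # Multiplicative scatter per ROI pixel.
    a = np.zeros((rows, cols))
    b = np.ones((rows, cols))
    if noise.scatter_offset_sd > 0:
        a[mask] = rng.normal(0.0, noise.scatter_offset_sd, mask.sum())
    if noise.scatter_slope_sd > 0:
        b[mask] = rng.normal(1.0, noise.scatter_slope_sd, mask.sum())
    refl = a[:, :, None] + b[:, :, None] * refl

    # Reference frames: smooth spatial falloff and spectral illuminant shape.
    falloff = 1.0 - 0.1 * (((rr - cy) / rows) ** 2 + ((cc - cx) / cols) ** 2)
    illum = 0.75 + 0.25 * np.exp(-(((wl - 760.0) / 260.0) ** 2))
    dark = noise.dark_level + 2.0 * (np.arange(bands) / bands)
    dark_frame = np.broadcast_to(dark, (rows, cols, bands)).copy()
    white_frame = (
        dark_frame + noise.white_level * falloff[:, :, None] * illum[None, None, :]
    )

    raw = dark_frame + (white_frame - dark_frame) * refl
    if noise.additive_sd > 0:
        noise_field = rng.normal(0.0, noise.additive_sd, (rows, cols, bands))
        noise_field[~mask] = 0.0
        raw = raw + noise_field

    return SyntheticScene(
        raw_cube=raw,
        white_frame=white_frame,
        dark_frame=dark_frame,
        truth_mask=mask,
        truth=q,
        truth_maps={"ssc": ssc_map, "ph": ph_map, "vc": vc_map},
        wavelengths=wl,
    )


def _group_profile(groups: int) -> list[tuple[float, float, float]]:
    """Storage-drift group means: SSC rises then falls (carbohydrate
    hydrolysis vs respiration); pH and VC decline monotonically."""
    means = []
    for g in range(groups):
        t = 0.5 if groups == 1 else g / (groups - 1)
        ssc = 5.2 + 1.8 * (1.0 - (2.0 * t - 1.0) ** 2)
        ph = 3.22 - 0.35 * t
        vc = 0.78 - 0.24 * t
        means.append((ssc, ph, vc))
    return means


def generate_dataset(
    n: int = 120,
    groups: int = 5,
    seed: int = 0,
    noise: NoiseConfig | None = None,
) -> tuple["SceneSequence", pd.DataFrame]:
    """Draw n fruit across storage-time groups and return (scenes, truth).

    Scenes are materialised lazily (a full cube is ~27 MB; 120 of them do
    not fit comfortably in memory at once): `scenes[i]` regenerates scene i
    deterministically from a per-scene seed.
    The truth table has columns id, group, ssc, ph, vc.
    """
    if n % groups != 0:
        raise ValueError(f"n={n} not divisible by groups={groups}")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    per = n // groups
    sds = (0.55, 0.05, 0.035)
    records = []
    latents = []
    for g, (m_ssc, m_ph, m_vc) in enumerate(_group_profile(groups)):
        ssc = np.clip(rng.normal(m_ssc, sds[0], per), *SSC_RANGE)
        ph = np.clip(rng.normal(m_ph, sds[1], per), *PH_RANGE)
        vc = np.clip(rng.normal(m_vc, sds[2], per), *VC_RANGE)
        for k in range(per):
            i = g * per + k
            q = LatentQuality(float(ssc[k]), float(ph[k]), float(vc[k]), g)
            latents.append(q)
            records.append(
                {"id": f"s{i:03d}", "group": g, "ssc": q.ssc, "ph": q.ph, "vc": q.vc}
            )
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)
    truth = pd.DataFrame.from_records(records)
    return SceneSequence(latents, scene_seeds, noise), truth


class SceneSequence(Sequence):
    """Lazy, deterministic sequence of scenes (regenerated on access)."""

    def __init__(
        self,
        latents: list[LatentQuality],
        seeds: np.ndarray,
        noise: NoiseConfig,
        effects: SpectralEffects | None = None,
    ):
        self._latents = latents
        self._seeds = np.asarray(seeds)
        self._noise = noise
        self._effects = effects

    def __len__(self) -> int:
        return len(self._latents)

    def __getitem__(self, i):
        if isinstance(i, slice):
            idx = range(*i.indices(len(self)))
            return SceneSequence(
                [self._latents[j] for j in idx],
                self._seeds[list(idx)],
                self._noise,
                self._effects,
            )
        return generate_scene(
            self._latents[i],
            noise=self._noise,
            seed=int(self._seeds[i]),
            effects=self._effects,
        )


def save_scene(scene: SyntheticScene, directory: str | Path, name: str) -> Path:
    """Write a scene as a compressed array container plus an ENVI-style
    header (wavelength list, interleave=BSQ) for external tools."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{name}.npz"
    np.savez_compressed(
        npz,
        raw_cube=scene.raw_cube,
        white_frame=scene.white_frame,
        dark_frame=scene.dark_frame,
        truth_mask=scene.truth_mask,
        wavelengths=scene.wavelengths,
        truth=np.array(
            [scene.truth.ssc, scene.truth.ph, scene.truth.vc, scene.truth.storage_group]
        ),
        truth_ssc=scene.truth_maps["ssc"],
        truth_ph=scene.truth_maps["ph"],
        truth_vc=scene.truth_maps["vc"],
    )
    rows, cols, bands = scene.raw_cube.shape
    wl_list = ", ".join(f"{w:.6f}" for w in scene.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl_list} }}\n"
    )
    (directory / f"{name}.hdr").write_text(header)
    return npz


def load_scene(path: str | Path) -> SyntheticScene:
    """Inverse of save_scene (reads the .npz container)."""
    with np.load(path) as z:
        truth = z["truth"]
        return SyntheticScene(
            raw_cube=z["raw_cube"],
            white_frame=z["white_frame"],
            dark_frame=z["dark_frame"],
            truth_mask=z["truth_mask"],
            truth=LatentQuality(
                float(truth[0]), float(truth[1]), float(truth[2]), int(truth[3])
            ),
            truth_maps={
                "ssc": z["truth_ssc"],
                "ph": z["truth_ph"],
                "vc": z["truth_vc"],
            },
            wavelengths=z["wavelengths"],
        )
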