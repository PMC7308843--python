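"""End-to-end experiment orchestration and pixel-wise quality maps.

An experiment is one cell of the (target x feature blocks x pretreatment
x model x selector) grid: calibrate every scene, segment the fruit,
extract mean spectra (cropped to 400-1000 nm), color and texture
features, split 3:1 by grouped Kennard-Stone, pretreat (the MSC reference
is frozen from the calibration rows), optionally select variables on the
calibration set, fit the model, and report Rc2/RMSEC/Rp2/RMSEP.

Distribution maps apply a model trained on the spectra of selected
wavelengths to every fruit pixel's reflectance, rendering predicted
quality over the fruit with a blue (low) to red (high) scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ContractError, PipelineStageError
from .features import (
    TEXTURE_BAND_PAIRS,
    assemble_features,
    color_moments,
    texture_block,
)
from .hsi_io import Hypercube, Mask, ReferenceFrames, calibrate, mean_spectrum, \
    nearest_band, segment_superred
from .models import (
    EvaluationReport,
    RegressionModel,
    evaluate,
    fit_plsr,
    fit_svr,
    kennard_stone_split,
    LWRModel,
)
from .preprocessing import SpectraTable, msc, msc_reference, wt_denoise
from .selection import cars, uve
from .synthetic import NoiseConfig, SceneSequence, SyntheticScene, generate_dataset

CROP_RANGE = (400.0, 1000.0)


@dataclass
class ExperimentConfig:
    """One experiment cell; defaults reproduce the spectra-only PLSR run."""

    target: str = "ssc"                       # ssc | ph | vc
    blocks: tuple[str, ...] = ("spectral",)   # subset of spectral/color/texture
    pretreatment: str = "none"                # none | wt | msc
    model: str = "plsr"                       # plsr | svr | lwr
    selector: str = "none"                    # none | cars | uve
    seed: int = 0
    n_samples: int = 120
    groups: int = 5
    model_params: dict = field(default_factory=dict)
    selector_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.target not in ("ssc", "ph", "vc"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.pretreatment not in ("none", "wt", "msc"):
            raise ValueError(f"unknown pretreatment {self.pretreatment!r}")
        if self.model not in ("plsr", "svr", "lwr"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.selector not in ("none", "cars", "uve"):
            raise ValueError(f"unknown selector {self.selector!r}")
        bad = set(self.blocks) - {"spectral", "color", "texture"}
        if bad:
            raise ValueError(f"unknown blocks {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "blocks" in raw:
            raw["blocks"] = tuple(raw["blocks"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocks"] = list(self.blocks)
        return d


@dataclass
class SampleFeatures:
    """Per-sample extracted features for a whole dataset."""

    spectra: SpectraTable                 # cropped to 400-1000 nm
    color: np.ndarray                     # n x 9
    texture: dict[str, np.ndarray]        # target -> n x 36
    truth: pd.DataFrame                   # id, group, ssc, ph, vc


def extract_scene_features(
    scene: SyntheticScene,
    texture_pairs: dict[str, tuple[float, float]] = TEXTURE_BAND_PAIRS,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], Mask]:
    """Calibrate one scene and extract (mean spectrum, color 9-vector,
    per-target texture 36-vectors, fruit mask)."""
    cube = calibrate(
        Hypercube(scene.raw_cube, scene.wavelengths, kind="raw"),
        ReferenceFrames(scene.white_frame, scene.dark_frame),
    )
    mask = segment_superred(cube)
    spectrum = mean_spectrum(cube, mask)
    color = color_moments(cube, mask)
    texture = {t: texture_block(cube, mask, pair)
               for t, pair in texture_pairs.items()}
    return spectrum, color, texture, mask


def extract_dataset(
    scenes: SceneSequence | list[SyntheticScene],
    truth: pd.DataFrame,
    crop: tuple[float, float] = CROP_RANGE,
) -> SampleFeatures:
    """Run calibration/segmentation/feature extraction over all scenes."""
    spectra_rows, color_rows = [], []
    texture_rows: dict[str, list[np.ndarray]] = {t: [] for t in TEXTURE_BAND_PAIRS}
    wavelengths = None
    for i in range(len(scenes)):
        scene = scenes[i]
        wavelengths = scene.wavelengths
        spectrum, color, texture, _ = extract_scene_features(scene)
        spectra_rows.append(spectrum)
        color_rows.append(color)
        for t, vec in texture.items():
            texture_rows[t].append(vec)
    table = SpectraTable(
        np.vstack(spectra_rows), wavelengths, list(truth["id"])
    ).crop(*crop)
    return SampleFeatures(
        spectra=table,
        color=np.vstack(color_rows),
        texture={t: np.vstack(rows) for t, rows in texture_rows.items()},
        truth=truth.reset_index(drop=True),
    )


def synthesize_sample_features(
    n: int = 120, groups: int = 5, seed: int = 0,
    noise: NoiseConfig | None = None,
) -> SampleFeatures:
    """Generate the default synthetic dataset and extract its features."""
    scenes, truth = generate_dataset(n, groups, seed, noise)
    return extract_dataset(scenes, truth)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_experiment(
    cfg: ExperimentConfig,
    data: SampleFeatures | None = None,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Execute one experiment cell; optionally persist report, selection,
    model and provenance JSON under out_dir."""
    if data is None:
        with _stage("synthesize"):
            data = synthesize_sample_features(cfg.n_samples, cfg.groups, cfg.seed)

    y_all = data.truth[cfg.target].to_numpy(float)
    ids = list(data.truth["id"])
    groups = data.truth["group"].to_numpy(int)

    with _stage("split"):
        plan = kennard_stone_split(data.spectra.X, ids, groups)
        cal_idx, pred_idx = plan.indices(ids)

    with _stage("pretreat"):
        if cfg.pretreatment == "wt":
            spectra = wt_denoise(data.spectra)
        elif cfg.pretreatment == "msc":
            ref = msc_reference(data.spectra.rows(cal_idx))
            spectra = msc(data.spectra, ref)
        else:
            spectra = data.spectra

    with _stage("features"):
        color = texture = None
        if "color" in cfg.blocks:
            color = _standardize_block(data.color, cal_idx)
        if "texture" in cfg.blocks:
            texture = _standardize_block(data.texture[cfg.target], cal_idx)
        table = assemble_features(
            spectra, color=color, texture=texture, include=cfg.blocks,
            texture_band_pair=TEXTURE_BAND_PAIRS.get(cfg.target),
        )

    selection = None
    columns = np.arange(table.F.shape[1])
    with _stage("select"):
        if cfg.selector != "none":
            Xc = table.F[cal_idx]
            yc = y_all[cal_idx]
            fn = cars if cfg.selector == "cars" else uve
            selection = fn(Xc, yc, seed=cfg.seed, **cfg.selector_params)
            if selection.selected.size:
                columns = selection.selected
            # else: fall back to the full variable set (warned inside uve)

    X = table.F[:, columns]
    with _stage("fit"):
        model = _fit_model(cfg, X[cal_idx], y_all[cal_idx])

    with _stage("evaluate"):
        report = evaluate(model, X[cal_idx], y_all[cal_idx],
                          X[pred_idx], y_all[pred_idx])

    if out_dir is not None:
        with _stage("persist"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(report.to_json())
            (out / "model.json").write_text(model.to_json())
            if selection is not None:
                selection.save(out / "selection.json")
            provenance = {
                "config": cfg.to_dict(),
                "package_version": __version__,
                "n_features": int(table.F.shape[1]),
                "n_selected": int(columns.size),
                "feature_blocks": {
                    b: int((np.array(table.blocks) == b).sum())
                    for b in sorted(set(table.blocks))
                },
                "calibration_ids": plan.calibration_ids,
                "prediction_ids": plan.prediction_ids,
            }
            (out / "provenance.json").write_text(
                json.dumps(provenance, sort_keys=True)
            )
    return report


def _standardize_block(block: np.ndarray, cal_idx: np.ndarray) -> np.ndarray:
    """Z-score a feature block by calibration-row statistics so that it is
    commensurate with reflectance-scale spectral columns."""
    mu = block[cal_idx].mean(axis=0)
    sd = block[cal_idx].std(axis=0)
    sd[sd == 0] = 1.0
    return (block - mu) / sd


def _fit_model(cfg: ExperimentConfig, X: np.ndarray, y: np.ndarray) -> RegressionModel:
    params = dict(cfg.model_params)
    if cfg.model == "plsr":
        return fit_plsr(X, y, seed=cfg.seed, **params)
    if cfg.model == "svr":
        return fit_svr(X, y, seed=cfg.seed, **params)
    model = LWRModel(**params)
    return model.fit(X, y)


# ---------------------------------------------------------------------------
# Pixel-wise distribution maps


def build_map_model(
    data: SampleFeatures,
    target: str,
    n_bands: int = 30,
    seed: int = 0,
):
    """PLSR map model on the raw spectra of the top-n CARS wavelengths.

    Maps deliberately use raw (un-pretreated) reflectance: WT is row-wise
    on whole spectra and MSC per single pixel regresses the quality signal
    itself into the scatter slope, so neither survives the per-pixel
    setting.  n_bands=30 sits inside the 27-59 wavelength range that CARS
    typically retains for these quality parameters.

    Returns (model, selected_wavelengths).
    """
    from .selection import rank_band_weights

    y = data.truth[target].to_numpy(float)
    _, wavelengths = rank_band_weights(data.spectra, y, k=n_bands, seed=seed)
    bands = [nearest_band(data.spectra.wavelengths, w) for w in wavelengths]
    model = fit_plsr(data.spectra.X[:, bands], y, seed=seed)
    return model, wavelengths


@dataclass
class DistributionMap:
    """Per-pixel predicted quality over the fruit mask (NaN outside)."""

    values: np.ndarray
    mask: Mask
    colormap: str = "jet"  # blue (low) -> red (high)

    def __post_init__(self):
        inside = self.values[self.mask.values]
        if not np.all(np.isfinite(inside)):
            raise ValueError("map must be finite inside the mask")

    @property
    def bounds(self) -> tuple[float, float]:
        inside = self.values[self.mask.values]
        return float(inside.min()), float(inside.max())


def distribution_map(
    cube: Hypercube,
    mask: Mask,
    model: RegressionModel,
    selected_wavelengths: np.ndarray,
    pixel_pretreat=None,
) -> DistributionMap:
    """Predict the quality parameter at every masked pixel.

    The model must have been trained on exactly the band values of
    `selected_wavelengths` (nearest-band resolution).  pixel_pretreat, if
    given, maps the (n_pixels, n_bands_of_cube) matrix of full pixel
    spectra before the selected bands are subset (e.g. per-pixel MSC
    against a frozen calibration reference on the cropped grid).
    """
    bands = [nearest_band(cube.wavelengths, w) for w in selected_wavelengths]
    P = cube.data[mask.values]
    if pixel_pretreat is not None:
        P = pixel_pretreat(P)
    P = P[:, bands]
    if model.n_features_ != P.shape[1]:
        raise ContractError(
            f"model expects {model.n_features_} bands, map supplies {P.shape[1]}"
        )
    values = np.full(mask.values.shape, np.nan)
    values[mask.values] = model.predict(P)
    return DistributionMap(values, mask)


def render_map(dmap: DistributionMap, out_path: str | Path) -> Path:
    """Write the map as an RGBA PNG (alpha 0 outside the mask) with a
    colorbar figure and a JSON sidecar recording the value bounds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors
    from PIL import Image

    out_path = Path(out_path)
    vmin, vmax = dmap.bounds
    lo, hi = (vmin - 0.5, vmax + 0.5) if vmin == vmax else (vmin, vmax)
    norm = colors.Normalize(vmin=lo, vmax=hi)
    cmap = plt.get_cmap(dmap.colormap)
    rgba = cmap(norm(np.nan_to_num(dmap.values, nan=lo)))
    rgba[..., 3] = np.where(dmap.mask.values, 1.0, 0.0)
    Image.fromarray((rgba * 255).astype(np.uint8), mode="RGBA").save(out_path)

    fig, ax = plt.subplots(figsize=(1.2, 4))
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), cax=ax)
    fig.savefig(out_path.with_name(out_path.stem + "_colorbar.png"),
                bbox_inches="tight", dpi=100)
    plt.close(fig)

    out_path.with_suffix(".json").write_text(
        json.dumps({"vmin": vmin, "vmax": vmax, "scale_min": lo,
                    "scale_max": hi, "colormap": dmap.colormap},
                   sort_keys=True)
    )
    return out_path
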