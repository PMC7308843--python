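"""Spectral pretreatment: wavelet denoising and multiplicative scatter
correction (MSC), operating row-wise on a samples x bands table.

MSC regresses each spectrum x on a reference spectrum m (least squares,
x ~ a + b*m) and returns (x - a)/b, removing per-sample additive offset
and multiplicative slope caused by light scattering.  The reference
defaults to the column mean; in a calibration/prediction workflow the
reference must come from the calibration rows only and be reused frozen
for prediction rows (see pipeline.run_experiment).

Wavelet denoising decomposes each row (db4, level 3, symmetric padding by
default), soft-thresholds the detail coefficients at the universal
threshold sigma*sqrt(2 ln n) with sigma estimated as
median(|finest details|)/0.6745, and reconstructs to the original length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .errors import DegenerateSpectrumError


@dataclass
class SpectraTable:
    """samples x bands reflectance matrix with wavelengths and ids."""

    X: np.ndarray
    wavelengths: np.ndarray
    ids: list[str]
    pretreatment: str = "none"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ids = list(self.ids)
        if self.X.ndim != 2:
            raise ValueError("X must be samples x bands")
        if self.X.shape[0] != len(self.ids):
            raise ValueError("row count != id count")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError("column count != wavelength count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def rows(self, indices) -> "SpectraTable":
        idx = np.asarray(indices)
        return SpectraTable(
            self.X[idx], self.wavelengths, [self.ids[i] for i in idx],
            self.pretreatment,
        )

    def crop(self, lo: float, hi: float) -> "SpectraTable":
        keep = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not keep.any():
            raise ValueError(f"no bands inside [{lo}, {hi}] nm")
        return SpectraTable(
            self.X[:, keep], self.wavelengths[keep], self.ids, self.pretreatment
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.X, columns=[repr(float(w)) for w in self.wavelengths])
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        ids = [str(v) for v in df["id"]]
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(df.iloc[:, 1:].to_numpy(float), wl, ids)


def msc_reference(table: SpectraTable) -> np.ndarray:
    """Column-mean reference spectrum (compute on calibration rows only)."""
    return table.X.mean(axis=0)


def msc(table: SpectraTable, reference: np.ndarray | str = "mean") -> SpectraTable:
    """Multiplicative scatter correction of every row against a reference."""
    if table.n_bands < 2:
        raise ValueError("MSC needs at least 2 bands")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown reference {reference!r}")
        m = msc_reference(table)
    else:
        m = np.asarray(reference, dtype=float)
        if m.shape != (table.n_bands,):
            raise ValueError("reference length must equal band count")
    mc = m - m.mean()
    denom = mc @ mc
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    Xc = table.X - table.X.mean(axis=1, keepdims=True)
    b = (Xc @ mc) / denom          # per-row slope
    a = table.X.mean(axis=1) - b * m.mean()
    if np.any(b == 0):
        row = int(np.argwhere(b == 0)[0])
        raise DegenerateSpectrumError(
            f"row {table.ids[row]!r} has zero slope against the reference"
        )
    corrected = (table.X - a[:, None]) / b[:, None]
    return SpectraTable(corrected, table.wavelengths, table.ids, "msc")


def wt_denoise(
    table: SpectraTable,
    wavelet: str = "db4",
    level: int = 3,
    rule: str = "universal-soft",
    mode: str = "symmetric",
) -> SpectraTable:
    """Per-row wavelet-threshold denoising, reconstructed to band count."""
    n = table.n_bands
    if 2**level > n:
        raise ValueError(f"level {level} too deep for {n} bands")
    if rule != "universal-soft":
        raise ValueError(f"unknown threshold rule {rule!r}")
    out = np.empty_like(table.X)
    for i, row in enumerate(table.X):
        coeffs = pywt.wavedec(row, wavelet, level=level, mode=mode)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(n))
        denoised = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
        out[i] = pywt.waverec(denoised, wavelet, mode=mode)[:n]
    return SpectraTable(out, table.wavelengths, table.ids, "wt")


PRETREATMENTS = ("none", "wt", "msc")


def pretreat(
    table: SpectraTable,
    method: str,
    msc_ref: np.ndarray | None = None,
) -> SpectraTable:
    """Dispatch helper: 'none' | 'wt' | 'msc' (msc_ref freezes the MSC
    reference, e.g. to the calibration-set mean)."""
    if method == "none":
        return replace(table)
    if method == "wt":
        return wt_denoise(table)
    if method == "msc":
        return msc(table, "mean" if msc_ref is None else msc_ref)
    raise ValueError(f"unknown pretreatment {method!r}")
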