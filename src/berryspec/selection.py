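"""Important-variable selection: CARS and UVE over feature matrices.

CARS (competitive adaptive reweighted sampling): across `runs` Monte-Carlo
iterations, a PLSR model is fitted on a random fraction of the calibration
rows using the currently retained variables; variables are ranked by
normalised |regression coefficient|, an exponentially decreasing fraction
of the original variable count is force-retained (from all variables at
run 1 down to 2 at the last run), and adaptive reweighted sampling
(draws proportional to weight, with replacement, keeping the unique set)
competes the rest away.  Each iteration's retained set is scored by
k-fold RMSECV; the subset with the lowest RMSECV wins.

UVE (uninformative variable elimination): an equal-width block of tiny
artificial noise variables is appended to X, PLSR coefficients are
collected over leave-one-out resampling, and each variable's stability
c_j = mean(b_j)/sd(b_j) is compared against a high quantile of |c| over
the noise block; real variables below the cutoff are eliminated.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import PLSRModel, cv_fold_assignment, rmsecv
from .preprocessing import SpectraTable

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    selected: np.ndarray          # sorted unique variable indices
    weights: np.ndarray           # per-variable importance, sums to 1
    rmsecv_trace: np.ndarray      # per-iteration RMSECV
    best_iteration: int
    method: str
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.rmsecv_trace = np.asarray(self.rmsecv_trace, dtype=float)
        if self.selected.size and np.unique(self.selected).size != self.selected.size:
            raise ValueError("selected indices must be unique")

    @property
    def best_rmsecv(self) -> float:
        return float(self.rmsecv_trace[self.best_iteration])

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "seed": self.seed,
                "selected": self.selected.tolist(),
                "weights": self.weights.tolist(),
                "rmsecv_trace": self.rmsecv_trace.tolist(),
                "best_iteration": self.best_iteration,
                "config": self.config,
            },
            sort_keys=True,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def _pls_weights(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Normalised |PLS regression coefficients| (sum to 1)."""
    ncomp = max(1, min(n_components, X.shape[0] - 1, X.shape[1]))
    coef = np.abs(PLSRModel(ncomp).fit(X, y).coefficients)
    total = coef.sum()
    if total == 0:
        return np.full(coef.size, 1.0 / coef.size)
    return coef / total


def cars(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    mc_fraction: float = 0.8,
    folds: int = 5,
    n_components: int | None = None,
    max_components: int = 15,
    ars_draws: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling over the columns of X.

    ars_draws scales the number of weighted survival draws (ars_draws * p
    with replacement) in the adaptive reweighted sampling step; at 5*p a
    variable must hold well under ~1/(5p) of the weight to be eliminated
    by sampling rather than by the retention schedule.

    n_components=None uses min(max_components, data caps) latent variables
    throughout (further capped per run by the retained-set and subsample
    sizes).  A cross-validated choice on the full matrix is deliberately
    not used: before selection the matrix is noise-dominated and its CV
    curve is flat, so an argmin over it is arbitrary and routinely lands
    on 1-2 components, which ruins the coefficient ranking.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n or n < folds:
        raise ValueError("need rows(X) == len(y) >= folds")
    if runs < 2:
        raise ValueError("runs must be >= 2")
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = max(1, min(max_components, p, n - 1 - n // folds))
    fold_idx = cv_fold_assignment(n, folds, seed)  # fixed before the run loop

    # Exponentially decreasing retention ratio r_i = a*exp(-k*i) with
    # r_1 = 1 (all variables) and r_runs = 2/p (two variables).
    a = (p / 2.0) ** (1.0 / (runs - 1))
    k = math.log(p / 2.0) / (runs - 1)

    retained = np.arange(p)
    accumulated = np.zeros(p)
    trace = np.empty(runs)
    subsets: list[np.ndarray] = []
    n_sub = max(2, int(round(mc_fraction * n)))
    for i in range(1, runs + 1):
        sample = rng.choice(n, size=n_sub, replace=False)
        w = _pls_weights(X[np.ix_(sample, retained)], y[sample], n_components)
        accumulated[retained] += w
        keep = int(np.ceil(a * math.exp(-k * i) * p))
        keep = max(2, min(keep, retained.size))
        order = np.argsort(-w, kind="stable")[:keep]  # ties -> lower index
        top = retained[order]
        w_top = w[order]
        # Adaptive reweighted sampling: many weighted draws with
        # replacement among the force-retained top set; only
        # negligible-weight variables fail to survive the draw, so the
        # exponential schedule (not sampling noise) drives the shrinkage.
        draws = rng.choice(
            top, size=ars_draws * p, replace=True, p=w_top / w_top.sum()
        )
        new = np.unique(draws)
        if new.size < 2:
            log.warning("CARS: retained set collapsed at run %d; clamping to 2", i)
            new = np.sort(top[:2])
        retained = new
        ncomp_i = min(n_components, retained.size)
        trace[i - 1] = rmsecv(
            X[:, retained], y, folds,
            lambda A, b, c=ncomp_i: PLSRModel(min(c, A.shape[0] - 1)).fit(A, b),
            fold_indices=fold_idx,
        )
        subsets.append(retained.copy())
    best = int(np.argmin(trace))
    total = accumulated.sum()
    return SelectionResult(
        selected=np.sort(subsets[best]),
        weights=accumulated / total,
        rmsecv_trace=trace,
        best_iteration=best,
        method="cars",
        seed=seed,
        config={
            "runs": runs,
            "mc_fraction": mc_fraction,
            "folds": folds,
            "n_components": int(n_components),
            "subset_sizes": [int(s.size) for s in subsets],
        },
    )


def uve(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    cutoff_quantile: float = 0.99,
    noise_amplitude: float = 1e-10,
    max_components: int = 15,
    seed: int = 0,
) -> SelectionResult:
    """Uninformative variable elimination by coefficient stability.

    Appends p artificial uniform noise columns scaled to
    noise_amplitude * (mean column SD of X), collects PLSR coefficients
    over leave-one-out resampling, and keeps real variables whose
    |mean/sd| stability exceeds the cutoff_quantile of |stability| over
    the noise block.  An empty result is returned as-is (the pipeline
    falls back to the full variable set with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("UVE needs at least 3 rows")
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = max(1, min(max_components, 2 * p, n - 2))
    scale = float(X.std(axis=0).mean()) or 1.0
    noise = rng.uniform(-1.0, 1.0, size=(n, p)) * noise_amplitude * scale
    Xa = np.hstack([X, noise])
    B = np.empty((n, 2 * p))
    for i in range(n):
        rows = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        ncomp = min(n_components, rows.size - 1, Xa.shape[1])
        B[i] = PLSRModel(ncomp).fit(Xa[rows], y[rows]).coefficients
    mean_b = B.mean(axis=0)
    sd_b = B.std(axis=0)
    stability = np.empty(2 * p)
    zero_sd = sd_b == 0
    if zero_sd.any():
        log.warning("UVE: %d variables have perfectly stable coefficients",
                    int(zero_sd.sum()))
    stability[~zero_sd] = mean_b[~zero_sd] / sd_b[~zero_sd]
    stability[zero_sd] = np.inf * np.sign(mean_b[zero_sd] + (mean_b[zero_sd] == 0))
    cutoff = float(np.quantile(np.abs(stability[p:]), cutoff_quantile))
    selected = np.where(np.abs(stability[:p]) > cutoff)[0]
    if selected.size == 0:
        log.warning("UVE: no variable exceeded the noise cutoff")
        trace_set = np.arange(p)
    else:
        trace_set = selected
    finite = np.abs(stability[:p])
    big = np.nanmax(finite[np.isfinite(finite)], initial=1.0)
    finite = np.where(np.isfinite(finite), finite, 10.0 * big)
    trace = np.array([
        rmsecv(X[:, trace_set], y, min(5, n),
               lambda A, b: PLSRModel(
                   min(n_components, A.shape[0] - 1, A.shape[1])).fit(A, b),
               seed=seed)
    ])
    return SelectionResult(
        selected=selected,
        weights=finite / finite.sum(),
        rmsecv_trace=trace,
        best_iteration=0,
        method="uve",
        seed=seed,
        config={
            "n_components": int(n_components),
            "cutoff_quantile": cutoff_quantile,
            "noise_amplitude": noise_amplitude,
            "cutoff": cutoff,
        },
    )


def rank_band_weights(
    spectra: SpectraTable,
    y: np.ndarray,
    k: int = 2,
    **cars_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band CARS importance and the top-k wavelengths.

    Weights are the CARS run-accumulated normalised |coefficient| weights
    (sum to 1); the returned wavelengths are the k largest, descending.
    """
    result = cars(spectra.X, np.asarray(y, dtype=float), **cars_kwargs)
    order = np.argsort(-result.weights, kind="stable")[:k]
    return result.weights, spectra.wavelengths[order]
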