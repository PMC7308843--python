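"""Calibration/prediction splitting, the three regression methods, and
evaluation metrics.

The sample set is partitioned 3:1 within each storage-time group by the
Kennard-Stone algorithm (deterministic max-min Euclidean selection on
column-standardised features), reproducing the 90/30 split of a 120-fruit
experiment with 5 groups of 24.

Models: PLSR (latent-variable linear regression, component count chosen
by RMSECV unless fixed), epsilon-SVR with an RBF kernel (hyperparameters
from a small seeded cross-validated grid unless fixed), and LWR (locally
weighted linear regression: per query, a distance-kernel-weighted linear
fit on the nearest calibration neighbours, with distances taken in a
PCA-compressed space).

Metrics: R^2 = 1 - SS_res/SS_tot (each set against its own mean) and
RMSE = sqrt(mean squared residual); RMSECV pools out-of-fold predictions
from seeded shuffled contiguous folds and computes one RMSE over all rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.svm import SVR as _SkSVR

from .errors import ContractError

# ---------------------------------------------------------------------------
# Kennard-Stone splitting


@dataclass
class SplitPlan:
    calibration_ids: list[str]
    prediction_ids: list[str]
    ratio: float = 0.75
    grouping: dict[str, int] = field(default_factory=dict)

    def indices(self, ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        pos = {s: i for i, s in enumerate(ids)}
        cal = np.array([pos[s] for s in self.calibration_ids])
        pred = np.array([pos[s] for s in self.prediction_ids])
        return cal, pred


def _kennard_stone(Z: np.ndarray, n_select: int) -> list[int]:
    """Max-min selection on rows of Z (rows must be pre-sorted by id so
    that np.argmax's first-occurrence rule breaks ties toward lower ids)."""
    n = Z.shape[0]
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    first = int(np.argmax(D.max(axis=1)))
    second = int(np.argmax(D[first]))
    if first > second:
        first, second = second, first
    chosen = [first, second]
    min_dist = np.minimum(D[first], D[second])
    remaining = np.ones(n, dtype=bool)
    remaining[chosen] = False
    while len(chosen) < n_select:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))
        chosen.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return chosen


def kennard_stone_split(
    X: np.ndarray,
    ids: Sequence[str],
    groups: Sequence[int],
    ratio: float = 0.75,
) -> SplitPlan:
    """Per-group Kennard-Stone 3:1 split into calibration/prediction ids.

    Within each group, ceil(ratio * group size) rows are chosen by max-min
    Euclidean distance on column-z-scored features (zero-variance columns
    are dropped from the metric); the rest go to prediction.  Deterministic
    and permutation-equivariant: shuffling input rows yields the same id
    sets, because rows are processed in id order and ties break toward the
    lower id.
    """
    X = np.asarray(X, dtype=float)
    ids = [str(s) for s in ids]
    groups = np.asarray(groups)
    if len(ids) != X.shape[0] or groups.shape[0] != X.shape[0]:
        raise ValueError("X, ids and groups must align")
    cal_ids: list[str] = []
    pred_ids: list[str] = []
    for g in np.unique(groups):
        rows = np.where(groups == g)[0]
        if rows.size < 4:
            raise ValueError(f"group {g} has {rows.size} < 4 samples")
        order = rows[np.argsort([ids[i] for i in rows])]
        Z = X[order]
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - mu) / sd
        n_cal = int(np.ceil(ratio * rows.size))
        chosen = _kennard_stone(Z, n_cal)
        chosen_set = set(chosen)
        cal_ids.extend(ids[order[k]] for k in sorted(chosen))
        pred_ids.extend(ids[order[k]] for k in range(rows.size) if k not in chosen_set)
    return SplitPlan(
        cal_ids, pred_ids, ratio, {str(s): int(g) for s, g in zip(ids, groups)}
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class EvaluationReport:
    rc2: float
    rmsec: float
    rp2: float
    rmsep: float
    n_cal: int
    n_pred: int

    def __post_init__(self):
        if self.rmsec < 0 or self.rmsep < 0:
            raise ValueError("RMSE must be >= 0")
        if self.rc2 > 1 + 1e-12 or self.rp2 > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "rc2": self.rc2,
            "rmsec": self.rmsec,
            "rp2": self.rp2,
            "rmsep": self.rmsep,
            "n_cal": self.n_cal,
            "n_pred": self.n_pred,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y has zero variance")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


# ---------------------------------------------------------------------------
# Regression models


class RegressionModel:
    """Common fitted-model surface: predict() refuses wrong widths."""

    method: str = "base"

    def __init__(self):
        self.n_features_: int | None = None

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_features_ is None:
            raise ContractError("model is not fitted")
        if X.shape[1] != self.n_features_:
            raise ContractError(
                f"model was trained on {self.n_features_} features, "
                f"got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def to_json(self) -> str:
        raise NotImplementedError


class PLSRModel(RegressionModel):
    method = "plsr"

    def __init__(self, n_components: int):
        super().__init__()
        self.n_components = int(n_components)
        self._pls: PLSRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSRModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        cap = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= cap:
            raise ValueError(
                f"n_components={self.n_components} outside [1, {cap}]"
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls.fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        return self._pls.predict(X).ravel()

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the original (centered) variables."""
        return np.asarray(self._pls.coef_).reshape(-1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "n_components": self.n_components,
                "coefficients": self.coefficients.tolist(),
                "x_mean": self._pls._x_mean.tolist(),
                "y_mean": np.atleast_1d(self._pls._y_mean).tolist(),
            },
            sort_keys=True,
        )


def select_plsr_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 15,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Component count minimising RMSECV over 1..max (capped by data size)."""
    X = np.asarray(X, dtype=float)
    cap = min(max_components, X.shape[1], X.shape[0] - 1 - X.shape[0] // folds)
    cap = max(cap, 1)
    scores = [
        rmsecv(X, y, folds, lambda A, b, a=a: PLSRModel(a).fit(A, b), seed=seed)
        for a in range(1, cap + 1)
    ]
    return 1 + int(np.argmin(scores))


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    max_components: int = 15,
    cv_folds: int = 5,
    seed: int = 0,
) -> PLSRModel:
    """Fit PLSR; when n_components is None it is chosen by RMSECV."""
    if n_components is None:
        n_components = select_plsr_components(X, y, max_components, cv_folds, seed)
    return PLSRModel(n_components).fit(X, y)


class SVRModel(RegressionModel):
    """RBF epsilon-SVR on column-standardised X and standardised y."""

    method = "svr"

    def __init__(self, C: float, epsilon: float, gamma: float | str = "scale"):
        super().__init__()
        if C <= 0 or epsilon < 0:
            raise ValueError("hyperparameters must be positive")
        self.C, self.epsilon, self.gamma = C, epsilon, gamma
        self._svr: _SkSVR | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVRModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in SVR inputs")
        self._x_mean = X.mean(axis=0)
        self._x_sd = X.std(axis=0)
        self._x_sd[self._x_sd == 0] = 1.0
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        Z = (X - self._x_mean) / self._x_sd
        t = (y - self._y_mean) / self._y_sd
        self._svr = _SkSVR(
            kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma
        ).fit(Z, t)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        Z = (X - self._x_mean) / self._x_sd
        return self._svr.predict(Z) * self._y_sd + self._y_mean

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "C": self.C,
                "epsilon": self.epsilon,
                "gamma": self.gamma if isinstance(self.gamma, str) else float(self.gamma),
                "n_support": int(self._svr.support_.size),
                "dual_coef": self._svr.dual_coef_.ravel().tolist(),
                "intercept": float(self._svr.intercept_[0]),
            },
            sort_keys=True,
        )


# Documented default grid for the seeded SVR search (on standardised data).
SVR_GRID = {"C": (1.0, 10.0, 100.0), "epsilon": (0.01, 0.1)}


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    epsilon: float | None = None,
    gamma: float | str = "scale",
    cv_folds: int = 5,
    seed: int = 0,
) -> SVRModel:
    """Fit epsilon-SVR; unset hyperparameters come from a seeded
    cross-validated search over SVR_GRID (deterministic per seed)."""
    if C is not None and epsilon is not None:
        return SVRModel(C, epsilon, gamma).fit(X, y)
    best = None
    for c in SVR_GRID["C"] if C is None else (C,):
        for eps in SVR_GRID["epsilon"] if epsilon is None else (epsilon,):
            score = rmsecv(
                X, y, cv_folds,
                lambda A, b, c=c, eps=eps: SVRModel(c, eps, gamma).fit(A, b),
                seed=seed,
            )
            if best is None or score < best[0]:
                best = (score, c, eps)
    return SVRModel(best[1], best[2], gamma).fit(X, y)


class LWRModel(RegressionModel):
    """Locally weighted linear regression with distance-kernel weights.

    Distances and local fits are taken in a PCA space retaining
    `pc_variance` of the calibration variance (None disables compression).
    bandwidth 'adaptive' scales the Gaussian kernel to each query's
    farthest retained neighbour.
    """

    method = "lwr"

    def __init__(
        self,
        n_neighbors: int | None = None,
        kernel: str = "gaussian",
        bandwidth: float | str = "adaptive",
        pc_variance: float | None = 0.99,
        ridge: float = 1e-8,
    ):
        super().__init__()
        if kernel not in ("gaussian", "uniform"):
            raise ValueError(f"unknown kernel {kernel!r}")
        if not (bandwidth == "adaptive" or bandwidth > 0):
            raise ValueError("bandwidth must be positive or 'adaptive'")
        self.n_neighbors = n_neighbors
        self.kernel = kernel
        self.bandwidth = bandwidth
        self.pc_variance = pc_variance
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LWRModel":
        X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=float)
        self.n_features_ = X.shape[1]
        if self.n_neighbors is None:
            self._k = min(30, X.shape[0])
        else:
            if self.n_neighbors > X.shape[0]:
                raise ValueError("n_neighbors exceeds calibration rows")
            self._k = int(self.n_neighbors)
        self._mean = X.mean(axis=0)
        if self.pc_variance is None:
            self._pca = None
            self._T = X - self._mean
        else:
            n_comp = min(X.shape[0], X.shape[1])
            pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
            keep = 1 + int(
                np.searchsorted(np.cumsum(pca.explained_variance_ratio_),
                                self.pc_variance)
            )
            keep = min(keep, n_comp)
            self._pca = PCA(n_components=keep, svd_solver="full").fit(X)
            self._T = self._pca.transform(X)
        return self

    def _weights(self, d: np.ndarray) -> np.ndarray:
        if self.kernel == "uniform":
            return np.ones_like(d)
        h = float(d.max()) if self.bandwidth == "adaptive" else float(self.bandwidth)
        if not np.isfinite(h):
            return np.ones_like(d)
        if h == 0:
            return np.where(d == 0, 1.0, 0.0)
        return np.exp(-(d**2) / (2.0 * h**2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check_width(X)
        T = (X - self._mean) if self._pca is None else self._pca.transform(X)
        out = np.empty(T.shape[0])
        for qi, t in enumerate(T):
            d = np.sqrt(((self._T - t) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[: self._k]
            w = self._weights(d[nn])
            if w.sum() == 0:
                w = np.ones_like(w)
            A = np.hstack([np.ones((nn.size, 1)), self._T[nn]])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(A * sw[:, None], self._y[nn] * sw, rcond=None)
            if not np.all(np.isfinite(beta)):
                # ridge fallback on a numerically singular local system
                warnings.warn("LWR: singular local fit, applying ridge jitter")
                AtW = (A * w[:, None]).T
                beta = np.linalg.solve(
                    AtW @ A + self.ridge * np.eye(A.shape[1]), AtW @ self._y[nn]
                )
            out[qi] = beta[0] + beta[1:] @ t
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "n_neighbors": self._k,
                "kernel": self.kernel,
                "bandwidth": self.bandwidth if isinstance(self.bandwidth, str)
                else float(self.bandwidth),
                "pc_variance": self.pc_variance,
                "n_cal": int(self._y.size),
            },
            sort_keys=True,
        )


def lwr_predict(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_query: np.ndarray,
    n_neighbors: int | None = None,
    kernel: str = "gaussian",
    bandwidth: float | str = "adaptive",
    pc_variance: float | None = 0.99,
) -> np.ndarray:
    """Functional form of LWRModel.fit(...).predict(X_query)."""
    model = LWRModel(n_neighbors, kernel, bandwidth, pc_variance)
    return model.fit(X_cal, y_cal).predict(X_query)


def evaluate(
    model: RegressionModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
) -> EvaluationReport:
    """Rc^2/RMSEC on the calibration set, Rp^2/RMSEP on the prediction set."""
    y_cal = np.asarray(y_cal, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_cal.size == 0 or y_pred.size == 0:
        raise ValueError("evaluation sets must be nonempty")
    yc = model.predict(X_cal)
    yp = model.predict(X_pred)
    return EvaluationReport(
        rc2=r_squared(y_cal, yc),
        rmsec=rmse(y_cal, yc),
        rp2=r_squared(y_pred, yp),
        rmsep=rmse(y_pred, yp),
        n_cal=int(y_cal.size),
        n_pred=int(y_pred.size),
    )


def cv_fold_assignment(n: int, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffled contiguous folds (fixed before any model fitting)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    perm = np.random.default_rng(seed).permutation(n)
    parts = np.array_split(perm, folds)
    if min(p.size for p in parts) < 2:
        raise ValueError(f"a fold would have < 2 rows (n={n}, folds={folds})")
    return parts


def rmsecv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    model_factory: Callable[[np.ndarray, np.ndarray], RegressionModel],
    seed: int = 0,
    fold_indices: list[np.ndarray] | None = None,
) -> float:
    """Pooled out-of-fold RMSE under seeded shuffled contiguous folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    parts = fold_indices or cv_fold_assignment(X.shape[0], folds, seed)
    y_hat = np.empty_like(y)
    for held in parts:
        train = np.setdiff1d(np.arange(X.shape[0]), held)
        model = model_factory(X[train], y[train])
        y_hat[held] = model.predict(X[held])
    value = rmse(y, y_hat)
    if not np.isfinite(value):
        raise ValueError("non-finite RMSECV")
    return value
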