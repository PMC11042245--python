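"""QSAR model benchmarking: ten regressors under seeded nested cross-validation.

The candidate set is the standard scikit-learn regression zoo for fingerprint
QSAR: k-nearest-neighbour, ridge, lasso, elastic net, decision tree, random
forest, extra trees, AdaBoost, gradient boosting and support vector
regression.  Each is evaluated with five-fold outer cross-validation; inside
every outer training set an exhaustive grid search is scored by inner
cross-validation (default 3-fold) mean test RMSE, so the held-out fold never
influences hyperparameter choice.  The champion is the model with the highest
mean test R², ties broken by the lowest mean test RMSE, then by name.

Metrics are the two regression criteria conventional in QSAR:

    R^2   = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2
    RMSE  = sqrt( sum_i (y_i - yhat_i)^2 / m )

computed from the defining sums (sklearn's versions serve only as an
independent cross-check in the tests).

Seed policy: one master seed deterministically derives the fold seed and one
model seed per specification (documented in :func:`derive_seed`), so every
cell of the benchmark table is reproducible from the master seed alone.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .fingerprints import FingerprintConfig

MODEL_NAMES = (
    "k_nearest_neighbour",
    "ridge",
    "lasso",
    "elastic_net",
    "decision_tree",
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
    "support_vector_regression",
)

_SEEDED = {
    "decision_tree",
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
}

#: default hyperparameter grids; deliberately compact and overridable via
#: config — grid contents are configuration, not science.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "k_nearest_neighbour": {"n_neighbors": [3, 5, 7]},
    "ridge": {"alpha": [0.01, 0.1, 1.0, 10.0]},
    "lasso": {"alpha": [0.001, 0.01, 0.1]},
    "elastic_net": {"alpha": [0.001, 0.01, 0.1], "l1_ratio": [0.5]},
    "decision_tree": {"max_depth": [None, 10]},
    "random_forest": {"n_estimators": [100, 300]},
    "extra_trees": {"n_estimators": [100, 300]},
    "adaboost": {"n_estimators": [50, 100]},
    "gradient_boosting": {"n_estimators": [100], "learning_rate": [0.05, 0.1]},
    "support_vector_regression": {"C": [1.0, 10.0], "gamma": ["scale"]},
}


def derive_seed(master_seed: int, purpose: str) -> int:
    """Deterministic sub-seed: CRC32 of the purpose tag mixed with the master."""
    return (master_seed * 2654435761 + zlib.crc32(purpose.encode())) % (2**31)


@dataclass(frozen=True)
class ModelSpec:
    """One named regressor plus its hyperparameter grid."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        object.__setattr__(
            self, "grid", dict(self.grid) or dict(DEFAULT_GRIDS[self.name])
        )
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        """Grid points in declaration order (the tie-break order)."""
        keys = list(self.grid)
        return [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]

    def build(self, params: dict, seed: int):
        cls = {
            "k_nearest_neighbour": KNeighborsRegressor,
            "ridge": Ridge,
            "lasso": Lasso,
            "elastic_net": ElasticNet,
            "decision_tree": DecisionTreeRegressor,
            "random_forest": RandomForestRegressor,
            "extra_trees": ExtraTreesRegressor,
            "adaboost": AdaBoostRegressor,
            "gradient_boosting": GradientBoostingRegressor,
            "support_vector_regression": SVR,
        }[self.name]
        kwargs = dict(params)
        if self.name in _SEEDED:
            kwargs["random_state"] = seed
        if self.name in {"lasso", "elastic_net"}:
            # sparse 0/1 descriptors converge slowly at weak regularisation
            kwargs.setdefault("max_iter", 20000)
        return cls(**kwargs)


def default_specs() -> list[ModelSpec]:
    return [ModelSpec(name=n) for n in MODEL_NAMES]


@dataclass(frozen=True)
class MetricPair:
    """R² and RMSE of one prediction set (RMSE in pChEMBL units)."""

    r2: float
    rmse: float
    m: int


class ConstantTargetError(ValueError):
    """R² is undefined when the actual values are constant."""


def metrics(y: Sequence[float], yhat: Sequence[float]) -> MetricPair:
    """R² and RMSE from their defining sums."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    m = y.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConstantTargetError("R² undefined: actual values are constant")
    return MetricPair(r2=1.0 - ss_res / ss_tot, rmse=math.sqrt(ss_res / m), m=m)


def kfold_partition(ids: Sequence, k: int = 5, seed: int = 0) -> list[list]:
    """Seeded partition into k disjoint folds with sizes differing by <= 1."""
    ids = list(ids)
    n = len(ids)
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    folds, start = [], 0
    for size in sizes:
        folds.append([ids[j] for j in order[start : start + size]])
        start += size
    return folds


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    inner_k: int = 3,
    seed: int = 0,
) -> dict:
    """Exhaustive grid search scored by inner-CV mean test RMSE.

    Ties break to the earliest point in grid declaration order (strict
    improvement required to displace the incumbent).
    """
    n = len(y)
    if n < 2 * inner_k or float(np.std(y)) == 0.0:
        raise ValueError("training set too small or degenerate for grid search")
    folds = kfold_partition(list(range(n)), k=inner_k, seed=seed)
    model_seed = derive_seed(seed, f"grid:{spec.name}")
    best_params, best_score = None, math.inf
    for params in spec.grid_points():
        rmses = []
        for fold in folds:
            test_idx = np.asarray(fold)
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            model = spec.build(params, model_seed)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            rmses.append(math.sqrt(float(np.mean((y[test_idx] - pred) ** 2))))
        score = float(np.mean(rmses))
        if score < best_score:
            best_score, best_params = score, params
    return best_params


@dataclass
class FoldResult:
    train: MetricPair
    test: MetricPair
    params: dict


@dataclass
class CVSummary:
    """Per-fold metrics plus their means and standard deviations."""

    folds: list[FoldResult]

    def _agg(self, attr: str, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(getattr(f, attr), metric) for f in self.folds])
        return float(vals.mean()), float(vals.std(ddof=0))

    @property
    def test_r2(self) -> tuple[float, float]:
        return self._agg("test", "r2")

    @property
    def test_rmse(self) -> tuple[float, float]:
        return self._agg("test", "rmse")

    @property
    def train_r2(self) -> tuple[float, float]:
        return self._agg("train", "r2")

    @property
    def train_rmse(self) -> tuple[float, float]:
        return self._agg("train", "rmse")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    k: int = 5,
    inner_k: int = 3,
    seed: int = 0,
) -> CVSummary:
    """Nested cross-validation of one model.

    In every outer fold the hyperparameters come from :func:`grid_search` on
    the outer-training data only; train metrics are the refit model's
    predictions on the same outer-training data (documented choice).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    fold_seed = derive_seed(seed, "outer_folds")
    folds = kfold_partition(list(range(n)), k=k, seed=fold_seed)
    results = []
    for i, fold in enumerate(folds):
        test_idx = np.asarray(fold)
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(train_idx) < 2 or len(test_idx) < 2:
            raise ValueError(f"fold {i} too small to fit and score")
        params = grid_search(
            X[train_idx], y[train_idx], spec, inner_k=inner_k,
            seed=derive_seed(seed, f"inner:{i}"),
        )
        model = spec.build(params, derive_seed(seed, f"fit:{spec.name}:{i}"))
        model.fit(X[train_idx], y[train_idx])
        results.append(
            FoldResult(
                train=metrics(y[train_idx], model.predict(X[train_idx])),
                test=metrics(y[test_idx], model.predict(X[test_idx])),
                params=params,
            )
        )
    return CVSummary(folds=results)


@dataclass
class BenchmarkRow:
    name: str
    summary: CVSummary | None
    error: str | None = None


@dataclass
class BenchmarkTable:
    """One row per model, all evaluated under identical outer folds."""

    rows: list[BenchmarkRow]
    champion: str
    seed: int
    k: int
    inner_k: int

    def to_records(self) -> list[dict]:
        records = []
        for row in self.rows:
            if row.summary is None:
                records.append({"model": row.name, "error": row.error})
                continue
            s = row.summary
            records.append(
                {
                    "model": row.name,
                    "train_r2_mean": s.train_r2[0],
                    "train_r2_std": s.train_r2[1],
                    "test_r2_mean": s.test_r2[0],
                    "test_r2_std": s.test_r2[1],
                    "train_rmse_mean": s.train_rmse[0],
                    "train_rmse_std": s.train_rmse[1],
                    "test_rmse_mean": s.test_rmse[0],
                    "test_rmse_std": s.test_rmse[1],
                }
            )
        return records


def benchmark(
    X: np.ndarray,
    y: np.ndarray,
    specs: Sequence[ModelSpec] | None = None,
    k: int = 5,
    inner_k: int = 3,
    seed: int = 0,
) -> BenchmarkTable:
    """Benchmark all specs under identical folds and pick the champion.

    A spec that fails to fit is flagged and excluded from champion selection;
    the run continues.  Champion rule: max mean test R², then min mean test
    RMSE, then name order.
    """
    specs = list(specs) if specs is not None else default_specs()
    if len(specs) < 1:
        raise ValueError("need at least one model spec")
    rows = []
    for spec in specs:
        try:
            rows.append(BenchmarkRow(spec.name, cross_validate(X, y, spec, k, inner_k, seed)))
        except Exception as exc:  # noqa: BLE001 — flagged, not fatal
            rows.append(BenchmarkRow(spec.name, None, error=str(exc)))
    scored = [r for r in rows if r.summary is not None]
    if not scored:
        raise RuntimeError("every model failed to fit")
    champion = min(
        scored, key=lambda r: (-r.summary.test_r2[0], r.summary.test_rmse[0], r.name)
    ).name
    return BenchmarkTable(rows=rows, champion=champion, seed=seed, k=k, inner_k=inner_k)


@dataclass
class ModelHandle:
    """A fitted regressor plus the descriptor config and training provenance.

    Carrying the fingerprint config prevents scoring a library with a
    different descriptor; carrying the training keys/matrix enables the
    train/eval disjointness check and novelty annotation downstream.
    """

    spec_name: str
    params: dict
    estimator: object
    fingerprint_config: FingerprintConfig
    training_keys: list[str]
    training_matrix: np.ndarray
    training_labels: np.ndarray
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.zeros(0)
        return np.asarray(self.estimator.predict(X), dtype=float)

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "ModelHandle":
        try:
            handle = joblib.load(path)
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise RuntimeError(f"cannot deserialise model from {path}: {exc}") from exc
        if not isinstance(handle, ModelHandle):
            raise RuntimeError(f"{path} does not contain a model handle")
        return handle


def fit_final(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    params: dict | None = None,
    seed: int = 0,
    fingerprint_config: FingerprintConfig | None = None,
    training_keys: Sequence[str] | None = None,
    inner_k: int = 3,
) -> ModelHandle:
    """Fit one model on the full provided dataset for deployment.

    If params is None a grid search on the whole set chooses them.  The
    returned handle is serialisable and reload-stable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if params is None:
        params = grid_search(X, y, spec, inner_k=inner_k, seed=derive_seed(seed, "final_grid"))
    model = spec.build(params, derive_seed(seed, f"final:{spec.name}"))
    model.fit(X, y)
    keys = list(training_keys) if training_keys is not None else [str(i) for i in range(len(y))]
    return ModelHandle(
        spec_name=spec.name,
        params=dict(params),
        estimator=model,
        fingerprint_config=fingerprint_config or FingerprintConfig(),
        training_keys=keys,
        training_matrix=X.astype(np.uint8) if X.max() <= 1 else X,
        training_labels=y,
        seed=seed,
    )
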