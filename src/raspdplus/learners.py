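"""Feature tables, robust scaling, regression models, and nested CV.

The evaluation protocol is a nested cross-validation: in an outer loop the
data set is split ``replicates`` times into a random test set (12.5% of
rows) and a cross-validation pool; in an inner loop a 6-fold CV grid search
picks each method's hyperparameters by mean validation Pearson r.  The six
winning-fold models of every replicate are then evaluated on that
replicate's test set, so each method is summarized by the mean and standard
deviation over ``replicates x inner_folds`` (by default 60) models.

Feature scaling is robust (median/IQR), fitted on training rows only inside
every split, so no test information leaks into training.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from raspdplus.ligand_features import LIGAND_FEATURE_NAMES
from raspdplus.pocket_features import POCKET_FEATURE_NAMES

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureTable",
    "ScalerParams",
    "robust_scale_fit",
    "robust_scale_apply",
    "MetricSet",
    "metrics",
    "ModelSpec",
    "DEFAULT_GRIDS",
    "METHODS",
    "default_specs",
    "train",
    "predict",
    "nested_cv",
    "CVReport",
    "NullModel",
]

#: Canonical 20-feature schema: six ligand + fourteen pocket descriptors.
FEATURE_COLUMNS: tuple[str, ...] = LIGAND_FEATURE_NAMES + POCKET_FEATURE_NAMES

METHODS = ("null", "LR", "kNN", "lSVR", "SVR", "DNN", "RF", "eRF")


@dataclass
class FeatureTable:
    """Rows = complexes; X = named features; y = binding dG in kcal/mol."""

    ids: list[str]
    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(self.X) or len(self.X) != len(self.y):
            raise ValueError("ids, X, and y must have equal length")
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")

    def __len__(self) -> int:
        return len(self.y)

    def subset_features(self, columns: Sequence[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.X.columns]
        if missing:
            raise ValueError(f"unknown feature name(s): {missing}")
        return FeatureTable(self.ids, self.X[list(columns)].copy(), self.y.copy())


# ---------------------------------------------------------------------------
# robust scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalerParams:
    """Per-column median and IQR, fitted on training rows only."""

    median: np.ndarray
    iqr: np.ndarray  # entries of 1.0 where the raw IQR was zero (center only)


def robust_scale_fit(X_train: np.ndarray | pd.DataFrame) -> ScalerParams:
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    med = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    iqr = q75 - q25
    zero = iqr == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} constant feature column(s): centering only",
            stacklevel=2,
        )
        iqr = np.where(zero, 1.0, iqr)
    return ScalerParams(median=med, iqr=iqr)


def robust_scale_apply(params: ScalerParams, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.median) / params.iqr


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    """RMSE (kcal/mol), Pearson r, Spearman rho, R^2, and Q^2_F3."""

    rmse: float
    r: float
    rho: float
    r2: float
    qf32: float

    def as_dict(self) -> dict[str, float]:
        return {"RMSE": self.rmse, "r": self.r, "rho": self.rho,
                "R2": self.r2, "QF32": self.qf32}


def metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_train: np.ndarray,
    qf32_variant: str = "consonni",
) -> MetricSet:
    """All five evaluation metrics for one test split.

    ``qf32_variant`` selects the external-validation coefficient:
    ``"consonni"`` (default) normalizes the test residual mean square by the
    training variance around the training mean,

        Q2F3 = 1 - [sum_test (yhat - y)^2 / n_test]
                 / [sum_train (y - ybar_train)^2 / n_train];

    ``"test-denominator"`` instead divides by the test-set sum of squared
    deviations of predictions from the training mean (an alternative reading
    of the formula as sometimes printed).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    if len(y_true) < 3:
        raise ValueError("need at least 3 test pairs")

    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))

    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(y_true, y_pred)[0])
        rho = float(stats.spearmanr(y_true, y_pred)[0])

    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    train_mean = float(y_train.mean())
    if qf32_variant == "consonni":
        denom = float(np.sum((y_train - train_mean) ** 2)) / len(y_train)
        qf32 = 1.0 - (ss_res / len(y_true)) / denom if denom > 0 else float("nan")
    elif qf32_variant == "test-denominator":
        denom = float(np.sum((y_pred - train_mean) ** 2))
        qf32 = 1.0 - ss_res / denom if denom > 0 else float("nan")
    else:
        raise ValueError(f"unknown qf32 variant {qf32_variant!r}")
    return MetricSet(rmse=rmse, r=r, rho=rho, r2=r2, qf32=qf32)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

class NullModel:
    """Predicts the training-set mean dG for every input."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NullModel":
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.mean_)


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "null": {},
    "LR": {},
    "kNN": {"n_neighbors": [1, 3, 5, 7, 11, 15, 21]},
    "lSVR": {"C": [0.1, 1, 10, 100], "epsilon": [0.01, 0.1, 0.5]},
    "SVR": {"C": [0.1, 1, 10, 100], "epsilon": [0.01, 0.1, 0.5],
            "gamma": ["scale", 0.01, 0.1]},
    # MLPRegressor has no dropout layer; L2 weight decay (alpha) plays the
    # analogous regularization role in the grid.
    "DNN": {"hidden_layer_sizes": [(32, 32), (64, 64), (128, 128)],
            "alpha": [1e-4, 1e-2]},
    "RF": {"n_estimators": [100, 200, 500], "max_features": [1.0, "sqrt"]},
    "eRF": {"n_estimators": [100, 200, 500], "max_features": [1.0, "sqrt"]},
}


@dataclass
class ModelSpec:
    """One learner: method name, hyperparameter grid, and RNG seed."""

    method: str
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.method].items()}

    def candidates(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = sorted(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def default_specs(
    methods: Iterable[str] = ("null", "LR", "kNN", "lSVR", "SVR", "RF", "eRF"),
    seed: int = 0,
    grids: dict[str, dict] | None = None,
) -> list[ModelSpec]:
    """Specs for the requested methods; DNN is opt-in (heavier training)."""
    grids = grids or {}
    return [ModelSpec(m, grid=grids.get(m), seed=seed) for m in methods]


def _build_estimator(method: str, params: dict, seed: int):
    if method == "null":
        return NullModel()
    if method == "LR":
        return LinearRegression(**params)
    if method == "kNN":
        return KNeighborsRegressor(**params)
    if method == "lSVR":
        return SVR(kernel="linear", **params)
    if method == "SVR":
        return SVR(kernel="rbf", **params)
    if method == "DNN":
        return MLPRegressor(max_iter=500, early_stopping=True,
                            random_state=seed, **params)
    if method == "RF":
        return RandomForestRegressor(random_state=seed, **params)
    if method == "eRF":
        defaults = {"n_estimators": 200, "min_samples_leaf": 1}
        defaults.update(params)
        return ExtraTreesRegressor(random_state=seed, **defaults)
    raise ValueError(f"unknown method {method!r}")


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray, params: dict | None = None):
    """Fit one model on (already scaled) features; returns the handle."""
    candidate = params if params is not None else (spec.candidates()[0])
    est = _build_estimator(spec.method, candidate, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SVR/MLP convergence chatter
        est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return est


def predict(handle, X: np.ndarray) -> np.ndarray:
    return np.asarray(handle.predict(np.asarray(X, dtype=float)), dtype=float)


def _complexity_key(params: dict) -> tuple:
    """Tie-break order: simplest model first.

    Fewer trees, stronger regularization (smaller C, larger epsilon/alpha),
    smoother kNN (larger k), smaller networks; then a lexicographic fallback.
    """
    return (
        params.get("n_estimators", 0),
        params.get("C", 0.0),
        -params.get("epsilon", 0.0),
        -params.get("alpha", 0.0),
        -params.get("n_neighbors", 0),
        sum(params.get("hidden_layer_sizes", (0,))),
        repr(sorted(params.items())),
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """A trained model plus the scaler fitted on its training rows."""

    estimator: object
    scaler: ScalerParams
    train_index: np.ndarray
    y_train: np.ndarray

    def predict(self, X_raw: np.ndarray | pd.DataFrame) -> np.ndarray:
        return predict(self.estimator, robust_scale_apply(self.scaler, X_raw))


@dataclass
class ReplicateResult:
    """One outer split: test rows, selected hyperparameters, fold models."""

    test_index: np.ndarray
    best_params: dict
    inner_validation_r: float
    fold_models: list[FoldModel]
    test_metrics: list[MetricSet]


@dataclass
class CVReport:
    """Nested-CV outcome: per-method, per-replicate results and aggregates."""

    methods: dict[str, list[ReplicateResult]]
    feature_names: tuple[str, ...]
    seed: int
    n_rows: int

    def n_models(self, method: str) -> int:
        return sum(len(rep.fold_models) for rep in self.methods[method])

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of each metric over all fold models, per method."""
        rows = []
        for method, reps in self.methods.items():
            per_model = [m.as_dict() for rep in reps for m in rep.test_metrics]
            frame = pd.DataFrame(per_model)
            row: dict[str, float | str] = {"method": method,
                                           "n_models": len(per_model)}
            for col in frame.columns:
                row[f"{col}_mean"] = frame[col].mean()
                row[f"{col}_sd"] = frame[col].std(ddof=1)
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")

    def predict(
        self, method: str, X_raw: np.ndarray | pd.DataFrame, replicate: int = 0
    ) -> np.ndarray:
        """Score new rows: average the predictions of one replicate's folds."""
        reps = self.methods[method]
        models = reps[replicate].fold_models
        return np.mean([fm.predict(X_raw) for fm in models], axis=0)


def nested_cv(
    table: FeatureTable,
    specs: Sequence[ModelSpec],
    replicates: int = 10,
    test_frac: float = 0.125,
    inner_folds: int = 6,
    seed: int = 0,
    qf32_variant: str = "consonni",
) -> CVReport:
    """Run the full nested cross-validation protocol.

    For each of ``replicates`` outer draws, ``round(n * test_frac)`` rows are
    held out for testing and the remainder is split into ``inner_folds``
    shuffled folds.  Hyperparameters maximizing the mean inner-validation
    Pearson r are selected per replicate (ties go to the simplest model), the
    winning configuration is trained once per fold, and all fold models are
    evaluated on the replicate's test rows.  Scaling is fitted inside every
    fold on its training rows only.
    """
    n = len(table)
    if n < 48:
        raise ValueError(f"need at least 48 rows, got {n}")
    X_all = table.X.to_numpy(dtype=float)
    y_all = table.y
    n_test = int(round(n * test_frac))
    if n_test < 3:
        raise ValueError("test split too small for metrics")

    master = np.random.default_rng(seed)
    results: dict[str, list[ReplicateResult]] = {s.method: [] for s in specs}

    for _rep in range(replicates):
        perm = master.permutation(n)
        test_idx = np.sort(perm[:n_test])
        pool_idx = np.sort(perm[n_test:])
        kf_seed = int(master.integers(2**31))
        folds = list(
            KFold(n_splits=inner_folds, shuffle=True, random_state=kf_seed).split(
                pool_idx
            )
        )

        for spec in specs:
            candidates = sorted(spec.candidates(), key=_complexity_key)
            # -- inner grid search ----------------------------------------
            best_params, best_score = None, -np.inf
            if len(candidates) == 1:  # nothing to select
                best_params, best_score = candidates[0], float("nan")
            for params in candidates if best_params is None else []:
                fold_scores = []
                failed = False
                for tr, va in folds:
                    tr_idx, va_idx = pool_idx[tr], pool_idx[va]
                    scaler = _fit_scaler_quiet(X_all[tr_idx])
                    try:
                        est = train(spec, robust_scale_apply(scaler, X_all[tr_idx]),
                                    y_all[tr_idx], params)
                    except Exception as exc:
                        warnings.warn(
                            f"{spec.method} candidate {params} failed: {exc}",
                            stacklevel=2,
                        )
                        failed = True
                        break
                    pred = predict(est, robust_scale_apply(scaler, X_all[va_idx]))
                    fold_scores.append(_safe_pearson(y_all[va_idx], pred))
                if failed:
                    continue
                finite = [s for s in fold_scores if not math.isnan(s)]
                score = float(np.mean(finite)) if finite else -np.inf
                if score > best_score:
                    best_score, best_params = score, params
            if best_params is None:
                best_params = candidates[0]
                best_score = float("nan")

            # -- train winning configuration per fold, evaluate on test ---
            fold_models: list[FoldModel] = []
            test_metrics: list[MetricSet] = []
            for tr, _va in folds:
                tr_idx = pool_idx[tr]
                scaler = _fit_scaler_quiet(X_all[tr_idx])
                est = train(spec, robust_scale_apply(scaler, X_all[tr_idx]),
                            y_all[tr_idx], best_params)
                fm = FoldModel(est, scaler, tr_idx, y_all[tr_idx])
                fold_models.append(fm)
                pred = predict(est, robust_scale_apply(scaler, X_all[test_idx]))
                test_metrics.append(
                    metrics(y_all[test_idx], pred, y_all[tr_idx],
                            qf32_variant=qf32_variant)
                )
            results[spec.method].append(
                ReplicateResult(test_idx, best_params, best_score,
                                fold_models, test_metrics)
            )

    return CVReport(results, tuple(table.X.columns), seed, n)


def _fit_scaler_quiet(X: np.ndarray) -> ScalerParams:
    """Fit the robust scaler without repeating constant-column warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return robust_scale_fit(X)


# ---------------------------------------------------------------------------
# feature-table assembly from structures
# ---------------------------------------------------------------------------

def assemble_feature_table(records, grid: float = 0.5) -> FeatureTable:
    """Featurize complex records into the canonical 20-column table.

    The pocket center is the reference ligand's center of mass, and each
    ligand supplies its own maxD.  Records lacking a dG are rejected.
    """
    from raspdplus.ligand_features import ligand_descriptors, max_distance
    from raspdplus.pocket_features import pocket_descriptors
    from raspdplus.structio import _atomic_mass

    ids, rows, ys = [], [], []
    for record in records:
        if record.dG is None:
            raise ValueError(f"complex {record.id!r} has no affinity/dG")
        lig = record.ligand
        coords = lig.coordinates
        masses = np.array([_atomic_mass(el) for el in lig.elements])
        center = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        ligdesc = ligand_descriptors(lig)
        maxd = ligdesc.maxD if ligdesc.maxD is not None else max_distance(lig)
        pocket = pocket_descriptors(record.protein, center, maxd, grid=grid)
        row = ligdesc.as_dict()
        row.update(pocket.as_dict())
        ids.append(record.id)
        rows.append([row[c] for c in FEATURE_COLUMNS])
        ys.append(record.dG)
    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return FeatureTable(ids, X, np.asarray(ys, dtype=float))
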