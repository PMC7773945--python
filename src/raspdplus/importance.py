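"""Permutation feature importance and feature-ablation retraining.

Importance of a feature is measured as the drop in test-set Pearson r when
that feature's column is shuffled (five seeded shuffles by default); larger
positive values mean the prediction leans harder on the feature.  Ablation
retrains the full nested-CV protocol on named feature subsets (single
features, ligand-only, protein-only) to bound how much signal each block of
descriptors carries on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from raspdplus.learners import (
    CVReport,
    FeatureTable,
    ModelSpec,
    nested_cv,
    _safe_pearson,
)
from raspdplus.ligand_features import LIGAND_FEATURE_NAMES
from raspdplus.pocket_features import POCKET_FEATURE_NAMES

__all__ = [
    "ImportanceReport",
    "permutation_importance",
    "ablation_models",
    "ABLATION_PRESETS",
]

#: Standard ablation subsets: single strongest descriptors, ligand block,
#: protein block, and the full 20-feature model.
ABLATION_PRESETS: dict[str, tuple[str, ...]] = {
    "MR only": ("MR",),
    "MASS only": ("MASS",),
    "ligand only": LIGAND_FEATURE_NAMES,
    "protein only": POCKET_FEATURE_NAMES,
    "all": LIGAND_FEATURE_NAMES + POCKET_FEATURE_NAMES,
}


@dataclass
class ImportanceReport:
    """Per-feature mean/sd of (baseline r - shuffled r) over the shuffles."""

    feature_names: tuple[str, ...]
    baseline_r: float
    delta_r_mean: np.ndarray
    delta_r_sd: np.ndarray
    n_shuffles: int
    model_id: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "delta_r_mean": self.delta_r_mean,
                "delta_r_sd": self.delta_r_sd,
            }
        ).set_index("feature")

    def ranking(self) -> list[str]:
        """Features from most to least important."""
        order = np.argsort(-self.delta_r_mean, kind="stable")
        return [self.feature_names[i] for i in order]


def permutation_importance(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    X_test: np.ndarray | pd.DataFrame,
    y_test: np.ndarray,
    feature_names: Sequence[str] | None = None,
    n_shuffles: int = 5,
    seed: int = 0,
    model_id: str = "",
) -> ImportanceReport:
    """Permutation importance on a held-out test set.

    ``predict_fn`` maps a feature matrix (same column order and scaling as
    training) to predictions; training data is never touched.  Each feature
    column is shuffled within the test set ``n_shuffles`` times and the mean
    change in Pearson r (baseline minus shuffled) is recorded.
    """
    if isinstance(X_test, pd.DataFrame):
        feature_names = feature_names or tuple(X_test.columns)
        X_test = X_test.to_numpy(dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(X_test) < 10:
        raise ValueError("need at least 10 test rows")
    if np.ptp(y_test) == 0:
        raise ValueError("constant y_test: Pearson r undefined")
    n_features = X_test.shape[1]
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(n_features))

    baseline = _safe_pearson(y_test, np.asarray(predict_fn(X_test), dtype=float))
    rng = np.random.default_rng(seed)
    deltas = np.empty((n_features, n_shuffles))
    for j in range(n_features):
        for s in range(n_shuffles):
            shuffled = X_test.copy()
            shuffled[:, j] = rng.permutation(shuffled[:, j])
            r_shuf = _safe_pearson(
                y_test, np.asarray(predict_fn(shuffled), dtype=float)
            )
            if np.isnan(r_shuf):
                r_shuf = 0.0  # constant predictions carry no correlation
            deltas[j, s] = baseline - r_shuf

    return ImportanceReport(
        feature_names=tuple(feature_names),
        baseline_r=baseline,
        delta_r_mean=deltas.mean(axis=1),
        delta_r_sd=deltas.std(axis=1, ddof=1),
        n_shuffles=n_shuffles,
        model_id=model_id,
    )


def ablation_models(
    table: FeatureTable,
    spec: ModelSpec,
    subsets: dict[str, Sequence[str]] | None = None,
    replicates: int = 10,
    test_frac: float = 0.125,
    inner_folds: int = 6,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Retrain one method on each named feature subset, identical protocol.

    With the default presets this reproduces the MR-only / MASS-only /
    ligand-only / protein-only / all-features comparison.
    """
    subsets = dict(subsets) if subsets is not None else dict(ABLATION_PRESETS)
    reports: dict[str, CVReport] = {}
    for name, columns in subsets.items():
        if len(columns) == 0:
            raise ValueError(f"subset {name!r} is empty")
        sub = table.subset_features(columns)
        reports[name] = nested_cv(
            sub, [spec], replicates=replicates, test_frac=test_frac,
            inner_folds=inner_folds, seed=seed,
        )
    return reports
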