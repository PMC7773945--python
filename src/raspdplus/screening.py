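"""Virtual-screening scoring, enrichment factors, and union ensembles.

A library of query ligands is scored against a fixed binding-site center:
each molecule contributes its own ligand descriptors and its own maxD-sized
pocket descriptors, the trained fold models of one replicate are averaged,
and molecules are ranked by predicted dG (lower = stronger predicted
binding).  Enrichment factors quantify how much better the top-ranked
fraction is populated with known actives than the library at large, and
union ensembles combine the top sets of several methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from raspdplus.learners import CVReport, FEATURE_COLUMNS
from raspdplus.ligand_features import ligand_descriptors
from raspdplus.pocket_features import cofactor_in_pocket, pocket_descriptors
from raspdplus.structio import MolecularGraph, ProteinStructure

__all__ = [
    "EnrichmentResult",
    "ScreenResult",
    "enrichment_factor",
    "union_selection",
    "screen",
    "UNION_PRESETS",
]

#: Named method combinations for union ensembles.
UNION_PRESETS: dict[str, tuple[str, ...]] = {
    "union": ("LR", "kNN", "lSVR", "SVR", "DNN", "RF", "eRF"),
    "union_wo_knn": ("LR", "lSVR", "SVR", "DNN", "RF", "eRF"),
    "union_top3": ("LR", "lSVR", "SVR"),
}


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of actives in the top-scored fraction of a library."""

    fraction: float  # percent of the library selected
    ef: float
    n_selected: int
    n_active_selected: int
    n_total: int
    n_active_total: int


def _top_ids(
    scores: Mapping[str, float], n_sel: int
) -> list[str]:
    """Best-scored ids (ascending score = best first); ties stable by id."""
    return [mid for mid, _ in sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))][
        :n_sel
    ]


def enrichment_factor(
    scores: Mapping[str, float],
    actives: Mapping[str, bool] | set[str],
    fraction: float,
) -> EnrichmentResult:
    """EF at a percentage cut: fraction of actives among the top-ranked
    ``ceil(fraction/100 * n)`` molecules divided by the active fraction of
    the whole library.  Lower score = better (predicted dG)."""
    if not (0 < fraction <= 100):
        raise ValueError(f"fraction must be in (0, 100], got {fraction}")
    if isinstance(actives, (set, frozenset)):
        actives = {mid: (mid in actives) for mid in scores}
    n_total = len(scores)
    n_active_total = sum(bool(actives.get(mid, False)) for mid in scores)
    if n_active_total == 0:
        raise ValueError("no active molecules in the library")
    n_sel = math.ceil(fraction / 100 * n_total)
    selected = _top_ids(scores, n_sel)
    n_active_selected = sum(bool(actives.get(mid, False)) for mid in selected)
    ef = (n_active_selected / n_sel) / (n_active_total / n_total)
    return EnrichmentResult(
        fraction=fraction,
        ef=ef,
        n_selected=n_sel,
        n_active_selected=n_active_selected,
        n_total=n_total,
        n_active_total=n_active_total,
    )


def union_selection(
    per_method_scores: Mapping[str, Mapping[str, float]],
    actives: Mapping[str, bool] | set[str],
    fraction: float,
    methods: Sequence[str] | None = None,
) -> tuple[set[str], EnrichmentResult]:
    """Union-of-top-sets ensemble: pool the top ``fraction``% of each method.

    The enrichment factor of the union is computed with the union size as
    the selected count (it can exceed the single-method selection size).
    """
    if methods is None:
        methods = list(per_method_scores)
    if len(methods) == 0:
        raise ValueError("empty method list")
    missing = [m for m in methods if m not in per_method_scores]
    if missing:
        raise ValueError(f"no scores for method(s): {missing}")

    any_scores = per_method_scores[methods[0]]
    n_total = len(any_scores)
    if isinstance(actives, (set, frozenset)):
        actives = {mid: (mid in actives) for mid in any_scores}
    n_active_total = sum(bool(v) for v in actives.values())
    if n_active_total == 0:
        raise ValueError("no active molecules in the library")

    n_sel = math.ceil(fraction / 100 * n_total)
    union: set[str] = set()
    for method in methods:
        union |= set(_top_ids(per_method_scores[method], n_sel))
    n_active_selected = sum(bool(actives.get(mid, False)) for mid in union)
    ef = (n_active_selected / len(union)) / (n_active_total / n_total)
    return union, EnrichmentResult(
        fraction=fraction,
        ef=ef,
        n_selected=len(union),
        n_active_selected=n_active_selected,
        n_total=n_total,
        n_active_total=n_active_total,
    )


@dataclass
class ScreenResult:
    """Ranked screening table: one row per molecule, one score per method."""

    table: pd.DataFrame  # index = molecule id; columns = methods (+ is_active)
    skipped: list[tuple[str, str]]  # (id, reason)
    cofactor_flag: bool

    def scores(self, method: str) -> dict[str, float]:
        return self.table[method].to_dict()

    def ranking(self, method: str) -> list[str]:
        return list(self.table.sort_values(method).index)


def screen(
    protein: ProteinStructure,
    center: np.ndarray,
    library: Iterable[MolecularGraph],
    report: CVReport,
    methods: Sequence[str] | None = None,
    replicate: int = 0,
    actives: set[str] | None = None,
    grid: float = 0.5,
) -> ScreenResult:
    """Score a ligand library against one binding site.

    Every molecule is featurized independently (its score never depends on
    the rest of the library): ligand descriptors plus pocket descriptors
    computed at the fixed ``center`` with that molecule's own maxD.  Each
    method's score is the mean prediction of the chosen replicate's
    cross-validation fold models.  Featurization failures skip the molecule
    with a warning rather than aborting the screen.
    """
    if methods is None:
        methods = [m for m in report.methods if m != "null"]
    center = np.asarray(center, dtype=float)

    ids: list[str] = []
    rows: list[list[float]] = []
    skipped: list[tuple[str, str]] = []
    pocket_cache: dict[float, dict[str, float]] = {}
    max_maxd = 0.0
    for k, mol in enumerate(library):
        mol_id = mol.name or f"mol{k}"
        try:
            ligdesc = ligand_descriptors(mol)
            if ligdesc.maxD is None:
                raise ValueError("no 3D coordinates: cannot size the pocket sphere")
            maxd = round(ligdesc.maxD, 6)
            if maxd not in pocket_cache:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pocket_cache[maxd] = pocket_descriptors(
                        protein, center, maxd, grid=grid
                    ).as_dict()
            row = ligdesc.as_dict()
            row.update(pocket_cache[maxd])
        except Exception as exc:
            warnings.warn(f"skipping {mol_id}: {exc}", stacklevel=2)
            skipped.append((mol_id, str(exc)))
            continue
        max_maxd = max(max_maxd, maxd)
        ids.append(mol_id)
        rows.append([row[c] for c in FEATURE_COLUMNS])

    if not ids:
        raise ValueError("no molecule in the library could be featurized")
    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS), index=ids)
    if report.feature_names != tuple(FEATURE_COLUMNS):
        raise ValueError("models were not trained on the 20-feature schema")

    out = pd.DataFrame(index=ids)
    for method in methods:
        out[method] = report.predict(method, X, replicate=replicate)
    if actives is not None:
        out["is_active"] = [mid in actives for mid in ids]
    flag = cofactor_in_pocket(protein, center, max_maxd) if max_maxd > 0 else False
    return ScreenResult(table=out, skipped=skipped, cofactor_flag=flag)
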