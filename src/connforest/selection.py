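"""Importance-based feature selection inside the LOO loop.

Selection never sees the held-out subject: per fold, permutation
importance is computed on the N - 1 training subjects only, the top-k
features are kept, a fresh forest is refitted on the reduced columns, and
the held-out subject is scored with the band rule.  The consensus subset
collects features selected in at least half of the folds.

The dose-vs-dose contrast uses mutually exclusive features: those selected
in exactly one of the two drug-vs-control comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import FeatureMatrix
from .forestclass import (
    ComparisonSummary,
    DEFAULT_BAND,
    ForestParams,
    ImportanceRanking,
    SubjectPrediction,
    _fold_seed,
    classify_outcome,
    fit_forest,
    permutation_importance,
)

__all__ = [
    "FeatureSubset",
    "select_top_k",
    "nested_loo_with_selection",
    "k_sweep",
    "mutually_exclusive_features",
]


@dataclass
class FeatureSubset:
    """A set of selected features with provenance."""

    feature_ids: tuple[int, ...]
    comparison: str = ""
    k: int | None = None
    fold: int | str | None = None
    importances: dict[int, float] = field(default_factory=dict)
    fold_frequency: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __contains__(self, fid: int) -> bool:
        return int(fid) in set(self.feature_ids)

    def pairs(self, pair_index) -> list[tuple[int, int]]:
        return [pair_index.backtrack(f) for f in self.feature_ids]

    def regions(self, pair_index) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs(pair_index):
            out.update((i, j))
        return out

    def to_frame(self, pair_index=None, atlas=None) -> pd.DataFrame:
        rows = []
        for f in self.feature_ids:
            row: dict = {"feature_id": f}
            if pair_index is not None:
                i, j = pair_index.backtrack(f)
                row["region_i"], row["region_j"] = i, j
                if atlas is not None:
                    row["name_i"], row["side_i"] = atlas.name_side(i)
                    row["name_j"], row["side_j"] = atlas.name_side(j)
            if f in self.importances:
                row["importance"] = self.importances[f]
            if f in self.fold_frequency:
                row["fold_frequency"] = self.fold_frequency[f]
            rows.append(row)
        return pd.DataFrame(rows)


def select_top_k(ranking: ImportanceRanking, k: int, comparison: str = "") -> FeatureSubset:
    """Keep the k highest-importance features (ties by ascending index)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = ranking.top_columns(k)
    fids = tuple(int(ranking.feature_ids[c]) for c in cols)
    return FeatureSubset(
        fids, comparison=comparison, k=k,
        importances={int(ranking.feature_ids[c]): float(ranking.scores[c]) for c in cols},
    )


def _score_heldout(forest, features: FeatureMatrix, row: int, band) -> SubjectPrediction:
    frac = forest.vote_fractions(features.X[[row]])[0]
    classes = list(forest.classes)
    true_group = features.groups[row]
    p_true = float(frac[classes.index(true_group)])
    return SubjectPrediction(
        features.subject_ids[row], true_group, classes[int(np.argmax(frac))],
        p_true, classify_outcome(p_true, band),
    )


def nested_loo_with_selection(
    features: FeatureMatrix,
    k: int,
    params: ForestParams,
    band: tuple[float, float] = DEFAULT_BAND,
    comparison: str = "",
    consensus_threshold: float = 0.5,
) -> tuple[list[SubjectPrediction], ComparisonSummary, list[FeatureSubset], FeatureSubset]:
    """LOO with per-fold importance ranking, top-k selection and refit.

    Returns predictions, the summary, the per-fold subsets, and the
    consensus subset (features selected in >= ``consensus_threshold`` of
    folds).
    """
    n = features.n_subjects
    if n < 4:
        raise ValueError("LOO needs at least 4 subjects")
    if len(set(features.groups)) != 2:
        raise ValueError("nested LOO requires exactly 2 groups")

    preds: list[SubjectPrediction] = []
    fold_subsets: list[FeatureSubset] = []
    for i in range(n):
        train_rows = [r for r in range(n) if r != i]
        train = features.subset_subjects(train_rows)
        fs = _fold_seed(params.seed, i)
        fold_params = ForestParams(
            params.n_trees, params.features_per_split, params.min_leaf, fs
        )
        forest = fit_forest(train, fold_params)
        ranking = permutation_importance(forest, train, seed=fs)
        subset = select_top_k(ranking, k, comparison=comparison)
        fold_subsets.append(
            FeatureSubset(subset.feature_ids, comparison, k, fold=i,
                          importances=subset.importances)
        )
        # refit on the selected columns in ascending id order and with the
        # same fold seed, so k = p reproduces plain LOO exactly
        kept = sorted(subset.feature_ids)
        refit = fit_forest(train.subset_features(kept), fold_params)
        preds.append(_score_heldout(refit, features.subset_features(kept), i, band))

    freq: dict[int, int] = {}
    for sub in fold_subsets:
        for f in sub.feature_ids:
            freq[f] = freq.get(f, 0) + 1
    consensus_ids = tuple(sorted(f for f, c in freq.items() if c >= consensus_threshold * n))
    mean_imp: dict[int, float] = {}
    for f in consensus_ids:
        vals = [s.importances[f] for s in fold_subsets if f in s.importances]
        mean_imp[f] = float(np.mean(vals))
    consensus = FeatureSubset(
        consensus_ids, comparison, k, fold="consensus",
        importances=mean_imp,
        fold_frequency={f: freq[f] / n for f in consensus_ids},
    )

    name = comparison or " vs ".join(sorted(set(features.groups)))
    counts = {"correct": 0, "false": 0, "unclassified": 0}
    for pr in preds:
        counts[pr.outcome] += 1
    summary = ComparisonSummary(
        name, counts["correct"], counts["false"], counts["unclassified"], n,
        seed=params.seed,
    )
    return preds, summary, fold_subsets, consensus


def k_sweep(
    features: FeatureMatrix,
    ks: Sequence[int],
    params: ForestParams,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Nested-LOO counts for each requested subset size k (shared seed)."""
    if not len(ks):
        raise ValueError("ks must be non-empty")
    p = features.n_features
    rows = []
    for k in ks:
        if k > p:
            raise ValueError(f"k={k} exceeds feature count {p}")
        _, summary, _, _ = nested_loo_with_selection(features, k, params, band)
        rows.append(
            {"k": k, "correct": summary.correct, "false": summary.false,
             "unclassified": summary.unclassified, "n_subjects": summary.k}
        )
    return pd.DataFrame(rows)


def mutually_exclusive_features(
    subset_a: FeatureSubset,
    subset_b: FeatureSubset,
    level: str = "pair",
    pair_index=None,
    comparison: str = "",
) -> FeatureSubset:
    """Features present in exactly one of two comparisons' subsets.

    ``level="pair"`` (default) takes the symmetric difference of the two
    feature-id sets.  ``level="region"`` first forms each comparison's
    region set and keeps pairs (from either subset) touching a region that
    appears in exactly one comparison; this requires ``pair_index``.
    """
    a, b = set(subset_a.feature_ids), set(subset_b.feature_ids)
    if level == "pair":
        keep = a ^ b
    elif level == "region":
        if pair_index is None:
            raise ValueError("region-level exclusion requires a pair_index")
        excl_regions = subset_a.regions(pair_index) ^ subset_b.regions(pair_index)
        keep = {
            f for f in a | b
            if set(pair_index.backtrack(f)) & excl_regions
        }
    else:
        raise ValueError(f"unknown exclusion level {level!r}")
    if not keep:
        warnings.warn(
            "mutually exclusive feature set is empty; downstream classification "
            "will refuse to run on zero features",
            stacklevel=2,
        )
    imp = {**subset_b.importances, **subset_a.importances}
    return FeatureSubset(
        tuple(sorted(keep)),
        comparison=comparison or f"exclusive({subset_a.comparison}, {subset_b.comparison})",
        importances={f: imp[f] for f in sorted(keep) if f in imp},
    )
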