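"""Random-forest classification with LOO cross-validation and OOB statistics.

The forest engine is scikit-learn's ``RandomForestClassifier``; this module
wraps it to expose per-tree votes and per-tree bootstrap (in-bag) masks, on
top of which the out-of-bag error and the per-tree mean-increase
permutation importance are computed directly (the importance is *not*
impurity-based: for each tree, each feature is permuted on the tree's OOB
subjects and the increase in that tree's OOB misclassification rate is
averaged over trees).

Subjects are scored by vote fraction; a fraction inside the inclusive band
[0.45, 0.55] is "unclassified", above it "correct", below it "false".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .connectivity import FeatureMatrix

__all__ = [
    "ForestParams",
    "ForestModel",
    "SubjectPrediction",
    "ImportanceRanking",
    "ComparisonSummary",
    "DEFAULT_BAND",
    "fit_forest",
    "oob_error",
    "permutation_importance",
    "loo_classify",
    "classify_outcome",
]

DEFAULT_BAND = (0.45, 0.55)


@dataclass(frozen=True)
class ForestParams:
    """Forest hyper-parameters; defaults follow the conventional RF setup."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"  # floor(sqrt(p)), min 1
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class ForestModel:
    """Fitted forest with per-tree in-bag bookkeeping."""

    rf: RandomForestClassifier
    classes: np.ndarray
    in_bag: np.ndarray  # (n_trees, n_train) bootstrap counts
    params: ForestParams
    n_train: int

    def encode(self, groups: Sequence[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[g] for g in groups])

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """Per-tree predicted class indices, shape (n_trees, n_samples)."""
        X = np.asarray(X, dtype=float)
        return np.vstack(
            [est.predict(X).astype(int) for est in self.rf.estimators_]
        )

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting each class, shape (n_samples, n_classes)."""
        votes = self.tree_votes(X)
        n_classes = len(self.classes)
        frac = np.empty((X.shape[0], n_classes))
        for c in range(n_classes):
            frac[:, c] = (votes == c).mean(axis=0)
        return frac


def fit_forest(features: FeatureMatrix, params: ForestParams) -> ForestModel:
    """Fit a bootstrap forest on the training subjects; deterministic per seed."""
    # single-class training is an error; one subject per class is allowed
    # because LOO at N=4 necessarily trains on a 2+1 split
    counts = pd.Series(features.groups).value_counts()
    if len(counts) < 2:
        raise ValueError("training set contains a single class")
    rf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.features_per_split,
        min_samples_leaf=params.min_leaf,
        bootstrap=True,
        random_state=params.seed,
        n_jobs=1,
    )
    y = np.asarray(features.groups)
    rf.fit(features.X, y)
    n = features.n_subjects
    in_bag = np.zeros((params.n_trees, n), dtype=int)
    for t, idx in enumerate(rf.estimators_samples_):
        np.add.at(in_bag[t], idx, 1)
    return ForestModel(rf, rf.classes_, in_bag, params, n)


def oob_error(forest: ForestModel, features: FeatureMatrix) -> float:
    """Proportion of training subjects misclassified by their OOB trees."""
    X = features.X
    if X.shape[0] != forest.n_train:
        raise ValueError("features do not match the training set")
    y = forest.encode(features.groups)
    votes = forest.tree_votes(X)  # (n_trees, n)
    oob_mask = forest.in_bag == 0
    n_classes = len(forest.classes)

    wrong = 0
    included = 0
    for i in range(X.shape[0]):
        trees = np.where(oob_mask[:, i])[0]
        if trees.size == 0:
            warnings.warn(
                f"subject {features.subject_ids[i]!r} was in-bag for every tree; "
                "excluded from the OOB error",
                stacklevel=2,
            )
            continue
        tally = np.bincount(votes[trees, i], minlength=n_classes)
        pred = int(np.argmax(tally))  # ties -> lowest class index
        included += 1
        wrong += int(pred != y[i])
    if included == 0:
        raise ValueError("no subject has out-of-bag trees; increase n_trees")
    return wrong / included


@dataclass
class ImportanceRanking:
    """Permutation importance per feature with a deterministic ranking."""

    scores: np.ndarray  # mean per-tree OOB error increase, by column
    feature_ids: np.ndarray  # pair-index ids, aligned with scores
    ranks: np.ndarray  # permutation of 1..p; 1 = most important

    @classmethod
    def from_scores(cls, scores: np.ndarray, feature_ids: np.ndarray) -> "ImportanceRanking":
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((np.arange(scores.size), -scores))
        ranks = np.empty(scores.size, dtype=int)
        ranks[order] = np.arange(1, scores.size + 1)
        return cls(scores, np.asarray(feature_ids, dtype=int), ranks)

    def top_columns(self, k: int) -> np.ndarray:
        """Column positions of the k best features (ties by ascending index)."""
        order = np.lexsort((np.arange(self.scores.size), -self.scores))
        return order[: min(k, self.scores.size)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "importance": self.scores,
             "rank": self.ranks}
        )


def permutation_importance(
    forest: ForestModel, features: FeatureMatrix, seed: int | None = None
) -> ImportanceRanking:
    """Per-tree mean-increase OOB permutation importance.

    For every tree and every feature, the feature's values are permuted
    across the tree's OOB subjects and the increase of that tree's OOB
    misclassification rate is recorded; the importance of a feature is the
    mean increase over trees.  A feature a tree never splits on cannot
    change its predictions, so its contribution from that tree is exactly
    0 — which also makes constant features score exactly 0.
    """
    X = features.X
    if X.shape[0] != forest.n_train:
        raise ValueError("features do not match the training set")
    y = forest.encode(features.groups)
    rng = np.random.default_rng(forest.params.seed if seed is None else seed)

    p = X.shape[1]
    total = np.zeros(p)
    n_used = 0
    for t, est in enumerate(forest.rf.estimators_):
        oob = np.where(forest.in_bag[t] == 0)[0]
        if oob.size == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y[oob]
        base = np.mean(est.predict(Xo).astype(int) != yo)
        used = np.unique(est.tree_.feature[est.tree_.feature >= 0])
        for f in used:
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            total[f] += np.mean(est.predict(Xp).astype(int) != yo) - base
    if n_used == 0:
        raise ValueError("no tree has out-of-bag subjects")
    return ImportanceRanking.from_scores(total / n_used, features.feature_ids)


@dataclass
class SubjectPrediction:
    subject_id: str
    true_group: str
    predicted_group: str
    p_true: float
    outcome: str  # correct | false | unclassified


@dataclass
class ComparisonSummary:
    comparison: str
    correct: int
    false: int
    unclassified: int
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.correct + self.false + self.unclassified != self.k:
            raise ValueError("outcome counts must sum to k")

    @property
    def accuracy(self) -> float:
        return self.correct / self.k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"comparison": self.comparison, "correct": self.correct,
              "false": self.false, "unclassified": self.unclassified,
              "k": self.k, "accuracy": self.accuracy, "seed": self.seed}]
        )


def classify_outcome(p_true: float, band: tuple[float, float] = DEFAULT_BAND) -> str:
    """Band rule: inside the inclusive band -> unclassified."""
    lo, hi = band
    if p_true > hi:
        return "correct"
    if p_true < lo:
        return "false"
    return "unclassified"


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def loo_classify(
    features: FeatureMatrix,
    params: ForestParams,
    band: tuple[float, float] = DEFAULT_BAND,
    comparison: str = "",
) -> tuple[list[SubjectPrediction], ComparisonSummary]:
    """Leave-one-out classification with the vote-fraction band rule.

    Each subject is held out once; a fresh forest is fitted on the other
    N - 1 subjects (per-fold seeds derived from ``params.seed``) and the
    held-out subject is scored by the fraction of trees voting for its true
    group.
    """
    n = features.n_subjects
    if n < 4:
        raise ValueError("LOO needs at least 4 subjects")
    if len(set(features.groups)) != 2:
        raise ValueError("LOO classification requires exactly 2 groups")

    preds: list[SubjectPrediction] = []
    for i in range(n):
        train = [r for r in range(n) if r != i]
        fold_params = ForestParams(
            params.n_trees, params.features_per_split, params.min_leaf,
            _fold_seed(params.seed, i),
        )
        forest = fit_forest(features.subset_subjects(train), fold_params)
        frac = forest.vote_fractions(features.X[[i]])[0]
        classes = list(forest.classes)
        true_group = features.groups[i]
        p_true = float(frac[classes.index(true_group)])
        predicted = classes[int(np.argmax(frac))]
        preds.append(
            SubjectPrediction(
                features.subject_ids[i], true_group, predicted, p_true,
                classify_outcome(p_true, band),
            )
        )

    name = comparison or " vs ".join(sorted(set(features.groups)))
    counts = {"correct": 0, "false": 0, "unclassified": 0}
    for pr in preds:
        counts[pr.outcome] += 1
    summary = ComparisonSummary(
        name, counts["correct"], counts["false"], counts["unclassified"], n,
        seed=params.seed,
    )
    return preds, summary
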