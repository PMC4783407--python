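"""All-pairs correlation features with a backtrackable pair index.

A subject's connectivity profile is the upper triangle (row-major, i < j)
of the ROI-by-ROI Pearson correlation matrix, Fisher z-transformed.  The
:class:`PairIndex` bijection maps each flat feature index back to its ROI
pair so selected features can always be resolved to named regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairIndex",
    "ConnectivityProfile",
    "FeatureMatrix",
    "pearson",
    "fisher_z",
    "connectivity_profile",
    "build_feature_matrix",
]

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class PairIndex:
    """Bijection between flat feature index k and unordered ROI pair (i, j).

    Region ids are 1-based; pairs are enumerated in row-major upper-triangle
    order: (1,2), (1,3), ..., (1,R), (2,3), ...
    """

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    def __len__(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_regions, k=1)
        return [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju)]

    def index_of(self, region_i: int, region_j: int) -> int:
        i, j = sorted((region_i, region_j))
        if i == j or not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions):
            raise KeyError(f"invalid region pair ({region_i}, {region_j})")
        i0, j0 = i - 1, j - 1
        r = self.n_regions
        return i0 * r - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)

    def backtrack(self, k: int) -> tuple[int, int]:
        if not 0 <= k < len(self):
            raise KeyError(f"feature index {k} out of range 0..{len(self) - 1}")
        r = self.n_regions
        i0 = 0
        offset = k
        while offset >= r - 1 - i0:
            offset -= r - 1 - i0
            i0 += 1
        return i0 + 1, i0 + offset + 2


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length series."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0 or sy == 0:
        raise ValueError("constant series has undefined correlation")
    return float((xd @ yd) / (sx * sy))


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform, z = 0.5 * log((1 + rho) / (1 - rho)).

    |rho| is clipped to 1 - 1e-7 so perfectly correlated degenerate inputs
    stay finite; values outside [-1, 1] are rejected.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    r = np.clip(r, -_CLIP, _CLIP)
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    return float(z) if np.isscalar(rho) or z.ndim == 0 else z


@dataclass
class ConnectivityProfile:
    """Fisher-z connectivity vector for one subject."""

    subject_id: str
    group: str
    z_values: np.ndarray
    pair_index: PairIndex

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.z_values.shape != (len(self.pair_index),):
            raise ValueError(
                f"expected {len(self.pair_index)} features, got {self.z_values.shape}"
            )
        if not np.isfinite(self.z_values).all():
            raise ValueError(f"subject {self.subject_id!r}: non-finite z values")


def connectivity_profile(
    reduced: dict[int, np.ndarray], subject_id: str = "", group: str = ""
) -> ConnectivityProfile:
    """Fisher-z correlations between all unordered ROI pairs.

    ``reduced`` maps region_id -> (T x d) reduced series.  With d > 1 the
    components are concatenated (column-major flatten) before correlating.
    """
    rids = sorted(reduced)
    if len(rids) < 2:
        raise ValueError("need at least 2 ROIs")
    flat = {}
    for rid in rids:
        m = np.asarray(reduced[rid], dtype=float)
        flat[rid] = m.ravel(order="F") if m.ndim > 1 else m
    lengths = {v.size for v in flat.values()}
    if len(lengths) > 1:
        raise ValueError("ROI series have unequal lengths")

    pi = PairIndex(len(rids))
    z = np.empty(len(pi))
    for k, (a, b) in enumerate(pi.pairs):
        z[k] = fisher_z(pearson(flat[rids[a - 1]], flat[rids[b - 1]]))
    return ConnectivityProfile(subject_id, group, z, pi)


@dataclass
class FeatureMatrix:
    """Subjects-by-features matrix with group labels and pair annotations.

    ``feature_ids`` are indices into the pair-index bijection; after
    subsetting they keep their original values so backtracking stays valid.
    """

    X: np.ndarray
    subject_ids: list[str]
    groups: list[str]
    pair_index: PairIndex
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.feature_ids is None:
            self.feature_ids = np.arange(self.X.shape[1])
        self.feature_ids = np.asarray(self.feature_ids, dtype=int)
        if len(self.subject_ids) != self.X.shape[0] or len(self.groups) != self.X.shape[0]:
            raise ValueError("labels do not match number of rows")
        if self.feature_ids.shape != (self.X.shape[1],):
            raise ValueError("feature annotation length must equal column count")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def pair_of_column(self, col: int) -> tuple[int, int]:
        return self.pair_index.backtrack(int(self.feature_ids[col]))

    def column_labels(self, atlas=None) -> list[str]:
        out = []
        for k in self.feature_ids:
            i, j = self.pair_index.backtrack(int(k))
            if atlas is not None:
                out.append(f"{atlas.label(i)}|{atlas.label(j)}")
            else:
                out.append(f"r{i:03d}|r{j:03d}")
        return out

    def subset_features(self, feature_ids: Sequence[int]) -> "FeatureMatrix":
        """Restrict to the given pair-index feature ids (order preserved)."""
        wanted = [int(f) for f in feature_ids]
        pos = {int(f): c for c, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in pos]
        if missing:
            raise KeyError(f"feature ids not present: {missing}")
        cols = [pos[f] for f in wanted]
        return FeatureMatrix(
            self.X[:, cols], list(self.subject_ids), list(self.groups),
            self.pair_index, np.asarray(wanted),
        )

    def subset_subjects(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = list(rows)
        return FeatureMatrix(
            self.X[rows], [self.subject_ids[r] for r in rows],
            [self.groups[r] for r in rows], self.pair_index,
            self.feature_ids.copy(),
        )

    def to_frame(self, atlas=None) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_labels(atlas))
        df.insert(0, "group", self.groups)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def build_feature_matrix(profiles: Sequence[ConnectivityProfile]) -> FeatureMatrix:
    """Stack per-subject profiles into a FeatureMatrix (manifest order)."""
    if not profiles:
        raise ValueError("no profiles given")
    pi = profiles[0].pair_index
    for p in profiles[1:]:
        if p.pair_index.n_regions != pi.n_regions:
            raise ValueError(
                f"subject {p.subject_id!r} has {len(p.pair_index)} features, "
                f"expected {len(pi)}"
            )
    X = np.vstack([p.z_values for p in profiles])
    return FeatureMatrix(
        X, [p.subject_id for p in profiles], [p.group for p in profiles], pi
    )
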