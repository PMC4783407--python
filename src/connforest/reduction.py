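"""Per-ROI dimensionality reduction and feature-vector preprocessing.

Each ROI's T x V voxel block is embedded with timepoints as samples and
voxels as features, producing a low-dimensional "reduced time data set"
per ROI.  Component signs are fixed so every component correlates
non-negatively with the ROI's mean voxel time course.  Preprocessing is a
moving-average-baseline high-pass filter followed by column
standardization (sample sd, n-1 convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE, Isomap, LocallyLinearEmbedding

from .connectivity import FeatureMatrix, build_feature_matrix, connectivity_profile
from .synthio import RoiTimeSeriesDataset

__all__ = [
    "ReductionParams",
    "ReducedSeries",
    "reduce_roi",
    "reduce_subject",
    "highpass_filter",
    "standardize_columns",
    "dataset_feature_matrix",
    "compare_reduction_methods",
]

METHODS = ("pca", "isomap", "tsne", "lle")


@dataclass(frozen=True)
class ReductionParams:
    method: str = "pca"
    n_components: int = 1
    n_neighbors: int = 10
    perplexity: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


@dataclass
class ReducedSeries:
    """Per-ROI reduced time courses for one subject."""

    series: dict[int, np.ndarray]  # region_id -> T x d
    params: ReductionParams


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def reduce_roi(
    series: np.ndarray, params: ReductionParams, roi: int | str = "?"
) -> np.ndarray:
    """Embed one ROI's T x V voxel block to a T x d component matrix."""
    m = np.asarray(series, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"ROI {roi}: series must be 2-D (T x V)")
    t, v = m.shape
    d = params.n_components
    if not np.isfinite(m).all():
        raise ValueError(f"ROI {roi}: series contains missing values")
    if t <= d:
        raise ValueError(f"ROI {roi}: need more timepoints than components")
    if v < d:
        raise ValueError(f"ROI {roi}: {v} voxels cannot support {d} components")
    if np.allclose(m.std(axis=0), 0.0):
        raise ValueError(f"ROI {roi}: degenerate constant input")

    mean_course = m.mean(axis=1)
    if v == 1:
        out = _zscore(m[:, 0])[:, None]
    else:
        if params.method == "pca":
            emb = PCA(n_components=d, svd_solver="full",
                      random_state=params.seed).fit_transform(m)
        elif params.method == "isomap":
            nn = min(params.n_neighbors, t - 1)
            emb = Isomap(n_neighbors=nn, n_components=d).fit_transform(m)
        elif params.method == "lle":
            nn = min(params.n_neighbors, t - 1)
            emb = LocallyLinearEmbedding(
                n_neighbors=nn, n_components=d, random_state=params.seed
            ).fit_transform(m)
        else:  # tsne
            perp = min(params.perplexity, (t - 1) / 3.0)
            emb = TSNE(
                n_components=d, perplexity=perp, init="pca",
                random_state=params.seed,
            ).fit_transform(m)
        out = np.asarray(emb, dtype=float)

    # sign convention: each component correlates non-negatively with the
    # ROI mean voxel course (embeddings are sign-indeterminate)
    mc = mean_course - mean_course.mean()
    for c in range(out.shape[1]):
        col = out[:, c] - out[:, c].mean()
        if mc @ col < 0:
            out[:, c] = -out[:, c]
    return out


def reduce_subject(record, params: ReductionParams) -> ReducedSeries:
    """Reduce every ROI of one subject record."""
    reduced = {
        rid: reduce_roi(mat, params, roi=rid) for rid, mat in sorted(record.series.items())
    }
    return ReducedSeries(reduced, params)


def highpass_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Subtract a centered moving-average baseline from each column.

    The window shrinks symmetrically at the edges, so constants and linear
    ramps are removed exactly while high-frequency content passes through.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    t = x.shape[0]
    if not 1 < window < t:
        raise ValueError(f"window must satisfy 1 < window < T={t}, got {window}")
    half = window // 2
    idx = np.arange(t)
    h = np.minimum(np.minimum(idx, t - 1 - idx), half)
    cs = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo, hi = idx - h, idx + h
    baseline = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)[:, None]
    out = x - baseline
    return out[:, 0] if squeeze else out


def standardize_columns(matrix: np.ndarray) -> np.ndarray:
    """Scale every column to mean 0, sample sd 1 (n-1 convention)."""
    x = np.asarray(matrix, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    sd = x.std(axis=0, ddof=1)
    bad = np.where(sd < 1e-12)[0]
    if bad.size:
        raise ValueError(f"constant column(s) cannot be standardized: {bad.tolist()}")
    out = (x - x.mean(axis=0)) / sd
    return out[:, 0] if squeeze else out


def preprocess_reduced(
    reduced: ReducedSeries,
    highpass_window: int | None = None,
    standardize: bool = True,
) -> ReducedSeries:
    """High-pass filter then standardize each reduced ROI time course.

    ``highpass_window=None`` uses the default T // 4; pass 0 to bypass the
    filter.
    """
    out = {}
    for rid, m in reduced.series.items():
        t = m.shape[0]
        w = t // 4 if highpass_window is None else highpass_window
        y = highpass_filter(m, w) if w else m
        out[rid] = standardize_columns(y) if standardize else y
    return ReducedSeries(out, reduced.params)


def dataset_feature_matrix(
    dataset: RoiTimeSeriesDataset,
    params: ReductionParams,
    highpass_window: int | None = None,
    standardize: bool = True,
    groups: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Reduce, preprocess and correlate a whole dataset into features."""
    ds = dataset if groups is None else dataset.subset(groups)
    profiles = []
    for s in ds.subjects:
        red = preprocess_reduced(reduce_subject(s, params), highpass_window, standardize)
        profiles.append(connectivity_profile(red.series, s.subject_id, s.group))
    return build_feature_matrix(profiles)


def compare_reduction_methods(
    dataset: RoiTimeSeriesDataset,
    methods: Sequence[str],
    forest_params=None,
    base_params: ReductionParams | None = None,
    highpass_window: int | None = None,
    standardize: bool = True,
    band: tuple[float, float] = (0.45, 0.55),
) -> dict[str, "object"]:
    """Run the downstream connectivity + LOO forest pipeline per method.

    Returns ``{method: ComparisonSummary}`` computed under identical seeds
    so the only varying factor is the embedding.
    """
    from .forestclass import ForestParams, loo_classify

    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    if len(set(dataset.groups)) != 2:
        raise ValueError("comparison harness requires a two-group dataset")
    if forest_params is None:
        forest_params = ForestParams()
    base = base_params or ReductionParams()

    results = {}
    for method in methods:
        params = replace(base, method=method)
        fm = dataset_feature_matrix(dataset, params, highpass_window, standardize)
        _, summary = loo_classify(fm, forest_params, band=band)
        results[method] = summary
    return results
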