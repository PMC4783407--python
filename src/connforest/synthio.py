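"""Synthetic multi-subject ROI time-series generation and dataset I/O.

The generator plants group-dependent connectivity on chosen ROI pairs:
latent ROI signals are drawn from a multivariate normal whose correlation
matrix has a common off-diagonal baseline, with the planted pairs shifted
on the Fisher-z scale by a per-group effect size.  Each voxel observes its
ROI's latent signal plus independent Gaussian noise, optionally passed
through an AR(1) filter and given a linear drift.

Datasets are stored as plain tab-separated text: a ``manifest.tsv``
(subject_id, group, relative path), an ``atlas.tsv`` (region_id, name,
side), and one series file per subject per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AtlasLabels",
    "SynthConfig",
    "SubjectRecord",
    "RoiTimeSeriesDataset",
    "make_atlas_labels",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "extract_roi_series",
]

SIDES = ("left", "right", "midline")

# Lateralized structures used for the default 45-region atlas; the remainder
# is padded with generically named bilateral pairs.
_NAMED_BILATERAL = (
    "sensorimotor cortex",
    "anterior cingulate",
    "entorhinal cortex",
    "insula",
    "hippocampus",
    "ventral thalamus",
    "posterior thalamus",
    "hypothalamus",
    "caudate putamen",
    "basolateral amygdala",
    "anterior amygdala",
    "nucleus accumbens",
    "superior colliculus",
    "inferior colliculus",
)


@dataclass(frozen=True)
class AtlasLabels:
    """Region id / name / side table for one atlas."""

    region_ids: tuple[int, ...]
    names: tuple[str, ...]
    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if not (len(self.names) == len(self.sides) == n):
            raise ValueError("region_ids, names and sides must have equal length")
        if self.region_ids != tuple(range(1, n + 1)):
            raise ValueError("region_ids must be contiguous from 1")
        bad = set(self.sides) - set(SIDES)
        if bad:
            raise ValueError(f"invalid sides: {sorted(bad)}")
        if len(set(zip(self.names, self.sides))) != n:
            raise ValueError("duplicate (name, side) entries in atlas")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def label(self, region_id: int) -> str:
        name, side = self.name_side(region_id)
        return name if side == "midline" else f"{name}/{side}"

    def name_side(self, region_id: int) -> tuple[str, str]:
        i = region_id - 1
        if not 0 <= i < self.n_regions:
            raise KeyError(f"region_id {region_id} not in atlas")
        return self.names[i], self.sides[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_id": self.region_ids, "name": self.names, "side": self.sides}
        )


def make_atlas_labels(n_rois: int = 45) -> AtlasLabels:
    """Build an atlas label table with ``n_rois`` regions.

    The named bilateral structures come first (left and right entries per
    name); if more regions are needed they are padded with deterministic
    generic bilateral pairs, and a final midline region absorbs an odd
    count.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    pairs: list[tuple[str, str]] = []
    for name in _NAMED_BILATERAL:
        pairs.append((name, "left"))
        pairs.append((name, "right"))
    i = 1
    while len(pairs) < n_rois - 1:
        pairs.append((f"region {i:02d}", "left"))
        pairs.append((f"region {i:02d}", "right"))
        i += 1
    if len(pairs) < n_rois:  # odd remainder -> midline region
        pairs.append(("midline region", "midline"))
    pairs = pairs[:n_rois]
    names, sides = zip(*pairs)
    return AtlasLabels(tuple(range(1, n_rois + 1)), names, sides)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset generator."""

    n_rois: int = 45
    n_timepoints: int = 600
    tr: float = 2.5
    voxels_per_roi: int = 20
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"saline": 13, "LD": 12, "HD": 12}
    )
    base_corr: float = 0.1
    planted_edges: tuple[tuple[int, int], ...] = ()
    effect_dz: Mapping[str, float] = field(
        default_factory=lambda: {"saline": 0.0, "LD": 0.5, "HD": 1.0}
    )
    voxel_noise_sd: float = 0.5
    ar1_coef: float = 0.0
    drift_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.voxels_per_roi < 1:
            raise ValueError("voxels_per_roi must be >= 1")
        if not -1.0 < self.base_corr < 1.0:
            raise ValueError("base_corr must lie in (-1, 1)")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        for i, j in self.planted_edges:
            if i == j:
                raise ValueError(f"planted edge ({i}, {j}) is not a distinct pair")
            for r in (i, j):
                if not 1 <= r <= self.n_rois:
                    raise ValueError(
                        f"planted edge ({i}, {j}) references invalid ROI id {r}"
                    )
        for g in self.group_sizes:
            if g not in self.effect_dz:
                raise ValueError(f"effect_dz missing entry for group {g!r}")


@dataclass
class SubjectRecord:
    """One subject's per-ROI voxel time series (T timepoints x V voxels)."""

    subject_id: str
    group: str
    series: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {m.shape[0] for m in self.series.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"subject {self.subject_id!r}: ROI series have unequal lengths"
            )
        for rid, m in self.series.items():
            if m.ndim != 2:
                raise ValueError(
                    f"subject {self.subject_id!r}, ROI {rid}: series must be 2-D"
                )
            if m.shape[0] < 4 or m.shape[1] < 1:
                raise ValueError(
                    f"subject {self.subject_id!r}, ROI {rid}: need T >= 4, V >= 1"
                )
            if not np.isfinite(m).all():
                raise ValueError(
                    f"subject {self.subject_id!r}, ROI {rid}: non-finite values"
                )

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.series.values())).shape[0]


@dataclass
class RoiTimeSeriesDataset:
    subjects: list[SubjectRecord]
    atlas: AtlasLabels
    tr: float = 2.5

    def __post_init__(self) -> None:
        rids = set(self.atlas.region_ids)
        ts = {s.n_timepoints for s in self.subjects}
        if len(ts) > 1:
            raise ValueError(f"subjects disagree on timepoint count: {sorted(ts)}")
        for s in self.subjects:
            if set(s.series) != rids:
                raise ValueError(
                    f"subject {s.subject_id!r} ROI set does not match the atlas"
                )

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.subjects]

    def subset(self, groups: Sequence[str]) -> "RoiTimeSeriesDataset":
        keep = [s for s in self.subjects if s.group in set(groups)]
        return RoiTimeSeriesDataset(keep, self.atlas, self.tr)


def _nearest_pd_correlation(corr: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``min_eig`` and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= min_eig:
        return corr
    vals = np.clip(vals, min_eig, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.linalg.eigvalsh(fixed).min() <= 0:
        raise ValueError("correlation matrix could not be repaired to positive definite")
    return fixed


def group_correlation_matrix(config: SynthConfig, group: str) -> np.ndarray:
    """Latent ROI correlation matrix for one group (after PD repair)."""
    r = config.n_rois
    corr = np.full((r, r), config.base_corr)
    np.fill_diagonal(corr, 1.0)
    dz = config.effect_dz[group]
    planted = np.tanh(np.arctanh(config.base_corr) + dz)
    for i, j in config.planted_edges:
        corr[i - 1, j - 1] = corr[j - 1, i - 1] = planted
    return _nearest_pd_correlation(corr)


def generate_dataset(config: SynthConfig) -> RoiTimeSeriesDataset:
    """Sample a multi-subject dataset with planted group-dependent connectivity.

    Deterministic given ``config.seed``: identical configs produce
    bit-identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    atlas = make_atlas_labels(config.n_rois)
    t, v = config.n_timepoints, config.voxels_per_roi
    ramp = np.linspace(0.0, 1.0, t)[:, None]

    subjects: list[SubjectRecord] = []
    for group, size in config.group_sizes.items():
        chol = np.linalg.cholesky(group_correlation_matrix(config, group))
        for k in range(size):
            latent = rng.standard_normal((t, config.n_rois)) @ chol.T
            series: dict[int, np.ndarray] = {}
            for rid in atlas.region_ids:
                vox = latent[:, [rid - 1]] + config.voxel_noise_sd * rng.standard_normal(
                    (t, v)
                )
                if config.ar1_coef > 0:
                    vox = signal.lfilter([1.0], [1.0, -config.ar1_coef], vox, axis=0)
                if config.drift_amplitude > 0:
                    slopes = config.drift_amplitude * rng.uniform(-1.0, 1.0, size=v)
                    vox = vox + ramp * slopes
                series[rid] = vox
            subjects.append(SubjectRecord(f"{group}-{k + 1:02d}", group, series))
    return RoiTimeSeriesDataset(subjects, atlas, config.tr)


# ---------------------------------------------------------------------------
# plain-text dataset directory


def write_dataset(dataset: RoiTimeSeriesDataset, directory: str | Path) -> Path:
    """Write a dataset as TSV files; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.atlas.to_frame().to_csv(directory / "atlas.tsv", sep="\t", index=False)
    rows = []
    for s in dataset.subjects:
        sub_dir = directory / "series" / s.subject_id
        sub_dir.mkdir(parents=True, exist_ok=True)
        for rid in sorted(s.series):
            np.savetxt(sub_dir / f"roi_{rid:03d}.tsv", s.series[rid],
                       fmt="%.17g", delimiter="\t")
        rows.append(
            {"subject_id": s.subject_id, "group": s.group,
             "path": str(Path("series") / s.subject_id)}
        )
    manifest = directory / "manifest.tsv"
    meta = pd.DataFrame(rows)
    meta.to_csv(manifest, sep="\t", index=False)
    with open(directory / "tr.txt", "w") as fh:
        fh.write(f"{dataset.tr:.17g}\n")
    return manifest


def read_dataset(directory: str | Path) -> RoiTimeSeriesDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {directory}")
    meta = pd.read_csv(manifest, sep="\t", dtype={"subject_id": str, "group": str})
    atlas_df = pd.read_csv(directory / "atlas.tsv", sep="\t")
    atlas = AtlasLabels(
        tuple(int(r) for r in atlas_df["region_id"]),
        tuple(atlas_df["name"]),
        tuple(atlas_df["side"]),
    )
    tr_file = directory / "tr.txt"
    tr = float(tr_file.read_text()) if tr_file.exists() else 2.5

    subjects = []
    for row in meta.itertuples(index=False):
        sub_dir = directory / row.path
        series = {}
        for rid in atlas.region_ids:
            f = sub_dir / f"roi_{rid:03d}.tsv"
            if not f.exists():
                raise FileNotFoundError(
                    f"subject {row.subject_id!r}: missing series file {f}"
                )
            series[rid] = np.atleast_2d(np.loadtxt(f, delimiter="\t", ndmin=2))
        subjects.append(SubjectRecord(str(row.subject_id), str(row.group), series))
    return RoiTimeSeriesDataset(subjects, atlas, tr)


# ---------------------------------------------------------------------------
# volumetric extraction


def _as_array(img) -> np.ndarray:
    if hasattr(img, "get_fdata"):  # nibabel image
        return np.asarray(img.get_fdata())
    return np.asarray(img)


def extract_roi_series(
    image_4d,
    label_volume,
    subject_id: str = "subject",
    group: str = "unknown",
    labels: Sequence[int] | None = None,
) -> SubjectRecord:
    """Extract per-label voxel time series from a 4-D image.

    Accepts numpy arrays or nibabel spatial images.  Voxels within a label
    are ordered lexicographically by (x, y, z) index.  ``labels`` restricts
    and validates the set of region ids; by default every nonzero label in
    the volume is extracted.
    """
    img = _as_array(image_4d)
    lab = _as_array(label_volume)
    if img.ndim != 4:
        raise ValueError(f"image must be 4-D, got shape {img.shape}")
    if lab.shape != img.shape[:3]:
        raise ValueError(
            f"label volume grid {lab.shape} does not match image grid {img.shape[:3]}"
        )
    if not np.issubdtype(np.asarray(lab).dtype, np.number):
        raise ValueError("label volume must be numeric")
    lab = lab.astype(np.int64)
    if (lab < 0).any():
        raise ValueError("labels must be non-negative integers (0 = background)")
    present = set(int(v) for v in np.unique(lab)) - {0}
    if labels is None:
        wanted = sorted(present)
    else:
        missing = sorted(set(int(v) for v in labels) - present)
        if missing:
            raise ValueError(f"labels absent from the volume: {missing}")
        wanted = sorted(set(int(v) for v in labels))
    if not wanted:
        raise ValueError("label volume contains no nonzero labels")

    series = {}
    for rid in wanted:
        idx = np.argwhere(lab == rid)  # lexicographic (x, y, z) order
        vox = img[idx[:, 0], idx[:, 1], idx[:, 2], :].T  # T x V
        series[rid] = np.ascontiguousarray(vox, dtype=float)
    return SubjectRecord(subject_id, group, series)
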