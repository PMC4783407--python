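import warnings

import numpy as np
import pytest

import connforest as cf

# sklearn's Isomap warns about disconnected kNN graphs on some synthetic
# fixtures; the embedding is still computed (graph is completed).
warnings.filterwarnings("ignore", message="The number of connected components")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small two-group dataset with a strongly planted edge."""
    cfg = cf.SynthConfig(
        n_rois=6, n_timepoints=100, voxels_per_roi=4,
        group_sizes={"A": 6, "B": 6},
        planted_edges=((1, 2), (3, 4)),
        effect_dz={"A": 0.0, "B": 2.0},
        voxel_noise_sd=0.3, seed=42,
    )
    return cf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_features(toy_dataset):
    return cf.dataset_feature_matrix(
        toy_dataset, cf.ReductionParams(method="pca", seed=0)
    )


@pytest.fixture(scope="session")
def noise_features():
    """25 subjects x 45 iid noise features, two groups, no signal."""
    rng = np.random.default_rng(123)
    X = rng.standard_normal((25, 45))
    groups = ["A"] * 13 + ["B"] * 12
    ids = [f"s{i:02d}" for i in range(25)]
    return cf.FeatureMatrix(X, ids, groups, cf.PairIndex(10), np.arange(45))


def separated_features(n_per=6, p=12, delta=10.0, seed=0, informative="some"):
    """Two far-separated point clouds (delta in units of the noise sd)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per, p))
    cols = slice(None) if informative == "all" else slice(0, 3)
    X[n_per:, cols] += delta
    groups = ["lo"] * n_per + ["hi"] * n_per
    ids = [f"s{i}" for i in range(2 * n_per)]
    return cf.FeatureMatrix(X, ids, groups, cf.PairIndex(6), np.arange(p))
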