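# connforest

Functional-connectivity feature engineering and random-forest group
segregation for multi-subject ROI time series.

Given per-subject, per-ROI voxel time series (or a 4-D image plus an
integer label volume), the pipeline:

1. **reduces** each ROI's voxel block to a low-dimensional time course
   (PCA, Isomap, t-SNE or LLE; timepoints are the samples, voxels the
   features), then high-pass filters and standardizes it;
2. **correlates** all ROI pairs, Fisher z-transforms the correlations and
   flattens the matrix into a feature vector with a bijective
   feature-index ↔ ROI-pair map (45 ROIs → 990 features);
3. **classifies** subjects into two groups with leave-one-out random
   forests; each held-out subject is scored by the fraction of trees
   voting for its true group, and vote fractions inside the inclusive
   band [0.45, 0.55] are reported as "unclassified";
4. **selects** discriminative features via per-tree out-of-bag
   permutation importance (mean increase of a tree's OOB error),
   re-classifies with the top-k features — selection and refit both
   inside the LOO loop — and supports a mutually-exclusive feature set
   for dose-vs-dose contrasts;
5. **reports** outcome counts per comparison and a region-level
   importance table with laterality.

A synthetic-data module generates multi-subject datasets with planted
group-dependent connectivity (effects planted on the Fisher-z scale,
positive-definite repair by eigenvalue clipping), so every stage is
testable without any download.

## CLI

All commands share one YAML config (see below).

```sh
connforest simulate -c config.yaml -o data/            # write a synthetic dataset
connforest run -c config.yaml -o results/              # full pipeline
connforest compare-reductions -c config.yaml -o out/ --methods pca,isomap,tsne
connforest sweep-k -c config.yaml -o out/ --ks 5,10,50 --groups saline,HD
connforest report -r results/                          # print summary table
```

Exit codes: 0 success, 2 config error, 3 stage failure.

```yaml
seed: 1
data:
  synthesis:                  # or: directory: path/to/dataset
    n_rois: 45
    n_timepoints: 600
    group_sizes: {saline: 13, LD: 12, HD: 12}
    planted_edges: [[1, 2], [5, 9]]
    effect_dz: {saline: 0.0, LD: 0.5, HD: 1.0}
reduction:
  method: isomap              # pca | isomap | tsne | lle
  n_components: 1
  n_neighbors: 10
  highpass_window: null       # null = T//4, 0 = bypass
  standardize: true
classification:
  n_trees: 500
  band: [0.45, 0.55]
selection:
  k: 10
  consensus_threshold: 0.5
  exclusion_level: pair       # pair | region
report:
  rule: max                   # max | sum | mean
  threshold: 2.0
```

`run` writes per-subject prediction TSVs, outcome summaries, consensus
feature subsets, a region-importance table, a provenance record (config
hash, seed, versions) and a log; re-running an identical config
reproduces every output byte-for-byte.

Dataset directories are plain text: `manifest.tsv` (subject_id, group,
path), `atlas.tsv` (region_id, name, side) and one TSV per subject per
ROI (rows = timepoints, columns = voxels).

## Python API

```python
import connforest as cf

ds = cf.generate_dataset(cf.SynthConfig(seed=1))
fm = cf.dataset_feature_matrix(ds, cf.ReductionParams(method="isomap", seed=1),
                               groups=["saline", "HD"])
preds, summary = cf.loo_classify(fm, cf.ForestParams(n_trees=500, seed=1))
preds, summary, folds, consensus = cf.nested_loo_with_selection(
    fm, k=10, params=cf.ForestParams(seed=1))
```
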