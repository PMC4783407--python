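import numpy as np
import pytest

import connforest as cf
from connforest.synthio import group_correlation_matrix


class TestMakeAtlasLabels:
    def test_default_45_unique_labels(self):
        atlas = cf.make_atlas_labels(45)
        assert atlas.n_regions == 45
        labels = [atlas.label(r) for r in atlas.region_ids]
        assert len(set(labels)) == 45

    def test_two_regions(self):
        assert cf.make_atlas_labels(2).n_regions == 2

    def test_default_contains_both_hippocampus_sides(self):
        atlas = cf.make_atlas_labels(45)
        pairs = set(zip(atlas.names, atlas.sides))
        assert ("hippocampus", "left") in pairs
        assert ("hippocampus", "right") in pairs

    def test_named_bilateral_structures_present(self):
        atlas = cf.make_atlas_labels(45)
        names = set(atlas.names)
        for want in ("sensorimotor cortex", "anterior cingulate", "insula",
                     "ventral thalamus", "posterior thalamus", "hypothalamus",
                     "caudate putamen", "nucleus accumbens",
                     "superior colliculus", "inferior colliculus"):
            assert want in names

    def test_every_lateralized_name_has_both_sides_at_default(self):
        atlas = cf.make_atlas_labels(45)
        by_name = {}
        for name, side in zip(atlas.names, atlas.sides):
            by_name.setdefault(name, set()).add(side)
        for name, sides in by_name.items():
            if "midline" not in sides:
                assert sides == {"left", "right"}, name

    def test_rejects_single_region(self):
        with pytest.raises(ValueError):
            cf.make_atlas_labels(1)


class TestSynthConfig:
    def test_invalid_edge_ids_rejected(self):
        cfg = cf.SynthConfig(n_rois=5, planted_edges=((1, 9),),
                             group_sizes={"A": 2}, effect_dz={"A": 0.0})
        with pytest.raises(ValueError, match="invalid ROI id"):
            cfg.validate()

    def test_self_edge_rejected(self):
        cfg = cf.SynthConfig(n_rois=5, planted_edges=((2, 2),),
                             group_sizes={"A": 2}, effect_dz={"A": 0.0})
        with pytest.raises(ValueError, match="distinct"):
            cfg.validate()

    def test_missing_effect_entry_rejected(self):
        cfg = cf.SynthConfig(group_sizes={"X": 2}, effect_dz={})
        with pytest.raises(ValueError, match="effect_dz"):
            cfg.validate()


class TestGenerateDataset:
    def test_default_shape(self):
        ds = cf.generate_dataset(cf.SynthConfig(n_timepoints=12, voxels_per_roi=2))
        # 13 + 12 + 12 subjects across the three groups
        assert len(ds.subjects) == 37
        sizes = {}
        for s in ds.subjects:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        assert sizes == {"saline": 13, "LD": 12, "HD": 12}
        assert ds.atlas.n_regions == 45
        assert all(s.n_timepoints == 12 for s in ds.subjects)

    def test_deterministic_given_seed(self):
        cfg = cf.SynthConfig(n_rois=4, n_timepoints=20, voxels_per_roi=2,
                             group_sizes={"A": 2}, effect_dz={"A": 0.5},
                             planted_edges=((1, 2),), seed=9,
                             ar1_coef=0.3, drift_amplitude=0.5)
        d1 = cf.generate_dataset(cfg)
        d2 = cf.generate_dataset(cfg)
        for s1, s2 in zip(d1.subjects, d2.subjects):
            for rid in s1.series:
                np.testing.assert_array_equal(s1.series[rid], s2.series[rid])

    def test_zero_effect_gives_no_group_difference(self):
        cfg = cf.SynthConfig(n_rois=4, n_timepoints=300, voxels_per_roi=1,
                             group_sizes={"A": 20, "B": 20},
                             planted_edges=((1, 2),),
                             effect_dz={"A": 0.0, "B": 0.0},
                             voxel_noise_sd=0.0, seed=5)
        ds = cf.generate_dataset(cfg)
        z = {"A": [], "B": []}
        for s in ds.subjects:
            z[s.group].append(
                cf.fisher_z(cf.pearson(s.series[1][:, 0], s.series[2][:, 0]))
            )
        diff = np.mean(z["A"]) - np.mean(z["B"])
        se = (1 / np.sqrt(300 - 3)) * np.sqrt(1 / 20 + 1 / 20)
        assert abs(diff) < 3 * se

    def test_planted_edge_mean_z_matches_target(self):
        # Monte-Carlo oracle: per-subject z has SE 1/sqrt(T-3); over n
        # subjects the group mean lands within 3 SE of atanh(0.1) + 1.0.
        cfg = cf.SynthConfig(n_rois=4, n_timepoints=600, voxels_per_roi=1,
                             group_sizes={"HD": 60}, planted_edges=((1, 2),),
                             effect_dz={"HD": 1.0}, base_corr=0.1,
                             voxel_noise_sd=0.0, seed=11)
        ds = cf.generate_dataset(cfg)
        zs = np.array([
            cf.fisher_z(cf.pearson(s.series[1][:, 0], s.series[2][:, 0]))
            for s in ds.subjects
        ])
        target = np.arctanh(0.1) + 1.0
        se = 1 / np.sqrt(600 - 3) / np.sqrt(60)
        assert abs(zs.mean() - target) < 3 * se

    def test_correlation_matrix_positive_definite_after_repair(self):
        # strong planted effects on many edges force a repair
        edges = tuple((1, j) for j in range(2, 10))
        cfg = cf.SynthConfig(n_rois=9, planted_edges=edges,
                             group_sizes={"X": 1}, effect_dz={"X": 3.0},
                             base_corr=-0.05)
        corr = group_correlation_matrix(cfg, "X")
        assert np.linalg.eigvalsh(corr).min() > 0
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)


class TestDatasetIO:
    def test_roundtrip(self, tmp_path):
        cfg = cf.SynthConfig(n_rois=3, n_timepoints=10, voxels_per_roi=2,
                             group_sizes={"A": 2, "B": 1},
                             effect_dz={"A": 0.0, "B": 0.0}, seed=1)
        ds = cf.generate_dataset(cfg)
        cf.write_dataset(ds, tmp_path / "d")
        back = cf.read_dataset(tmp_path / "d")
        assert [s.subject_id for s in back.subjects] == [s.subject_id for s in ds.subjects]
        assert back.groups == ds.groups
        assert back.tr == ds.tr
        for s1, s2 in zip(ds.subjects, back.subjects):
            for rid in s1.series:
                np.testing.assert_allclose(s1.series[rid], s2.series[rid],
                                           atol=1e-12, rtol=0)

    def test_missing_series_file_names_subject(self, tmp_path):
        cfg = cf.SynthConfig(n_rois=3, n_timepoints=10, voxels_per_roi=1,
                             group_sizes={"A": 2}, effect_dz={"A": 0.0})
        ds = cf.generate_dataset(cfg)
        cf.write_dataset(ds, tmp_path / "d")
        victim = ds.subjects[1].subject_id
        (tmp_path / "d" / "series" / victim / "roi_002.tsv").unlink()
        with pytest.raises(FileNotFoundError, match=victim):
            cf.read_dataset(tmp_path / "d")

    def test_heterogeneous_timepoints_rejected(self, tmp_path):
        cfg = cf.SynthConfig(n_rois=3, n_timepoints=10, voxels_per_roi=1,
                             group_sizes={"A": 2}, effect_dz={"A": 0.0})
        ds = cf.generate_dataset(cfg)
        cf.write_dataset(ds, tmp_path / "d")
        victim = ds.subjects[0].subject_id
        f = tmp_path / "d" / "series" / victim / "roi_001.tsv"
        lines = f.read_text().splitlines()
        f.write_text("\n".join(lines[:-2]) + "\n")
        with pytest.raises(ValueError):
            cf.read_dataset(tmp_path / "d")

    def test_no_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            cf.read_dataset(tmp_path)


class TestExtractRoiSeries:
    def _fixture(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((4, 4, 2, 10))
        lab = np.zeros((4, 4, 2), dtype=int)
        lab[0, 0, 0] = lab[1, 2, 1] = lab[3, 3, 0] = 1
        lab[2, 2, 0] = 2
        return img, lab

    def test_known_values_exact(self):
        img, lab = self._fixture()
        rec = cf.extract_roi_series(img, lab)
        got = rec.series[1]
        assert got.shape == (10, 3)
        # lexicographic (x, y, z) voxel order
        expected = np.stack(
            [img[0, 0, 0], img[1, 2, 1], img[3, 3, 0]], axis=1
        )
        np.testing.assert_array_equal(got, expected)

    def test_roi_mean_matches_brute_force(self):
        img, lab = self._fixture()
        rec = cf.extract_roi_series(img, lab)
        for rid in (1, 2):
            vox = np.argwhere(lab == rid)
            for t in range(10):
                manual = np.mean([img[x, y, z, t] for x, y, z in vox])
                assert rec.series[rid][t].mean() == pytest.approx(manual, abs=1e-14)

    def test_all_zero_labels_rejected(self):
        img, _ = self._fixture()
        with pytest.raises(ValueError, match="no nonzero labels"):
            cf.extract_roi_series(img, np.zeros((4, 4, 2), dtype=int))

    def test_grid_mismatch_rejected(self):
        img, _ = self._fixture()
        with pytest.raises(ValueError, match="grid"):
            cf.extract_roi_series(img, np.ones((3, 4, 2), dtype=int))

    def test_absent_requested_label_listed(self):
        img, lab = self._fixture()
        with pytest.raises(ValueError, match=r"\[7\]"):
            cf.extract_roi_series(img, lab, labels=[1, 7])
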