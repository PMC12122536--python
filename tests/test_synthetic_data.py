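"""Generator tests: geometry priors, count bias structure, BOLD coupling."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from striocompart import synthetic_data as sd
from striocompart.anatomy_metrics import cluster_sizes
from striocompart.parcellation import compute_bias


class TestStriatumGeometry:
    def test_realized_fraction_matches_histologic_prior(self, default_gt):
        # striosome should occupy ~15% of striatal volume
        frac = default_gt.striosome_mask.sum() / default_gt.striatum_mask.sum()
        assert 0.12 <= frac <= 0.18

    def test_near_zero_fraction_limit(self, small_spec):
        spec = dataclasses.replace(small_spec, striosome_fraction=0.001)
        gt = sd.generate_striatum(spec)
        frac_matrix = gt.matrix_mask.sum() / gt.striatum_mask.sum()
        assert frac_matrix >= 0.99

    def test_determinism(self, small_spec):
        a = sd.generate_striatum(small_spec)
        b = sd.generate_striatum(small_spec)
        assert np.array_equal(a.nucleus_labels, b.nucleus_labels)
        assert np.array_equal(a.compartment_labels, b.compartment_labels)

    def test_compartment_defined_exactly_on_striatum(self, small_gt):
        assert np.array_equal(small_gt.compartment_labels != 0,
                              small_gt.nucleus_labels != 0)

    def test_striosome_islands_matrix_sea(self, default_gt):
        # per nucleus: matrix one dominant component, striosome fragmented
        for code in sd.NUCLEUS_NAMES:
            nuc = default_gt.nucleus_mask(code)
            mat = cluster_sizes(default_gt.matrix_mask & nuc)
            strio = cluster_sizes(default_gt.striosome_mask & nuc)
            assert mat.largest >= 0.9 * mat.total
            assert strio.largest <= 0.2 * strio.total
            assert len(strio.sizes) > 1

    def test_rostro_ventro_medial_enrichment(self):
        # planted gradient: striosome centroid rostral (+y), ventral (-z),
        # medial (|x| smaller) of the matrix centroid, in both hemispheres
        from striocompart.cli_io import world_coordinates

        diffs = []
        for seed in range(4):
            gt = sd.generate_striatum(sd.StriatumSpec(rng_seed=seed))
            w = world_coordinates(gt.nucleus_labels.shape, gt.affine)
            for side in ("L", "R"):
                hemi = gt.hemisphere_mask(side)
                cs = w[gt.striosome_mask & hemi].mean(axis=0)
                cm = w[gt.matrix_mask & hemi].mean(axis=0)
                diffs.append((cs[1] - cm[1], cs[2] - cm[2],
                              abs(cs[0]) - abs(cm[0])))
        diffs = np.array(diffs)
        # island discreteness makes single draws noisy; the planted gradient
        # shows in the aggregate and in the majority of draws
        mean = diffs.mean(axis=0)
        assert mean[0] > 0 and mean[1] < 0 and mean[2] < 0
        votes = (diffs[:, 0] > 0), (diffs[:, 1] < 0), (diffs[:, 2] < 0)
        assert all(v.mean() > 0.5 for v in votes)

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            sd.generate_striatum(sd.StriatumSpec(grid_shape=(6, 6, 6)))

    @pytest.mark.parametrize("field,value", [
        ("striosome_fraction", 0.0), ("striosome_fraction", 1.0),
        ("island_radius", 0), ("gradient_strength", -1.0),
    ])
    def test_invalid_spec_rejected(self, small_spec, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(small_spec, **{field: value}).validate()


class TestCounts:
    def test_unmixed_bias_ratio_equals_odds(self, small_gt):
        # sigma=0: class-summed expectation favors the true compartment 9:1
        model = sd.CountModel(base_rate=2000.0, bias_odds=9.0,
                              partial_volume_sigma=0.0)
        counts = sd.generate_counts(small_gt, sd.BaitRegionSet(), model, seed=5)
        s = counts.summed("striosome")
        m = counts.summed("matrix")
        strio = small_gt.striosome_mask
        ratio = s[strio].sum() / m[strio].sum()
        assert ratio == pytest.approx(9.0, rel=0.02)
        mat = small_gt.matrix_mask
        assert (m[mat].sum() / s[mat].sum()) == pytest.approx(9.0, rel=0.02)

    def test_unbiased_null(self, small_gt):
        model = sd.CountModel(base_rate=500.0, bias_odds=1.0,
                              partial_volume_sigma=0.0)
        counts = sd.generate_counts(small_gt, sd.BaitRegionSet(), model, seed=6)
        p = compute_bias(counts).p_striosome
        assert np.nanmean(p) == pytest.approx(0.5, abs=0.02)

    def test_partial_volume_mixing_dilutes_bias(self, small_gt):
        # a compact striosome slab mixed at 2 mm: recovered bias strictly
        # between the unbiased 0.5 and the pure-voxel 0.9, and matching the
        # first-principles mixing oracle
        gt = dataclasses.replace(small_gt)
        comp = np.where(gt.striatum_mask, sd.COMP_MATRIX, sd.COMP_NONE)
        slab = gt.striatum_mask.copy()
        slab[:, :12, :] = False
        slab[:, 18:, :] = False
        comp[slab] = sd.COMP_STRIOSOME
        gt = sd.GroundTruthStriatum(nucleus_labels=gt.nucleus_labels,
                                    compartment_labels=comp.astype(np.uint8),
                                    affine=gt.affine, spec=gt.spec)
        assert slab.sum() >= 100

        sigma_mm = 2.0
        model = sd.CountModel(base_rate=500.0, bias_odds=9.0,
                              partial_volume_sigma=sigma_mm)
        p_means = []
        for seed in range(3):
            counts = sd.generate_counts(gt, sd.BaitRegionSet(), model, seed=seed)
            p = compute_bias(counts).p_striosome
            p_means.append(np.nanmean(p[slab]))
        p_mean = float(np.mean(p_means))
        assert 0.5 < p_mean < 0.9

        # oracle: normalized-Gaussian mixture of pure-compartment rates
        sig_vox = sigma_mm / gt.spec.voxel_size
        ind = ndimage.gaussian_filter(slab.astype(float), sig_vox)
        sup = ndimage.gaussian_filter(gt.striatum_mask.astype(float), sig_vox)
        f = np.where(gt.striatum_mask, ind / np.maximum(sup, 1e-12), 0.0)
        s_exp = f + (1 - f) / 9.0
        m_exp = f / 9.0 + (1 - f)
        oracle = float((s_exp / (s_exp + m_exp))[slab].mean())
        assert p_mean == pytest.approx(oracle, abs=0.02)

    def test_counts_zero_outside_striatum(self, small_gt):
        counts = sd.generate_counts(small_gt, sd.BaitRegionSet(),
                                    sd.CountModel(), seed=7)
        outside = ~small_gt.striatum_mask
        for grid in counts.counts.values():
            assert not grid[outside].any()
            assert (grid >= 0).all()

    def test_negative_binomial_family(self, small_gt):
        model = sd.CountModel(noise_family="negative-binomial", dispersion=0.5)
        counts = sd.generate_counts(small_gt, sd.BaitRegionSet(), model, seed=8)
        assert all((g >= 0).all() for g in counts.counts.values())

    def test_determinism(self, small_gt):
        a = sd.generate_counts(small_gt, sd.BaitRegionSet(), sd.CountModel(), 9)
        b = sd.generate_counts(small_gt, sd.BaitRegionSet(), sd.CountModel(), 9)
        for name in a.counts:
            assert np.array_equal(a.counts[name], b.counts[name])


class TestBold:
    def test_null_coupling_gives_null_correlations(self, small_gt):
        t = 800
        spec = sd.BoldSpec(n_timepoints=t, coupling=(
            (("striosome", "ipsi"), 0.0), (("matrix", "contra"), 0.0)),
            rng_seed=3)
        bold, nodes = sd.generate_bold(small_gt, spec)
        node = nodes["DMN-L"]
        tc = bold.data[node.mask].mean(axis=0)
        tc = (tc - tc.mean()) / tc.std()
        strio = small_gt.striosome_mask & small_gt.hemisphere_mask("L")
        x = bold.data[strio].astype(float)
        x -= x.mean(axis=1, keepdims=True)
        r = (x @ tc) / (np.linalg.norm(x, axis=1) * np.sqrt(t))
        assert np.mean(np.abs(r) < 3 / np.sqrt(t)) >= 0.95

    def test_planted_coupling_recovered(self, small_gt):
        # mean sample correlation of striosome voxels with the ipsilateral
        # node approaches the planted amplitude at the study timepoint count
        coupling = ((("striosome", "ipsi"), 0.6), (("matrix", "contra"), 0.5))
        r_means = []
        for seed in range(3):
            spec = sd.BoldSpec(n_timepoints=2400, coupling=coupling,
                               rng_seed=seed)
            bold, nodes = sd.generate_bold(small_gt, spec)
            node_tc = bold.data[nodes["SN-R"].mask].mean(axis=0)
            node_tc = node_tc - node_tc.mean()
            strio = small_gt.striosome_mask & small_gt.hemisphere_mask("R")
            x = bold.data[strio].astype(float)
            x -= x.mean(axis=1, keepdims=True)
            r = (x @ node_tc) / (np.linalg.norm(x, axis=1)
                                 * np.linalg.norm(node_tc))
            r_means.append(r.mean())
        assert np.mean(r_means) == pytest.approx(0.6, abs=0.05)

    def test_zero_mean_series(self, small_gt):
        bold, _ = sd.generate_bold(small_gt, sd.BoldSpec(n_timepoints=50))
        means = bold.data.mean(axis=3)
        assert np.abs(means).max() < 1e-4

    def test_determinism(self, small_gt):
        spec = sd.BoldSpec(n_timepoints=40, rng_seed=21)
        a, _ = sd.generate_bold(small_gt, spec)
        b, _ = sd.generate_bold(small_gt, spec)
        assert np.array_equal(a.data, b.data)

    def test_invalid_covariance_rejected(self, small_gt):
        spec = sd.BoldSpec(coupling=((("striosome", "ipsi"), 0.9),
                                     (("striosome", "contra"), 0.9)))
        with pytest.raises(ValueError, match="covariance"):
            sd.generate_bold(small_gt, spec)

    def test_nodes_disjoint_from_striatum(self, small_gt):
        nodes = sd.default_network_nodes(small_gt)
        assert len(nodes) == 6
        for node in nodes.values():
            assert not (node.mask & small_gt.striatum_mask).any()


class TestCohortIO:
    def test_manifest_counts_files(self, tmp_path, small_spec):
        manifest = sd.write_cohort(
            3, tmp_path, striatum_spec=small_spec,
            bold_spec=sd.BoldSpec(n_timepoints=10), seed=1)
        import json
        m = json.loads(manifest.read_text())
        assert len(m["subjects"]) == 3
        for entry in m["subjects"]:
            files = entry["files"]
            assert len(files["counts"]) == 10
            assert "labels" in files and "bold" in files

    def test_regeneration_is_byte_identical(self, tmp_path, small_spec):
        import json
        from pathlib import Path

        kw = dict(striatum_spec=small_spec,
                  bold_spec=sd.BoldSpec(n_timepoints=10), seed=5)
        m1 = json.loads(sd.write_cohort(2, tmp_path / "a", **kw).read_text())
        m2 = json.loads(sd.write_cohort(2, tmp_path / "b", **kw).read_text())
        f1 = m1["subjects"][0]["files"]["truth"]
        f2 = m2["subjects"][0]["files"]["truth"]
        import gzip
        assert gzip.open(f1).read() == gzip.open(f2).read()

    def test_zero_subjects_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="n_subjects"):
            sd.write_cohort(0, tmp_path)

    def test_bundle_density_requires_seed(self):
        with pytest.raises(ValueError):
            sd.simulate_bundle_density(np.zeros((4, 4, 4), dtype=bool))
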