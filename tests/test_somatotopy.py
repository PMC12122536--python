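"""N-1 contribution maps, zone segmentation and refinement, zone ANOVA."""

import warnings

import numpy as np
import pytest

from striocompart import synthetic_data as sd
from striocompart.parcellation import classify_voxels, compute_bias
from striocompart.somatotopy import (ContributionMap, contribution_maps,
                                     fwhm_volume, refine_zones, segment_zones,
                                     zone_bias_anova)


@pytest.fixture(scope="module")
def cohort_maps(cohort4):
    baits = sd.BaitRegionSet()
    maps = contribution_maps([s.counts for s in cohort4], baits)
    return cohort4, baits, maps


def _add_region(tcm, name, cls, values=None):
    tcm.counts[name] = (np.zeros_like(tcm.counts["S"]) if values is None
                        else np.asarray(values, dtype=float).reshape(
                            tcm.counts["S"].shape))
    tcm.favored[name] = cls
    return tcm


class TestContributionMaps:
    def test_zero_count_region_contributes_nothing(self, toy_counts_factory):
        tcm = toy_counts_factory([9, 1], [1, 9])
        _add_region(tcm, "S2", "striosome")
        _add_region(tcm, "M2", "matrix")
        maps = contribution_maps([tcm])
        np.testing.assert_allclose(maps["S2"].delta, 0.0)

    def test_identical_regions_identical_maps(self, toy_counts_factory):
        tcm = toy_counts_factory([9, 1, 4], [1, 9, 4])
        _add_region(tcm, "S2", "striosome", tcm.counts["S"])
        _add_region(tcm, "M2", "matrix")
        maps = contribution_maps([tcm])
        np.testing.assert_allclose(maps["S"].delta, maps["S2"].delta)

    def test_matches_hand_computed_p_differences(self, toy_counts_factory):
        # 5-voxel algebraic oracle, single subject
        s1 = np.array([8.0, 2, 4, 0, 6])
        s2 = np.array([2.0, 6, 1, 0, 3])
        m1 = np.array([1.0, 1, 5, 0, 2])
        tcm = toy_counts_factory(s1, m1)
        _add_region(tcm, "S2", "striosome", s2)
        _add_region(tcm, "M2", "matrix")
        maps = contribution_maps([tcm])
        with np.errstate(invalid="ignore", divide="ignore"):
            p_full = (s1 + s2) / (s1 + s2 + m1)
            p_n1 = s1 / (s1 + m1)
        expect = p_full - p_n1
        got = maps["S2"].delta.ravel()
        np.testing.assert_allclose(got[:3], expect[:3], atol=1e-12)
        assert np.isnan(got[3])  # undefined where all counts vanish
        # own-class amplitude positive where the region pushed its own class
        assert (maps["S2"].own_amplitude.ravel()[:3] >= 0).all()

    def test_cohort_averaging_before_subtraction(self, toy_counts_factory):
        a = toy_counts_factory([9, 1], [1, 9])
        b = toy_counts_factory([1, 9], [9, 1])
        for t in (a, b):
            _add_region(t, "S2", "striosome", np.ones_like(t.counts["S"]))
            _add_region(t, "M2", "matrix")
        maps = contribution_maps([a, b])
        # average of per-subject P values, then subtract: symmetric cohort
        # gives identical deltas at both voxels
        d = maps["S2"].delta.ravel()
        assert d[0] == pytest.approx(d[1])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="cohort"):
            contribution_maps([])


class TestSegmentZones:
    def _map(self, name, favored, delta):
        return ContributionMap(region=name, favored=favored,
                               delta=np.asarray(delta, dtype=float))

    def test_single_dominant_region(self):
        a = self._map("a", "striosome", np.full((2, 2, 2), 0.2))
        b = self._map("b", "striosome", np.full((2, 2, 2), 0.1))
        zones = segment_zones({"a": a, "b": b})
        assert (zones.coarse == 1).all()

    def test_two_regions_split_halves(self):
        d_a = np.zeros((4, 2, 1))
        d_a[:2] = 0.3
        d_b = np.zeros((4, 2, 1))
        d_b[2:] = 0.3
        zones = segment_zones({"a": self._map("a", "striosome", d_a),
                               "b": self._map("b", "matrix", -d_b)})
        assert (zones.coarse[:2] == 1).all()
        assert (zones.coarse[2:] == 2).all()

    def test_no_positive_contribution_is_unlabeled(self):
        a = self._map("a", "striosome", np.full((2, 2, 2), -0.1))
        b = self._map("b", "matrix", np.full((2, 2, 2), 0.1))
        zones = segment_zones({"a": a, "b": b})
        assert (zones.coarse == 0).all()

    def test_tie_break_by_region_order(self):
        a = self._map("a", "striosome", np.full((2, 2, 2), 0.2))
        b = self._map("b", "striosome", np.full((2, 2, 2), 0.2))
        zones = segment_zones({"a": a, "b": b})
        assert (zones.coarse == 1).all()

    def test_mirror_symmetry_oracle(self, cohort_maps):
        # segmenting x-mirrored contribution maps mirrors the segmentation
        _, _, maps = cohort_maps
        flipped = {n: ContributionMap(region=m.region, favored=m.favored,
                                      delta=m.delta[::-1])
                   for n, m in maps.items()}
        z = segment_zones(maps)
        zf = segment_zones(flipped)
        np.testing.assert_array_equal(zf.coarse, z.coarse[::-1])

    def test_left_right_zones_mirror_on_synthetic_cohort(self, cohort_maps):
        # hemispheres are parcellated from mirrored generative anchors, so
        # zone labels should largely agree under x reflection
        cohort, _, maps = cohort_maps
        gt = cohort[0].gt
        zones = segment_zones(maps)
        left = gt.hemisphere_mask("L") & gt.striatum_mask
        lab = zones.coarse.copy()
        lab[~gt.striatum_mask] = -1
        mirrored = lab[::-1]
        both = left & (mirrored >= 0)
        agree = np.mean(zones.coarse[both] == mirrored[both])
        # count noise keeps agreement below identity, but well above the
        # ~1/10 chance level of a 10-region labeling
        assert agree > 0.5


class TestRefineZones:
    def _setup(self, n_zone=75, amp_kind="graded"):
        shape = (10, 10, 4)
        delta = np.zeros(shape)
        zone = np.zeros(shape, dtype=bool)
        zone[:5, :5, :] = True          # left-half zone
        zone[5:, :5, :] = True          # right half mirrors
        rng = np.random.default_rng(0)
        if amp_kind == "graded":
            delta[zone] = rng.random(int(zone.sum())) + 0.01
        else:
            delta[zone] = 0.5
        cm = ContributionMap(region="a", favored="striosome", delta=delta)
        zones = segment_zones({"a": cm,
                               "b": ContributionMap("b", "matrix",
                                                    np.zeros(shape))})
        hemis = {"L": np.zeros(shape, dtype=bool),
                 "R": np.zeros(shape, dtype=bool)}
        hemis["L"][:5] = True
        hemis["R"][5:] = True
        return {"a": cm, "b": ContributionMap("b", "matrix", np.zeros(shape))}, zones, hemis

    def test_zone_within_range_kept(self):
        maps, zones, hemis = self._setup()
        refined = refine_zones(maps, zones, hemis, target_size=(50, 100))
        for side in ("L", "R"):
            n = refined.refined[("a", side)].sum()
            assert 50 <= n <= 100

    def test_uniform_amplitude_tie_break(self):
        maps, zones, hemis = self._setup(amp_kind="uniform")
        refined = refine_zones(maps, zones, hemis, target_size=(50, 100))
        sizes = {s: int(refined.refined[("a", s)].sum()) for s in ("L", "R")}
        assert all(50 <= n <= 100 for n in sizes.values())
        assert abs(sizes["L"] - sizes["R"]) <= 3

    def test_left_right_volumes_matched(self):
        maps, zones, hemis = self._setup()
        refined = refine_zones(maps, zones, hemis)
        nl = refined.refined[("a", "L")].sum()
        nr = refined.refined[("a", "R")].sum()
        assert abs(int(nl) - int(nr)) <= 3

    def test_refined_subset_of_coarse(self, cohort_maps):
        cohort, _, maps = cohort_maps
        gt = cohort[0].gt
        zones = segment_zones(maps)
        hemis = {s: gt.hemisphere_mask(s) for s in ("L", "R")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined = refine_zones(maps, zones, hemis)
        inv_regions = {n: i for i, n in refined.regions.items()}
        masks = list(refined.refined.items())
        for (region, side), mask in masks:
            assert (zones.coarse[mask] == inv_regions[region]).all()
        # pairwise disjoint
        total = np.zeros(gt.nucleus_labels.shape, dtype=int)
        for _, mask in masks:
            total += mask
        assert total.max() <= 1

    def test_undersized_zone_dropped_with_warning(self):
        maps, zones, hemis = self._setup()
        with pytest.warns(UserWarning, match="dropped"):
            refined = refine_zones(maps, zones, hemis, target_size=(500, 600))
        assert ("a", "L") not in refined.refined

    def test_hemisphere_independence(self, cohort_maps):
        # corrupting right-hemisphere amplitudes leaves left zones unchanged
        cohort, _, maps = cohort_maps
        gt = cohort[0].gt
        zones = segment_zones(maps)
        hemis = {s: gt.hemisphere_mask(s) for s in ("L", "R")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = refine_zones(maps, zones, hemis, lr_tolerance=10 ** 9)
            corrupted = {}
            for n, m in maps.items():
                delta = m.delta.copy()
                delta[hemis["R"]] *= 0.5
                corrupted[n] = ContributionMap(n, m.favored, delta)
            zc = segment_zones(corrupted)
            zc.coarse[hemis["L"]] = zones.coarse[hemis["L"]]
            ref_c = refine_zones(corrupted, zc, hemis, lr_tolerance=10 ** 9)
        for key in ref.refined:
            region, side = key
            if side == "L" and key in ref_c.refined:
                np.testing.assert_array_equal(ref.refined[key],
                                              ref_c.refined[key])

    def test_dispersed_regions_have_larger_fwhm(self, cohort_maps):
        _, baits, maps = cohort_maps
        disp = np.mean([fwhm_volume(maps[n]) for n in baits.dispersed])
        focal = np.mean([fwhm_volume(maps[n]) for n in baits.names
                         if n not in baits.dispersed])
        assert disp > focal


class TestZoneAnova:
    @pytest.fixture(scope="class")
    def refined_setup(self, cohort_maps):
        cohort, baits, maps = cohort_maps
        gt = cohort[0].gt
        zones = segment_zones(maps)
        hemis = {s: gt.hemisphere_mask(s) for s in ("L", "R")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refined = refine_zones(maps, zones, hemis)
        labels = [classify_voxels(compute_bias(s.counts)) for s in cohort]
        return refined, labels, baits

    def test_identical_fractions_give_null_f(self, refined_setup):
        refined, labels, baits = refined_setup
        # all-striosome labels: the fraction is 1 in every zone, so the
        # compartment effect vanishes
        flat = np.full_like(labels[0], 1)
        _, res = zone_bias_anova(refined, [flat] * len(labels), baits.favored)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_compartment_effect_detected(self, refined_setup):
        refined, labels, baits = refined_setup
        table, res = zone_bias_anova(refined, labels, baits.favored)
        by_class = table.groupby("compartment")["striosome_fraction"].mean()
        assert by_class["striosome"] > by_class["matrix"]
        assert res["p"] < 0.05
        assert 0 < res["r_squared"] <= 1

    def test_permutation_null_calibration(self, refined_setup):
        from striocompart.somatotopy import permute_zone_classes

        refined, labels, baits = refined_setup
        # destroy the compartment signal by shuffling each subject's labels
        rng = np.random.default_rng(0)
        null_labels = []
        for lab in labels:
            flat = lab.copy().ravel()
            idx = np.flatnonzero(flat > 0)
            flat[idx] = flat[rng.permutation(idx)]
            null_labels.append(flat.reshape(lab.shape))
        f_obs, null, p_perm = permute_zone_classes(
            refined, null_labels, baits.favored, n_perm=60, seed=1)
        assert p_perm > 0.01  # no signal -> permutation p not extreme
        # and with the real labels the permutation test is significant
        f_obs2, _, p2 = permute_zone_classes(refined, labels, baits.favored,
                                             n_perm=60, seed=1)
        assert p2 < 0.05
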