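import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from epispread.network import threshold_network
from epispread.patterns import (ClinicalPattern, FitConfig, FitResult,
                                fit_threshold, fully_connected_baseline,
                                load_clinical_pattern, median_correlation_curve,
                                midpoint_ranks, model_pattern,
                                nearest_roi_assignment, pattern_correlation)

from conftest import make_net, make_rois, random_symmetric
from oracles import rank_correlation_literal


class TestRanksAndLoading:
    def test_midpoint_ranks_of_stepped_pattern(self):
        ranks = midpoint_ranks([1, 1, 2, 3, 3, 3])
        assert np.array_equal(ranks, [1.5, 1.5, 3, 5, 5, 5])

    @given(st.lists(st.integers(1, 6), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_rank_mean_is_preserved(self, steps):
        ranks = midpoint_ranks(steps)
        assert np.mean(ranks) == pytest.approx((len(steps) + 1) / 2)

    def test_contact_points_merged_to_earliest_step(self, tmp_path):
        rois = make_rois(6)
        tsv = ("cp_id\telectrode_id\troi_id\tactivation_step\n"
               "1\tE1\t3\t4\n2\tE1\t3\t2\n3\tE2\t5\t1\n")
        path = tmp_path / "p.tsv"
        path.write_text(tsv)
        pat = load_clinical_pattern(path, rois)
        assert pat.n_sampled == 2
        assert dict(zip(pat.roi_ids, pat.steps)) == {3: 2, 5: 1}

    def test_six_distinct_rois_ranked_by_midpoint_rule(self, tmp_path):
        rois = make_rois(6)
        lines = ["cp_id\telectrode_id\troi_id\tactivation_step"]
        for i, s in enumerate([1, 1, 2, 3, 3, 3], start=1):
            lines.append(f"{i}\tE1\t{i}\t{s}")
        path = tmp_path / "p.tsv"
        path.write_text("\n".join(lines) + "\n")
        pat = load_clinical_pattern(path, rois)
        assert np.array_equal(pat.ranks, [1.5, 1.5, 3, 5, 5, 5])

    def test_nonpositive_step_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("cp_id\telectrode_id\troi_id\tactivation_step\n1\tE1\t1\t0\n")
        with pytest.raises(ValueError, match="positive"):
            load_clinical_pattern(path, make_rois(3))

    def test_coordinates_resolved_via_nearest_centroid(self, tmp_path):
        rois = make_rois(5)
        x, y, z = rois.centroids[2]
        path = tmp_path / "p.tsv"
        path.write_text("cp_id\telectrode_id\tx_mm\ty_mm\tz_mm\tactivation_step\n"
                        f"1\tE1\t{x}\t{y}\t{z}\t1\n")
        pat = load_clinical_pattern(path, rois)
        assert list(pat.roi_ids) == [3]


class TestNearestRoi:
    def test_exact_centroid_hit(self):
        rois = make_rois(4)
        assert nearest_roi_assignment([rois.centroids[1]], rois)[0] == 2

    def test_equidistant_tie_goes_to_smaller_id(self):
        rois = make_rois(2)
        c = rois.centroids.copy()
        c[0] = [0, 0, 0]
        c[1] = [2, 0, 0]
        object.__setattr__(rois, "centroids", c)
        assert nearest_roi_assignment([[1, 0, 0]], rois)[0] == 1

    def test_three_roi_hand_check(self):
        rois = make_rois(3)
        c = np.array([[0, 0, 0], [10, 0, 0], [0, 6, 0]], dtype=float)
        object.__setattr__(rois, "centroids", c)
        assert nearest_roi_assignment([[1, 4, 0]], rois)[0] == 3


class TestModelPattern:
    def test_strictly_increasing_times_rank_identically(self):
        rois = make_rois(5)
        mp = model_pattern([0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5], rois)
        assert np.array_equal(mp.ranks, [1, 2, 3, 4, 5])

    def test_full_tie_is_degenerate(self):
        rois = make_rois(4)
        mp = model_pattern([0.5] * 4, [1, 2, 3, 4], rois)
        assert mp.degenerate
        assert np.all(mp.ranks == 2.5)

    def test_partial_tie_midpoint(self):
        rois = make_rois(3)
        mp = model_pattern([0.2, 0.2, 0.9], [1, 2, 3], rois)
        assert np.array_equal(mp.ranks, [1.5, 1.5, 3])

    def test_subset_only_is_ranked(self):
        rois = make_rois(5)
        mp = model_pattern([9, 1, 2, 3, 0], [2, 3, 4], rois)
        assert np.array_equal(mp.ranks, [1, 2, 3])

    def test_missing_time_is_an_error(self):
        rois = make_rois(3)
        with pytest.raises(ValueError, match="missing"):
            model_pattern([0.1, np.nan, 0.2], [1, 2, 3], rois)


class TestPatternCorrelation:
    def test_identical_and_reversed(self):
        r = midpoint_ranks([1, 2, 3, 4, 5])
        assert pattern_correlation(r, r, n_perm=200)[0] == pytest.approx(1.0)
        assert pattern_correlation(r, r[::-1], n_perm=200)[0] == pytest.approx(-1.0)

    def test_hand_computed_tied_example(self):
        c, _ = pattern_correlation([1.5, 1.5, 3], [1, 2, 3], n_perm=200)
        assert c == pytest.approx(0.866, abs=5e-4)

    @pytest.mark.parametrize("rng_seed", [0, 1, 2, 3])
    def test_equals_literal_formula_and_tied_spearman(self, rng_seed):
        rng = np.random.default_rng(rng_seed)
        a = midpoint_ranks(rng.integers(1, 6, size=25))
        b = midpoint_ranks(rng.integers(1, 6, size=25))
        c, _ = pattern_correlation(a, b, n_perm=100)
        assert c == pytest.approx(rank_correlation_literal(a, b), abs=1e-12)
        assert c == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)

    def test_permutation_pvalue_calibration(self):
        # unrelated rankings should rarely be significant
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(40):
            a = midpoint_ranks(rng.permutation(20))
            b = midpoint_ranks(rng.permutation(20))
            ps.append(pattern_correlation(a, b, n_perm=500, rng_seed=1)[1])
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_constant_ranking_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            pattern_correlation([2, 2, 2], [1, 2, 3], n_perm=10)


class TestFitThreshold:
    def _planted_patient(self, rng_seed=0):
        from epispread.synth import SyntheticPatientConfig, generate_patient

        cfg = SyntheticPatientConfig(n_rois=90, n_sampled=30, seed_size=4,
                                     theta_true=0.10, rng_seed=rng_seed)
        return generate_patient(cfg)

    def test_default_grid_contains_atlas_kappa_anchor(self):
        from epispread.network import DEFAULT_THETA_GRID

        assert 0.10 in DEFAULT_THETA_GRID
        assert 0.10 * 246 == pytest.approx(24.60)

    def test_recovers_planted_density_neighbourhood(self):
        p = self._planted_patient(11)
        fr = fit_threshold(p.network, p.clinical, p.seed_ids,
                           cfg=FitConfig(n_runs=800, n_perm=1000, rng_seed=1))
        assert fr.significant
        assert fr.c_max > 0.8
        assert 0.08 <= fr.theta_max <= 0.15  # within one grid step of 0.10
        assert fr.kappa_max == pytest.approx(fr.theta_max * 90)

    def test_deterministic_given_master_seed(self):
        p = self._planted_patient(12)
        kw = dict(cfg=FitConfig(n_runs=200, n_perm=500, rng_seed=5))
        a = fit_threshold(p.network, p.clinical, p.seed_ids, **kw)
        b = fit_threshold(p.network, p.clinical, p.seed_ids, **kw)
        assert np.array_equal(a.correlations, b.correlations)
        assert a.theta_max == b.theta_max

    def test_permuted_pattern_is_not_significant(self):
        from epispread.synth import permuted_control

        p = self._planted_patient(13)
        ctrl = permuted_control(p, rng_seed=3)
        fr = fit_threshold(p.network, ctrl.clinical, p.seed_ids,
                           cfg=FitConfig(n_runs=400, n_perm=1000, rng_seed=2))
        assert not fr.significant or fr.c_max < 0.5

    def test_unknown_seed_roi_rejected(self):
        p = self._planted_patient(14)
        with pytest.raises(KeyError):
            fit_threshold(p.network, p.clinical, [999],
                          cfg=FitConfig(n_runs=10, n_perm=10))


class TestMedianCurve:
    def _fit(self, thetas, cs):
        thetas = np.asarray(thetas, float)
        return FitResult(thetas=thetas, correlations=np.asarray(cs, float),
                         pvalues=np.zeros_like(thetas), theta_max=thetas[0],
                         kappa_max=0, c_max=max(cs), p_max=0, significant=True)

    def test_single_patient_returns_own_curve(self):
        f = self._fit([0.1, 0.2], [0.5, 0.3])
        df = median_correlation_curve([f])
        assert np.array_equal(df["median_C"], f.correlations)

    def test_median_of_three(self):
        fits = [self._fit([0.1], [c]) for c in (0.2, 0.9, 0.4)]
        assert median_correlation_curve(fits)["median_C"].iloc[0] == 0.4

    def test_median_argmax_can_differ_from_every_individual_argmax(self):
        thetas = [0.1, 0.2, 0.3]
        fits = [
            self._fit(thetas, [0.9, 0.5, 0.1]),   # argmax 0.1
            self._fit(thetas, [0.1, 0.5, 0.9]),   # argmax 0.3
            self._fit(thetas, [0.0, 0.6, 0.2]),   # argmax 0.2
        ]
        df = median_correlation_curve(fits)
        assert df.loc[df["best"], "theta"].iloc[0] == pytest.approx(0.2)
        assert np.array_equal(df["median_C"], [0.1, 0.5, 0.2])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            median_correlation_curve([self._fit([0.1], [0.5]),
                                      self._fit([0.2], [0.5])])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            median_correlation_curve([])


class TestFullyConnectedBaseline:
    def test_no_sampled_seed_roi_is_degenerate(self):
        rois = make_rois(10)
        pat = ClinicalPattern.from_steps([5, 6, 7], [1, 2, 3])
        out = fully_connected_baseline(pat, [1, 2], rois)
        assert out["degenerate"] and out["C"] == 0.0

    def test_sampled_seed_roi_gives_onset_signal(self):
        rois = make_rois(10)
        # seed ROI 1 activates first clinically: baseline captures that
        pat = ClinicalPattern.from_steps([1, 5, 6, 7], [1, 2, 3, 3])
        out = fully_connected_baseline(pat, [1], rois)
        assert not out["degenerate"]
        assert out["C"] > 0

    def test_baseline_below_individual_fit_on_planted_patient(self):
        from epispread.synth import SyntheticPatientConfig, generate_patient

        cfg = SyntheticPatientConfig(n_rois=90, n_sampled=30, seed_size=4,
                                     theta_true=0.10, rng_seed=21)
        p = generate_patient(cfg)
        fr = fit_threshold(p.network, p.clinical, p.seed_ids,
                           cfg=FitConfig(n_runs=600, n_perm=500, rng_seed=0))
        base = fully_connected_baseline(p.clinical, p.seed_ids, p.rois)
        assert base["C"] <= fr.c_max
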