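"""Resampling machinery: LOO-CV selection, permutation p-values, bootstrap
ratios, display fill, and the adjusted/unadjusted chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skelcca import (
    SaliencyVolume,
    SimulationConfig,
    adjusted_and_unadjusted,
    bootstrap_saliency,
    compute_bootstrap_ratio,
    fill_for_display,
    generate_cohort,
    loocv_select_q,
    permutation_test,
    threshold_ratios,
)
from skelcca.errors import DegenerateDataError, SchemaError


class TestLoocvSelectQ:
    def test_noise_free_rank_one_signal_selects_one(self, rng):
        z = rng.standard_normal(30)
        a = rng.normal(size=100)
        x = np.outer(z, a) + 1e-6 * rng.normal(size=(30, 100))
        y = z + 0.05 * rng.standard_normal(30)
        sel = loocv_select_q(x, y, range(1, 6))
        assert sel.selected_q == 1
        assert sel.n_folds == 30

    def test_three_spike_signal_peaks_low_near_oracle(self):
        """Signal spread over 3 orthogonal spikes: CV peak near the generating
        correlation and at small q (20-replicate averages)."""
        n, p, rho = 120, 400, 0.6
        peaks, argmaxes, oracles = [], [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            spikes = np.zeros((3, p))
            for k in range(3):
                spikes[k, 100 * k : 100 * k + 30] = 1 / np.sqrt(30)
            zs = rng.standard_normal((n, 3))
            x = 7.0 * zs @ spikes + rng.standard_normal((n, p))
            w = zs.sum(axis=1) / np.sqrt(3)
            alpha = rho / np.sqrt(1 - rho**2)
            y = alpha * w + rng.standard_normal(n)
            oracles.append(np.corrcoef(w, y)[0, 1])
            sel = loocv_select_q(x, y, range(1, 9))
            peaks.append(max(sel.cv_correlations.values()))
            argmaxes.append(sel.selected_q)
        assert abs(np.mean(peaks) - np.mean(oracles)) < 0.15
        assert np.median(argmaxes) <= 5

    def test_null_cohort_selection_well_defined(self, small_cohort):
        ds, tb, _ = small_cohort
        rng = np.random.default_rng(4)
        y_null = rng.standard_normal(ds.n_subjects)
        sel = loocv_select_q(ds, y_null, range(1, 6))
        assert sel.selected_q in range(1, 6)
        assert all(abs(v) < 0.6 for v in sel.cv_correlations.values())

    def test_constant_fold_score_reported(self, rng):
        x = rng.normal(size=(10, 20))
        y = np.zeros(10)
        y[0] = 1.0  # every fold keeping subject 0 removed leaves a constant y
        with pytest.raises(DegenerateDataError, match="fold"):
            loocv_select_q(x, y, [1, 2])


class TestPermutationTest:
    def test_add_one_p_when_observed_beats_all(self, rng):
        # y is (nearly) a column of x -> observed R ~ 1 beats all permutations
        y = rng.standard_normal(20)
        x = np.column_stack([y, rng.normal(size=(20, 10))])
        res = permutation_test(x, y, q=3, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_p_is_one_when_observed_never_wins(self, rng):
        # force the degenerate ranking by thresholding on the formula directly:
        # all null draws >= observed gives the upper bound (1+n)/(1+n) = 1
        y = rng.standard_normal(15)
        x = rng.normal(size=(15, 30))
        res = permutation_test(x, y, q=2, n_perm=99, seed=1)
        worst = (1 + np.sum(res.null_rs >= 0.0)) / (1 + res.n_perm)
        assert worst == 1.0
        assert res.p_value == (1 + np.sum(res.null_rs >= res.observed_r)) / 100

    def test_observed_matches_full_fit_and_null_in_unit_interval(self, small_cohort):
        from skelcca import fit_cca_single, fit_truncated_svd

        ds, tb, _ = small_cohort
        y = tb.score("score")
        res = permutation_test(ds, y, q=4, n_perm=199, seed=3)
        _, scores = fit_truncated_svd(ds.matrix, 4)
        assert res.observed_r == pytest.approx(
            fit_cca_single(scores, y).correlation, abs=1e-10
        )
        assert np.all((res.null_rs >= 0) & (res.null_rs <= 1))
        assert 0 < res.p_value <= 1

    def test_reproducible_from_seed(self, small_cohort):
        ds, tb, _ = small_cohort
        y = tb.score("score")
        r1 = permutation_test(ds, y, q=3, n_perm=199, seed=42)
        r2 = permutation_test(ds, y, q=3, n_perm=199, seed=42)
        np.testing.assert_array_equal(r1.null_rs, r2.null_rs)
        assert r1.p_value == r2.p_value

    def test_null_p_values_uniform(self):
        """Empirical CDF of null p-values stays within a KS band around uniform."""
        ps = []
        for i in range(200):
            rng = np.random.default_rng(5000 + i)
            x = rng.normal(size=(30, 50))
            y = rng.standard_normal(30)
            ps.append(permutation_test(x, y, q=3, n_perm=99, seed=6000 + i).p_value)
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        ks = np.max(np.abs(ecdf - ps))
        assert ks < 1.63 / np.sqrt(len(ps))  # 1% KS critical value

    def test_constant_score_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            permutation_test(rng.normal(size=(12, 20)), np.ones(12), q=2, n_perm=99)


class TestBootstrapRatio:
    def test_mean_over_sd_example(self):
        w = np.array([[1.0], [2.0], [3.0]])
        ratio, flags = compute_bootstrap_ratio(w)
        assert ratio[0] == pytest.approx(2.0)
        assert not flags[0]

    def test_zero_variance_sentinel(self):
        w = np.array([[2.0, -1.0, 0.0]] * 5)
        ratio, flags = compute_bootstrap_ratio(w)
        assert ratio[0] == np.inf and ratio[1] == -np.inf and ratio[2] == 0.0
        assert flags.all()

    def test_threshold_sign_mask(self):
        mask = threshold_ratios(np.array([2.5, -2.2, 1.0]), 1.96)
        np.testing.assert_array_equal(mask, [1, -1, 0])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        t1=st.floats(0.0, 3.0),
        dt=st.floats(0.0, 2.0),
    )
    def test_raising_threshold_never_adds_voxels(self, seed, t1, dt):
        ratio = np.random.default_rng(seed).normal(scale=2.0, size=50)
        low = threshold_ratios(ratio, t1) != 0
        high = threshold_ratios(ratio, t1 + dt) != 0
        assert not np.any(high & ~low)


class TestBootstrapSaliency:
    def test_sign_correction_keeps_mean_weights_aligned(self, small_cohort):
        ds, tb, _ = small_cohort
        res = bootstrap_saliency(ds, tb.score("score"), q=2, b_folds=50, seed=0)
        r = np.corrcoef(res.weight_distribution.mean(axis=0), res.reference_weights)[0, 1]
        assert r >= 0
        # every stored fold respects the sign correction
        dots = res.weight_distribution @ res.reference_weights
        assert np.all(dots >= 0)

    def test_deterministic_given_seed(self, small_cohort):
        ds, tb, _ = small_cohort
        a = bootstrap_saliency(ds, tb.score("score"), q=2, b_folds=30, seed=5)
        b = bootstrap_saliency(ds, tb.score("score"), q=2, b_folds=30, seed=5)
        np.testing.assert_array_equal(a.ratio, b.ratio)
        np.testing.assert_array_equal(a.signed_mask, b.signed_mask)

    def test_signed_mask_consistent_with_ratio(self, small_cohort):
        ds, tb, _ = small_cohort
        res = bootstrap_saliency(ds, tb.score("score"), q=2, b_folds=40, seed=1)
        np.testing.assert_array_equal(
            res.signed_mask, threshold_ratios(res.ratio, res.threshold)
        )

    def test_recovers_planted_salient_voxels(self):
        cfg = SimulationConfig(n_subjects=100, grid_shape=(10, 10, 8),
                               skeleton_fraction=0.5, n_salient=25, rho=0.7, seed=17)
        ds, tb, gt = generate_cohort(cfg)
        res = bootstrap_saliency(ds, tb.score("score"), q=2, b_folds=150, seed=2)
        flags = gt.salient_flags(ds.voxel_index)
        salient = flags != 0
        # |ratio| separates planted from background voxels
        assert np.median(np.abs(res.ratio[salient])) > np.percentile(
            np.abs(res.ratio[~salient]), 95
        )
        supra_salient = (res.signed_mask != 0) & salient
        assert supra_salient.sum() > 0
        agree = (res.signed_mask[supra_salient] == flags[supra_salient]).mean()
        assert agree > 0.9


class TestFillForDisplay:
    @staticmethod
    def _volume(shape=(7, 7, 7)):
        mask = np.ones(shape, dtype=bool)
        values = np.zeros(shape)
        values[3, 3, 3] = 1.0
        return SaliencyVolume(values, mask)

    def test_radius_zero_is_identity(self):
        vol = self._volume()
        out = fill_for_display(vol, np.full(vol.values.shape, 0.5), radius=0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_single_voxel_dilates_to_cube(self):
        vol = self._volume()
        out = fill_for_display(vol, np.full(vol.values.shape, 0.5), radius=1)
        assert int((out.values == 1).sum()) == 27
        assert out.meta["filled"] is True

    def test_low_fa_neighbors_not_filled(self):
        vol = self._volume()
        fa = np.full(vol.values.shape, 0.5)
        fa[3, 3, 4] = 0.1
        out = fill_for_display(vol, fa, radius=1)
        assert out.values[3, 3, 4] == 0
        assert int((out.values == 1).sum()) == 26

    def test_contested_voxels_stay_zero(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        values = np.zeros((5, 5, 5))
        values[2, 2, 1] = 1.0
        values[2, 2, 3] = -1.0
        out = fill_for_display(SaliencyVolume(values, mask),
                               np.full((5, 5, 5), 0.5), radius=1)
        assert out.values[2, 2, 2] == 0  # reached by both signs
        assert out.values[2, 2, 0] == 1 and out.values[2, 2, 4] == -1


class TestAdjustedAndUnadjusted:
    def test_arms_agree_without_confounding(self):
        rs_diff = []
        for seed in range(5):
            cfg = SimulationConfig(n_subjects=150, grid_shape=(8, 8, 8),
                                   skeleton_fraction=0.4, n_salient=20, rho=0.6,
                                   seed=800 + seed)
            ds, tb, _ = generate_cohort(cfg)
            res = adjusted_and_unadjusted(
                ds, tb, "score", q_grid=range(1, 4), n_perm=99, seed=1,
                run_bootstrap=False,
            )
            rs_diff.append(abs(res["unadjusted"].solution.correlation
                               - res["adjusted"].solution.correlation))
        assert np.mean(rs_diff) < 0.05

    def test_pure_age_effect_killed_by_adjustment(self):
        """Score driven only by age: the adjusted permutation p is null."""
        nonsig = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SimulationConfig(n_subjects=80, grid_shape=(8, 8, 4),
                                   skeleton_fraction=0.5, n_salient=10, rho=0.0,
                                   confound_beta_age=0.8, seed=900 + seed)
            ds, tb, _ = generate_cohort(cfg)
            res = adjusted_and_unadjusted(
                ds, tb, "score", q_grid=range(1, 4), n_perm=99, seed=2,
                run_bootstrap=False,
            )
            nonsig += res["adjusted"].permutation.p_value > 0.05
        assert nonsig >= 0.9 * n_rep

    def test_missing_covariates_schema_error(self, small_cohort):
        ds, tb, _ = small_cohort
        with pytest.raises(SchemaError):
            adjusted_and_unadjusted(ds, tb, "score",
                                    covariate_columns=("age", "education"))
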