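"""Permutation testing, FDR, rank correlation, sensitivity and power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mstconnect.stats import (
    classify_response,
    cluster_perm_test,
    fdr_bh,
    kendall_tau,
    kendall_tau_many,
    min_detectable_effect,
    motion_sensitivity_suite,
    motion_summary_metrics,
    omnibus_group_by_metric,
    perm_test_two_group,
    perm_test_two_group_many,
    remove_outliers_3iqr,
)


def tau_b_bruteforce(x, y):
    """Tie-corrected Kendall tau by exhaustive pair counting."""
    n = len(x)
    num = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
        num += a * b
        tx += a == 0
        ty += b == 0
    n0 = n * (n - 1) / 2
    return num / np.sqrt((n0 - tx) * (n0 - ty))


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "pre, post, responder",
        [(100, 70, True), (100, 71, False), (70.33, 32, True)],
    )
    def test_thirty_percent_rule(self, pre, post, responder):
        assert classify_response(pre, post) is responder

    def test_nonpositive_baseline_raises(self):
        with pytest.raises(ValueError):
            classify_response(0.0, 0.0)


class TestMotionSummary:
    def test_basic_metrics(self):
        m = motion_summary_metrics(np.array([0.1, 0.1, 0.3, 0.1]))
        assert m["median_fd"] == 0.1
        assert m["max_fd"] == 0.3
        assert m["n_outliers"] == 1

    def test_constant_fd_iqr_zero(self):
        assert motion_summary_metrics(np.full(10, 0.05))["iqr_fd"] == 0.0

    def test_iqr_linear_interpolation_convention(self):
        m = motion_summary_metrics(np.array([0.1, 0.2, 0.3, 0.4]))
        assert m["iqr_fd"] == pytest.approx(0.15)


class TestOutlierRemoval:
    def test_extreme_value_removed(self):
        kept, removed = remove_outliers_3iqr([1.0, 2.0, 3.0, 4.0, 100.0])
        assert removed.tolist() == [4]
        assert kept.tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_all_equal_kept(self):
        kept, removed = remove_outliers_3iqr(np.full(6, 2.0))
        assert removed.size == 0 and kept.size == 6

    def test_clean_sample_untouched(self, rng):
        kept, removed = remove_outliers_3iqr(rng.normal(size=50))
        assert removed.size == 0


class TestPermTestTwoGroup:
    def test_identical_samples_p_one(self):
        x = np.arange(10.0)
        res = perm_test_two_group(x, x, n_perm=500, seed=1)
        assert res.observed_stat == 0.0
        assert res.p_value == 1.0

    def test_extreme_separation_minimal_p(self):
        res = perm_test_two_group(
            np.zeros(20), np.full(20, 10.0), n_perm=10000, seed=2
        )
        assert res.p_value == pytest.approx(1 / 10001, rel=1e-9)

    def test_pvalue_floor(self):
        res = perm_test_two_group(np.zeros(5), np.ones(5), n_perm=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_vectorized_matches_scalar(self, rng):
        x = rng.normal(size=(12, 3))
        y = rng.normal(0.5, 1, size=(10, 3))
        obs, p = perm_test_two_group_many(x, y, n_perm=2000, seed=7)
        for j in range(3):
            res = perm_test_two_group(x[:, j], y[:, j], n_perm=2000, seed=7)
            assert obs[j] == pytest.approx(res.observed_stat)
            # same statistic, independent permutation streams
            assert p[j] == pytest.approx(res.p_value, abs=0.05)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            perm_test_two_group(np.array([1.0]), np.ones(5))


class TestOmnibus:
    def test_null_calibration(self, rng):
        rejections = np.zeros(2)
        p_metric = []
        n_reps = 150
        for _ in range(n_reps):
            X = rng.normal(size=(16, 3))
            groups = np.repeat([0, 1], 8)
            res = omnibus_group_by_metric(X, groups, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += [res["p_group"] < 0.05, res["p_interaction"] < 0.05]
            p_metric.append(res["p_metric"])
        rates = rejections / n_reps
        # discrete grid (n_perm = 99) makes the effective level 0.04
        assert np.all(rates >= 0.005) and np.all(rates <= 0.10)
        # the metric main effect is degenerate by construction: per-metric
        # z-standardization forces all column means to 0, so observed F ~ 0
        # and p ~ 1 (the analysis design tests group and interaction)
        assert np.median(p_metric) == 1.0

    def test_planted_interaction_detected(self, rng):
        X = rng.normal(size=(40, 3))
        groups = np.repeat([0, 1], 20)
        X[groups == 0, 1] += 3.0  # one metric shifted in one group only
        res = omnibus_group_by_metric(X, groups, n_perm=2000, seed=5)
        assert res["p_interaction"] < 0.01

    def test_constant_column_raises(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = 1.0
        df = pd.DataFrame(X, columns=["a", "b", "flat"])
        with pytest.raises(ValueError, match="flat"):
            omnibus_group_by_metric(df, np.repeat([0, 1], 5))


class TestFdrBh:
    def test_hand_computed_stepup(self):
        reject, p_adj = fdr_bh(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert reject.all()  # step-up passes at rank 3 since 0.04 <= 0.05
        assert np.allclose(p_adj, [0.03, 0.03, 0.04])

    def test_single_p_identity(self):
        reject, p_adj = fdr_bh(np.array([0.04]))
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_all_ones(self):
        reject, p_adj = fdr_bh(np.ones(5))
        assert not reject.any() and np.all(p_adj == 1.0)

    def test_bonferroni_rejections_subset_of_bh(self, rng):
        for _ in range(20):
            p = rng.random(15) ** 2
            bh, _ = fdr_bh(p, alpha=0.05)
            bonf = p <= 0.05 / p.size
            assert np.all(bh[bonf])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.1, 1.2]))


class TestKendallTau:
    def test_monotone_extremes(self):
        x = np.arange(6.0)
        assert kendall_tau(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert kendall_tau(x, -x)[0] == pytest.approx(-1.0)

    def test_pair_enumeration_example(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(4 / 6)

    def test_matches_bruteforce_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 11))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert kendall_tau(x, y)[0] == pytest.approx(tau_b_bruteforce(x, y))

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            kendall_tau(np.ones(5), np.arange(5.0))

    def test_vectorized_matches_scipy(self, rng):
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 8))
        tau, p = kendall_tau_many(x, Y)
        for j in range(8):
            ref = sps.kendalltau(x, Y[:, j], method="asymptotic")
            assert tau[j] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[j] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_vectorized_constant_column_is_nan(self, rng):
        Y = np.column_stack([rng.normal(size=20), np.ones(20)])
        tau, p = kendall_tau_many(rng.normal(size=20), Y)
        assert np.isnan(tau[1]) and np.isnan(p[1])


class TestMotionSensitivitySuite:
    def make_inputs(self, rng, n_subj=30, n_nodes=8, fd=None, confound=0.0):
        mats = []
        fd = rng.uniform(0.02, 0.2, n_subj) if fd is None else fd
        for s in range(n_subj):
            A = rng.normal(0.3, 0.1, (n_nodes, n_nodes)) + confound * fd[s]
            W = np.clip((A + A.T) / 2, -0.99, 0.99)
            np.fill_diagonal(W, 1.0)
            mats.append(W)
        deg = rng.normal(2, 0.5, (n_subj, n_nodes))
        bc = rng.random((n_subj, n_nodes))
        glob = pd.DataFrame(
            {
                "avg_strength": rng.normal(0.3, 0.05, n_subj),
                "leaf_fraction": rng.uniform(0.3, 0.8, n_subj),
            }
        )
        return np.array(mats), deg, bc, glob, fd

    def test_null_fd_yields_few_significant_edges(self, rng):
        mats, deg, bc, glob, fd = self.make_inputs(rng, n_subj=40)
        rep = motion_sensitivity_suite(mats, deg, bc, glob, fd)
        assert rep.pct_significant_edges <= 5.0
        assert abs(rep.edge_tau_mean) <= 0.05
        assert not rep.leaf_fraction_motion_confounded

    def test_planted_confound_detected(self, rng):
        mats, deg, bc, glob, fd = self.make_inputs(rng, n_subj=46, confound=2.0)
        rep = motion_sensitivity_suite(mats, deg, bc, glob, fd)
        assert rep.pct_significant_edges > 50.0

    def test_constant_edges_reported_not_raised(self, rng):
        n_subj = 20
        W = np.clip(rng.normal(0.3, 0.1, (8, 8)), -0.9, 0.9)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        mats = np.repeat(W[None], n_subj, axis=0)  # identical subjects
        deg = rng.normal(2, 0.5, (n_subj, 8))
        bc = rng.random((n_subj, 8))
        glob = pd.DataFrame({"avg_strength": rng.normal(0.3, 0.05, n_subj)})
        rep = motion_sensitivity_suite(
            mats, deg, bc, glob, rng.uniform(0.02, 0.2, n_subj)
        )
        assert rep.n_undefined_edges == 28  # all 8*7/2 edges constant
        assert rep.pct_significant_edges == 0.0

    def test_subject_count_mismatch_raises(self, rng):
        mats, deg, bc, glob, fd = self.make_inputs(rng)
        with pytest.raises(ValueError):
            motion_sensitivity_suite(mats, deg[:-1], bc, glob, fd)


class TestClusterPermTest:
    def test_single_voxel_reduces_to_t_perm_test(self, rng):
        n1, n2 = 10, 10
        maps = rng.normal(size=(n1 + n2, 1, 1, 1))
        maps[:n1] += 2.0
        groups = np.repeat([0, 1], [n1, n2])
        table = cluster_perm_test(
            maps, groups, cdt_p=0.5, n_perm=3000, seed=3
        )
        assert len(table) == 1
        ref = perm_test_two_group(
            maps[:n1, 0, 0, 0], maps[n1:, 0, 0, 0],
            n_perm=3000, seed=3, statistic="t",
        )
        assert table["p_fwe"].iloc[0] == pytest.approx(ref.p_value, abs=0.02)

    def test_planted_block_detected(self, rng):
        maps = rng.normal(size=(20, 8, 8, 8))
        maps[:10, 2:5, 2:5, 2:5] += 2.0
        groups = np.repeat([0, 1], 10)
        table = cluster_perm_test(maps, groups, n_perm=500, seed=1)
        assert table["significant"].any()
        top = table.iloc[0]
        assert top["n_voxels"] >= 14  # most of the 27-voxel block

    def test_covariate_regression_removes_confound(self, rng):
        # group difference fully explained by a covariate: no detection
        n = 24
        cov = np.concatenate([np.zeros(12), np.ones(12)])
        maps = rng.normal(size=(n, 6, 6, 6)) + 3.0 * cov[:, None, None, None]
        table = cluster_perm_test(
            maps, cov.astype(int), covariates=cov, n_perm=300, seed=2
        )
        assert not table["significant"].any()

    def test_grid_mismatch_raises(self, rng):
        maps = rng.normal(size=(12, 4, 4, 4))
        with pytest.raises(ValueError, match="mask"):
            cluster_perm_test(
                maps, np.repeat([0, 1], 6), mask=np.ones((5, 5, 5), dtype=bool)
            )


class TestMinDetectableEffect:
    def test_study_sample_size(self):
        d = min_detectable_effect(24, 22, 0.05, 0.80)
        assert d == pytest.approx(0.84, abs=0.01)

    def test_matches_statsmodels_solver(self):
        from statsmodels.stats.power import TTestIndPower

        ref = TTestIndPower().solve_power(
            nobs1=24, ratio=22 / 24, alpha=0.05, power=0.80, alternative="two-sided"
        )
        assert min_detectable_effect(24, 22) == pytest.approx(ref, abs=1e-3)

    def test_large_sample_normal_limit(self):
        d = min_detectable_effect(1000, 1000, 0.05, 0.50)
        assert d == pytest.approx(1.959964 * np.sqrt(2 / 1000), abs=2e-3)

    def test_monotone_in_sample_size(self):
        assert min_detectable_effect(48, 44) < min_detectable_effect(24, 22)

    def test_invalid_power_raises(self):
        with pytest.raises(ValueError):
            min_detectable_effect(24, 22, 0.05, 1.5)


class TestPermutationPValueUniformity:
    def test_null_pvalues_uniform_on_grid(self, rng):
        # p-values of a true-null permutation test are uniform on the
        # achievable grid; Kolmogorov-Smirnov should not reject at 1%
        pvals = []
        n_perm = 99
        for _ in range(500):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            pvals.append(perm_test_two_group(x, y, n_perm=n_perm, seed=int(rng.integers(2**31))).p_value)
        stat = sps.kstest(pvals, "uniform").statistic
        # allow for the discrete grid: KS distance inflated by ~1/(n_perm+1)
        assert stat <= 0.01 + 1.63 / np.sqrt(500) + 1 / (n_perm + 1)
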