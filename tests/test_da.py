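"""Differential tests: frozen oracles, limits, calibration, dispatch."""

import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import atacbench as ab
from atacbench.da import (
    MethodSpec,
    _partition_cdf,
    bh_adjust,
    estimate_common_dispersion,
    logcpm_transform,
    moderated_t_test,
    nb_exact_test,
    run_method,
    student_t_test,
    wilcoxon_test,
)


class TestLogCPM:
    def test_zero_counts_finite(self):
        v = logcpm_transform(np.zeros((3, 2)), np.array([1e6, 2e6]), prior_count=2)
        assert np.isfinite(v).all()

    def test_worked_example(self):
        v = logcpm_transform(np.array([[100.0]]), np.array([1e6]), prior_count=2)
        assert v[0, 0] == pytest.approx(np.log2(102 / 1_000_004 * 1e6), abs=1e-9)
        assert v[0, 0] == pytest.approx(6.6724, abs=1e-4)

    def test_depth_invariance_as_prior_vanishes(self):
        # positive counts: for zero counts the pseudo-count itself is the
        # signal, so exact invariance holds only in the prior -> 0 limit
        # of the nonzero cells
        counts = np.array([[10, 40], [100, 200], [5, 3]], dtype=float)
        libs = counts.sum(axis=0)
        a = logcpm_transform(counts, libs, prior_count=1e-9)
        b = logcpm_transform(2 * counts, 2 * libs, prior_count=1e-9)
        assert np.allclose(a, b, atol=1e-6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            logcpm_transform(np.zeros((2, 2)), np.array([0.0, 1.0]))


class TestBHAdjust:
    def test_handworked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        # non-decreasing in raw rank
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @given(st.permutations(list(range(8))))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, perm):
        p = np.array([0.9, 0.01, 0.2, 0.04, 0.6, 0.33, 0.05, 0.0005])
        perm = np.array(perm)
        assert np.allclose(bh_adjust(p[perm]), bh_adjust(p)[perm])


class TestWilcoxon:
    def test_complete_separation_small_n(self, groups6):
        res = wilcoxon_test(np.array([[1, 2, 3, 4, 5, 6.0]]), groups6)
        assert res.pvalue[0] == pytest.approx(0.1)

    def test_complete_separation_5v5(self):
        g = np.array(["A"] * 5 + ["B"] * 5)
        res = wilcoxon_test(np.arange(10.0)[None, :], g)
        assert res.pvalue[0] == pytest.approx(2 / 252)

    def test_all_tied_values(self, groups6):
        res = wilcoxon_test(np.ones((1, 6)), groups6)
        assert res.pvalue[0] == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_test(np.ones((1, 3)), np.array(["A", "B", "B"]))

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_exact_distribution_matches_enumeration(self, n1, n2):
        """DP null CDF equals brute-force enumeration over all labelings."""
        from itertools import combinations

        m = n1 * n2
        counts = np.zeros(m + 1)
        for comb in combinations(range(n1 + n2), n1):
            ranks = np.array(comb)
            u = ranks.sum() + n1 - n1 * (n1 + 1) / 2  # 0-based ranks
            counts[int(u)] += 1
        pmf = counts / counts.sum()
        assert np.allclose(_partition_cdf(n1, n2), np.cumsum(pmf), atol=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 8))
        g = np.array(["A"] * 4 + ["B"] * 4)
        mine = wilcoxon_test(x, g).pvalue
        ref = np.array(
            [
                stats.mannwhitneyu(r[:4], r[4:], method="exact", alternative="two-sided").pvalue
                for r in x
            ]
        )
        assert np.allclose(mine, ref, atol=1e-12)

    def test_tie_path_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, size=(100, 30)).astype(float)  # heavy ties
        g = np.array(["A"] * 15 + ["B"] * 15)
        mine = wilcoxon_test(x, g).pvalue
        ref = np.array(
            [
                stats.mannwhitneyu(
                    r[:15], r[15:], method="asymptotic", alternative="two-sided"
                ).pvalue
                for r in x
            ]
        )
        assert np.allclose(mine, ref, atol=1e-10)


class TestStudentT:
    def test_equal_means_p_one(self, groups6):
        v = np.array([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        res = student_t_test(v, groups6)
        assert res.statistic[0] == 0.0
        assert res.pvalue[0] == 1.0

    def test_handworked_example(self, groups6):
        # equal group variances: Welch and pooled coincide
        v = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        for ev in (False, True):
            res = student_t_test(v, groups6, equal_var=ev)
            assert res.statistic[0] == pytest.approx(-3.674, abs=1e-3)
            assert res.pvalue[0] == pytest.approx(0.02131, abs=1e-5)

    def test_scale_invariance(self, groups6):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(50, 6))
        a = student_t_test(v, groups6)
        b = student_t_test(2 * v, groups6)
        assert np.allclose(a.statistic, b.statistic)
        assert np.allclose(a.pvalue, b.pvalue)

    def test_zero_variance_flagged(self, groups6):
        v = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        res = student_t_test(v, groups6)
        assert res.pvalue[0] > 0  # never exactly zero, BH-safe
        assert res.pvalue[0] < 1e-300
        assert np.isinf(res.statistic[0])

    def test_welch_matches_scipy(self, groups6):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(200, 6)) * np.array([1, 1, 1, 3, 3, 3.0])
        mine = student_t_test(v, groups6)
        t, p = stats.ttest_ind(v[:, :3], v[:, 3:], axis=1, equal_var=False)
        assert np.allclose(mine.statistic, t)
        assert np.allclose(mine.pvalue, p)


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self, groups6):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(300, 6))
        mod = moderated_t_test(v, groups6, prior_df=0)
        ref = student_t_test(v, groups6, equal_var=True)
        assert np.allclose(mod.pvalue, ref.pvalue, atol=1e-10)

    def test_infinite_prior_df_uses_common_variance(self, groups6):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(300, 6))
        mod = moderated_t_test(v, groups6, prior_df=np.inf)
        # all peaks share one denominator: statistic proportional to mean diff
        diff = v[:, :3].mean(axis=1) - v[:, 3:].mean(axis=1)
        ratio = mod.statistic / diff
        assert np.allclose(ratio, ratio[0])

    def test_null_type_i_calibration(self, groups6):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(5000, 6))
        mod = moderated_t_test(v, groups6)
        frac = (mod.pvalue < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert frac < 0.05 + 3 * se

    def test_batch_covariate_removes_additive_batch(self, groups6):
        rng = np.random.default_rng(8)
        batch = np.array([0, 0, 1, 0, 1, 1])
        v = rng.normal(size=(2000, 6)) + 5.0 * batch  # batch shift, no condition effect
        plain = moderated_t_test(v, groups6)
        adj = moderated_t_test(v, groups6, batch=batch)
        # without the covariate the batch shift inflates residual variance
        # and deflates everything; with it, type-I calibration is restored
        assert (plain.pvalue < 0.05).mean() <= (adj.pvalue < 0.05).mean()
        assert 0.03 < (adj.pvalue < 0.05).mean() < 0.08

    def test_rank_deficient_design_rejected(self, groups6):
        batch = np.array([0, 0, 0, 1, 1, 1])  # aliased with condition
        with pytest.raises(ValueError, match="rank deficient"):
            moderated_t_test(np.ones((5, 6)), groups6, batch=batch)

    def test_voom_weights_run(self, small_matrix):
        res = run_method(MethodSpec("moderated_t", voom_weights=True), small_matrix)
        assert np.isfinite(res.pvalue).all()
        assert ((res.pvalue >= 0) & (res.pvalue <= 1)).all()


class TestNBExact:
    def test_binomial_limit(self, groups6):
        """At dispersion -> 0 the conditional test equals the binomial test."""
        rng = np.random.default_rng(9)
        counts = rng.poisson(15, size=(150, 6))
        res = nb_exact_test(counts, groups6, dispersion=1e-8)
        ref = np.array(
            [
                stats.binomtest(int(r[:3].sum()), int(r.sum()), 0.5).pvalue
                if r.sum() > 0
                else 1.0
                for r in counts
            ]
        )
        assert np.abs(res.pvalue - ref).max() < 1e-6

    def test_balanced_sums_give_p_one(self, groups6):
        res = nb_exact_test(np.array([[5, 6, 7, 7, 6, 5]]), groups6, dispersion=0.1)
        assert res.pvalue[0] == pytest.approx(1.0)

    def test_all_zero_peak(self, groups6):
        m = np.vstack([np.zeros(6, dtype=int), np.full(6, 10)])
        res = nb_exact_test(m, groups6, dispersion=0.1)
        assert res.pvalue[0] == 1.0

    def test_non_integer_rejected(self, groups6):
        with pytest.raises(ValueError, match="integer"):
            nb_exact_test(np.full((2, 6), 1.5), groups6, dispersion=0.1)

    def test_dispersion_recovery(self, groups6):
        rng = np.random.default_rng(10)
        phi, mu = 0.05, 100.0
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + mu), size=(20000, 6))
        est = estimate_common_dispersion(y, groups6)
        assert est == pytest.approx(phi, rel=0.15)

    def test_null_calibration_conservative(self, groups6):
        rng = np.random.default_rng(11)
        r = 1 / 0.05
        y = rng.negative_binomial(r, r / (r + 80), size=(4000, 6))
        res = nb_exact_test(y, groups6)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert (res.pvalue < 0.05).mean() <= 0.05 + 3 * se

    def test_moment_mode_runs(self, groups6):
        rng = np.random.default_rng(12)
        y = rng.poisson(40, size=(60, 6))
        res = nb_exact_test(y, groups6, dispersion_mode="moment")
        assert ((res.pvalue >= 0) & (res.pvalue <= 1)).all()


class TestNullCalibrationAllMethods:
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_super_uniform_p_on_null_simulation(self, alpha):
        """No method exceeds alpha + 3 binomial SD false positives on nulls."""
        design = ab.SimulationDesign(
            classes=(ab.DifferenceClass(0.0, 1.0),),
            n_peaks=4000,
            replicates_per_condition=4,
            seed=13,
        )
        m = ab.simulate_counts(design)
        se = np.sqrt(alpha * (1 - alpha) / len(m.peak_ids))
        for name in ("wilcoxon", "ttest", "moderated_t", "nb_exact"):
            res = run_method(MethodSpec(name), m)
            assert (res.pvalue < alpha).mean() <= alpha + 3 * se, name


class TestRunMethod:
    def test_wilcoxon_dispatch_min_p(self, small_matrix):
        res = run_method(MethodSpec("wilcoxon"), small_matrix)
        assert res.pvalue.min() == pytest.approx(0.1)

    def test_dispatch_transparency(self, small_matrix):
        res = run_method(MethodSpec("ttest"), small_matrix)
        direct = student_t_test(
            logcpm_transform(small_matrix.counts),
            small_matrix.condition,
            peak_ids=small_matrix.peak_ids,
        )
        assert np.array_equal(res.pvalue, direct.pvalue)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec("deseq99")

    def test_external_stub_echoing_p_one(self, small_matrix, tmp_path):
        stub = tmp_path / "stub.py"
        stub.write_text(
            "import sys, pandas as pd\n"
            "df = pd.read_csv(sys.argv[1], sep='\\t', index_col=0)\n"
            "out = pd.DataFrame({'pvalue': 1.0}, index=df.index)\n"
            "out.to_csv(sys.argv[2], sep='\\t')\n"
        )
        spec = MethodSpec("external", external_cmd=f"{sys.executable} {stub} {{counts}} {{out}}")
        res = run_method(spec, small_matrix)
        assert (res.pvalue == 1.0).all()
        assert not res.calls(0.05).any()

    def test_external_missing_peaks_rejected(self, small_matrix, tmp_path):
        stub = tmp_path / "bad.py"
        stub.write_text(
            "import sys, pandas as pd\n"
            "df = pd.read_csv(sys.argv[1], sep='\\t', index_col=0).iloc[:10]\n"
            "pd.DataFrame({'pvalue': 0.5}, index=df.index).to_csv(sys.argv[2], sep='\\t')\n"
        )
        spec = MethodSpec("external", external_cmd=f"{sys.executable} {stub} {{counts}} {{out}}")
        with pytest.raises(ValueError, match="missing"):
            run_method(spec, small_matrix)
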