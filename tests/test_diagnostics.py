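"""Recovery statistics, RMSE, Durbin-Watson, t/F comparison and EJCR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from specresolve.diagnostics import (
    compare_methods,
    durbin_watson,
    ejcr,
    recovery_stats,
    regression_fom,
    rmse,
)

# printed validation-recovery columns for paracetamol (PCR and ANN engines)
PCR_PARA = [98.88, 102.54, 99.91, 99.40, 99.81]
ANN_PARA = [99.83, 100.00, 100.00, 101.16, 100.00]


class TestRecovery:
    def test_published_worked_examples(self):
        nominal = np.full((5, 1), 100.0)
        pcr = recovery_stats(np.array(PCR_PARA)[:, None], nominal)
        assert round(pcr.mean[0], 2) == 100.11
        assert round(pcr.sd[0], 2) == 1.42
        ann = recovery_stats(np.array(ANN_PARA)[:, None], nominal)
        assert round(ann.mean[0], 2) == 100.20
        assert round(ann.sd[0], 2) == 0.54

    def test_exact_agreement(self):
        nominal = np.array([[4.0, 3.0], [20.0, 15.0]])
        table = recovery_stats(nominal, nominal)
        np.testing.assert_allclose(table.recovery, 100.0)
        np.testing.assert_allclose(table.sd, 0.0)

    def test_zero_nominal_rejected(self):
        with pytest.raises(ValueError):
            recovery_stats([[1.0]], [[0.0]])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=50.0, max_value=150.0, allow_nan=False),
            min_size=2,
            max_size=12,
        )
    )
    def test_matches_streaming_oracle(self, values):
        """Mean/SD agree with an independent single-pass Welford accumulator."""
        found = np.asarray(values)[:, None]
        table = recovery_stats(found, np.ones_like(found))
        mean = 0.0
        m2 = 0.0
        for k, v in enumerate(100.0 * np.asarray(values), start=1):
            delta = v - mean
            mean += delta / k
            m2 += delta * (v - mean)
        assert abs(table.mean[0] - mean) < 1e-10
        assert abs(table.sd[0] - np.sqrt(m2 / (len(values) - 1))) < 1e-10


class TestRMSE:
    def test_closed_forms(self):
        x = np.arange(5.0)
        assert rmse(x, x) == 0.0
        assert abs(rmse(x + 0.3, x) - 0.3) < 1e-12

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        found = rng.normal(size=(5, 4))
        ref = rng.normal(size=(5, 4))
        per_col = rmse(found, ref)
        for j in range(4):
            acc = sum((found[i, j] - ref[i, j]) ** 2 for i in range(5))
            assert abs(per_col[j] - np.sqrt(acc / 5)) < 1e-12


class TestDurbinWatson:
    def test_alternating_residuals(self):
        e = np.tile([1.0, -1.0], 5)  # n = 10
        dw, _ = durbin_watson(e, n_permutations=10)
        assert abs(dw - 3.6) < 1e-12

    def test_identical_residuals(self):
        dw, _ = durbin_watson(np.full(6, 2.5), n_permutations=10)
        assert dw == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(5))

    def test_iid_mean_near_two(self):
        rng = np.random.default_rng(0)
        stats_ = []
        for _ in range(1000):
            e = rng.normal(size=25)
            stats_.append(np.sum(np.diff(e) ** 2) / np.sum(e * e))
        assert abs(np.mean(stats_) - 2.0) < 0.1

    def test_permutation_p_uniform_under_null(self):
        """p-values from i.i.d. residuals pass a KS uniformity check."""
        rng = np.random.default_rng(7)
        pvals = [
            durbin_watson(rng.normal(size=25), n_permutations=300, seed=k)[1]
            for k in range(1000)
        ]
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_seeded_determinism(self):
        e = np.random.default_rng(3).normal(size=10)
        assert durbin_watson(e, seed=5) == durbin_watson(e, seed=5)

    def test_statistic_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.stattools")
        e = np.random.default_rng(9).normal(size=25)
        dw, _ = durbin_watson(e, n_permutations=10)
        assert abs(dw - sm.durbin_watson(e)) < 1e-12


class TestCompareMethods:
    def test_published_worked_examples(self):
        # ascorbic acid, network engine vs official titration (printed variances)
        res = compare_methods((99.60, np.sqrt(0.62), 5), (98.46, np.sqrt(0.85), 5))
        assert abs(abs(res.t_stat) - 2.100) < 0.02
        assert abs(res.f_stat - 1.37) < 0.02
        # paracetamol, PCR variance vs official
        res2 = compare_methods((100.11, np.sqrt(2.02), 5), (101.48, np.sqrt(0.79), 5))
        assert abs(res2.f_stat - 2.56) < 0.02
        # caffeine, curve-resolution variance vs official
        res3 = compare_methods((97.80, np.sqrt(2.13), 5), (99.58, np.sqrt(1.49), 5))
        assert abs(res3.f_stat - 1.43) < 0.02

    def test_identical_groups(self):
        g = np.array([99.0, 100.0, 101.0])
        res = compare_methods(g, g.copy())
        assert res.t_stat == 0.0
        assert res.f_stat == 1.0
        assert not res.t_significant and not res.f_significant

    def test_raw_equals_summary(self):
        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(100, 1, 5), rng.normal(99, 2, 5)
        raw = compare_methods(g1, g2)
        summ = compare_methods(
            (g1.mean(), g1.std(ddof=1), 5), (g2.mean(), g2.std(ddof=1), 5)
        )
        assert abs(raw.t_stat - summ.t_stat) < 1e-10
        assert abs(raw.f_stat - summ.f_stat) < 1e-10

    def test_f_at_least_one_and_criticals(self):
        res = compare_methods((100.0, 0.5, 5), (100.0, 2.0, 5))
        assert res.f_stat >= 1.0
        assert abs(res.f_crit - 9.605) < 0.01   # two-sided 95%, (4, 4) df
        assert abs(res.t_crit - 2.306) < 0.001  # 95%, df = 8

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            compare_methods((1.0, 0.0, 5), (2.0, 0.0, 5))


class TestEJCR:
    def test_perfect_predictions_contain_ideal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ejcr(x, x)
        assert res.contains_ideal
        assert res.s2 < 1e-20

    def test_gross_bias_excludes_ideal(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 10, 8)
        y = 2.0 * x + 0.01 * rng.normal(size=8)
        assert not ejcr(y, x).contains_ideal

    def test_membership_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        x = np.linspace(2, 20, 10)
        y = x + 0.2 * rng.normal(size=10)
        res = ejcr(y, x)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rhs = 2 * res.s2 * res.f_crit
        for a in np.linspace(-1, 1, 7):
            for b in np.linspace(0.8, 1.2, 7):
                d = beta - np.array([a, b])
                inside = d @ (X.T @ X) @ d <= rhs + 1e-10
                assert inside == res.contains(a, b)

    def test_region_shrinks_with_residual_variance(self):
        x = np.linspace(2, 20, 10)
        rng = np.random.default_rng(8)
        noise = rng.normal(size=10)
        areas = []
        for scale in (0.5, 0.1, 0.02):
            res = ejcr(x + scale * noise, x)
            w = np.linalg.eigvalsh(np.linalg.inv(res.shape) * 2 * res.s2 * res.f_crit)
            areas.append(np.pi * np.sqrt(np.prod(w)))
        assert areas[0] > areas[1] > areas[2]

    def test_degenerate_nominal_rejected(self):
        with pytest.raises(ValueError):
            ejcr([1.0, 1.1, 0.9], [5.0, 5.0, 5.0])


class TestRegressionFOM:
    def test_perfect_fit(self):
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        fom = regression_fom(x, x)
        assert abs(fom.slope - 1.0) < 1e-12
        assert abs(fom.intercept) < 1e-12
        assert fom.rmsep == 0.0
        assert fom.dw is None  # zero residuals: autocorrelation undefined

    def test_known_offset(self):
        x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        fom = regression_fom(x + 0.5, x)
        assert abs(fom.rmsep - 0.5) < 1e-12
        assert abs(fom.slope - 1.0) < 1e-12
        assert abs(fom.intercept - 0.5) < 1e-12
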