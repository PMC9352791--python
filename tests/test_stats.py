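"""Statistical toolbox against closed-form and enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mfarm import stats
from mfarm.stats import (PowerSpec, bonferroni, minimal_n, partial_pearson,
                         pearson, power_correlation_sim, power_paired_sim,
                         rm_anova_continuous_between,
                         shapiro_gated_paired_test)


def wilcoxon_exact_p(diff):
    """Exhaustive sign-flip enumeration of the two-sided signed-rank p-value
    (oracle for n <= 10; assumes no zeros)."""
    diff = np.asarray(diff, float)
    n = diff.size
    ranks = sps.rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


class TestShapiroGatedPairedTest:
    def test_all_zero_differences_degenerate(self):
        x = np.arange(10.0)
        res = shapiro_gated_paired_test(x, x)
        assert res.degenerate and res.p_value == pytest.approx(1.0)

    def test_forced_wilcoxon_n6_all_positive(self):
        x = np.array([3.0, 4, 5, 6, 7, 8])
        y = x - np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        res = shapiro_gated_paired_test(x, y, force="wilcoxon")
        assert res.test == "wilcoxon_signed_rank"
        assert res.p_value == pytest.approx(2 / 64)

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for n in (5, 7, 9, 10):
            for _ in range(5):
                diff = np.round(rng.normal(0.3, 1.0, n), 3)
                diff[diff == 0] = 0.1
                x = rng.normal(5, 1, n)
                res = shapiro_gated_paired_test(x + diff, x, force="wilcoxon")
                assert res.p_value == pytest.approx(wilcoxon_exact_p(diff),
                                                    abs=1e-10)

    def test_t_branch_matches_scipy_and_cohens_d(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(5, 1, 40), rng.normal(4.5, 1, 40)
        res = shapiro_gated_paired_test(x, y, force="paired_t")
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        d = (x - y).mean() / (x - y).std(ddof=1)
        assert res.effect_size == pytest.approx(d)

    def test_gate_picks_wilcoxon_for_heavy_tails(self):
        rng = np.random.default_rng(2)
        x = rng.standard_cauchy(200)
        res = shapiro_gated_paired_test(x + 1.0, x * 0.0)
        assert res.test == "wilcoxon_signed_rank"
        assert 0.0 <= res.effect_size <= 1.0

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(400):
            d = rng.standard_normal(120)
            ps.append(shapiro_gated_paired_test(d, np.zeros(120)).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        r, p, df = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 18

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))

    def test_partial_matches_recursive_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            z = rng.standard_normal(30)
            x = 0.5 * z + rng.standard_normal(30)
            y = -0.3 * z + rng.standard_normal(30)
            r_xy = np.corrcoef(x, y)[0, 1]
            r_xz = np.corrcoef(x, z)[0, 1]
            r_yz = np.corrcoef(y, z)[0, 1]
            expect = (r_xy - r_xz * r_yz) / np.sqrt(
                (1 - r_xz**2) * (1 - r_yz**2))
            got, _, df = partial_pearson(x, y, z[:, None])
            assert got == pytest.approx(expect, abs=1e-10)
            assert df == 30 - 2 - 1

    def test_partial_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((50, 4)),
                          columns=["x", "y", "a", "b"])
        got_r, got_p, _ = partial_pearson(df.x, df.y, df[["a", "b"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert got_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert got_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_independent_covariates_leave_r_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(5000)
        y = 0.4 * x + rng.standard_normal(5000)
        covs = rng.standard_normal((5000, 2))
        r, _, _ = pearson(x, y)
        rp, _, _ = partial_pearson(x, y, covs)
        assert abs(r - rp) < 0.02


def test_bonferroni():
    assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
    assert bonferroni([0.5], 12)[0] == 1.0
    assert bonferroni([0.0], 7)[0] == 0.0
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], 1)


def glm_anova_oracle(short, long, score):
    """Independent least-squares oracle on the long-format data.

    Projects the stacked outcome on nested design matrices and forms each
    F statistic from the explicit SS difference, using the between-participant
    error for the between effect and the within error for horizon terms.
    """
    short, long, score = map(np.asarray, (short, long, score))
    n = short.size
    sc = score - score.mean()

    def ss_resid(y, X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    out = {}
    # between: participant totals on score
    tot = short + long
    X0, X1 = np.ones((n, 1)), np.column_stack([np.ones(n), sc])
    ss_full = ss_resid(tot, X1)
    F_b = (ss_resid(tot, X0) - ss_full) / (ss_full / (n - 2))
    out["between"] = F_b
    # within: differences; horizon = mean-offset, interaction = slope
    dif = long - short
    ss_full_d = ss_resid(dif, X1)
    X_noint = sc[:, None]
    F_h = (ss_resid(dif, X_noint) - ss_full_d) / (ss_full_d / (n - 2))
    X_noslope = np.ones((n, 1))
    F_i = (ss_resid(dif, X_noslope) - ss_full_d) / (ss_full_d / (n - 2))
    out["horizon"], out["interaction"] = F_h, F_i
    return out


class TestRmAnova:
    def test_matches_glm_oracle(self):
        rng = np.random.default_rng(7)
        score = rng.standard_normal(12)
        short = 5 + 0.5 * score + rng.standard_normal(12)
        long = 6 + 0.8 * score + rng.standard_normal(12)
        res = rm_anova_continuous_between(short, long, score)
        oracle = glm_anova_oracle(short, long, score)
        assert res.between.F == pytest.approx(oracle["between"], rel=1e-9)
        assert res.horizon.F == pytest.approx(oracle["horizon"], rel=1e-9)
        assert res.interaction.F == pytest.approx(oracle["interaction"],
                                                  rel=1e-9)
        assert 0 <= res.between.eta_p2 <= 1

    def test_constructed_horizon_shift(self):
        rng = np.random.default_rng(8)
        score = rng.standard_normal(40)
        short = rng.standard_normal(40)
        res = rm_anova_continuous_between(short, short + 1.0, score)
        assert res.horizon.p < 1e-6
        assert res.interaction.p > 0.001  # no constructed interaction

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        ps = {"between": [], "horizon": [], "interaction": []}
        for _ in range(400):
            score = rng.standard_normal(30)
            s = rng.standard_normal(30)
            l = rng.standard_normal(30)
            res = rm_anova_continuous_between(s, l, score)
            ps["between"].append(res.between.p)
            ps["horizon"].append(res.horizon.p)
            ps["interaction"].append(res.interaction.p)
        for k, v in ps.items():
            assert sps.kstest(v, "uniform").pvalue > 0.01, k

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            rm_anova_continuous_between(np.arange(12.0), np.arange(12.0),
                                        np.ones(12))


class TestPower:
    def test_size_equals_alpha_under_null(self):
        p = power_correlation_sim(PowerSpec("correlation", 0.0, 100,
                                            n_reps=10_000, seed=0))
        assert p == pytest.approx(0.05, abs=0.01)
        p = power_paired_sim(PowerSpec("paired", 0.0, 30,
                                       n_reps=10_000, seed=0))
        assert p == pytest.approx(0.05, abs=0.01)

    def test_monotone_in_n_and_effect(self):
        p1 = power_correlation_sim(PowerSpec("correlation", 0.2, 100,
                                             n_reps=20_000, seed=1))
        p2 = power_correlation_sim(PowerSpec("correlation", 0.2, 200,
                                             n_reps=20_000, seed=1))
        p3 = power_correlation_sim(PowerSpec("correlation", 0.3, 200,
                                             n_reps=20_000, seed=1))
        assert p1 < p2 < p3

    def test_agrees_with_fisher_z_approximation(self):
        for r, n in [(0.2, 150), (0.26, 190)]:
            sim = power_correlation_sim(PowerSpec("correlation", r, n,
                                                  n_reps=100_000, seed=2))
            z = np.arctanh(r) * np.sqrt(n - 3)
            crit = sps.norm.isf(0.025)
            approx = sps.norm.sf(crit - z) + sps.norm.cdf(-crit - z)
            assert sim == pytest.approx(approx, abs=0.01)

    def test_paired_agrees_with_noncentral_t(self):
        d, n = 0.446, 71
        sim = power_paired_sim(PowerSpec("paired", d, n,
                                         n_reps=100_000, seed=3))
        tc = sps.t.isf(0.025, n - 1)
        nc = d * np.sqrt(n)
        exact = sps.nct.sf(tc, n - 1, nc) + sps.nct.cdf(-tc, n - 1, nc)
        assert sim == pytest.approx(exact, abs=0.01)

    def test_minimal_n_for_moderate_correlation(self):
        n = minimal_n("correlation", 0.26, 0.95, n_max=400,
                      n_reps=10_000, seed=4)
        assert 180 <= n <= 195
        # monotone consistency at the returned n
        p = power_correlation_sim(PowerSpec("correlation", 0.26, n,
                                            n_reps=10_000, seed=4))
        assert p >= 0.95

    def test_minimal_n_large_effect_is_small(self):
        assert minimal_n("paired", 2.0, 0.95, n_reps=10_000, seed=5) <= 8

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec("correlation", 0.2, 2)
        with pytest.raises(ValueError):
            PowerSpec("paired", 0.2, 10, alpha=1.5)
        with pytest.raises(ValueError):
            minimal_n("correlation", 0.0)
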