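"""Statistical toolbox for the analysis pipeline.

Shapiro-gated paired tests (paired t or Wilcoxon signed-rank, with Cohen's d
or r = |Z|/sqrt(N) effect sizes), Pearson and partial Pearson correlations,
Bonferroni correction, a two-level repeated-measures ANOVA with a continuous
between-participant variable, and the simulation-based power analyses
(bivariate-normal correlation power and paired-test power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "PairedTestResult",
    "AnovaEffect",
    "AnovaResult",
    "PowerSpec",
    "shapiro_gated_paired_test",
    "pearson",
    "partial_pearson",
    "bonferroni",
    "rm_anova_continuous_between",
    "power_correlation_sim",
    "power_paired_sim",
    "minimal_n",
]

SHAPIRO_ALPHA = 0.05  # gate level on the paired differences


@dataclass(frozen=True)
class PairedTestResult:
    test: str            # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    statistic: float
    p_value: float
    effect_size: float   # Cohen's d, or Wilcoxon r = |Z|/sqrt(N)
    n: int
    degenerate: bool = False


def _wilcoxon_z(diff: np.ndarray) -> float:
    """Normal-approximation Z of the signed-rank statistic, with tie
    correction; zeros already discarded."""
    n = diff.size
    ranks = sps.rankdata(np.abs(diff))
    w_plus = ranks[diff > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return 0.0
    return (w_plus - mu) / sigma


def shapiro_gated_paired_test(x, y, force: str | None = None) -> PairedTestResult:
    """Paired t-test, or Wilcoxon signed-rank if the Shapiro normality test
    on the differences rejects at alpha = 0.05.

    ``force`` ("paired_t"/"wilcoxon") overrides the gate (used for oracle
    checks).  All-zero differences are flagged degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors, n >= 3")
    diff = x - y
    if np.allclose(diff, 0.0):
        return PairedTestResult("degenerate", 0.0, 1.0, 0.0, x.size, True)
    if force is None:
        shapiro_p = sps.shapiro(diff).pvalue
        use_t = shapiro_p > SHAPIRO_ALPHA
    else:
        use_t = force == "paired_t"
    if use_t:
        res = sps.ttest_rel(x, y)
        d = diff.mean() / diff.std(ddof=1)
        return PairedTestResult("paired_t", float(res.statistic),
                                float(res.pvalue), float(d), x.size)
    nz = diff[diff != 0.0]  # discard zero differences (wilcox convention)
    if nz.size == 0:
        return PairedTestResult("degenerate", 0.0, 1.0, 0.0, x.size, True)
    res = sps.wilcoxon(nz, zero_method="wilcox", alternative="two-sided")
    z = _wilcoxon_z(nz)
    r = abs(z) / np.sqrt(nz.size)
    return PairedTestResult("wilcoxon_signed_rank", float(res.statistic),
                            float(res.pvalue), float(min(r, 1.0)), int(nz.size))


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p, and df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), x.size - 2


def partial_pearson(x, y, covariates, df_extra: int = 0) -> tuple[float, float, int]:
    """Partial correlation of x and y given covariates.

    Computed as the correlation of the OLS residuals of x and y on the
    covariates (with intercept); df = n - 2 - n_covariates - ``df_extra``
    (the knob lets callers match alternative published df conventions).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] == x.size and Z.ndim == 2:
        pass
    elif Z.shape[1] == x.size:
        Z = Z.T
    k = Z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k - df_extra
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p), df


def bonferroni(p_values, n_tests: int | None = None) -> np.ndarray:
    """p_cor = min(1, p * n_tests); n_tests defaults to len(p_values)."""
    p = np.atleast_1d(np.asarray(p_values, float))
    n = n_tests if n_tests is not None else p.size
    if n < p.size:
        raise ValueError("n_tests must cover all p-values")
    return np.minimum(1.0, p * n)


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    p: float
    eta_p2: float
    df: tuple[int, int]


@dataclass(frozen=True)
class AnovaResult:
    between: AnovaEffect
    horizon: AnovaEffect
    interaction: AnovaEffect


def _reg_effect(y: np.ndarray, score: np.ndarray, which: str) -> AnovaEffect:
    """F test of the slope ("slope") or intercept ("intercept") in the OLS
    regression y ~ 1 + centered score, with eta_p^2 = SS_eff/(SS_eff+SS_err)."""
    X = sm.add_constant(score - score.mean())
    fit = sm.OLS(y, X).fit()
    idx = 1 if which == "slope" else 0
    t = fit.tvalues[idx]
    F = float(t * t)
    p = float(fit.pvalues[idx])
    ss_err = float(fit.ssr)
    ss_eff = F * ss_err / fit.df_resid
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaEffect(F, p, float(eta), (1, int(fit.df_resid)))


def rm_anova_continuous_between(short_values, long_values, between) -> AnovaResult:
    """Repeated-measures ANOVA, horizon within (2 levels) x a continuous
    between-participant variable.

    Exact for two within-levels via the sum/difference decomposition: the
    between main effect is the regression of the participant mean on the
    (centered) score; the horizon main effect is the intercept test on the
    long-short differences; the interaction is the slope of that difference
    regression.
    """
    s = np.asarray(short_values, float)
    l = np.asarray(long_values, float)
    b = np.asarray(between, float)
    if not (s.size == l.size == b.size) or s.size < 10:
        raise ValueError("aligned vectors of length >= 10 required")
    if np.std(b) == 0:
        raise ValueError("constant between-participant score: "
                         "between effects undefined")
    mean = (s + l) / 2.0
    diff = l - s
    return AnovaResult(
        between=_reg_effect(mean, b, "slope"),
        horizon=_reg_effect(diff, b, "intercept"),
        interaction=_reg_effect(diff, b, "slope"),
    )


# ---------------------------------------------------------------------------
# simulation-based power analysis

@dataclass(frozen=True)
class PowerSpec:
    design: str                 # "correlation" | "paired"
    effect_size: float          # r, or standardized mean difference d
    n: int
    alpha: float = 0.05
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("correlation", "paired"):
            raise ValueError("design must be 'correlation' or 'paired'")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        min_n = 3 if self.design == "correlation" else 2
        if self.n < min_n:
            raise ValueError(f"n must be >= {min_n} for a {self.design} design")


_CHUNK = 2_000  # replicates per vectorized block (memory bound)


def power_correlation_sim(spec: PowerSpec) -> float:
    """Fraction of simulated bivariate-normal samples (means 0, unit
    variances, correlation = effect size) whose two-sided Pearson test is
    significant at ``alpha``."""
    r, n = spec.effect_size, spec.n
    rng = np.random.default_rng(spec.seed)
    t_crit = sps.t.isf(spec.alpha / 2.0, n - 2)
    r_crit = t_crit / np.sqrt(n - 2 + t_crit**2)
    hits = 0
    left = spec.n_reps
    while left > 0:
        m = min(left, _CHUNK)
        x = rng.standard_normal((m, n))
        e = rng.standard_normal((m, n))
        y = r * x + np.sqrt(1.0 - r * r) * e
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        num = (xc * yc).sum(axis=1)
        den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
        rr = num / den
        hits += int((np.abs(rr) >= r_crit).sum())
        left -= m
    return hits / spec.n_reps


def power_paired_sim(spec: PowerSpec) -> float:
    """Fraction of simulated difference-score samples (normal, mean = effect
    size, sd 1) whose two-sided one-sample t-test is significant at
    ``alpha``."""
    d, n = spec.effect_size, spec.n
    rng = np.random.default_rng(spec.seed)
    t_crit = sps.t.isf(spec.alpha / 2.0, n - 1)
    hits = 0
    left = spec.n_reps
    while left > 0:
        m = min(left, 10 * _CHUNK)
        diff = rng.standard_normal((m, n)) + d
        t = diff.mean(axis=1) / (diff.std(axis=1, ddof=1) / np.sqrt(n))
        hits += int((np.abs(t) >= t_crit).sum())
        left -= m
    return hits / spec.n_reps


def _power_at(design: str, effect: float, n: int, alpha: float,
              n_reps: int, seed: int) -> float:
    spec = PowerSpec(design, effect, n, alpha, n_reps, seed)
    return (power_correlation_sim(spec) if design == "correlation"
            else power_paired_sim(spec))


def minimal_n(design: str, effect_size: float, target_power: float = 0.95,
              alpha: float = 0.05, n_min: int = 3, n_max: int = 5000,
              n_reps: int = 10_000, seed: int = 0) -> int:
    """Smallest n whose simulated power reaches ``target_power``.

    Bisection over n on the power curve; the same seed is used at every n
    (common random numbers) so the estimated curve is effectively monotone.
    """
    if effect_size == 0:
        raise ValueError("effect_size must be non-zero")
    lo_n = max(n_min, 3 if design == "correlation" else 2)
    if _power_at(design, effect_size, n_max, alpha, n_reps, seed) < target_power:
        raise ValueError(f"target power unreachable below n = {n_max}")
    lo, hi = lo_n, n_max
    if _power_at(design, effect_size, lo, alpha, n_reps, seed) >= target_power:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _power_at(design, effect_size, mid, alpha, n_reps, seed) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
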