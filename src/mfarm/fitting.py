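"""MAP parameter estimation, BIC model comparison, and recovery analyses.

Fitting follows the study design: only the *first draw* of each trial enters
the likelihood; per-horizon parameters (epsilon, eta, sigma0, info_bonus,
inv_temp) are fitted jointly for both horizons with Q0 (and the hybrid
weight w) shared.  Estimation is maximum a posteriori: bounded L-BFGS-B from
Latin-hypercube multi-starts on the negative log posterior, with weakly
informative priors on the task's natural parameter scales.  Model comparison
uses BIC = k ln(n) - 2 lnL computed from the (unpenalized) likelihood at the
MAP point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from . import models
from .beliefs import DEFAULT_OBS_SD
from .models import ModelSpec, choice_prob_matrix, param_names, params_for_horizon
from .taskgen import Session

__all__ = [
    "PARAM_BOUNDS",
    "FirstDrawData",
    "FitResult",
    "RecoveryMatrices",
    "compile_first_draws",
    "neg_log_posterior",
    "fit_map",
    "fit_table",
    "compare_models",
    "model_recovery",
    "parameter_recovery",
]

# bounds / starting ranges / prior log-densities by base parameter name
PARAM_BOUNDS = {
    "epsilon": (1e-6, 1.0 - 1e-6),
    "eta": (0.0, 10.0),
    "sigma0": (0.05, 5.0),
    "Q0": (0.0, 10.0),
    "info_bonus": (0.0, 5.0),
    "inv_temp": (0.01, 20.0),
    "w": (1e-6, 1.0 - 1e-6),
}

_START_RANGES = {
    "epsilon": (0.01, 0.5),
    "eta": (0.1, 5.0),
    "sigma0": (0.3, 3.0),
    "Q0": (3.0, 7.0),
    "info_bonus": (0.05, 2.0),
    "inv_temp": (0.2, 5.0),
    "w": (0.2, 0.8),
}

# closed-form log prior densities (scipy frozen-dist logpdf is too slow for
# the optimizer's inner loop; these match stats.beta/halfnorm/norm/gamma)
from math import lgamma, log, pi  # noqa: E402


def _log_beta_pdf(x, a, b):
    if not 0.0 < x < 1.0:
        return -np.inf
    return ((a - 1) * log(x) + (b - 1) * log(1 - x)
            - (lgamma(a) + lgamma(b) - lgamma(a + b)))


def _log_halfnorm_pdf(x, s):
    if x < 0:
        return -np.inf
    return log(2.0) - 0.5 * log(2 * pi * s * s) - x * x / (2 * s * s)


def _log_norm_pdf(x, m, s):
    return -0.5 * log(2 * pi * s * s) - (x - m) ** 2 / (2 * s * s)


def _log_gamma_pdf(x, a, s):
    if x <= 0:
        return -np.inf
    return (a - 1) * log(x) - x / s - a * log(s) - lgamma(a)


_PRIOR_LOGPDF = {
    "epsilon": lambda x: _log_beta_pdf(x, 1.2, 3.0),
    "eta": lambda x: _log_halfnorm_pdf(x, 3.0),
    "sigma0": lambda x: _log_halfnorm_pdf(x, 2.0),
    "Q0": lambda x: _log_norm_pdf(x, 5.0, 2.0),
    "info_bonus": lambda x: _log_halfnorm_pdf(x, 2.0),
    "inv_temp": lambda x: _log_gamma_pdf(x, 2.0, 1.0),
    "w": lambda x: _log_beta_pdf(x, 1.2, 1.2),
}


def _base_name(name: str) -> str:
    for suffix in ("_short", "_long"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def log_prior(params: dict) -> float:
    return float(sum(_PRIOR_LOGPDF[_base_name(k)](v) for k, v in params.items()))


@dataclass(frozen=True)
class FirstDrawData:
    """First-draw sufficient statistics, one block per horizon.

    For each horizon: ``n_init``/``sum_init`` are (n_trials, 3) counts and
    sums of the displayed initial samples, ``choice`` the chosen position.
    """

    n_init: dict[str, np.ndarray]
    sum_init: dict[str, np.ndarray]
    choice: dict[str, np.ndarray]

    @property
    def n_obs(self) -> int:
        return sum(len(c) for c in self.choice.values())

    def horizons(self):
        return tuple(sorted(self.choice, reverse=True))  # ("short", "long")


def compile_first_draws(session: Session, choices: pd.DataFrame) -> FirstDrawData:
    """Pair a session's trial structure with recorded first draws."""
    first = choices[choices["draw_index"] == 0]
    chosen = dict(zip(first["trial_id"], first["chosen_position"]))
    n_init, sum_init, choice = {}, {}, {}
    for horizon in ("short", "long"):
        trials = [t for t in session.trials if t.horizon == horizon]
        if not trials:
            continue
        missing = [t.trial_id for t in trials if t.trial_id not in chosen]
        if missing:
            raise ValueError(f"trials without a recorded first draw: {missing[:5]}")
        n_init[horizon] = np.array(
            [[len(b.initial_samples) for b in t.bandits] for t in trials], float)
        sum_init[horizon] = np.array(
            [[sum(b.initial_samples) for b in t.bandits] for t in trials], float)
        choice[horizon] = np.array([chosen[t.trial_id] for t in trials], int)
    return FirstDrawData(n_init, sum_init, choice)


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    params_hat: dict
    log_likelihood: float
    log_posterior: float
    bic: float
    n_obs: int
    n_free_params: int
    n_restarts: int
    converged: bool


def _neg_log_likelihood(spec: ModelSpec, params: dict, data: FirstDrawData,
                        obs_sd: float, gh_nodes: int) -> float:
    nll = 0.0
    for h in data.choice:
        ph = params_for_horizon(params, h)
        p = choice_prob_matrix(spec, ph, data.n_init[h], data.sum_init[h],
                               obs_sd, "quadrature", gh_nodes)
        liked = p[np.arange(len(data.choice[h])), data.choice[h]]
        nll -= np.log(np.maximum(liked, models.LIKELIHOOD_FLOOR)).sum()
    return float(nll)


def neg_log_posterior(spec: ModelSpec, params: dict, data: FirstDrawData,
                      obs_sd: float = DEFAULT_OBS_SD, gh_nodes: int = 12) -> float:
    """-log L - log prior; +inf outside the parameter bounds."""
    for k, v in params.items():
        lo, hi = PARAM_BOUNDS[_base_name(k)]
        if not lo <= v <= hi:
            return np.inf
    lp = log_prior(params)
    if not np.isfinite(lp):
        return np.inf
    return _neg_log_likelihood(spec, params, data, obs_sd, gh_nodes) - lp


def fit_map(
    spec: ModelSpec,
    data: FirstDrawData,
    n_restarts: int = 10,
    seed: int = 0,
    obs_sd: float = DEFAULT_OBS_SD,
    gh_nodes: int = 12,
    require_both_horizons: bool = True,
) -> FitResult:
    """Bounded multi-start MAP fit; the best restart is returned.

    Deterministic given ``seed`` (Latin-hypercube starts, quadrature
    likelihood).
    """
    if data.n_obs == 0:
        raise ValueError("no first-draw data to fit")
    if require_both_horizons and set(data.choice) != {"short", "long"}:
        raise ValueError("fitting requires data from both horizons "
                         "(per-horizon parameters are fitted jointly)")
    names = param_names(spec)
    k = len(names)
    if k == 0:  # uniform-random baseline: nothing to optimize
        ll = -_neg_log_likelihood(spec, {}, data, obs_sd, gh_nodes)
        return FitResult(spec, {}, ll, ll, -2.0 * ll, data.n_obs, 0, 0, True)

    lo = np.array([PARAM_BOUNDS[_base_name(n)][0] for n in names])
    hi = np.array([PARAM_BOUNDS[_base_name(n)][1] for n in names])
    s_lo = np.array([_START_RANGES[_base_name(n)][0] for n in names])
    s_hi = np.array([_START_RANGES[_base_name(n)][1] for n in names])

    def objective(x):
        params = dict(zip(names, x))
        lp = log_prior(params)
        if not np.isfinite(lp):
            return 1e12
        return _neg_log_likelihood(spec, params, data, obs_sd, gh_nodes) - lp

    sampler = qmc.LatinHypercube(d=k, seed=seed)
    starts = s_lo + sampler.random(n_restarts) * (s_hi - s_lo)
    best, best_val, converged = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"maxiter": 300, "ftol": 1e-7})
        if res.fun < best_val:
            best, best_val, converged = res.x, float(res.fun), bool(res.success)
    params_hat = dict(zip(names, best))
    ll = -_neg_log_likelihood(spec, params_hat, data, obs_sd, gh_nodes)
    bic = k * np.log(data.n_obs) - 2.0 * ll
    return FitResult(spec, params_hat, ll, -best_val, float(bic),
                     data.n_obs, k, n_restarts, converged)


def fit_table(fits: dict[str, dict[str, FitResult]]) -> pd.DataFrame:
    """Flatten nested {participant -> {model label -> FitResult}} fits into a
    long table (one row per participant x model)."""
    rows = []
    for pid, by_model in fits.items():
        for label, fr in by_model.items():
            row = {"participant_id": pid, "model": label, "bic": fr.bic,
                   "log_likelihood": fr.log_likelihood, "n_obs": fr.n_obs,
                   "k": fr.n_free_params, "converged": fr.converged}
            row.update(fr.params_hat)
            rows.append(row)
    return pd.DataFrame(rows)


def compare_models(fit_frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank models by mean BIC (lower = better) and test each against the
    winner with Shapiro-gated paired tests on per-participant BICs.

    Requires every participant fitted under every model.
    """
    from .stats import shapiro_gated_paired_test

    pivot = fit_frame.pivot(index="participant_id", columns="model", values="bic")
    if pivot.isna().any().any():
        gaps = [(pid, m) for pid, row in pivot.iterrows()
                for m in pivot.columns if np.isnan(row[m])]
        raise ValueError(f"missing fits for participant/model pairs: {gaps[:10]}")
    ranking = (pivot.mean().sort_values().rename("mean_bic").reset_index())
    winner = ranking["model"].iloc[0]
    rows = []
    for m in ranking["model"].iloc[1:]:
        diff_zero = np.allclose(pivot[m], pivot[winner])
        if diff_zero:
            rows.append({"model": m, "test": "degenerate", "statistic": 0.0,
                         "p_value": 1.0, "effect_size": 0.0})
            continue
        r = shapiro_gated_paired_test(pivot[m].to_numpy(), pivot[winner].to_numpy())
        rows.append({"model": m, "test": r.test, "statistic": r.statistic,
                     "p_value": r.p_value, "effect_size": r.effect_size})
    return ranking, pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryMatrices:
    """Simulate-and-refit model recovery summaries.

    ``confusion[g, f]`` = P(best-fit model f | generating model g); rows sum
    to 1.  ``inversion[g, f]`` = P(generating g | best-fit f) by Bayes rule
    under the simulation design's (uniform) generating frequencies; columns
    sum to 1 wherever the fit model ever won.
    """

    generating: tuple[str, ...]
    fitted: tuple[str, ...]
    confusion: np.ndarray
    inversion: np.ndarray
    best_fit_counts: pd.DataFrame = field(repr=False, default=None)


def model_recovery(
    zoo: list[ModelSpec],
    generating_param_sampler,
    n_sim_per_model: int,
    session_design,
    seed: int = 0,
    generating_specs: list[ModelSpec] | None = None,
    n_restarts: int = 3,
    gh_nodes: int = 12,
) -> RecoveryMatrices:
    """Confusion/inversion matrices: simulate ``n_sim_per_model`` sessions per
    generating model, fit every zoo model to each, tabulate best-BIC wins.

    ``generating_param_sampler(spec, rng) -> dict`` supplies generating
    parameters; ``session_design(index) -> Session`` supplies task sessions.
    ``generating_specs`` restricts the generating side (a subset of rows)
    without touching the fitted model space.
    """
    if not zoo:
        raise ValueError("empty model zoo")
    gens = generating_specs or zoo
    labels_g = tuple(s.label for s in gens)
    labels_f = tuple(s.label for s in zoo)
    counts = np.zeros((len(gens), len(zoo)), int)
    ss = np.random.SeedSequence(seed)
    for gi, gspec in enumerate(gens):
        for si in range(n_sim_per_model):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            session = session_design(gi * n_sim_per_model + si)
            gparams = generating_param_sampler(gspec, rng)
            choices = models.simulate_session(gspec, gparams, session, rng)
            data = compile_first_draws(session, choices)
            bics = [fit_map(fspec, data, n_restarts=n_restarts,
                            seed=int(child.generate_state(1)[0] % (2**31)),
                            gh_nodes=gh_nodes).bic
                    for fspec in zoo]
            counts[gi, int(np.argmin(bics))] += 1
    confusion = counts / counts.sum(axis=1, keepdims=True)
    # uniform generating frequencies -> Bayes rule is a column normalization
    col = confusion.sum(axis=0, keepdims=True)
    inversion = np.divide(confusion, col, out=np.zeros_like(confusion),
                          where=col > 0)
    count_df = pd.DataFrame(counts, index=list(labels_g), columns=list(labels_f))
    return RecoveryMatrices(labels_g, labels_f, confusion, inversion, count_df)


def parameter_recovery(
    spec: ModelSpec,
    population_param_sampler,
    session_design,
    n_participants: int,
    seed: int = 0,
    n_restarts: int = 3,
    gh_nodes: int = 12,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Generating-vs-recovered Pearson correlation per parameter.

    Returns the correlations and a table with ``gen_*`` / ``fit_*`` columns,
    one row per simulated participant.  Degenerate (zero-spread) generating
    parameters get correlation NaN.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for i in range(n_participants):
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        session = session_design(i)
        gparams = population_param_sampler(rng)
        choices = models.simulate_session(spec, gparams, session, rng)
        data = compile_first_draws(session, choices)
        fit = fit_map(spec, data, n_restarts=n_restarts,
                      seed=int(child.generate_state(1)[0] % (2**31)),
                      gh_nodes=gh_nodes)
        row = {f"gen_{k}": v for k, v in gparams.items() if k in fit.params_hat}
        row.update({f"fit_{k}": v for k, v in fit.params_hat.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    corrs = {}
    for name in param_names(spec):
        g, f = table.get(f"gen_{name}"), table.get(f"fit_{name}")
        if g is None or f is None:
            continue
        if np.std(g) < 1e-12:
            corrs[name] = float("nan")
        else:
            corrs[name] = float(np.corrcoef(g, f)[0, 1])
    return corrs, table
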