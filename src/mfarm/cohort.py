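"""Synthetic participant cohorts with a trait-linked exploration profile.

Emulates the study population: each participant carries individual
generating parameters for the winning choice model (per-horizon epsilon,
eta, sigma0; shared Q0), a latent impulsivity trait score (a continuous
stand-in for questionnaire totals), and age / IQ covariates.  The trait is
linked to value-free random exploration: participant-level epsilon lives on
the logit scale and receives a trait contribution whose strength is
calibrated by Monte-Carlo search to induce a configurable target Pearson
correlation (default 0.26) between trait and generating epsilon.

eta and sigma0 are log-normal around their population means; per-horizon
parameters are correlated within participant (they co-vary empirically even
though they are fitted separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import models, taskgen
from .models import ModelSpec

__all__ = ["CohortConfig", "CohortTable", "sample_participant",
           "sample_parameters", "calibrate_link", "generate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 580
    model: ModelSpec = field(
        default_factory=lambda: ModelSpec("thompson", use_epsilon=True,
                                          use_novelty=True))
    # population means of the generating parameters (short, long)
    epsilon_mean: tuple[float, float] = (0.099, 0.134)
    eta_mean: tuple[float, float] = (1.919, 2.884)
    sigma0_mean: tuple[float, float] = (1.085, 1.186)
    Q0_mean: float = 5.0
    # population dispersions
    epsilon_logit_sd: float = 0.7
    eta_log_sd: float = 0.4
    sigma0_log_sd: float = 0.25
    Q0_sd: float = 0.5
    #: correlation of a parameter's short/long values within a participant
    within_corr: float = 0.7
    #: target Pearson correlation between trait and generating epsilon
    trait_link: float = 0.26
    # covariates: age and IQ (ICAR-style sum score), weakly trait-correlated
    age_mean: float = 38.0
    age_sd: float = 12.0
    iq_mean: float = 9.0
    iq_sd: float = 3.0
    trait_age_corr: float = -0.1
    trait_iq_corr: float = -0.1
    seed: int = 0
    task: taskgen.GenerativeConfig = field(default_factory=taskgen.GenerativeConfig)

    def __post_init__(self):
        if not -1.0 < self.trait_link < 1.0:
            raise ValueError("trait_link must lie in (-1, 1)")


@dataclass(frozen=True)
class CohortTable:
    config: CohortConfig
    participants: pd.DataFrame   # trait, covariates, generating parameters
    sessions: list
    choices: pd.DataFrame


def _corr_pair(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """(n, 2) standard-normal pairs with correlation rho (0 <= rho <= 1)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("within-participant correlation must lie in [0, 1]")
    shared = rng.standard_normal(n)
    e = rng.standard_normal((n, 2))
    return np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * e


def _logit_normal_intercept(target_mean: float, sd: float) -> float:
    """Intercept a such that E[expit(a + sd*Z)] = target_mean (Z std normal),
    by Gauss-Hermite quadrature and root bracketing."""
    t, w = np.polynomial.hermite.hermgauss(64)

    def mean_at(a):
        return float((expit(a + sd * np.sqrt(2.0) * t) * w).sum() / np.sqrt(np.pi))

    lo, hi = logit(target_mean) - 5.0, logit(target_mean) + 5.0
    return brentq(lambda a: mean_at(a) - target_mean, lo, hi, xtol=1e-10)


def calibrate_link(cfg: CohortConfig, rho_target: float | None = None,
                   n_mc: int = 10_000, tol: float = 0.02,
                   seed: int | None = None) -> tuple[float, float]:
    """Find the trait slope (and residual noise scale) on the epsilon logit
    scale inducing a trait-epsilon Pearson correlation within ``tol`` of
    ``rho_target`` at ``n_mc`` simulated participants.

    The total logit-scale sd is held at ``cfg.epsilon_logit_sd``; the search
    is a monotone bisection over the share of that sd carried by the trait.
    Returns ``(slope, noise_sd)``.
    """
    rho_target = cfg.trait_link if rho_target is None else rho_target
    if rho_target < 0 or rho_target >= 1:
        raise ValueError("rho_target must lie in [0, 1)")
    if rho_target == 0.0:
        return 0.0, cfg.epsilon_logit_sd
    rng = np.random.default_rng(cfg.seed + 7_654_321 if seed is None else seed)
    z = rng.standard_normal(n_mc)
    e = _corr_pair(rng, n_mc, cfg.within_corr)
    a_s = _logit_normal_intercept(cfg.epsilon_mean[0], cfg.epsilon_logit_sd)
    a_l = _logit_normal_intercept(cfg.epsilon_mean[1], cfg.epsilon_logit_sd)

    def induced(rho_l):
        c = np.sqrt(1.0 - rho_l**2)
        eps_s = expit(a_s + cfg.epsilon_logit_sd * (rho_l * z + c * e[:, 0]))
        eps_l = expit(a_l + cfg.epsilon_logit_sd * (rho_l * z + c * e[:, 1]))
        eps = (eps_s + eps_l) / 2.0
        return float(np.corrcoef(z, eps)[0, 1])

    max_r = induced(0.999)
    if rho_target > max_r:
        raise ValueError(
            f"trait-epsilon correlation {rho_target} unreachable: the logit "
            f"link saturates at about {max_r:.3f} for these dispersions")
    lo, hi = 0.0, 0.999
    for _ in range(40):
        mid = (lo + hi) / 2.0
        r = induced(mid)
        if abs(r - rho_target) <= tol / 2.0:
            lo = hi = mid
            break
        if r < rho_target:
            lo = mid
        else:
            hi = mid
    rho_l = (lo + hi) / 2.0
    slope = cfg.epsilon_logit_sd * rho_l
    noise = cfg.epsilon_logit_sd * np.sqrt(1.0 - rho_l**2)
    return float(slope), float(noise)


def sample_parameters(cfg: CohortConfig, rng: np.random.Generator, n: int,
                      link: tuple[float, float] | None = None) -> pd.DataFrame:
    """Sample n participants' traits, covariates and generating parameters."""
    slope, noise = calibrate_link(cfg) if link is None else link
    z = rng.standard_normal(n)

    a_s = _logit_normal_intercept(cfg.epsilon_mean[0], cfg.epsilon_logit_sd)
    a_l = _logit_normal_intercept(cfg.epsilon_mean[1], cfg.epsilon_logit_sd)
    e = _corr_pair(rng, n, cfg.within_corr)
    eps_s = expit(a_s + slope * z + noise * e[:, 0])
    eps_l = expit(a_l + slope * z + noise * e[:, 1])

    def lognorm_pair(means, log_sd):
        f = _corr_pair(rng, n, cfg.within_corr)
        m = np.log(np.asarray(means)) - log_sd**2 / 2.0
        return np.exp(m[0] + log_sd * f[:, 0]), np.exp(m[1] + log_sd * f[:, 1])

    eta_s, eta_l = lognorm_pair(cfg.eta_mean, cfg.eta_log_sd)
    sg_s, sg_l = lognorm_pair(cfg.sigma0_mean, cfg.sigma0_log_sd)
    q0 = rng.normal(cfg.Q0_mean, cfg.Q0_sd, n)

    def covar(mean, sd, r):
        u = rng.standard_normal(n)
        return mean + sd * (r * z + np.sqrt(1.0 - r**2) * u)

    age = np.maximum(18.0, covar(cfg.age_mean, cfg.age_sd, cfg.trait_age_corr))
    iq = covar(cfg.iq_mean, cfg.iq_sd, cfg.trait_iq_corr)

    df = pd.DataFrame({
        "trait": z, "age": age, "iq": iq,
        "epsilon_short": eps_s, "epsilon_long": eps_l,
        "eta_short": eta_s, "eta_long": eta_l,
        "sigma0_short": sg_s, "sigma0_long": sg_l,
        "Q0": np.clip(q0, 0.0, 10.0),
    })
    df.insert(0, "participant_id", [f"p{i:04d}" for i in range(n)])
    return df


def sample_participant(cfg: CohortConfig, rng: np.random.Generator,
                       link: tuple[float, float] | None = None) -> pd.Series:
    """One participant's generating parameters, trait and covariates."""
    return sample_parameters(cfg, rng, 1, link).iloc[0]


_PARAM_COLS = ["epsilon_short", "epsilon_long", "eta_short", "eta_long",
               "sigma0_short", "sigma0_long", "Q0"]


def generate_cohort(cfg: CohortConfig) -> CohortTable:
    """Full synthetic dataset: participants, one task session each, and
    simulated choices; bit-reproducible from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    s_params, s_sessions, s_sim = ss.spawn(3)
    link = calibrate_link(cfg)
    participants = sample_parameters(cfg, np.random.default_rng(s_params),
                                     cfg.n_participants, link)
    session_seeds = np.random.default_rng(s_sessions).integers(
        0, 2**31, cfg.n_participants)
    sessions = [
        taskgen.make_session(pid, int(s), cfg.task)
        for pid, s in zip(participants["participant_id"], session_seeds)
    ]
    needed = set(models.param_names(cfg.model))
    param_table = {
        row.participant_id: {k: getattr(row, k) for k in _PARAM_COLS
                             if k in needed}
        for row in participants.itertuples()
    }
    choices = models.simulate_cohort_choices(
        cfg.model, param_table, sessions,
        int(s_sim.generate_state(1)[0] % (2**31)), cfg.task)
    return CohortTable(cfg, participants, sessions, choices)
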