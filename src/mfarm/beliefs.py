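"""Gaussian conjugate beliefs over bandit means.

Every choice model shares the same belief structure: before seeing any
samples the agent believes a bandit's mean reward is N(Q0, sigma0^2); each
observed sample (initial sample or own draw) is treated as a draw from a
Gaussian with known observation sd (tied by default to the task's generative
reward dispersion, 0.8), giving the standard precision-weighted posterior

    1/s^2 = 1/sigma0^2 + n/obs_sd^2
    Q     = s^2 * (Q0/sigma0^2 + sum(x)/obs_sd^2)

Rewards are integers on screen but are treated as real-valued observations
(no discretization correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Prior", "BeliefEntry", "posterior_from_samples", "belief_for_trial",
           "posterior_arrays", "DEFAULT_OBS_SD"]

#: observation sd of the belief model; a fixed model constant, not a fitted
#: parameter (matches the task's generative reward dispersion)
DEFAULT_OBS_SD = 0.8


@dataclass(frozen=True)
class Prior:
    Q0: float
    sigma0: float

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")


@dataclass(frozen=True)
class BeliefEntry:
    Q: float      # posterior mean
    s: float      # posterior sd
    n_obs: int    # number of samples seen


def posterior_from_samples(
    prior: Prior, samples, obs_sd: float = DEFAULT_OBS_SD
) -> BeliefEntry:
    """Conjugate Gaussian update of one bandit's belief from its samples."""
    if obs_sd <= 0:
        raise ValueError("obs_sd must be positive")
    x = np.asarray(samples, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    n = x.size
    prec = 1.0 / prior.sigma0**2 + n / obs_sd**2
    mean = (prior.Q0 / prior.sigma0**2 + x.sum() / obs_sd**2) / prec
    return BeliefEntry(float(mean), float(prec**-0.5), int(n))


def belief_for_trial(
    prior: Prior,
    trial,
    observed_so_far: dict[int, list[float]] | None = None,
    obs_sd: float = DEFAULT_OBS_SD,
) -> tuple[BeliefEntry, BeliefEntry, BeliefEntry]:
    """Belief over the 3 displayed bandits of a trial.

    ``observed_so_far`` maps display position -> extra outcomes the agent has
    drawn itself within the trial (long-horizon draws); initial samples are
    always included.  For first-draw likelihoods it is empty.
    """
    observed_so_far = observed_so_far or {}
    for pos in observed_so_far:
        if not 0 <= pos <= 2:
            raise ValueError(f"observed sample attributed to position {pos}, "
                             "but the trial shows bandits at positions 0-2")
    out = []
    for pos, b in enumerate(trial.bandits):
        samples = list(b.initial_samples) + list(observed_so_far.get(pos, []))
        out.append(posterior_from_samples(prior, samples, obs_sd))
    return tuple(out)


def posterior_arrays(
    Q0: float,
    sigma0: float,
    n_obs: np.ndarray,
    sum_obs: np.ndarray,
    obs_sd: float = DEFAULT_OBS_SD,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized conjugate update from per-bandit sufficient statistics.

    ``n_obs`` and ``sum_obs`` are arrays of matching shape (e.g. n_trials x 3);
    returns posterior means and sds of the same shape.  This is the fast path
    used by the likelihood code.
    """
    prec = 1.0 / sigma0**2 + n_obs / obs_sd**2
    Q = (Q0 / sigma0**2 + sum_obs / obs_sd**2) / prec
    return Q, prec**-0.5
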