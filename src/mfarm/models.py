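"""The exploration-strategy model zoo.

Choice models over the three displayed bandits, built from shared Gaussian
beliefs (:mod:`mfarm.beliefs`):

* **Thompson sampling** — choose the arm whose single posterior draw is
  largest; choice probability = P(arm's posterior sample exceeds the others).
* **UCB + softmax** — decision value V = Q + information_bonus * s, passed
  through a softmax with precision ``inverse_temperature``.
* **Hybrid** — probability-level mixture w * UCB + (1-w) * Thompson.
* **Novelty bonus (eta)** — an additive intrinsic reward on any bandit with
  zero observations so far; once the bandit has been sampled the bonus no
  longer applies.
* **Value-free random exploration (epsilon)** — final-probability mixture
  p' = (1-eps) * p + eps/3, ignoring all value and uncertainty information.

The 16-model space crosses {UCB, Thompson, hybrid} x {plain, +eps, +eta,
+eps+eta} and adds four reduced baselines (uniform random, eps-greedy on
posterior means, softmax on posterior means, novelty-only).

All per-horizon parameters carry ``_short`` / ``_long`` suffixes in a flat
parameter dict; Q0 and the hybrid weight w are shared across horizons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import taskgen
from .beliefs import DEFAULT_OBS_SD, posterior_arrays

__all__ = [
    "ModelSpec",
    "enumerate_model_zoo",
    "get_model",
    "param_names",
    "apply_epsilon",
    "hybrid_choice_probs",
    "thompson_choice_probs",
    "ucb_choice_probs",
    "choice_prob_matrix",
    "choice_likelihood",
    "simulate_session",
    "simulate_cohort_choices",
    "LIKELIHOOD_FLOOR",
]

#: floor applied to choice probabilities before taking logs
LIKELIHOOD_FLOOR = 1e-10

_BASES = ("thompson", "ucb", "hybrid", "uniform", "greedy_means",
          "softmax_means", "novelty_only")


@dataclass(frozen=True)
class ModelSpec:
    base: str
    use_epsilon: bool = False
    use_novelty: bool = False

    def __post_init__(self):
        if self.base not in _BASES:
            raise ValueError(f"unknown base model {self.base!r}")

    @property
    def label(self) -> str:
        names = {"thompson": "Thompson", "ucb": "UCB", "hybrid": "Hybrid",
                 "uniform": "Random", "greedy_means": "eps-greedy",
                 "softmax_means": "Softmax", "novelty_only": "Novelty"}
        lab = names[self.base]
        if self.base in ("thompson", "ucb", "hybrid"):
            if self.use_novelty:
                lab += "+eta"
            if self.use_epsilon:
                lab += "+eps"
        return lab


def enumerate_model_zoo() -> list[ModelSpec]:
    """The 16-model space: 3 complex bases x 4 heuristic combinations, plus
    4 reduced baselines."""
    zoo = [
        ModelSpec(base, use_epsilon=eps, use_novelty=eta)
        for base in ("thompson", "ucb", "hybrid")
        for eta in (False, True)
        for eps in (False, True)
    ]
    zoo += [
        ModelSpec("uniform"),
        ModelSpec("greedy_means", use_epsilon=True),
        ModelSpec("softmax_means"),
        ModelSpec("novelty_only", use_novelty=True),
    ]
    return zoo


def get_model(label: str) -> ModelSpec:
    for spec in enumerate_model_zoo():
        if spec.label == label:
            return spec
    raise KeyError(f"no model labelled {label!r} in the zoo")


def param_names(spec: ModelSpec) -> list[str]:
    """Flat parameter names of a spec, per-horizon ones split into
    ``_short`` / ``_long``."""
    per_h: list[str] = []
    shared: list[str] = []
    if spec.base in ("thompson", "ucb", "hybrid", "greedy_means", "softmax_means"):
        per_h.append("sigma0")
        shared.append("Q0")
    if spec.base in ("ucb", "hybrid"):
        per_h += ["info_bonus", "inv_temp"]
    if spec.base == "softmax_means":
        per_h.append("inv_temp")
    if spec.base == "hybrid":
        shared.append("w")
    if spec.use_novelty:
        per_h.append("eta")
    if spec.use_epsilon:
        per_h.append("epsilon")
    names = []
    for p in per_h:
        names += [f"{p}_short", f"{p}_long"]
    return names + shared


def params_for_horizon(params: dict, horizon: str) -> dict:
    """Collapse a flat parameter dict to generic keys for one horizon."""
    out = {}
    suffix = f"_{horizon}"
    for k, v in params.items():
        if k.endswith("_short") or k.endswith("_long"):
            if k.endswith(suffix):
                out[k[: -len(suffix)]] = v
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# choice probabilities (single trial and vectorized)

def apply_epsilon(probs, epsilon: float):
    """Value-free random exploration: p' = (1-eps) p + eps/3."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    p = np.asarray(probs, dtype=float)
    return (1.0 - epsilon) * p + epsilon / p.shape[-1]


def hybrid_choice_probs(p_ucb, p_thompson, w: float):
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return w * np.asarray(p_ucb, float) + (1.0 - w) * np.asarray(p_thompson, float)


def _softmax(values: np.ndarray) -> np.ndarray:
    v = values - values.max(axis=-1, keepdims=True)
    e = np.exp(v)
    return e / e.sum(axis=-1, keepdims=True)


def ucb_choice_probs(belief, information_bonus: float, inverse_temperature: float,
                     eta: float = 0.0, novel_mask=None) -> np.ndarray:
    """Softmax over V = Q + information_bonus * s (+ eta on novel arms)."""
    Q = np.array([b.Q for b in belief], float)
    s = np.array([b.s for b in belief], float)
    if novel_mask is None:
        novel_mask = np.array([b.n_obs == 0 for b in belief])
    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(s))):
        raise ValueError("non-finite belief")
    V = Q + information_bonus * s + eta * np.asarray(novel_mask, float)
    return _softmax(inverse_temperature * V)


_HERMGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _hermgauss(n: int):
    if n not in _HERMGAUSS_CACHE:
        _HERMGAUSS_CACHE[n] = np.polynomial.hermite.hermgauss(n)
    return _HERMGAUSS_CACHE[n]


def _thompson_probs_gh(m: np.ndarray, s: np.ndarray, n_nodes: int = 24) -> np.ndarray:
    """Exact P(arm i's posterior draw is largest) for independent Gaussians,
    by 1-D Gauss-Hermite quadrature over arm i's draw.

    ``m``/``s`` have shape (..., k).  Deterministic and smooth in (m, s),
    which is what the optimizer needs.
    """
    t, w = _hermgauss(n_nodes)
    s = np.maximum(s, 1e-9)
    k = m.shape[-1]
    # x: (..., arm i, node) draws of each arm at the quadrature nodes
    x = m[..., :, None] + np.sqrt(2.0) * s[..., :, None] * t
    # z: (..., i, j, node) standardized gap between arm i's draw and arm j
    z = (x[..., :, None, :] - m[..., None, :, None]) / s[..., None, :, None]
    cdf = ndtr(z)
    cdf[..., np.arange(k), np.arange(k), :] = 1.0
    out = (cdf.prod(axis=-2) * w).sum(axis=-1) / np.sqrt(np.pi)
    return out / out.sum(axis=-1, keepdims=True)


def _thompson_probs_mc(m, s, n_draws: int, seed: int = 0) -> np.ndarray:
    """Monte-Carlo Thompson probabilities with common random numbers."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, m.shape[-1]))
    draws = m[..., None, :] + s[..., None, :] * z
    winner = draws.argmax(axis=-1)
    k = m.shape[-1]
    counts = np.stack([(winner == i).mean(axis=-1) for i in range(k)], axis=-1)
    return counts


def thompson_choice_probs(belief, eta: float = 0.0, novel_mask=None,
                          method: str = "quadrature", n_nodes: int = 24,
                          n_draws: int = 100_000, seed: int = 0) -> np.ndarray:
    """P(choose arm) under Thompson sampling, with the novelty bonus added to
    novel arms' posterior means."""
    m = np.array([b.Q for b in belief], float)
    s = np.array([b.s for b in belief], float)
    if novel_mask is None:
        novel_mask = np.array([b.n_obs == 0 for b in belief])
    m = m + eta * np.asarray(novel_mask, float)
    if method == "quadrature":
        return _thompson_probs_gh(m, s, n_nodes)
    return _thompson_probs_mc(m, s, n_draws, seed)


def choice_prob_matrix(
    spec: ModelSpec,
    params_h: dict,
    n_init: np.ndarray,
    sum_init: np.ndarray,
    obs_sd: float = DEFAULT_OBS_SD,
    method: str = "quadrature",
    gh_nodes: int = 24,
) -> np.ndarray:
    """Vectorized first-draw choice probabilities for one horizon.

    ``params_h`` holds generic (horizon-collapsed) keys; ``n_init`` /
    ``sum_init`` are (n_trials, 3) sufficient statistics of the displayed
    initial samples.  Returns an (n_trials, 3) probability matrix.
    """
    n_trials = n_init.shape[0]
    novel = n_init == 0
    eta = params_h.get("eta", 0.0)

    if spec.base == "uniform":
        p = np.full((n_trials, 3), 1.0 / 3.0)
    elif spec.base == "novelty_only":
        p = _softmax(eta * novel.astype(float))
    else:
        Q, S = posterior_arrays(params_h["Q0"], params_h["sigma0"],
                                n_init, sum_init, obs_sd)
        if spec.base == "greedy_means":
            p = np.zeros((n_trials, 3))
            p[np.arange(n_trials), Q.argmax(axis=1)] = 1.0
        elif spec.base == "softmax_means":
            p = _softmax(params_h["inv_temp"] * Q)
        else:
            need_th = spec.base in ("thompson", "hybrid")
            need_ucb = spec.base in ("ucb", "hybrid")
            if need_th:
                m = Q + eta * novel
                p_th = (_thompson_probs_gh(m, S, gh_nodes)
                        if method == "quadrature"
                        else _thompson_probs_mc(m, S, 100_000))
            if need_ucb:
                V = Q + params_h["info_bonus"] * S + eta * novel
                p_ucb = _softmax(params_h["inv_temp"] * V)
            if spec.base == "thompson":
                p = p_th
            elif spec.base == "ucb":
                p = p_ucb
            else:
                p = hybrid_choice_probs(p_ucb, p_th, params_h["w"])
    if spec.use_epsilon or "epsilon" in params_h:
        p = apply_epsilon(p, params_h.get("epsilon", 0.0))
    return p


def choice_likelihood(spec: ModelSpec, params: dict, trial, chosen_index: int,
                      obs_sd: float = DEFAULT_OBS_SD,
                      method: str = "quadrature") -> float:
    """The model's probability of the observed first-draw choice on one trial."""
    if chosen_index not in (0, 1, 2):
        raise ValueError("chosen_index must be 0, 1 or 2")
    n_init = np.array([[len(b.initial_samples) for b in trial.bandits]], float)
    sum_init = np.array([[sum(b.initial_samples) for b in trial.bandits]], float)
    ph = params_for_horizon(params, trial.horizon)
    p = choice_prob_matrix(spec, ph, n_init, sum_init, obs_sd, method)
    return float(max(p[0, chosen_index], LIKELIHOOD_FLOOR))


# ---------------------------------------------------------------------------
# generative simulation

_CHOICE_COLUMNS = ["participant_id", "trial_id", "pair_id", "horizon",
                   "draw_index", "chosen_position", "chosen_bandit_type", "reward"]


def _sample_choice(spec: ModelSpec, ph: dict, Q, S, novel, rng) -> int:
    """One choice from the generative model (exact sampling, no quadrature)."""
    eps = ph.get("epsilon", 0.0)
    if eps and rng.random() < eps:
        return int(rng.integers(3))
    eta = ph.get("eta", 0.0)
    base = spec.base
    if base == "hybrid":
        base = "ucb" if rng.random() < ph["w"] else "thompson"
    if base == "uniform":
        return int(rng.integers(3))
    if base == "thompson":
        draws = Q + eta * novel + S * rng.standard_normal(3)
        return int(draws.argmax())
    if base == "ucb":
        V = Q + ph["info_bonus"] * S + eta * novel
        p = _softmax(ph["inv_temp"] * V)
        return int(rng.choice(3, p=p))
    if base == "greedy_means":
        return int(Q.argmax())
    if base == "softmax_means":
        return int(rng.choice(3, p=_softmax(ph["inv_temp"] * Q)))
    if base == "novelty_only":
        return int(rng.choice(3, p=_softmax(eta * novel.astype(float))))
    raise AssertionError(base)


def simulate_session(
    spec: ModelSpec,
    params: dict,
    session: taskgen.Session,
    rng: np.random.Generator,
    cfg: taskgen.GenerativeConfig | None = None,
    obs_sd: float = DEFAULT_OBS_SD,
) -> pd.DataFrame:
    """Simulate an agent playing a session: 1 draw per short-horizon trial,
    6 per long-horizon trial, with within-trial belief updating (and loss of
    the novelty bonus once an arm has been sampled)."""
    cfg = cfg or taskgen.GenerativeConfig()
    rows = []
    sigma0_cache: dict[str, tuple[float, float]] = {}
    for trial in session.trials:
        ph = params_for_horizon(params, trial.horizon)
        Q0 = ph.get("Q0", 5.0)
        sigma0 = ph.get("sigma0", 1.0)
        n_obs = np.array([len(b.initial_samples) for b in trial.bandits], float)
        s_obs = np.array([sum(b.initial_samples) for b in trial.bandits], float)
        true_means = np.array([b.true_mean for b in trial.bandits])
        n_draws = cfg.horizon_lengths[trial.horizon]
        for draw in range(n_draws):
            Q, S = posterior_arrays(Q0, sigma0, n_obs, s_obs, obs_sd)
            novel = n_obs == 0
            c = _sample_choice(spec, ph, Q, S, novel, rng)
            reward = taskgen.draw_reward(true_means[c], cfg, rng)
            rows.append((session.participant_id, trial.trial_id, trial.pair_id,
                         trial.horizon, draw, c, trial.bandits[c].type, reward))
            n_obs[c] += 1
            s_obs[c] += reward
    return pd.DataFrame(rows, columns=_CHOICE_COLUMNS)


def simulate_cohort_choices(spec, param_table, sessions, seed: int,
                            cfg=None) -> pd.DataFrame:
    """Simulate one session per participant; ``param_table`` maps
    participant_id -> flat parameter dict."""
    streams = np.random.SeedSequence(seed).spawn(len(sessions))
    frames = []
    for sess, ss in zip(sessions, streams):
        rng = np.random.default_rng(ss)
        frames.append(simulate_session(spec, param_table[sess.participant_id],
                                       sess, rng, cfg))
    return pd.concat(frames, ignore_index=True)
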