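"""Generative model of the three-armed "apple picking" bandit task.

Each trial shows three bandits (trees) drawn from four types that differ in
their generative mean and in how many *initial samples* (previously picked
apples) are shown before the first choice:

* ``certain_standard`` — standard mean, 3 initial samples
* ``standard``         — standard mean, 1 initial sample
* ``novel``            — standard mean, 0 initial samples
* ``low_value``        — lowest mean,   1 initial sample

Rewards are integer apple sizes: Gaussian draws around the bandit's true
mean, truncated to [2, 10] and rounded to the nearest integer.  Trials come
in a short-horizon (1 draw) and a long-horizon (6 draws) condition, and each
trial configuration is duplicated so that choice consistency can be computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "BANDIT_TYPES",
    "N_INITIAL_SAMPLES",
    "GenerativeConfig",
    "Bandit",
    "Trial",
    "Session",
    "draw_reward",
    "draw_rewards",
    "make_trial_means",
    "realize_bandit",
    "make_trial",
    "label_high_value",
    "make_session",
    "session_to_frame",
    "write_session",
    "read_sessions",
]

BANDIT_TYPES = ("certain_standard", "standard", "novel", "low_value")

#: fixed number of initial samples shown for each bandit type
N_INITIAL_SAMPLES = {
    "certain_standard": 3,
    "standard": 1,
    "novel": 0,
    "low_value": 1,
}

#: bandit types eligible for the "high-value" label (highest initial-sample mean)
_HIGH_VALUE_ELIGIBLE = ("certain_standard", "standard")


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the task's generative process.

    ``reward_dispersion`` and ``mean_dispersion`` are standard deviations by
    default; set ``dispersion_is_variance`` to reinterpret them as variances.
    """

    reward_dispersion: float = 0.8
    mean_dispersion: float = 1.4
    dispersion_is_variance: bool = False
    reward_bounds: tuple[int, int] = (2, 10)
    certain_overall_means: tuple[float, ...] = (4.5, 6.5)
    offset_set: tuple[int, ...] = (-2, -1, 1, 2)
    n_trials_per_horizon: int = 200
    horizon_lengths: dict = field(
        default_factory=lambda: {"short": 1, "long": 6}
    )
    #: probability that a trial includes the low-value bandit; 0.75 is the
    #: uniform-over-3-subsets rate, raise it to oversample low-value trials
    p_low_value: float = 0.75
    max_resample_attempts: int = 1000
    max_trial_regenerations: int = 50

    def __post_init__(self):
        if self.reward_dispersion <= 0 or self.mean_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.reward_bounds[0] >= self.reward_bounds[1]:
            raise ValueError("reward_bounds lower must be below upper")
        if not 0.0 <= self.p_low_value <= 1.0:
            raise ValueError("p_low_value must lie in [0, 1]")
        if self.n_trials_per_horizon % 2:
            raise ValueError(
                "n_trials_per_horizon must be even (trials are duplicated in pairs)"
            )

    @property
    def reward_sd(self) -> float:
        d = self.reward_dispersion
        return math.sqrt(d) if self.dispersion_is_variance else d

    @property
    def mean_sd(self) -> float:
        d = self.mean_dispersion
        return math.sqrt(d) if self.dispersion_is_variance else d


@dataclass(frozen=True)
class Bandit:
    type: str
    overall_mean: float
    true_mean: float
    initial_samples: tuple[int, ...]

    def __post_init__(self):
        if self.type not in BANDIT_TYPES:
            raise ValueError(f"unknown bandit type {self.type!r}")
        if len(self.initial_samples) != N_INITIAL_SAMPLES[self.type]:
            raise ValueError(
                f"{self.type} bandit must carry "
                f"{N_INITIAL_SAMPLES[self.type]} initial samples"
            )


@dataclass(frozen=True)
class Trial:
    trial_id: int
    pair_id: int
    horizon: str  # "short" | "long"
    bandits: tuple[Bandit, Bandit, Bandit]  # display positions left/middle/right
    high_value_index: int | None = None

    def __post_init__(self):
        types = [b.type for b in self.bandits]
        if len(self.bandits) != 3 or len(set(types)) != 3:
            raise ValueError("a trial shows exactly 3 bandits of distinct types")


@dataclass(frozen=True)
class Session:
    participant_id: str
    seed: int
    trials: tuple[Trial, ...]


def _truncnorm_draw(mean: float, sd: float, lo: float, hi: float, rng) -> float:
    """One draw from a Gaussian truncated to [lo, hi], by inversion of the
    conditional CDF (exact, loop-free)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-300:  # mean pathologically far outside the bounds: clamp
        return min(max(mean, lo), hi)
    u = a + (b - a) * rng.random()
    x = mean + sd * float(ndtri(u))
    # guard against u rounding onto 0/1 when the truncation mass is tiny
    return min(max(x, lo), hi)


def draw_reward(true_mean: float, cfg: GenerativeConfig, rng: np.random.Generator) -> int:
    """Integer apple size: truncated-then-rounded Gaussian around ``true_mean``."""
    lo, hi = cfg.reward_bounds
    x = _truncnorm_draw(true_mean, cfg.reward_sd, lo, hi, rng)
    return int(math.floor(x + 0.5))  # round half-up


def draw_rewards(true_means, cfg: GenerativeConfig, rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`draw_reward` (independent draws, one per entry)."""
    mu = np.asarray(true_means, dtype=float)
    lo, hi = cfg.reward_bounds
    a = ndtr((lo - mu) / cfg.reward_sd)
    b = ndtr((hi - mu) / cfg.reward_sd)
    u = a + (b - a) * rng.random(mu.shape)
    x = np.clip(mu + cfg.reward_sd * ndtri(u), lo, hi)
    return np.floor(x + 0.5).astype(int)


def make_trial_means(cfg: GenerativeConfig, rng: np.random.Generator,
                     certain: float | None = None) -> dict[str, float]:
    """Overall (type-level) means for one trial.

    The certain-standard mean is 4.5 or 6.5 (or the supplied ``certain``
    anchor); the standard mean adds a uniform offset from {-2,-1,+1,+2}; the
    novel mean adds such an offset to either of the former (anchor chosen
    uniformly); the low-value mean is 1 below the minimum of the other three.
    """
    if certain is None:
        certain = float(rng.choice(cfg.certain_overall_means))
    standard = certain + float(rng.choice(cfg.offset_set))
    anchor = certain if rng.random() < 0.5 else standard
    novel = anchor + float(rng.choice(cfg.offset_set))
    low = min(certain, standard, novel) - 1.0
    return {
        "certain_standard": certain,
        "standard": standard,
        "novel": novel,
        "low_value": low,
    }


def realize_bandit(
    btype: str, overall_mean: float, cfg: GenerativeConfig, rng: np.random.Generator
) -> Bandit:
    """Sample a bandit's true mean around its overall mean and draw its
    initial samples."""
    true_mean = rng.normal(overall_mean, cfg.mean_sd)
    samples = tuple(
        draw_reward(true_mean, cfg, rng) for _ in range(N_INITIAL_SAMPLES[btype])
    )
    return Bandit(btype, overall_mean, true_mean, samples)


def _choose_types(cfg: GenerativeConfig, rng: np.random.Generator) -> list[str]:
    """3-of-4 bandit type subset.  With probability ``p_low_value`` the
    low-value bandit is included (dropping one of the other three uniformly);
    p_low_value = 0.75 is equivalent to a uniform draw over the four subsets."""
    others = ["certain_standard", "standard", "novel"]
    if rng.random() < cfg.p_low_value:
        drop = rng.integers(3)
        return [t for i, t in enumerate(others) if i != drop] + ["low_value"]
    return others


def _resample_low_value_below(low: Bandit, bandits: list[Bandit],
                              cfg: GenerativeConfig, rng) -> Bandit:
    """Redraw the low-value bandit's initial sample conditional on it being
    strictly below every other displayed initial sample.

    Equivalent in distribution to rejection-resampling from the bandit's
    truncated-rounded reward distribution until the strict-minimum constraint
    holds (the paper's procedure), but drawn in one step: a rounded value
    below ``m`` corresponds to a continuous draw below ``m - 0.5``.  If no
    integer below ``m`` exists within the reward bounds the constraint is
    unsatisfiable and the caller regenerates the trial.
    """
    lo, hi = cfg.reward_bounds
    others = [s for b in bandits if b.type != "low_value" for s in b.initial_samples]
    m = min(others)
    if m <= lo:  # another bandit already shows the smallest possible apple
        return low
    x = _truncnorm_draw(low.true_mean, cfg.reward_sd, lo, min(m - 0.5, hi), rng)
    sample = int(math.floor(x + 0.5))
    return replace(low, initial_samples=(min(sample, m - 1),))


def _low_value_is_strict_min(bandits: list[Bandit]) -> bool:
    low = [b for b in bandits if b.type == "low_value"]
    if not low:
        return True
    low_sample = low[0].initial_samples[0]
    others = [s for b in bandits if b.type != "low_value" for s in b.initial_samples]
    return all(low_sample < s for s in others)


def make_trial(
    cfg: GenerativeConfig,
    rng: np.random.Generator,
    trial_id: int = 0,
    pair_id: int = 0,
    horizon: str = "short",
) -> Trial:
    """Generate one trial: pick 3 of the 4 bandit types, realize them, enforce
    the low-value strict-minimum constraint by resampling its initial sample,
    shuffle display positions, and label the high-value bandit.

    The type subset and overall means are drawn once per trial; when the
    constraint is unsatisfiable (another bandit already shows the smallest
    possible apple) only the bandit realizations are redrawn, so neither the
    4.5/6.5 anchor balance nor the type-subset mix is distorted by the
    constraint.
    """
    means = make_trial_means(cfg, rng)
    types = _choose_types(cfg, rng)
    for _ in range(cfg.max_trial_regenerations):
        bandits = [realize_bandit(t, means[t], cfg, rng) for t in types]
        ok = True
        if "low_value" in types:
            idx = types.index("low_value")
            if not _low_value_is_strict_min(bandits):
                bandits[idx] = _resample_low_value_below(
                    bandits[idx], bandits, cfg, rng)
            ok = _low_value_is_strict_min(bandits)
        if ok:
            order = rng.permutation(3)
            trial = Trial(trial_id, pair_id, horizon, tuple(bandits[i] for i in order))
            return label_high_value(trial)
    raise RuntimeError(
        "could not satisfy the low-value strict-minimum constraint; "
        "check the generative configuration"
    )


def label_high_value(trial: Trial) -> Trial:
    """Label the certain-standard/standard bandit with the highest mean of its
    initial samples; novel and low-value bandits are never labelled.  Exact
    ties break toward the lower display position."""
    best, best_mean = None, -math.inf
    for i, b in enumerate(trial.bandits):
        if b.type in _HIGH_VALUE_ELIGIBLE:
            m = float(np.mean(b.initial_samples))
            if m > best_mean:
                best, best_mean = i, m
    if best is None:
        raise ValueError(
            "trial contains neither a certain-standard nor a standard bandit; "
            "the high-value label is undefined"
        )
    return replace(trial, high_value_index=best)


def _duplicate_trial(
    trial: Trial, trial_id: int, rng: np.random.Generator
) -> Trial:
    """Copy a trial's choice-relevant content exactly; display positions are
    re-randomized (cosmetic)."""
    order = rng.permutation(3)
    dup = Trial(
        trial_id, trial.pair_id, trial.horizon, tuple(trial.bandits[i] for i in order)
    )
    return label_high_value(dup)


def make_session(
    participant_id: str,
    seed: int,
    cfg: GenerativeConfig | None = None,
) -> Session:
    """Full session: ``n_trials_per_horizon`` trials per horizon, built from
    half as many unique configurations per horizon, each duplicated; trial
    order is shuffled (intermixed horizons)."""
    cfg = cfg or GenerativeConfig()
    rng = np.random.default_rng(seed)
    n_unique = cfg.n_trials_per_horizon // 2
    trials: list[Trial] = []
    pair_id = 0
    for horizon in ("short", "long"):
        for _ in range(n_unique):
            t = make_trial(cfg, rng, trial_id=0, pair_id=pair_id, horizon=horizon)
            trials.append(t)
            trials.append(_duplicate_trial(t, 0, rng))
            pair_id += 1
    order = rng.permutation(len(trials))
    trials = [replace(trials[i], trial_id=k) for k, i in enumerate(order)]
    return Session(str(participant_id), int(seed), tuple(trials))


# ---------------------------------------------------------------------------
# serialization: one row per trial per bandit

_SESSION_COLUMNS = [
    "participant_id",
    "trial_id",
    "pair_id",
    "horizon",
    "position",
    "bandit_type",
    "true_mean",
    "overall_mean",
    "initial_samples",
    "high_value_flag",
]


def session_to_frame(session: Session) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        for pos, b in enumerate(t.bandits):
            rows.append(
                (
                    session.participant_id,
                    t.trial_id,
                    t.pair_id,
                    t.horizon,
                    pos,
                    b.type,
                    b.true_mean,
                    b.overall_mean,
                    ";".join(str(s) for s in b.initial_samples),
                    int(pos == t.high_value_index),
                )
            )
    return pd.DataFrame(rows, columns=_SESSION_COLUMNS)


def write_session(session: Session, path) -> None:
    session_to_frame(session).to_csv(path, index=False, encoding="utf-8")


def _session_from_frame(df: pd.DataFrame, participant_id: str) -> Session:
    trials = []
    for tid, g in df.sort_values(["trial_id", "position"]).groupby("trial_id", sort=True):
        bandits = tuple(
            Bandit(
                r.bandit_type,
                float(r.overall_mean),
                float(r.true_mean),
                tuple(int(s) for s in str(r.initial_samples).split(";") if s != ""),
            )
            for r in g.itertuples()
        )
        hv = g.reset_index(drop=True)["high_value_flag"].to_numpy().argmax()
        trials.append(
            Trial(int(tid), int(g.pair_id.iloc[0]), g.horizon.iloc[0], bandits, int(hv))
        )
    trials.sort(key=lambda t: t.trial_id)
    return Session(participant_id, -1, tuple(trials))


def read_sessions(path) -> list[Session]:
    """Read sessions written by :func:`write_session` (any number of
    participants in one file)."""
    df = pd.read_csv(path)
    df["initial_samples"] = df["initial_samples"].fillna("")
    return [
        _session_from_frame(g, str(pid)) for pid, g in df.groupby("participant_id")
    ]
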