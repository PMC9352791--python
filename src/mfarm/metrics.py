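"""Behavioural measures computed from sessions and recorded choices.

Per participant and horizon: first-draw frequencies of the high-value /
novel / low-value bandit categories, the expected value (mean of the chosen
bandit's initial samples) and information content (number of initial
samples) of the chosen bandit, reward summaries, duplicate-pair choice
consistency, and the study's performance-based exclusion filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .taskgen import Session

__all__ = [
    "first_draw_frequencies",
    "expected_value_metrics",
    "reward_metrics",
    "consistency",
    "participant_metrics",
    "cohort_metrics",
    "apply_exclusions",
    "MIN_MEAN_SCORE",
    "MIN_MEAN_RT_MS",
]

#: exclusion thresholds: chance-level mean apple size, and minimum mean
#: first-draw reaction time (ms) indicating considered choices
MIN_MEAN_SCORE = 5.5
MIN_MEAN_RT_MS = 1500.0


def _first_draws(session: Session, choices: pd.DataFrame) -> pd.DataFrame:
    first = choices[choices["draw_index"] == 0]
    trial_ids = {t.trial_id for t in session.trials}
    missing = trial_ids - set(first["trial_id"])
    if missing:
        raise ValueError(f"trials without a recorded first draw: "
                         f"{sorted(missing)[:5]}")
    info = {
        t.trial_id: (t.horizon, t.pair_id, t.high_value_index,
                     tuple(len(b.initial_samples) for b in t.bandits),
                     tuple(b.initial_samples for b in t.bandits))
        for t in session.trials
    }
    rows = []
    for r in first.itertuples():
        horizon, pair_id, hv, n_init, init = info[r.trial_id]
        pos = int(r.chosen_position)
        samples = init[pos]
        rows.append({
            "trial_id": r.trial_id, "pair_id": pair_id, "horizon": horizon,
            "chosen_position": pos, "chosen_type": r.chosen_bandit_type,
            "is_high_value": pos == hv,
            "is_novel": n_init[pos] == 0,
            "is_low_value": r.chosen_bandit_type == "low_value",
            "n_init_chosen": n_init[pos],
            "ev_chosen": float(np.mean(samples)) if samples else np.nan,
            "reward": r.reward,
        })
    return pd.DataFrame(rows)


def first_draw_frequencies(session: Session, choices: pd.DataFrame) -> pd.DataFrame:
    """Percentage of first draws on the high-value, novel and low-value
    bandit categories, per horizon."""
    fd = _first_draws(session, choices)
    out = (
        fd.groupby("horizon")[["is_high_value", "is_novel", "is_low_value"]]
        .mean() * 100.0
    )
    return out.rename(columns={"is_high_value": "high_value_pct",
                               "is_novel": "novel_pct",
                               "is_low_value": "low_value_pct"})


def expected_value_metrics(session: Session, choices: pd.DataFrame) -> pd.DataFrame:
    """Per-horizon mean expected value of the chosen bandit (mean of its
    initial samples; novel-bandit choices carry none and are excluded) and
    mean number of initial samples of the chosen bandit (novel counts as 0)."""
    fd = _first_draws(session, choices)
    out = fd.groupby("horizon").agg(
        ev_chosen=("ev_chosen", "mean"),  # pandas skips NaN (novel choices)
        n_init_chosen=("n_init_chosen", "mean"),
    )
    return out


def reward_metrics(session: Session, choices: pd.DataFrame) -> pd.Series:
    """Short-horizon mean reward, long-horizon first-draw mean reward, and
    long-horizon mean reward across all 6 draws."""
    first = choices[choices["draw_index"] == 0]
    short_first = first.loc[first["horizon"] == "short", "reward"].mean()
    long_first = first.loc[first["horizon"] == "long", "reward"].mean()
    long_all = choices.loc[choices["horizon"] == "long", "reward"].mean()
    return pd.Series({"short_reward": short_first,
                      "long_first_reward": long_first,
                      "long_mean_reward": long_all})


def consistency(session: Session, choices: pd.DataFrame) -> pd.Series:
    """Fraction of duplicated trial pairs whose first choices land on the
    same bandit type, within each horizon and overall."""
    fd = _first_draws(session, choices)
    counts = fd.groupby("pair_id").size()
    unpaired = counts[counts != 2]
    if len(unpaired):
        raise ValueError(f"pair_ids without exactly 2 first draws: "
                         f"{list(unpaired.index)[:5]}")
    agree = fd.groupby("pair_id").agg(
        same=("chosen_type", lambda s: s.iloc[0] == s.iloc[1]),
        horizon=("horizon", "first"),
    )
    out = {"consistency_overall": float(agree["same"].mean())}
    for h, g in agree.groupby("horizon"):
        out[f"consistency_{h}"] = float(g["same"].mean())
    return pd.Series(out)


def participant_metrics(session: Session, choices: pd.DataFrame,
                        reaction_times: pd.Series | None = None) -> pd.Series:
    """Flat per-participant summary combining all the above (columns used by
    the Step-1 battery and the exclusion filters)."""
    freq = first_draw_frequencies(session, choices)
    ev = expected_value_metrics(session, choices)
    rew = reward_metrics(session, choices)
    cons = consistency(session, choices)
    out = {"participant_id": session.participant_id,
           "mean_score": float(choices["reward"].mean())}
    for h in ("short", "long"):
        for col in freq.columns:
            out[f"{col}_{h}"] = float(freq.loc[h, col]) if h in freq.index else np.nan
        for col in ev.columns:
            out[f"{col}_{h}"] = float(ev.loc[h, col]) if h in ev.index else np.nan
    out.update(rew.to_dict())
    out.update(cons.to_dict())
    out["mean_first_rt_ms"] = (
        float(np.mean(reaction_times)) if reaction_times is not None else np.nan
    )
    return pd.Series(out)


def cohort_metrics(sessions, choices: pd.DataFrame) -> pd.DataFrame:
    """One metrics row per participant (sessions iterable + pooled choices)."""
    rows = []
    for sess in sessions:
        sub = choices[choices["participant_id"] == sess.participant_id]
        rows.append(participant_metrics(sess, sub))
    return pd.DataFrame(rows).set_index("participant_id")


def apply_exclusions(summaries: pd.DataFrame,
                     incomplete: pd.Series | None = None,
                     attention_failed: pd.Series | None = None) -> pd.DataFrame:
    """Exclusion flags: mean score below 5.5 (chance-level play), mean
    first-draw RT below 1500 ms (no deliberation), incomplete data, or a
    failed questionnaire attention check (pass-through boolean).  RT is
    optional for synthetic data (missing RT never excludes)."""
    out = pd.DataFrame(index=summaries.index)
    out["low_score"] = summaries["mean_score"] < MIN_MEAN_SCORE
    rt = summaries.get("mean_first_rt_ms")
    out["fast_rt"] = (rt < MIN_MEAN_RT_MS).fillna(False) if rt is not None else False
    out["incomplete"] = (incomplete.reindex(summaries.index).fillna(False)
                         if incomplete is not None else False)
    out["attention_failed"] = (
        attention_failed.reindex(summaries.index).fillna(False)
        if attention_failed is not None else False)
    out["excluded"] = out.any(axis=1)
    reasons = out.drop(columns="excluded")
    out["reason"] = reasons.apply(
        lambda r: ";".join(c for c in reasons.columns if r[c]), axis=1)
    return out
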