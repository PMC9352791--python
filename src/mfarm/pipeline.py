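"""Orchestration of the full analysis workflow.

Step 1 replicates the task-effect battery on a synthetic cohort: the six
directional horizon effects on behaviour (high-value frequency down, novel
and low-value frequencies up, expected value down, first-draw reward down,
6-draw mean reward up in the long horizon), optional MAP fitting of the
model zoo with BIC ranking, and horizon tests on fitted parameters.

Step 2 runs the individual-differences analysis: bivariate and partial
(age, IQ) correlations of the trait score with fitted epsilon and with the
low-value bandit frequency, plus repeated-measures ANOVAs with horizon
within and the trait as a continuous between-participant variable.

Every stochastic stage receives a seed derived deterministically from the
master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import fitting, metrics, models, stats

__all__ = ["RunConfig", "Step1Report", "Step2Report", "build_cohort",
           "fit_cohort", "run_step1", "run_step2", "write_report"]

#: (label, short column, long column, expected sign of short - long)
STEP1_BATTERY = [
    ("high_value_freq", "high_value_pct_short", "high_value_pct_long", +1),
    ("novel_freq", "novel_pct_short", "novel_pct_long", -1),
    ("low_value_freq", "low_value_pct_short", "low_value_pct_long", -1),
    ("expected_value", "ev_chosen_short", "ev_chosen_long", +1),
    ("first_draw_reward", "short_reward", "long_first_reward", +1),
    ("mean_reward", "short_reward", "long_mean_reward", -1),
]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_participants: int = 100
    trait_link: float = 0.26
    fit_models: bool = False        # fit the winning model in step 1/2
    model_label: str = "Thompson+eta+eps"
    n_restarts: int = 3
    alpha: float = 0.05
    cohort_overrides: dict = field(default_factory=dict)

    def cohort_config(self) -> cohort_mod.CohortConfig:
        return cohort_mod.CohortConfig(
            n_participants=self.n_participants,
            trait_link=self.trait_link,
            seed=int(np.random.SeedSequence(self.seed).generate_state(1)[0]
                     % (2**31)),
            **self.cohort_overrides,
        )


@dataclass
class Step1Report:
    config: RunConfig
    metrics: pd.DataFrame
    tests: pd.DataFrame
    bic_ranking: pd.DataFrame | None = None
    parameter_tests: pd.DataFrame | None = None


@dataclass
class Step2Report:
    config: RunConfig
    correlations: pd.DataFrame
    anovas: dict


def build_cohort(cfg: RunConfig) -> cohort_mod.CohortTable:
    return cohort_mod.generate_cohort(cfg.cohort_config())


def fit_cohort(table: cohort_mod.CohortTable, spec: models.ModelSpec,
               n_restarts: int = 3, seed: int = 0) -> pd.DataFrame:
    """MAP-fit one model to every participant; one row per participant with
    the fitted parameters and BIC."""
    rows = []
    ss = np.random.SeedSequence(seed)
    for sess in table.sessions:
        sub = table.choices[table.choices["participant_id"] == sess.participant_id]
        data = fitting.compile_first_draws(sess, sub)
        fr = fitting.fit_map(spec, data, n_restarts=n_restarts,
                             seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)))
        row = {"participant_id": sess.participant_id, "bic": fr.bic,
               "log_likelihood": fr.log_likelihood}
        row.update(fr.params_hat)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def _paired_battery(mtab: pd.DataFrame, battery) -> pd.DataFrame:
    rows = []
    for label, col_s, col_l, sign in battery:
        # pairwise-complete observations (a participant who e.g. never chose
        # a sampled bandit in one horizon has no expected-value entry there)
        sub = mtab[[col_s, col_l]].dropna()
        res = stats.shapiro_gated_paired_test(sub[col_s], sub[col_l])
        observed = float(np.sign(np.mean(sub[col_s] - sub[col_l])))
        rows.append({
            "measure": label, "short_mean": float(sub[col_s].mean()),
            "long_mean": float(sub[col_l].mean()), "test": res.test,
            "statistic": res.statistic, "p_value": res.p_value,
            "effect_size": res.effect_size, "expected_sign": sign,
            "sign_ok": observed == sign,
        })
    return pd.DataFrame(rows)


def run_step1(cfg: RunConfig,
              table: cohort_mod.CohortTable | None = None) -> Step1Report:
    """Task-effect battery on a synthetic cohort (generated from ``cfg`` if
    not supplied)."""
    table = table or build_cohort(cfg)
    mtab = metrics.cohort_metrics(table.sessions, table.choices)
    tests = _paired_battery(mtab, STEP1_BATTERY)
    ranking = param_tests = None
    if cfg.fit_models:
        spec = models.get_model(cfg.model_label)
        fits = fit_cohort(table, spec, cfg.n_restarts,
                          seed=int(np.random.SeedSequence(cfg.seed + 1)
                                   .generate_state(1)[0] % (2**31)))
        battery = [(p, f"{p}_short", f"{p}_long", -1)
                   for p in ("epsilon", "eta", "sigma0")
                   if f"{p}_short" in fits.columns]
        param_tests = _paired_battery(fits, battery)
        ranking = pd.DataFrame({"model": [spec.label],
                                "mean_bic": [fits["bic"].mean()]})
    return Step1Report(cfg, mtab, tests, ranking, param_tests)


def run_step2(cfg: RunConfig,
              table: cohort_mod.CohortTable | None = None,
              fits: pd.DataFrame | None = None) -> Step2Report:
    """Trait-exploration association analysis on a synthetic cohort."""
    table = table or build_cohort(cfg)
    mtab = metrics.cohort_metrics(table.sessions, table.choices)
    part = table.participants.set_index("participant_id")
    mtab = mtab.loc[part.index]
    if fits is None and cfg.fit_models:
        fits = fit_cohort(table, models.get_model(cfg.model_label),
                          cfg.n_restarts,
                          seed=int(np.random.SeedSequence(cfg.seed + 2)
                                   .generate_state(1)[0] % (2**31)))
    trait = part["trait"].to_numpy()
    covs = part[["age", "iq"]].to_numpy()
    low_value = ((mtab["low_value_pct_short"] + mtab["low_value_pct_long"]) / 2
                 ).to_numpy()

    measures = {"low_value_freq": low_value}
    if fits is not None:
        fits = fits.loc[part.index]
        measures["epsilon_fitted"] = (
            (fits["epsilon_short"] + fits["epsilon_long"]) / 2).to_numpy()
    rows = []
    for name, vals in measures.items():
        r, p, df = stats.pearson(trait, vals)
        rp, pp, dfp = stats.partial_pearson(trait, vals, covs)
        rows.append({"measure": name, "r": r, "p": p, "df": df,
                     "r_partial": rp, "p_partial": pp, "df_partial": dfp})
    correlations = pd.DataFrame(rows)

    anovas = {"low_value_freq": stats.rm_anova_continuous_between(
        mtab["low_value_pct_short"], mtab["low_value_pct_long"], trait)}
    if fits is not None:
        anovas["epsilon_fitted"] = stats.rm_anova_continuous_between(
            fits["epsilon_short"], fits["epsilon_long"], trait)
    return Step2Report(cfg, correlations, anovas)


def write_report(report, path) -> None:
    """Machine-readable JSON dump of a step report (config, seed, version)."""
    from . import __version__

    def conv(v):
        if isinstance(v, pd.DataFrame):
            return v.reset_index().to_dict(orient="records")
        if hasattr(v, "__dataclass_fields__"):
            return asdict(v)
        return v

    payload = {"version": __version__,
               **{k: conv(v) for k, v in vars(report).items()}}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
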