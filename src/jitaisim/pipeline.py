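"""End-to-end pipeline: simulate -> trigger -> inject effects -> analyze -> report.

All tabular artifacts are long-format CSV with stable snake_case headers and
empty fields for missing values; run summaries are JSON.  Outputs are
byte-identical across reruns with the same (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from .charts import charts_to_frame
from .config import ACTIVE_CONDITIONS, DISTRESS_VARS, RunConfig
from .engine import TrialLog, run_trial
from .synthetic import (
    GroundTruth,
    PersonParams,
    Schedule,
    apply_intervention_effects,
    generate_cohort,
    generate_cohort_streams,
    generate_evening_helpfulness,
    ground_truth_frame,
)

EMA_COLUMNS = [
    "person_id", "day", "slot", "timestamp", "completed",
    *DISTRESS_VARS, "support_need", "support_seeking",
    "attention_check_shown", "attention_check_value",
    "appropriate_timing", "behavior_adoption",
]


# ---------------------------------------------------------------------------
# CSV round-tripping


def write_ema_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=[c for c in EMA_COLUMNS if c in records])


def read_ema_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in ("completed", "attention_check_shown"):
        df[col] = _to_bool(df[col])
    for col in ("support_need", "behavior_adoption"):
        df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df


def _to_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.map({"True": True, "False": False, True: True, False: False}).astype(bool)


def read_trial_log(path: str | Path) -> TrialLog:
    """Round-trip a decisions CSV back into a :class:`TrialLog`."""
    decisions = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for col in ("fixed_cutoff_vars", "spc_vars"):
        decisions[col] = decisions[col].fillna("")
    for col in ("delivered", "omitted_control", "fixed_cutoff_met", "spc_met",
                "support_need_met", "any_met", "spc_evaluable"):
        decisions[col] = _to_bool(decisions[col])
    return TrialLog.from_frame(decisions)


def params_to_frame(cohort: list[PersonParams]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {"person_id": p.person_id, "index": p.index}
        for j, var in enumerate(DISTRESS_VARS):
            row[f"mu_{var}"] = p.mu[j]
            row[f"sd_within_{var}"] = p.sd_within[j]
        row.update(
            ar_coef=p.ar_coef, compliance_prob=p.compliance_prob,
            support_need_intercept=p.support_need_intercept,
            support_need_slope=p.support_need_slope,
            no_worries_threshold=p.no_worries_threshold,
            careless_prob=p.careless_prob,
            effect_delta=p.effect_delta, support_seek_shift=p.support_seek_shift,
            support_seek_mu=p.support_seek_mu, support_seek_sd=p.support_seek_sd,
            timing_sd=p.timing_sd, helpfulness_sd=p.helpfulness_sd,
        )
        for cond in ACTIVE_CONDITIONS:
            row[f"adoption_prob_{cond}"] = p.adoption_prob[cond]
            row[f"timing_mu_{cond}"] = p.timing_mu[cond]
            row[f"helpfulness_mu_{cond}"] = p.helpfulness_mu[cond]
        rows.append(row)
    return pd.DataFrame(rows)


def params_from_frame(frame: pd.DataFrame) -> list[PersonParams]:
    cohort = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        cohort.append(
            PersonParams(
                person_id=d["person_id"],
                index=int(d["index"]),
                mu=np.array([d[f"mu_{v}"] for v in DISTRESS_VARS]),
                sd_within=np.array([d[f"sd_within_{v}"] for v in DISTRESS_VARS]),
                ar_coef=d["ar_coef"],
                compliance_prob=d["compliance_prob"],
                support_need_intercept=d["support_need_intercept"],
                support_need_slope=d["support_need_slope"],
                no_worries_threshold=d["no_worries_threshold"],
                careless_prob=d["careless_prob"],
                adoption_prob={c: d[f"adoption_prob_{c}"] for c in ACTIVE_CONDITIONS},
                effect_delta=d["effect_delta"],
                support_seek_shift=d["support_seek_shift"],
                support_seek_mu=d["support_seek_mu"],
                support_seek_sd=d["support_seek_sd"],
                timing_mu={c: d[f"timing_mu_{c}"] for c in ACTIVE_CONDITIONS},
                timing_sd=d["timing_sd"],
                helpfulness_mu={c: d[f"helpfulness_mu_{c}"] for c in ACTIVE_CONDITIONS},
                helpfulness_sd=d["helpfulness_sd"],
            )
        )
    return cohort


def truths_from_frame(frame: pd.DataFrame) -> dict[str, GroundTruth]:
    truths = {}
    for idx, (pid, sub) in enumerate(frame.groupby("person_id", sort=True)):
        sub = sub.sort_values(["day", "slot"])
        truths[pid] = GroundTruth(
            person_id=pid,
            index=idx,
            day=sub["day"].to_numpy(),
            slot=sub["slot"].to_numpy(),
            latent=sub[[f"latent_{v}" for v in DISTRESS_VARS]].to_numpy(),
            latent_seek=sub["latent_support_seeking"].to_numpy(),
            spawn_key=(),
        )
    return truths


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    config: RunConfig
    seed: int
    cohort: list[PersonParams]
    records: pd.DataFrame  # post-effect EMA streams
    truths: dict[str, GroundTruth]
    trial_log: TrialLog
    helpfulness: pd.DataFrame
    compliance: an.ComplianceSummary
    careless: an.CarelessSummary
    contrasts: pd.DataFrame
    summary: dict


def analyze(
    records: pd.DataFrame,
    trial_log: TrialLog,
    helpfulness: pd.DataFrame,
    config: RunConfig,
) -> tuple[an.ComplianceSummary, an.CarelessSummary, pd.DataFrame, dict]:
    """Run the aim 1-3 analyses and assemble the run summary."""
    acfg = config.analysis
    compliance = an.compliance_summary(
        records, acfg.compliance_threshold, acfg.feasibility_share
    )
    careless = an.careless_rate(records, acfg.careless_threshold)

    results = []
    for outcome in ("appropriate_timing", "behavior_adoption"):
        for res in an.condition_outcome_contrasts(records, trial_log, outcome):
            results.append((outcome, res))
    for res in an.condition_outcome_contrasts(records, trial_log, "helpfulness", helpfulness):
        results.append(("helpfulness", res))
    for res in an.condition_outcome_contrasts(records, trial_log, "support_seeking"):
        results.append(("support_seeking", res))
    for var in DISTRESS_VARS:
        for res in an.condition_outcome_contrasts(records, trial_log, var):
            results.append((f"delta_{var}", res))
    contrasts = an.comparisons_frame(results)

    scores = an.change_scores(records, trial_log)
    nd = acfg.round_decimals
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_persons": config.n_persons,
        "scheduled_per_person": config.schedule.n_days * config.schedule.slots_per_day,
        "compliance": {
            "n_completed": compliance.n_completed,
            "n_scheduled": compliance.n_scheduled,
            "mean_rate_pct": round(100 * compliance.mean_rate, nd),
            "sd_rate_pct": round(100 * compliance.sd_rate, nd)
            if np.isfinite(compliance.sd_rate) else None,
            "share_meeting_threshold_pct": round(100 * compliance.share_meeting_threshold, nd),
            "feasible": compliance.feasible,
        },
        "careless": {
            "n_shown": careless.n_shown,
            "n_careless": careless.n_careless,
            "rate_pct": None if careless.rate is None else round(100 * careless.rate, nd),
            "high_quality": careless.high_quality,
        },
        "trial": trial_log.summary(),
        "change_scores": {
            "n_same_day_pairs": scores.n_pairs,
            "n_dropped_overnight": scores.n_dropped_overnight,
        },
    }
    return compliance, careless, contrasts, summary


def run_pipeline(
    config: RunConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage in order; optionally write the artifact bundle to ``out_dir``."""
    config = config or RunConfig()
    if seed is not None:
        config = config.model_copy(update={"seed": int(seed)})
    seed = config.seed

    cohort = generate_cohort(config.n_persons, config.population, seed, config.effects)
    schedule = Schedule.from_config(config.schedule, config.trigger.intervention_start_day)
    records, truths = generate_cohort_streams(cohort, schedule, seed)
    trial_log = run_trial(records, config.trigger, seed)
    records, truths = apply_intervention_effects(records, trial_log, cohort, truths, seed)
    helpfulness = generate_evening_helpfulness(trial_log, cohort, seed)
    compliance, careless, contrasts, summary = analyze(records, trial_log, helpfulness, config)

    result = PipelineResult(
        config=config, seed=seed, cohort=cohort, records=records, truths=truths,
        trial_log=trial_log, helpfulness=helpfulness, compliance=compliance,
        careless=careless, contrasts=contrasts, summary=summary,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ema_csv(result.records, out / "ema.csv")
    ground_truth_frame(result.truths).to_csv(out / "ground_truth.csv", index=False)
    params_to_frame(result.cohort).to_csv(out / "cohort_params.csv", index=False)
    result.trial_log.decisions.to_csv(out / "trial_log.csv", index=False)
    charts_to_frame(result.trial_log.final_charts).to_csv(out / "charts.csv", index=False)
    result.helpfulness.to_csv(out / "helpfulness.csv", index=False)
    result.compliance.per_person.to_csv(out / "compliance.csv", index=False)
    result.contrasts.to_csv(out / "contrasts.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    result.config.save(out / "config.yaml")
    (out / "report.txt").write_text(render_report(result))


def render_report(result: PipelineResult) -> str:
    s = result.summary
    t = s["trial"]
    lines = [
        "Simulated social-support JITAI micro-randomized trial",
        f"config hash {s['config_hash']}  seed {s['seed']}",
        "",
        f"Cohort: {s['n_persons']} persons, {s['scheduled_per_person']} scheduled EMAs each",
        (
            f"Compliance: {s['compliance']['n_completed']}/{s['compliance']['n_scheduled']} "
            f"completed ({s['compliance']['mean_rate_pct']}%); "
            f"{s['compliance']['share_meeting_threshold_pct']}% of persons >= "
            f"{round(100 * result.compliance.person_threshold)}% "
            f"-> feasible: {s['compliance']['feasible']}"
        ),
        (
            f"Careless responding: {s['careless']['n_careless']}/{s['careless']['n_shown']} "
            f"({s['careless']['rate_pct']}%) -> high quality: {s['careless']['high_quality']}"
        ),
        "",
        f"Interventions delivered: {t['total_delivered']} "
        f"(fixed_cutoff {t['delivered_by_condition']['fixed_cutoff']}, "
        f"spc {t['delivered_by_condition']['spc']}, "
        f"support_need {t['delivered_by_condition']['support_need']}; "
        f"identity holds: {t['accounting_identity_holds']})",
        f"Daily-cap suppressions: {t['cap_suppressions']}; "
        f"omitted controls: {t['omitted_controls']}",
        f"Change-score pairs (same-day): {s['change_scores']['n_same_day_pairs']}, "
        f"overnight lags dropped: {s['change_scores']['n_dropped_overnight']}",
        "",
        "Contrasts (Welch t, Cohen d):",
    ]
    for row in result.contrasts.itertuples(index=False):
        if row.estimable:
            lines.append(
                f"  {row.outcome}: {row.group_a} vs {row.group_b}  "
                f"d={row.cohen_d:+.2f}  t({row.df:.1f})={row.t:+.2f}  p={row.p:.3f}"
            )
        else:
            lines.append(
                f"  {row.outcome}: {row.group_a} vs {row.group_b}  not estimable ({row.reason})"
            )
    return "\n".join(lines) + "\n"
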