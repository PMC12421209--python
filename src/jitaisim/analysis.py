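"""Feasibility and proximal-outcome analyses.

Covers the study's three analysis aims on a simulated trial:

1. feasibility descriptives — per-person and overall EMA compliance against
   the double-70% rule (>=70% of persons each completing >=70% of their 126
   scheduled prompts), the careless-responding rate from attention checks
   (<5% = high data quality), and grand-mean / between-person-SD /
   mean-within-person-SD decompositions of any item;
2. contrasts of the three triggering strategies on appropriate timing,
   helpfulness (single-delivery days only) and behaviour adoption, via Welch
   two-sample two-tailed t tests with Cohen d;
3. proximal intervention effects — support seeking at T+1 and T -> T+1
   change scores of the distress items (delta = value(T+1) - value(T), so
   negative means reduction), contrasting delivered interventions against
   omitted controls (no-intervention condition with at least one criterion
   met).  T+1 is the next *completed* EMA; lags spanning overnight are
   excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DISTRESS_VARS
from .errors import ConsistencyError, DegenerateVarianceError, InsufficientDataError

CONDITION_PAIRS = (("fixed_cutoff", "spc"), ("fixed_cutoff", "support_need"), ("spc", "support_need"))

STATUS_DELIVERED = "delivered"
STATUS_OMITTED = "omitted"
STATUS_NOT_TRIGGERED = "not_triggered"
STATUS_CAP = "cap_suppressed"


# ---------------------------------------------------------------------------
# aim 1: compliance, careless responding, descriptives


@dataclass
class ComplianceSummary:
    per_person: pd.DataFrame  # person_id, completed, scheduled, rate
    mean_rate: float
    sd_rate: float
    pooled_rate: float
    n_completed: int
    n_scheduled: int
    share_meeting_threshold: float
    person_threshold: float
    share_required: float
    feasible: bool


def compliance_summary(
    records: pd.DataFrame,
    person_threshold: float = 0.70,
    share_required: float = 0.70,
) -> ComplianceSummary:
    """Per-person completion rates and the double-70% feasibility rule.

    ``scheduled`` is the number of prompt rows present per person (126 under
    the default 21x6 schedule).
    """
    grouped = records.groupby("person_id")["completed"]
    per_person = grouped.agg(completed="sum", scheduled="size").reset_index()
    if (per_person["scheduled"] == 0).any():
        raise ConsistencyError("person with zero scheduled prompts")
    per_person["rate"] = per_person["completed"] / per_person["scheduled"]
    rates = per_person["rate"].to_numpy()
    share = float(np.mean(rates >= person_threshold))
    return ComplianceSummary(
        per_person=per_person,
        mean_rate=float(rates.mean()),
        sd_rate=float(rates.std(ddof=1)) if len(rates) > 1 else float("nan"),
        pooled_rate=float(per_person["completed"].sum() / per_person["scheduled"].sum()),
        n_completed=int(per_person["completed"].sum()),
        n_scheduled=int(per_person["scheduled"].sum()),
        share_meeting_threshold=share,
        person_threshold=person_threshold,
        share_required=share_required,
        feasible=share >= share_required,
    )


@dataclass
class CarelessSummary:
    n_shown: int
    n_careless: int
    rate: float | None  # None when no attention checks were shown
    quality_threshold: float
    high_quality: bool | None


def careless_rate(records: pd.DataFrame, quality_threshold: float = 0.05) -> CarelessSummary:
    """Share of shown attention checks answered with anything but the target 5."""
    shown = records.loc[records["attention_check_shown"].astype(bool)]
    n_shown = int(len(shown))
    if n_shown == 0:
        return CarelessSummary(0, 0, None, quality_threshold, None)
    n_careless = int((shown["attention_check_value"] != 5).sum())
    rate = n_careless / n_shown
    return CarelessSummary(n_shown, n_careless, rate, quality_threshold, rate < quality_threshold)


@dataclass
class DescriptiveSummary:
    item: str
    n_obs: int
    n_persons: int
    grand_mean: float
    person_means: pd.Series
    between_sd: float  # SD of person means; NaN with a single person
    mean_within_sd: float  # mean of per-person SDs over persons with >=2 obs


def descriptives(records: pd.DataFrame, item: str) -> DescriptiveSummary:
    """Grand mean, person means, between-person SD, and mean within-person SD."""
    obs = records.loc[records[item].notna(), ["person_id", item]]
    if obs.empty:
        raise InsufficientDataError(f"no observations for item {item!r}")
    person_means = obs.groupby("person_id")[item].mean()
    counts = obs.groupby("person_id")[item].size()
    within = obs.groupby("person_id")[item].std(ddof=1)
    within = within[counts >= 2]
    return DescriptiveSummary(
        item=item,
        n_obs=int(len(obs)),
        n_persons=int(len(person_means)),
        grand_mean=float(obs[item].mean()),
        person_means=person_means,
        between_sd=float(person_means.std(ddof=1)) if len(person_means) > 1 else float("nan"),
        mean_within_sd=float(within.mean()) if len(within) else float("nan"),
    )


# ---------------------------------------------------------------------------
# Welch contrasts


@dataclass
class ComparisonResult:
    """Welch two-sample contrast with Satterthwaite df and pooled-SD Cohen d.

    Sign convention: ``t`` and ``cohen_d`` share the sign of
    ``mean(first group) - mean(second group)``; swapping the groups flips both
    signs and leaves ``p`` unchanged.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    sd_a: float = float("nan")
    sd_b: float = float("nan")
    t: float = float("nan")
    df: float = float("nan")
    p: float = float("nan")
    cohen_d: float = float("nan")
    estimable: bool = True
    reason: str = ""

    @classmethod
    def not_estimable(cls, label_a: str, label_b: str, n_a: int, n_b: int, reason: str):
        return cls(label_a=label_a, label_b=label_b, n_a=n_a, n_b=n_b,
                   estimable=False, reason=reason)


def welch_contrast(group_a, group_b, label_a: str = "a", label_b: str = "b") -> ComparisonResult:
    """Welch two-sample two-tailed t test with Cohen d (pooled, n-1 weighted)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise InsufficientDataError(
            f"each group needs >=2 values (got {na} and {nb})"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both groups have zero variance")
    ma, mb = a.mean(), b.mean()
    se2a, se2b = va / na, vb / nb
    t = (ma - mb) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    pooled_sd = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (ma - mb) / pooled_sd
    return ComparisonResult(
        label_a=label_a, label_b=label_b, n_a=na, n_b=nb,
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        t=float(t), df=float(df), p=float(p), cohen_d=float(d),
    )


def _safe_contrast(a, b, label_a: str, label_b: str) -> ComparisonResult:
    try:
        return welch_contrast(a, b, label_a, label_b)
    except (InsufficientDataError, DegenerateVarianceError) as exc:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        return ComparisonResult.not_estimable(
            label_a, label_b, int(np.sum(~np.isnan(a))), int(np.sum(~np.isnan(b))), str(exc)
        )


def comparisons_frame(results) -> pd.DataFrame:
    """Tidy table, one row per contrast."""
    rows = []
    for outcome, res in results:
        rows.append({
            "outcome": outcome, "group_a": res.label_a, "group_b": res.label_b,
            "n_a": res.n_a, "n_b": res.n_b, "mean_a": res.mean_a, "mean_b": res.mean_b,
            "sd_a": res.sd_a, "sd_b": res.sd_b, "t": res.t, "df": res.df, "p": res.p,
            "cohen_d": res.cohen_d, "estimable": res.estimable, "reason": res.reason,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aim 3 plumbing: lagged pairs, trigger status, change scores


def _decision_status(decisions: pd.DataFrame) -> pd.Series:
    status = pd.Series(STATUS_NOT_TRIGGERED, index=decisions.index)
    status[decisions["suppressed_reason"] == "daily_cap"] = STATUS_CAP
    status[decisions["omitted_control"].astype(bool)] = STATUS_OMITTED
    status[decisions["delivered"].astype(bool)] = STATUS_DELIVERED
    return status


def lagged_pairs(records: pd.DataFrame, trial_log) -> pd.DataFrame:
    """Pair each intervention-phase completed EMA (T) with the next completed EMA (T+1).

    One row per T that has any later completed EMA; carries the T distress
    values, the T+1 values and post-intervention items, the calendar-day flag
    ``same_day``, the trigger ``status`` of T (delivered / omitted /
    cap_suppressed / not_triggered) and T's assigned condition.
    """
    decisions = trial_log.decisions if hasattr(trial_log, "decisions") else trial_log
    completed = (
        records.loc[records["completed"].astype(bool)]
        .sort_values(["person_id", "day", "slot"], kind="mergesort")
        .reset_index(drop=True)
    )
    grp = completed.groupby("person_id")
    nxt_cols = list(DISTRESS_VARS) + [
        "day", "slot", "support_seeking", "appropriate_timing", "behavior_adoption"
    ]
    nxt = grp[nxt_cols].shift(-1)

    pairs = completed[["person_id", "day", "slot", *DISTRESS_VARS]].copy()
    for var in DISTRESS_VARS:
        pairs[f"{var}_t1"] = nxt[var]
    pairs["day_t1"] = nxt["day"]
    pairs["slot_t1"] = nxt["slot"]
    pairs["support_seeking_t1"] = nxt["support_seeking"]
    pairs["appropriate_timing_t1"] = nxt["appropriate_timing"]
    pairs["behavior_adoption_t1"] = nxt["behavior_adoption"]
    pairs = pairs.loc[pairs["day_t1"].notna()].copy()
    pairs["same_day"] = pairs["day_t1"] == pairs["day"]

    dec = decisions.loc[
        decisions["suppressed_reason"] != "ema_missing",
        ["person_id", "day", "slot", "assigned_condition", "delivered",
         "omitted_control", "suppressed_reason"],
    ].copy()
    dec["status"] = _decision_status(dec)
    merged = pairs.merge(
        dec[["person_id", "day", "slot", "assigned_condition", "status"]],
        on=["person_id", "day", "slot"],
        how="inner",
    )
    return merged


@dataclass
class ChangeScoreSet:
    """Long-format T -> T+1 change scores, same-day pairs only."""

    frame: pd.DataFrame  # person_id, day, slot, variable, value_t, value_t1, delta, status
    n_dropped_overnight: int
    n_pairs: int = field(default=0)

    def __post_init__(self):
        self.n_pairs = int(len(self.frame)) // max(len(DISTRESS_VARS), 1)


def change_scores(records: pd.DataFrame, trial_log) -> ChangeScoreSet:
    """Per-variable change scores delta = value(T+1) - value(T) for same-day lags.

    Pairs whose next completed EMA falls on a later calendar day are dropped
    (overnight-lag exclusion) and counted in ``n_dropped_overnight``.
    """
    pairs = lagged_pairs(records, trial_log)
    n_dropped = int((~pairs["same_day"]).sum())
    same = pairs.loc[pairs["same_day"]]
    frames = []
    for var in DISTRESS_VARS:
        f = same[["person_id", "day", "slot", "status", "assigned_condition"]].copy()
        f["variable"] = var
        f["value_t"] = same[var]
        f["value_t1"] = same[f"{var}_t1"]
        f["delta"] = f["value_t1"] - f["value_t"]
        frames.append(f)
    frame = pd.concat(frames, ignore_index=True)
    return ChangeScoreSet(frame=frame, n_dropped_overnight=n_dropped)


# ---------------------------------------------------------------------------
# aim 2 & 3 contrasts


def condition_outcome_contrasts(
    records: pd.DataFrame,
    trial_log,
    outcome: str,
    helpfulness: pd.DataFrame | None = None,
) -> list[ComparisonResult]:
    """Welch contrasts for one outcome.

    * ``appropriate_timing`` / ``behavior_adoption`` — pairwise between the
      three triggering strategies, on T+1 reports after delivered
      interventions (same-day lags only; adoption is analyzed as 0/1 means);
    * ``helpfulness`` — pairwise between strategies on evening ratings of
      single-delivery days (requires the ``helpfulness`` table);
    * ``support_seeking`` — delivered vs omitted controls on the T+1 report;
    * any distress variable — delivered vs omitted on the T -> T+1 delta.

    Cells with fewer than 2 observations or zero variance everywhere yield a
    result marked not estimable rather than an exception.
    """
    if outcome == "helpfulness":
        if helpfulness is None:
            raise ValueError("helpfulness contrasts need the evening helpfulness table")
        single = helpfulness.loc[helpfulness["n_deliveries"] == 1]
        groups = {c: single.loc[single["condition"] == c, "helpfulness"] for c in
                  ("fixed_cutoff", "spc", "support_need")}
        return [
            _safe_contrast(groups[a], groups[b], a, b) for a, b in CONDITION_PAIRS
        ]

    pairs = lagged_pairs(records, trial_log)
    same = pairs.loc[pairs["same_day"]]

    if outcome in ("appropriate_timing", "behavior_adoption"):
        col = f"{outcome}_t1"
        delivered = same.loc[(same["status"] == STATUS_DELIVERED) & same[col].notna()]
        if outcome == "behavior_adoption":
            vals = delivered[col].map({"yes": 1.0, "no": 0.0})
        else:
            vals = delivered[col].astype(float)
        out = []
        for a, b in CONDITION_PAIRS:
            ga = vals[delivered["assigned_condition"] == a]
            gb = vals[delivered["assigned_condition"] == b]
            out.append(_safe_contrast(ga, gb, a, b))
        return out

    if outcome == "support_seeking":
        col = "support_seeking_t1"
        ga = same.loc[same["status"] == STATUS_DELIVERED, col].astype(float)
        gb = same.loc[same["status"] == STATUS_OMITTED, col].astype(float)
        return [_safe_contrast(ga, gb, STATUS_DELIVERED, STATUS_OMITTED)]

    if outcome in DISTRESS_VARS:
        scores = change_scores(records, trial_log).frame
        sub = scores.loc[scores["variable"] == outcome]
        ga = sub.loc[sub["status"] == STATUS_DELIVERED, "delta"]
        gb = sub.loc[sub["status"] == STATUS_OMITTED, "delta"]
        return [_safe_contrast(ga, gb, STATUS_DELIVERED, STATUS_OMITTED)]

    raise ValueError(f"unknown outcome {outcome!r}")
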