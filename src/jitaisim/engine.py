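"""Micro-randomized trigger engine.

At every completed EMA in the intervention phase (day >= 4 by default) the
engine randomizes the prompt into one of four conditions and evaluates all
three triggering criteria:

* **fixed_cutoff** — any of the four distress items is >= 5 (non-strict,
  disjunctive over items);
* **spc** — any item lies strictly above its personalized Shewhart upper
  control limit; evaluable only once at least 7 completed baseline EMAs
  exist;
* **support_need** — the momentary support-need item was answered "yes";
* **no_intervention** — never delivers; when any criterion is nonetheless
  met, the decision point is logged as an *omitted control*.

An intervention is delivered iff the assigned condition's own criterion is
met and fewer than 2 interventions were already delivered that calendar day
(the daily cap counts deliveries only).  All three criteria are evaluated at
every decision point regardless of assignment, so criterion overlap and
omitted-control accounting come for free; evaluation is side-effect free.

Charts follow the two-phase design of :mod:`jitaisim.charts`: a growing
window over completed observations strictly prior to the current EMA while
the baseline phase lasts, frozen at the full day-1..7 window afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from ._rng import TRIAL_TAG, child_rng
from .charts import D2_PAIR, ControlChart
from .config import DISTRESS_VARS, TriggerConfig
from .errors import ConfigurationError, ConsistencyError, PhaseError


class Condition(str, Enum):
    FIXED_CUTOFF = "fixed_cutoff"
    SPC = "spc"
    SUPPORT_NEED = "support_need"
    NO_INTERVENTION = "no_intervention"


CONDITION_NAMES = tuple(c.value for c in Condition)
ACTIVE = CONDITION_NAMES[:3]

SUPPRESSED_NONE = "none"
SUPPRESSED_CRITERION = "criterion_not_met"
SUPPRESSED_CONDITION4 = "condition4"
SUPPRESSED_CAP = "daily_cap"
SUPPRESSED_BASELINE = "insufficient_baseline"
SUPPRESSED_MISSING = "ema_missing"

DECISION_COLUMNS = (
    "person_id",
    "day",
    "slot",
    "assigned_condition",
    "fixed_cutoff_met",
    "fixed_cutoff_vars",
    "spc_met",
    "spc_vars",
    "spc_evaluable",
    "support_need_met",
    "any_met",
    "delivered",
    "suppressed_reason",
    "omitted_control",
    "deliveries_today_before",
)


@dataclass
class ConditionAssignment:
    condition: str
    probabilities: tuple[float, float, float, float]


@dataclass
class TriggerDecision:
    """Full audit record of one per-EMA trigger decision."""

    person_id: str
    day: int
    slot: int
    assigned_condition: str | None
    fixed_cutoff_met: bool
    fixed_cutoff_vars: tuple[str, ...]
    spc_met: bool
    spc_vars: tuple[str, ...]
    spc_evaluable: bool
    support_need_met: bool
    any_met: bool
    delivered: bool
    suppressed_reason: str
    omitted_control: bool
    deliveries_today_before: int

    def as_row(self) -> tuple:
        return (
            self.person_id,
            self.day,
            self.slot,
            self.assigned_condition,
            self.fixed_cutoff_met,
            "|".join(self.fixed_cutoff_vars),
            self.spc_met,
            "|".join(self.spc_vars),
            self.spc_evaluable,
            self.support_need_met,
            self.any_met,
            self.delivered,
            self.suppressed_reason,
            self.omitted_control,
            self.deliveries_today_before,
        )


def _check_probs(probabilities) -> tuple[float, float, float, float]:
    probs = tuple(float(p) for p in probabilities)
    if len(probs) != 4 or any(p < 0 for p in probs):
        raise ConfigurationError("need 4 non-negative condition probabilities")
    if abs(sum(probs) - 1.0) > 1e-12:
        raise ConfigurationError(f"condition probabilities must sum to 1, got {sum(probs)!r}")
    return probs


def randomize_condition(rng: np.random.Generator, probabilities) -> ConditionAssignment:
    """Draw the condition for one decision point."""
    probs = _check_probs(probabilities)
    code = int(rng.choice(4, p=probs))
    return ConditionAssignment(condition=CONDITION_NAMES[code], probabilities=probs)


def draw_conditions(rng: np.random.Generator, probabilities, n: int) -> np.ndarray:
    """Vectorized condition codes (0..3) for ``n`` decision points."""
    probs = _check_probs(probabilities)
    # inverse-CDF on uniforms keeps a single rng call per batch
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _get(record, name):
    try:
        return getattr(record, name)
    except AttributeError:
        return record[name]


def _distress_values(record) -> tuple[float, ...]:
    return tuple(float(_get(record, v)) for v in DISTRESS_VARS)


def evaluate_fixed_cutoff(record, cutoff: float = 5) -> tuple[bool, tuple[str, ...]]:
    """Disjunctive fixed rule: any distress item at or above ``cutoff``."""
    values = _distress_values(record)
    if any(np.isnan(v) for v in values):
        raise ValueError("fixed-cutoff rule is not evaluable on an incomplete record")
    hits = tuple(v for v, x in zip(DISTRESS_VARS, values) if x >= cutoff)
    return bool(hits), hits


def evaluate_spc(
    charts: dict[str, ControlChart | None],
    record,
    min_baseline_obs: int = 7,
) -> tuple[bool, tuple[str, ...], bool]:
    """Disjunctive personalized rule: any item strictly above its UCL.

    Returns ``(met, exceeding_variables, evaluable)``; not evaluable while any
    chart lacks the required completed-baseline count.
    """
    values = _distress_values(record)
    for var in DISTRESS_VARS:
        chart = charts.get(var)
        if chart is None or chart.n_baseline < min_baseline_obs:
            return False, (), False
    hits = tuple(
        var for var, x in zip(DISTRESS_VARS, values) if x > charts[var].ucl
    )
    return bool(hits), hits, True


def evaluate_support_need(record) -> bool:
    """True iff the support-need item was answered "yes"."""
    return _get(record, "support_need") == "yes"


def decide(
    record,
    charts: dict[str, ControlChart | None],
    deliveries_today_before: int,
    config: TriggerConfig,
    assigned: str | None = None,
    rng: np.random.Generator | None = None,
) -> TriggerDecision:
    """One full trigger decision for a completed intervention-phase EMA.

    Evaluates all three criteria, randomizes (or accepts) the condition, and
    applies the delivery rule with the daily cap.  Records before the
    intervention phase raise :class:`PhaseError`.
    """
    day = int(_get(record, "day"))
    slot = int(_get(record, "slot"))
    person_id = _get(record, "person_id")
    if day < config.intervention_start_day:
        raise PhaseError(
            f"day {day} precedes the intervention phase (starts day {config.intervention_start_day})"
        )
    if assigned is None:
        if rng is None:
            raise ValueError("either an assigned condition or an rng must be provided")
        assigned = randomize_condition(rng, config.probs).condition

    fixed_met, fixed_vars = evaluate_fixed_cutoff(record, config.cutoff)
    spc_met, spc_vars, spc_evaluable = evaluate_spc(charts, record, config.min_baseline_obs)
    need_met = evaluate_support_need(record)
    any_met = fixed_met or spc_met or need_met

    delivered = False
    omitted = False
    if assigned == Condition.NO_INTERVENTION.value:
        reason = SUPPRESSED_CONDITION4
        omitted = any_met
    else:
        if assigned == Condition.SPC.value and not spc_evaluable:
            reason = SUPPRESSED_BASELINE
        else:
            own_met = {
                Condition.FIXED_CUTOFF.value: fixed_met,
                Condition.SPC.value: spc_met,
                Condition.SUPPORT_NEED.value: need_met,
            }[assigned]
            if not own_met:
                reason = SUPPRESSED_CRITERION
            elif deliveries_today_before >= config.max_per_day:
                reason = SUPPRESSED_CAP
            else:
                reason = SUPPRESSED_NONE
                delivered = True

    return TriggerDecision(
        person_id=person_id,
        day=day,
        slot=slot,
        assigned_condition=assigned,
        fixed_cutoff_met=fixed_met,
        fixed_cutoff_vars=fixed_vars,
        spc_met=spc_met,
        spc_vars=spc_vars,
        spc_evaluable=spc_evaluable,
        support_need_met=need_met,
        any_met=any_met,
        delivered=delivered,
        suppressed_reason=reason,
        omitted_control=omitted,
        deliveries_today_before=deliveries_today_before,
    )


@dataclass
class TrialLog:
    """Ordered decisions plus the trial's accounting summaries."""

    decisions: pd.DataFrame
    probabilities: tuple[float, float, float, float] | None = None
    seed: int | None = None
    final_charts: list = field(default_factory=list)

    @classmethod
    def from_frame(cls, decisions: pd.DataFrame, **kwargs) -> "TrialLog":
        return cls(decisions=decisions.reset_index(drop=True), **kwargs)

    @property
    def total_delivered(self) -> int:
        return int(self.decisions["delivered"].sum())

    @property
    def delivered_by_condition(self) -> dict[str, int]:
        d = self.decisions.loc[self.decisions["delivered"]]
        counts = d["assigned_condition"].value_counts()
        return {c: int(counts.get(c, 0)) for c in ACTIVE}

    @property
    def delivered_shares(self) -> dict[str, float]:
        """Per-condition share of all delivered interventions, as fractions."""
        total = self.total_delivered
        by_cond = self.delivered_by_condition
        if total == 0:
            return {c: float("nan") for c in ACTIVE}
        return {c: by_cond[c] / total for c in ACTIVE}

    @property
    def cap_suppressions(self) -> int:
        return int((self.decisions["suppressed_reason"] == SUPPRESSED_CAP).sum())

    @property
    def cap_suppressions_by_condition(self) -> dict[str, int]:
        capped = self.decisions.loc[self.decisions["suppressed_reason"] == SUPPRESSED_CAP]
        counts = capped["assigned_condition"].value_counts()
        return {c: int(counts.get(c, 0)) for c in ACTIVE}

    @property
    def delivered_per_person(self) -> pd.Series:
        d = self.decisions.loc[self.decisions["delivered"]]
        return d.groupby("person_id").size()

    def overlap_table(self) -> pd.DataFrame:
        """Co-occurrence counts of criterion hits over evaluated decision points."""
        evald = self.decisions.loc[self.decisions["suppressed_reason"] != SUPPRESSED_MISSING]
        flags = evald[["fixed_cutoff_met", "spc_met", "support_need_met"]].astype(bool)
        return flags.groupby(list(flags.columns)).size().reset_index(name="count")

    def summary(self) -> dict:
        by_cond = self.delivered_by_condition
        return {
            "total_delivered": self.total_delivered,
            "delivered_by_condition": by_cond,
            "delivered_shares_pct": {
                c: round(100.0 * s, 1) for c, s in self.delivered_shares.items()
            },
            "accounting_identity_holds": sum(by_cond.values()) == self.total_delivered,
            "cap_suppressions": self.cap_suppressions,
            "cap_suppressions_by_condition": self.cap_suppressions_by_condition,
            "n_decisions": int(len(self.decisions)),
            "n_missing_placeholders": int(
                (self.decisions["suppressed_reason"] == SUPPRESSED_MISSING).sum()
            ),
            "omitted_controls": int(self.decisions["omitted_control"].sum()),
            "criterion_overlap": [
                {k: (bool(v) if isinstance(v, (bool, np.bool_)) else int(v))
                 for k, v in row.items()}
                for row in self.overlap_table().to_dict(orient="records")
            ],
        }


class _ChartAccumulator:
    """Incremental phase-1 chart state for one person (all four variables)."""

    __slots__ = ("n", "total", "mr_sum", "last", "L")

    def __init__(self, L: float):
        k = len(DISTRESS_VARS)
        self.n = 0
        self.total = np.zeros(k)
        self.mr_sum = np.zeros(k)
        self.last = np.zeros(k)
        self.L = L

    def update(self, values: np.ndarray) -> None:
        if self.n > 0:
            self.mr_sum += np.abs(values - self.last)
        self.total += values
        self.last = values
        self.n += 1

    def charts(self, person_id: str, frozen: bool) -> dict[str, ControlChart | None]:
        out: dict[str, ControlChart | None] = {}
        for j, var in enumerate(DISTRESS_VARS):
            if self.n < 2:
                out[var] = None
                continue
            mean = self.total[j] / self.n
            mr_mean = self.mr_sum[j] / (self.n - 1)
            sigma = mr_mean / D2_PAIR
            out[var] = ControlChart(
                phase1_mean=mean,
                mr_mean=mr_mean,
                sigma_hat=sigma,
                L=self.L,
                ucl=mean + self.L * sigma,
                n_baseline=self.n,
                frozen=frozen,
                person_id=person_id,
                variable=var,
            )
        return out


class _EmaView:
    """Lightweight record view handed to the decision rules."""

    __slots__ = ("person_id", "day", "slot", "negative_affect", "stress", "loneliness",
                 "rumination", "support_need")

    def __init__(self, person_id, day, slot, values, support_need):
        self.person_id = person_id
        self.day = day
        self.slot = slot
        self.negative_affect = values[0]
        self.stress = values[1]
        self.loneliness = values[2]
        self.rumination = values[3]
        self.support_need = support_need


def run_trial(
    records: pd.DataFrame,
    config: TriggerConfig | None = None,
    seed: int = 0,
) -> TrialLog:
    """Run the full micro-randomized trial over a cohort of EMA streams.

    Iterates each person's prompts chronologically, maintains the
    growing/frozen charts and the per-day delivery count, and emits one
    decision per intervention-phase prompt (completed EMAs get full
    decisions; missed prompts get ``ema_missing`` placeholders).  Fully
    reproducible under a fixed seed; per-person randomization streams are
    derived from (seed, person index in appearance order).
    """
    config = config or TriggerConfig()
    _check_probs(config.probs)
    rows: list[tuple] = []
    final_charts: list[ControlChart] = []

    for pidx, (person_id, sub) in enumerate(records.groupby("person_id", sort=True)):
        day = sub["day"].to_numpy()
        slot = sub["slot"].to_numpy()
        order = np.lexsort((slot, day))
        if not np.array_equal(order, np.arange(len(sub))):
            raise ConsistencyError(
                f"records for {person_id!r} are not sorted by (day, slot)"
            )
        completed = sub["completed"].to_numpy(dtype=bool)
        values = sub[list(DISTRESS_VARS)].to_numpy(dtype=float)
        support_need = sub["support_need"].to_numpy(dtype=object)

        rng = child_rng(seed, TRIAL_TAG, pidx)
        in_phase = (day >= config.intervention_start_day) & completed
        codes = draw_conditions(rng, config.probs, int(in_phase.sum()))

        acc = _ChartAccumulator(config.L)
        charts: dict[str, ControlChart | None] | None = None
        charts_stale = True
        frozen_state = False
        k = 0
        cur_day = -1
        delivered_today = 0
        any_delivery = False

        for i in range(len(sub)):
            d = int(day[i])
            if d != cur_day:
                cur_day = d
                delivered_today = 0
            if d >= config.intervention_start_day:
                if not completed[i]:
                    rows.append(
                        (person_id, d, int(slot[i]), None, False, "", False, "", False,
                         False, False, False, SUPPRESSED_MISSING, False, delivered_today)
                    )
                else:
                    frozen = d > config.baseline_end_day
                    if charts_stale or frozen != frozen_state:
                        charts = acc.charts(person_id, frozen)
                        charts_stale = False
                        frozen_state = frozen
                    view = _EmaView(person_id, d, int(slot[i]), values[i], support_need[i])
                    decision = decide(
                        view, charts, delivered_today, config,
                        assigned=CONDITION_NAMES[codes[k]],
                    )
                    k += 1
                    if decision.delivered:
                        delivered_today += 1
                        any_delivery = True
                    rows.append(decision.as_row())
            if (
                completed[i]
                and d <= config.baseline_end_day
                and (config.include_post_delivery_baseline or not any_delivery)
            ):
                acc.update(values[i])
                charts_stale = True

        final = acc.charts(person_id, frozen=True)
        final_charts.extend(c for c in final.values() if c is not None)

    decisions = pd.DataFrame(rows, columns=DECISION_COLUMNS)
    return TrialLog(
        decisions=decisions,
        probabilities=tuple(config.probs),
        seed=seed,
        final_charts=final_charts,
    )
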