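"""Synthetic EMA cohort generator.

Emulates the data structure of an intensive-longitudinal feasibility study:
a cohort of persons, each prompted 6 times daily for 21 days (126 scheduled
prompts), answering four 1-7 Likert distress items (negative affect, stress,
loneliness, rumination), a trinary momentary support-need item, a 1-7
support-seeking item, and an occasional attention check shown with
probability 1/7.

Generative model, per person:

* latent distress follows an independent first-order autoregressive Gaussian
  process per variable (stationary mean ``mu``, within-person SD
  ``sd_within``, lag-1 coefficient ``ar_coef``), discretized by round-half-up
  and clipped to [1, 7];
* prompt completion is independent Bernoulli(``compliance_prob``);
* the support-need answer is "I have no worries" when the mean latent
  distress falls below a threshold, otherwise "yes" with a logistic
  probability in the mean latent distress, else "no, it would not help";
* attention checks are answered 5 except on careless events
  (probability ``careless_prob``), which draw uniformly from {1..7}\\{5}.

Intervention effects are *injectable*: after the trigger engine has decided
which prompts received an intervention, :func:`apply_intervention_effects`
draws behaviour adoption per delivery, shifts the next same-day EMA's latent
distress and support seeking when support was sought, and attaches the
post-intervention items (appropriate timing, behaviour adoption) to the next
completed EMA.  Ground-truth latent trajectories and realized adoptions are
returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from ._rng import COHORT_TAG, EFFECTS_TAG, EVENING_TAG, STREAM_TAG, child_rng
from .config import DISTRESS_VARS, EffectsConfig, PopulationConfig, ScheduleConfig
from .errors import ConfigurationError, ConsistencyError

SUPPORT_NEED_LEVELS = ("yes", "would_not_help", "no_worries")
ATTENTION_TARGET = 5
ATTENTION_SHOW_PROB = 1.0 / 7.0


def discretize_likert(latent) -> np.ndarray:
    """Round-half-up to the nearest integer, clipped to the 1-7 scale.

    Monotone in the latent value: raising a latent score never lowers the item.
    """
    return np.clip(np.floor(np.asarray(latent, dtype=float) + 0.5), 1, 7)


@dataclass
class Schedule:
    """Scheduled prompt grid: ``n_days`` x ``slots_per_day`` two-hour windows."""

    n_days: int = 21
    slots_per_day: int = 6
    start_hour: int = 8
    window_hours: int = 2
    start_date: str = "2024-01-01"
    intervention_start_day: int = 4

    @classmethod
    def from_config(cls, cfg: ScheduleConfig, intervention_start_day: int = 4) -> "Schedule":
        return cls(
            n_days=cfg.n_days,
            slots_per_day=cfg.slots_per_day,
            start_hour=cfg.start_hour,
            window_hours=cfg.window_hours,
            start_date=cfg.start_date,
            intervention_start_day=intervention_start_day,
        )

    @property
    def n_prompts(self) -> int:
        return self.n_days * self.slots_per_day

    @property
    def window_bounds(self) -> list[tuple[int, int]]:
        """Start/end hour of each daily window; disjoint, ordered, within a day."""
        return [
            (self.start_hour + s * self.window_hours, self.start_hour + (s + 1) * self.window_hours)
            for s in range(self.slots_per_day)
        ]

    def validate(self) -> None:
        if self.n_days < 1 or self.slots_per_day < 1:
            raise ConfigurationError("schedule requires n_days >= 1 and slots_per_day >= 1")
        if self.start_hour + self.slots_per_day * self.window_hours > 24:
            raise ConfigurationError("schedule windows must fit within one calendar day")


@dataclass
class PersonParams:
    """Generative parameters for one synthetic person.

    ``mu`` and ``sd_within`` are per-variable arrays ordered as
    :data:`jitaisim.config.DISTRESS_VARS`.  ``adoption_prob`` maps each active
    triggering condition to the probability of seeking support after a
    delivered intervention; ``effect_delta`` / ``support_seek_shift`` are the
    injected mean changes at the next same-day EMA when support was sought.
    """

    person_id: str
    index: int
    mu: np.ndarray
    sd_within: np.ndarray
    ar_coef: float
    compliance_prob: float
    support_need_intercept: float
    support_need_slope: float
    no_worries_threshold: float
    careless_prob: float
    adoption_prob: dict[str, float]
    effect_delta: float
    support_seek_shift: float
    support_seek_mu: float = 2.7
    support_seek_sd: float = 2.2
    timing_mu: dict[str, float] = field(
        default_factory=lambda: {"fixed_cutoff": 3.0, "spc": 2.3, "support_need": 4.4}
    )
    timing_sd: float = 1.8
    helpfulness_mu: dict[str, float] = field(
        default_factory=lambda: {"fixed_cutoff": 3.5, "spc": 3.6, "support_need": 4.65}
    )
    helpfulness_sd: float = 1.8

    def validate(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sd_within = np.asarray(self.sd_within, dtype=float)
        if self.mu.shape != (len(DISTRESS_VARS),):
            raise ConfigurationError("mu must have one component per distress variable")
        if np.any(self.mu < 1) or np.any(self.mu > 7):
            raise ConfigurationError(f"mu components must lie in [1, 7] (person {self.person_id})")
        if np.any(self.sd_within < 0):
            raise ConfigurationError(f"sd_within must be >= 0 (person {self.person_id})")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigurationError(f"ar_coef must lie in [0, 1) (person {self.person_id})")
        for name in ("compliance_prob", "careless_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1] (person {self.person_id})")
        for cond, p in self.adoption_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"adoption_prob[{cond!r}] must lie in [0, 1]")
        if self.effect_delta < 0:
            raise ConfigurationError("effect_delta must be >= 0")
        if self.support_seek_shift < 0:
            raise ConfigurationError("support_seek_shift must be >= 0")


@dataclass
class GroundTruth:
    """Latent trajectories and realized intervention effects for one person."""

    person_id: str
    index: int
    day: np.ndarray  # (n_prompts,)
    slot: np.ndarray  # (n_prompts,)
    latent: np.ndarray  # (n_prompts, 4) latent distress
    latent_seek: np.ndarray  # (n_prompts,) latent support seeking
    spawn_key: tuple
    # one row per delivered intervention once effects were applied:
    # (day, slot, condition, adopted, effect_row) with effect_row = index of
    # the next completed same-day EMA that was shifted, or -1
    adoptions: list[tuple] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        data = {
            "person_id": self.person_id,
            "day": self.day,
            "slot": self.slot,
        }
        for k, var in enumerate(DISTRESS_VARS):
            data[f"latent_{var}"] = self.latent[:, k]
        data["latent_support_seeking"] = self.latent_seek
        return pd.DataFrame(data)


def generate_cohort(
    n_persons: int,
    population: PopulationConfig | None = None,
    seed: int = 0,
    effects: EffectsConfig | None = None,
) -> list[PersonParams]:
    """Draw ``n_persons`` parameter sets from the configured population.

    Identical ``(population, effects, seed)`` yields identical output.
    """
    if n_persons < 1:
        raise ConfigurationError("n_persons must be >= 1")
    pop = population or PopulationConfig()
    eff = effects or EffectsConfig()
    rng = child_rng(seed, COHORT_TAG)
    k = len(DISTRESS_VARS)

    mu = np.clip(rng.normal(pop.mu_mean, pop.mu_sd, size=(n_persons, k)), 1.0, 7.0)
    sd_within = np.clip(
        rng.normal(pop.sd_within_mean, pop.sd_within_sd, size=(n_persons, k)), 0.05, None
    )
    ar = np.clip(rng.normal(pop.ar_mean, pop.ar_sd, size=n_persons), 0.0, 0.95)
    a = pop.compliance_mean * pop.compliance_concentration
    b = (1.0 - pop.compliance_mean) * pop.compliance_concentration
    compliance = rng.beta(a, b, size=n_persons)
    if pop.careless_mean > 0:
        ca = pop.careless_mean * pop.careless_concentration
        cb = (1.0 - pop.careless_mean) * pop.careless_concentration
        careless = rng.beta(ca, cb, size=n_persons)
    else:
        careless = np.zeros(n_persons)
    seek_mu = np.clip(
        rng.normal(pop.support_seek_mu_mean, pop.support_seek_mu_sd, size=n_persons), 1.0, 7.0
    )

    width = max(3, len(str(n_persons)))
    cohort = []
    for i in range(n_persons):
        params = PersonParams(
            person_id=f"p{i + 1:0{width}d}",
            index=i,
            mu=mu[i],
            sd_within=sd_within[i],
            ar_coef=float(ar[i]),
            compliance_prob=float(compliance[i]),
            support_need_intercept=pop.support_need_intercept,
            support_need_slope=pop.support_need_slope,
            no_worries_threshold=pop.no_worries_threshold,
            careless_prob=float(careless[i]),
            adoption_prob=dict(eff.adoption_prob),
            effect_delta=eff.effect_delta,
            support_seek_shift=eff.support_seek_shift,
            support_seek_mu=float(seek_mu[i]),
            support_seek_sd=pop.support_seek_sd,
            timing_mu=dict(eff.timing_mu),
            timing_sd=eff.timing_sd,
            helpfulness_mu=dict(eff.helpfulness_mu),
            helpfulness_sd=eff.helpfulness_sd,
        )
        params.validate()
        cohort.append(params)
    return cohort


def generate_ema_stream(
    params: PersonParams, schedule: Schedule, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one person's full EMA stream (one row per scheduled prompt)."""
    schedule.validate()
    params.validate()
    spawn_key = (STREAM_TAG, params.index)
    rng = child_rng(seed, *spawn_key)

    n = schedule.n_prompts
    k = len(DISTRESS_VARS)
    day = np.repeat(np.arange(1, schedule.n_days + 1), schedule.slots_per_day)
    slot = np.tile(np.arange(1, schedule.slots_per_day + 1), schedule.n_days)

    # stationary AR(1) per variable, shared lag-1 coefficient within person
    dev = np.empty((n, k))
    dev[0] = rng.standard_normal(k) * params.sd_within
    innov_scale = params.sd_within * np.sqrt(1.0 - params.ar_coef**2)
    eps = rng.standard_normal((n - 1, k)) * innov_scale
    for t in range(1, n):
        dev[t] = params.ar_coef * dev[t - 1] + eps[t - 1]
    latent = params.mu + dev

    completed = rng.random(n) < params.compliance_prob

    latent_mean = latent.mean(axis=1)
    yes_prob = 1.0 / (
        1.0 + np.exp(-(params.support_need_intercept + params.support_need_slope * latent_mean))
    )
    u_need = rng.random(n)
    latent_seek = params.support_seek_mu + rng.standard_normal(n) * params.support_seek_sd
    shown = rng.random(n) < ATTENTION_SHOW_PROB
    careless = rng.random(n) < params.careless_prob
    # uniform over {1..7}\{5}: draw 1..6 then skip the target value
    careless_vals = rng.integers(1, 7, size=n)
    careless_vals = np.where(careless_vals >= ATTENTION_TARGET, careless_vals + 1, careless_vals)
    u_time = rng.random(n)

    items = discretize_likert(latent)
    support_need = np.where(
        latent_mean < params.no_worries_threshold,
        "no_worries",
        np.where(u_need < yes_prob, "yes", "would_not_help"),
    ).astype(object)
    seeking = discretize_likert(latent_seek)
    attention_value = np.where(careless, careless_vals, ATTENTION_TARGET).astype(float)

    start = datetime.fromisoformat(schedule.start_date)
    window_secs = schedule.window_hours * 3600
    offset_secs = (
        (day - 1) * 86400
        + (schedule.start_hour + (slot - 1) * schedule.window_hours) * 3600
        + np.floor(u_time * window_secs)
    ).astype(int)
    timestamps = [start + timedelta(seconds=int(s)) for s in offset_secs]

    frame = pd.DataFrame(
        {
            "person_id": params.person_id,
            "day": day,
            "slot": slot,
            "timestamp": pd.to_datetime(timestamps),
            "completed": completed,
        }
    )
    for j, var in enumerate(DISTRESS_VARS):
        frame[var] = np.where(completed, items[:, j], np.nan)
    frame["support_need"] = np.where(completed, support_need, None)
    frame["support_seeking"] = np.where(completed, seeking, np.nan)
    frame["attention_check_shown"] = shown & completed
    frame["attention_check_value"] = np.where(shown & completed, attention_value, np.nan)
    frame["appropriate_timing"] = np.nan
    frame["behavior_adoption"] = None

    truth = GroundTruth(
        person_id=params.person_id,
        index=params.index,
        day=day,
        slot=slot,
        latent=latent,
        latent_seek=latent_seek,
        spawn_key=(seed,) + spawn_key,
    )
    return frame, truth


def generate_cohort_streams(
    cohort: list[PersonParams], schedule: Schedule, seed: int
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Generate and concatenate the full cohort's streams.

    Each person's stream depends only on (seed, person index), so cohort
    subsets reproduce bit-identically.
    """
    frames, truths = [], {}
    for params in cohort:
        frame, truth = generate_ema_stream(params, schedule, seed)
        frames.append(frame)
        truths[params.person_id] = truth
    records = pd.concat(frames, ignore_index=True)
    return records, truths


def _deliveries_frame(trial_log) -> pd.DataFrame:
    decisions = trial_log.decisions if hasattr(trial_log, "decisions") else trial_log
    return decisions.loc[decisions["delivered"]]


def apply_intervention_effects(
    records: pd.DataFrame,
    trial_log,
    cohort: list[PersonParams],
    truths: dict[str, GroundTruth],
    seed: int,
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Inject post-delivery effects and attach post-intervention items.

    For each delivered intervention: adoption is drawn with the assigned
    condition's ``adoption_prob``; the post-intervention items (appropriate
    timing on 1-7, behaviour adoption yes/no) are attached to the next
    completed EMA regardless of missed prompts in between; and when support
    was sought, the next completed *same-day* EMA's latent distress is reduced
    by ``effect_delta`` and its latent support seeking raised by
    ``support_seek_shift`` before re-discretization.

    Returns an updated copy of ``records`` and the ground truths augmented
    with realized adoptions.  A delivery referencing a prompt that does not
    exist in ``records`` raises :class:`ConsistencyError`.
    """
    out = records.copy()
    params_by_id = {p.person_id: p for p in cohort}
    deliveries = _deliveries_frame(trial_log)

    col = {name: out.columns.get_loc(name) for name in out.columns}
    for person_id, dels in deliveries.groupby("person_id", sort=False):
        if person_id not in params_by_id:
            raise ConsistencyError(f"delivery references unknown person {person_id!r}")
        params = params_by_id[person_id]
        truth = truths[person_id]
        rng = child_rng(seed, EFFECTS_TAG, params.index)

        sub = out.index[out["person_id"] == person_id]
        sub_day = out.loc[sub, "day"].to_numpy()
        sub_slot = out.loc[sub, "slot"].to_numpy()
        sub_completed = out.loc[sub, "completed"].to_numpy(dtype=bool)
        pos_of = {(int(d), int(s)): i for i, (d, s) in enumerate(zip(sub_day, sub_slot))}
        completed_pos = np.flatnonzero(sub_completed)

        for row in dels.sort_values(["day", "slot"]).itertuples(index=False):
            key = (int(row.day), int(row.slot))
            if key not in pos_of:
                raise ConsistencyError(
                    f"delivery references nonexistent prompt {key} for {person_id!r}"
                )
            p = pos_of[key]
            later = completed_pos[completed_pos > p]
            adopted = bool(rng.random() < params.adoption_prob[row.assigned_condition])
            timing_latent = rng.normal(params.timing_mu[row.assigned_condition], params.timing_sd)
            if later.size == 0:
                truth.adoptions.append((key[0], key[1], row.assigned_condition, adopted, -1))
                continue
            q = int(later[0])
            ridx = sub[q]
            out.iat[out.index.get_loc(ridx), col["appropriate_timing"]] = float(
                discretize_likert(timing_latent)
            )
            out.iat[out.index.get_loc(ridx), col["behavior_adoption"]] = (
                "yes" if adopted else "no"
            )
            effect_row = -1
            if adopted and sub_day[q] == sub_day[p]:
                truth.latent[q] = truth.latent[q] - params.effect_delta
                truth.latent_seek[q] = truth.latent_seek[q] + params.support_seek_shift
                new_items = discretize_likert(truth.latent[q])
                for j, var in enumerate(DISTRESS_VARS):
                    out.iat[out.index.get_loc(ridx), col[var]] = new_items[j]
                out.iat[out.index.get_loc(ridx), col["support_seeking"]] = float(
                    discretize_likert(truth.latent_seek[q])
                )
                effect_row = q
            truth.adoptions.append((key[0], key[1], row.assigned_condition, adopted, effect_row))
    return out, truths


def generate_evening_helpfulness(
    trial_log, cohort: list[PersonParams], seed: int
) -> pd.DataFrame:
    """Evening helpfulness ratings for person-days with at least one delivery.

    The rating is generated around the helpfulness mean of the day's first
    delivered condition.  ``n_deliveries`` is carried so downstream analyses
    can restrict to single-delivery days.
    """
    params_by_id = {p.person_id: p for p in cohort}
    deliveries = _deliveries_frame(trial_log)
    rows = []
    for person_id, dels in deliveries.groupby("person_id", sort=False):
        params = params_by_id[person_id]
        rng = child_rng(seed, EVENING_TAG, params.index)
        for day, day_dels in dels.sort_values(["day", "slot"]).groupby("day", sort=True):
            cond = day_dels.iloc[0]["assigned_condition"]
            value = float(discretize_likert(rng.normal(params.helpfulness_mu[cond], params.helpfulness_sd)))
            rows.append(
                {
                    "person_id": person_id,
                    "day": int(day),
                    "n_deliveries": int(len(day_dels)),
                    "condition": cond,
                    "helpfulness": value,
                }
            )
    return pd.DataFrame(
        rows, columns=["person_id", "day", "n_deliveries", "condition", "helpfulness"]
    )


def ground_truth_frame(truths: dict[str, GroundTruth]) -> pd.DataFrame:
    """Cohort-level ground-truth table keyed by (person_id, day, slot)."""
    return pd.concat([t.frame() for t in truths.values()], ignore_index=True)
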