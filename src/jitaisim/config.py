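"""Run configuration for the simulated micro-randomized trial.

A single :class:`RunConfig` drives the whole pipeline: cohort population
distributions, the EMA schedule, trigger-engine settings, injected
intervention effects, and analysis conventions.  Configs load from a YAML
file with nested sections and serialize back losslessly; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError

#: Canonical order of the four momentary-distress items (1-7 Likert each).
DISTRESS_VARS = ("negative_affect", "stress", "loneliness", "rumination")

#: Trigger conditions that can actually deliver an intervention.
ACTIVE_CONDITIONS = ("fixed_cutoff", "spc", "support_need")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PopulationConfig(_Section):
    """Population distributions the per-person generative parameters are drawn from.

    Location/scale values are calibrated to a psychotherapy-waitlist EMA cohort:
    moderate average distress with marked between-person heterogeneity, high but
    imperfect compliance (mean ~0.85), and a rare careless-responding rate
    (~1.5% of attention checks).
    """

    mu_mean: float = Field(3.0, ge=1.0, le=7.0)
    mu_sd: float = Field(0.8, ge=0.0)
    sd_within_mean: float = Field(1.2, gt=0.0)
    sd_within_sd: float = Field(0.25, ge=0.0)
    ar_mean: float = Field(0.4, ge=0.0, lt=1.0)
    ar_sd: float = Field(0.15, ge=0.0)
    compliance_mean: float = Field(0.85, gt=0.0, lt=1.0)
    # Beta concentration (a+b); 3.83 reproduces a between-person SD of ~0.16
    compliance_concentration: float = Field(3.83, gt=0.0)
    careless_mean: float = Field(0.015, ge=0.0, lt=1.0)
    careless_concentration: float = Field(30.0, gt=0.0)
    support_need_intercept: float = -5.0
    support_need_slope: float = Field(1.0, ge=0.0)
    no_worries_threshold: float = 2.0
    support_seek_mu_mean: float = Field(2.7, ge=1.0, le=7.0)
    support_seek_mu_sd: float = Field(0.6, ge=0.0)
    support_seek_sd: float = Field(2.2, gt=0.0)


class ScheduleConfig(_Section):
    """Six two-hour prompt windows per day between 08:00 and 20:00, 21 days."""

    n_days: int = Field(21, ge=1)
    slots_per_day: int = Field(6, ge=1)
    start_hour: int = Field(8, ge=0, le=23)
    window_hours: int = Field(2, ge=1)
    start_date: str = "2024-01-01"

    @model_validator(mode="after")
    def _windows_fit_in_day(self) -> "ScheduleConfig":
        if self.start_hour + self.slots_per_day * self.window_hours > 24:
            raise ValueError(
                "schedule windows must be disjoint and fall within one calendar day"
            )
        return self


class TriggerConfig(_Section):
    """Micro-randomization and decision-rule settings.

    ``probs`` are the per-EMA randomization probabilities over
    (fixed_cutoff, spc, support_need, no_intervention).  ``cutoff`` is the
    non-strict disjunctive threshold for the fixed rule; ``L`` the control-limit
    multiplier; the chart learns through ``baseline_end_day`` and freezes after.
    """

    probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cutoff: int = Field(5, ge=1, le=7)
    L: float = Field(2.0, ge=0.0)
    baseline_end_day: int = Field(7, ge=1)
    min_baseline_obs: int = Field(7, ge=2)
    intervention_start_day: int = Field(4, ge=1)
    max_per_day: int = Field(2, ge=0)
    # keep phase-1 observations recorded after a delivered intervention
    include_post_delivery_baseline: bool = True

    @model_validator(mode="after")
    def _probs_valid(self) -> "TriggerConfig":
        if any(p < 0 for p in self.probs):
            raise ValueError("probs must be non-negative")
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"probs must sum to 1 (got {sum(self.probs)!r})")
        return self


class EffectsConfig(_Section):
    """Injectable intervention effects and post-intervention item models.

    ``adoption_prob`` gives, per triggering condition, the probability the
    participant actually seeks support after a delivered intervention.
    ``effect_delta`` is subtracted from the next same-day EMA's latent distress
    when support was sought; ``support_seek_shift`` is added to the latent
    support-seeking item at the same point.  Timing/helpfulness means are
    per-condition 1-7 Likert locations.
    """

    adoption_prob: dict[str, float] = Field(
        default_factory=lambda: {"fixed_cutoff": 0.23, "spc": 0.22, "support_need": 0.43}
    )
    effect_delta: float = Field(0.6, ge=0.0)
    support_seek_shift: float = Field(2.1, ge=0.0)
    timing_mu: dict[str, float] = Field(
        default_factory=lambda: {"fixed_cutoff": 3.0, "spc": 2.3, "support_need": 4.4}
    )
    timing_sd: float = Field(1.8, ge=0.0)
    helpfulness_mu: dict[str, float] = Field(
        default_factory=lambda: {"fixed_cutoff": 3.5, "spc": 3.6, "support_need": 4.65}
    )
    helpfulness_sd: float = Field(1.8, ge=0.0)

    @model_validator(mode="after")
    def _condition_keys(self) -> "EffectsConfig":
        for name in ("adoption_prob", "timing_mu", "helpfulness_mu"):
            mapping: Mapping[str, float] = getattr(self, name)
            if set(mapping) != set(ACTIVE_CONDITIONS):
                raise ValueError(
                    f"{name} must have exactly the keys {ACTIVE_CONDITIONS}"
                )
        for cond, p in self.adoption_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"adoption_prob[{cond!r}] must lie in [0, 1]")
        return self


class AnalysisConfig(_Section):
    compliance_threshold: float = Field(0.70, gt=0.0, le=1.0)
    feasibility_share: float = Field(0.70, gt=0.0, le=1.0)
    careless_threshold: float = Field(0.05, gt=0.0, le=1.0)
    round_decimals: int = Field(2, ge=0)


class RunConfig(_Section):
    """Top-level configuration: one object describes one reproducible run."""

    n_persons: int = Field(25, ge=1)
    seed: int = Field(0, ge=0)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    trigger: TriggerConfig = Field(default_factory=TriggerConfig)
    effects: EffectsConfig = Field(default_factory=EffectsConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")

    def config_hash(self) -> str:
        """Stable sha256 over the canonical JSON form, for provenance stamps."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty or absent file yields the full defaults (25 persons, 21 days,
    6 slots, cutoff 5, L=2, cap 2).  Unknown keys and invariant violations
    raise :class:`ConfigurationError` naming the offending field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(loaded)}")
        data = loaded
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(f"invalid config at {loc}: {first['msg']}") from exc
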