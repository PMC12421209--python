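"""Shewhart individuals control charts with moving-range sigma estimation.

Each person gets one univariate chart per distress variable.  The chart is
fitted in a classical two-phase design: during phase 1 (days 1 through
``baseline_end_day``) natural variability is estimated from the moving range

    MR_j = |x_j - x_{j-1}|

over successive completed observations, the process SD is estimated as
``sigma_hat = mean(MR) / d2`` with the unbiasing constant ``d2 = 1.128`` for
subgroups of size two, and the personalized upper control limit is

    UCL = phase1_mean + L * sigma_hat.

Before the end of phase 1 the chart is re-fitted from a growing window of all
completed observations so far; after phase 1 it freezes.  An observation
signals (strictly) above the UCL; there is no lower limit because only
elevated distress is of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

#: Mean-range unbiasing constant for subgroups of size 2 (successive pairs).
D2_PAIR = 1.128


def exact_d2_pair() -> float:
    """Expected range of two independent standard-normal variates, 2/sqrt(pi).

    Rounds to the conventional tabulated value ``1.128`` at 3 decimals.
    """
    return 2.0 / math.sqrt(math.pi)


def false_alarm_rate(L: float) -> float:
    """One-sided Gaussian tail probability beyond ``L`` sigma.

    For an in-control Gaussian process monitored against a UCL at
    ``mean + L*sigma`` this is the per-observation type-I signal rate
    (0.02275 at L=2).
    """
    from scipy.stats import norm

    return float(norm.sf(L))


@dataclass
class MovingRangeSeries:
    """Ordered completed observations for one (person, variable) and their MRs."""

    observations: np.ndarray
    moving_ranges: np.ndarray
    person_id: str | None = None
    variable: str | None = None
    positions: list[tuple[int, int]] | None = None  # (day, slot) per observation

    @property
    def insufficient(self) -> bool:
        """True when fewer than two observations exist (no moving range)."""
        return self.moving_ranges.size == 0


def moving_ranges(
    observations,
    person_id: str | None = None,
    variable: str | None = None,
    positions: list[tuple[int, int]] | None = None,
) -> MovingRangeSeries:
    """Absolute differences between successive completed observations.

    Gaps from missed prompts or overnight breaks are ignored: the moving range
    is always taken between consecutive *completed* values in (day, slot)
    order.  With fewer than two observations the series is empty and flagged
    insufficient.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 1:
        raise ValueError("observations must be one-dimensional")
    mr = np.abs(np.diff(obs))
    return MovingRangeSeries(
        observations=obs,
        moving_ranges=mr,
        person_id=person_id,
        variable=variable,
        positions=positions,
    )


def estimate_sigma(series: MovingRangeSeries | np.ndarray) -> float:
    """Moving-range estimate of the process SD: mean(MR) / d2.

    Unlike the ordinary sample SD this is a *dynamic* measure built from
    changes between subsequent observations, so slow level shifts inflate it
    less than raw spread would.
    """
    mr = series.moving_ranges if isinstance(series, MovingRangeSeries) else np.asarray(series, float)
    if mr.size == 0:
        raise InsufficientDataError("at least one moving range is required to estimate sigma")
    return float(np.mean(mr) / D2_PAIR)


@dataclass
class ControlChart:
    """Fitted individuals chart for one (person, variable).

    ``ucl`` is always recomputable as ``phase1_mean + L * sigma_hat`` and
    ``sigma_hat`` as ``mr_mean / d2_constant``; the components are stored so
    exported chart tables are auditable.
    """

    phase1_mean: float
    mr_mean: float
    sigma_hat: float
    L: float
    ucl: float
    n_baseline: int
    frozen: bool = False
    person_id: str | None = None
    variable: str | None = None
    d2_constant: float = field(default=D2_PAIR)

    def exceeds(self, values) -> np.ndarray | bool:
        """Strict exceedance of the UCL (vectorized); ties do not signal."""
        result = np.asarray(values, dtype=float) > self.ucl
        return bool(result) if result.ndim == 0 else result


def chart_from_values(
    values,
    L: float = 2.0,
    *,
    frozen: bool = False,
    person_id: str | None = None,
    variable: str | None = None,
) -> ControlChart:
    """Fit a chart directly from an ordered array of completed observations."""
    obs = np.asarray(values, dtype=float)
    if obs.size < 2:
        raise InsufficientDataError(
            f"need >=2 completed baseline observations to fit a chart, got {obs.size}"
        )
    series = moving_ranges(obs)
    mr_mean = float(np.mean(series.moving_ranges))
    sigma_hat = mr_mean / D2_PAIR
    phase1_mean = float(np.mean(obs))
    return ControlChart(
        phase1_mean=phase1_mean,
        mr_mean=mr_mean,
        sigma_hat=sigma_hat,
        L=float(L),
        ucl=phase1_mean + float(L) * sigma_hat,
        n_baseline=int(obs.size),
        frozen=frozen,
        person_id=person_id,
        variable=variable,
    )


def fit_chart(
    records: pd.DataFrame,
    variable: str,
    L: float = 2.0,
    baseline_end_day: int = 7,
    as_of: tuple[int, int] | None = None,
) -> ControlChart:
    """Fit the two-phase chart for one person from long-format EMA records.

    Uses all completed observations of ``variable`` from day 1 up to the
    earlier of ``as_of`` (inclusive, in (day, slot) order) and the end of
    ``baseline_end_day``.  Before the freeze this is a growing window; once
    ``as_of`` lies beyond ``baseline_end_day`` the full phase-1 window is used
    and the chart is marked frozen.

    ``records`` must hold a single person's rows sorted by (day, slot), with
    ``day``, ``slot``, ``completed`` and the variable column.
    """
    if "person_id" in records and records["person_id"].nunique() > 1:
        raise ValueError("fit_chart expects records for a single person")
    day = records["day"].to_numpy()
    slot = records["slot"].to_numpy()
    completed = records["completed"].to_numpy(dtype=bool)
    vals = records[variable].to_numpy(dtype=float)

    mask = completed & (day <= baseline_end_day)
    frozen = False
    if as_of is not None:
        a_day, a_slot = as_of
        mask &= (day < a_day) | ((day == a_day) & (slot <= a_slot))
        frozen = a_day > baseline_end_day
    else:
        frozen = True
    obs = vals[mask]
    person_id = records["person_id"].iloc[0] if "person_id" in records else None
    return chart_from_values(
        obs, L=L, frozen=frozen, person_id=person_id, variable=variable
    )


def exceeds_ucl(chart: ControlChart, value: float) -> bool:
    """True iff ``value`` lies strictly above the chart's UCL."""
    return bool(float(value) > chart.ucl)


def charts_to_frame(charts) -> pd.DataFrame:
    """Audit table of fitted charts, one row per (person, variable)."""
    rows = [
        {
            "person_id": c.person_id,
            "variable": c.variable,
            "phase1_mean": c.phase1_mean,
            "mr_mean": c.mr_mean,
            "sigma_hat": c.sigma_hat,
            "L": c.L,
            "ucl": c.ucl,
            "n_baseline": c.n_baseline,
            "frozen": c.frozen,
        }
        for c in charts
    ]
    return pd.DataFrame(rows)
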