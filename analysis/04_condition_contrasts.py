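#!/usr/bin/env python
"""Aim-2 and aim-3 contrasts of the simulated trial.

Welch t tests with Cohen d comparing the three triggering strategies on
appropriate timing, helpfulness (single-delivery days) and behaviour
adoption, and delivered vs omitted-control decision points on subsequent
support seeking and T -> T+1 distress change scores.
"""

from pathlib import Path

import pandas as pd

import jitaisim as js
from jitaisim.analysis import comparisons_frame, condition_outcome_contrasts
from jitaisim.config import DISTRESS_VARS
from jitaisim.pipeline import read_ema_csv, read_trial_log

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_ema_csv(OUT / "ema.csv")
    log = read_trial_log(OUT / "trial_log.csv")
    helpfulness = pd.read_csv(OUT / "helpfulness.csv")

    results = []
    for outcome in ("appropriate_timing", "behavior_adoption"):
        for res in condition_outcome_contrasts(records, log, outcome):
            results.append((outcome, res))
    for res in condition_outcome_contrasts(records, log, "helpfulness", helpfulness):
        results.append(("helpfulness", res))
    for res in condition_outcome_contrasts(records, log, "support_seeking"):
        results.append(("support_seeking", res))
    for var in DISTRESS_VARS:
        for res in condition_outcome_contrasts(records, log, var):
            results.append((f"delta_{var}", res))

    table = comparisons_frame(results)
    table.to_csv(OUT / "contrasts.csv", index=False)

    print("Welch contrasts (positive d favours the first group):")
    for row in table.itertuples(index=False):
        if row.estimable:
            print(f"  {row.outcome:<22} {row.group_a} vs {row.group_b}: "
                  f"d={row.cohen_d:+.2f}, t({row.df:.1f})={row.t:+.2f}, p={row.p:.3f}")
        else:
            print(f"  {row.outcome:<22} {row.group_a} vs {row.group_b}: "
                  f"not estimable ({row.reason})")

    scores = js.change_scores(records, log)
    print(f"\nchange-score pairs (same day): {scores.n_pairs}; "
          f"overnight lags excluded: {scores.n_dropped_overnight}")


if __name__ == "__main__":
    main()
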