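#!/usr/bin/env python
"""Aim-1 feasibility summaries of the simulated trial.

Computes EMA compliance against the double-70% rule, the careless-responding
rate from attention checks, and grand-mean / between-person / within-person
descriptive decompositions of the distress and support-seeking items.
"""

from pathlib import Path

import pandas as pd

import jitaisim as js
from jitaisim.config import DISTRESS_VARS
from jitaisim.pipeline import read_ema_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_ema_csv(OUT / "ema.csv")

    comp = js.compliance_summary(records)
    comp.per_person.to_csv(OUT / "compliance.csv", index=False)
    print(f"compliance: {comp.n_completed}/{comp.n_scheduled} "
          f"({100 * comp.mean_rate:.2f}%, between-person SD {100 * comp.sd_rate:.2f}%)")
    print(f"persons at >= {100 * comp.person_threshold:.0f}%: "
          f"{100 * comp.share_meeting_threshold:.0f}% -> feasible: {comp.feasible}")

    care = js.careless_rate(records)
    print(f"careless responses: {care.n_careless}/{care.n_shown} "
          f"({100 * care.rate:.1f}%) -> high quality: {care.high_quality}")

    rows = []
    for item in list(DISTRESS_VARS) + ["support_seeking"]:
        d = js.descriptives(records, item)
        rows.append({
            "item": item, "n_obs": d.n_obs, "grand_mean": round(d.grand_mean, 2),
            "between_sd": round(d.between_sd, 2), "mean_within_sd": round(d.mean_within_sd, 2),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "descriptives.csv", index=False)
    print("\nitem descriptives (grand mean, between-person SD, mean within-person SD):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
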