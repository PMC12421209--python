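#!/usr/bin/env python
"""Run the micro-randomized trigger engine over the simulated streams.

Randomizes every intervention-phase EMA into one of the four conditions,
evaluates the fixed-cutoff / control-chart / support-need rules, applies the
two-per-day delivery cap, injects the post-delivery effects into the streams,
and reports the trigger accounting (total delivered, per-condition split,
cap suppressions, omitted controls).
"""

import json
from pathlib import Path

import pandas as pd

import jitaisim as js
from jitaisim.charts import charts_to_frame
from jitaisim.pipeline import params_from_frame, read_ema_csv, truths_from_frame, write_ema_csv

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = js.load_config(OUT / "config.yaml")
    records = read_ema_csv(OUT / "ema_raw.csv")
    cohort = params_from_frame(pd.read_csv(OUT / "cohort_params.csv"))
    truths = truths_from_frame(pd.read_csv(OUT / "ground_truth.csv"))

    log = js.run_trial(records, cfg.trigger, cfg.seed)
    records, truths = js.apply_intervention_effects(records, log, cohort, truths, cfg.seed)
    helpfulness = js.generate_evening_helpfulness(log, cohort, cfg.seed)

    write_ema_csv(records, OUT / "ema.csv")
    log.decisions.to_csv(OUT / "trial_log.csv", index=False)
    charts_to_frame(log.final_charts).to_csv(OUT / "charts.csv", index=False)
    helpfulness.to_csv(OUT / "helpfulness.csv", index=False)
    summary = log.summary()
    (OUT / "trigger_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    by = summary["delivered_by_condition"]
    print(f"delivered {summary['total_delivered']} interventions "
          f"(fixed_cutoff {by['fixed_cutoff']}, spc {by['spc']}, "
          f"support_need {by['support_need']})")
    print(f"per-condition counts sum to total: {summary['accounting_identity_holds']}")
    print(f"daily-cap suppressions: {summary['cap_suppressions']}; "
          f"omitted controls: {summary['omitted_controls']}")


if __name__ == "__main__":
    main()
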