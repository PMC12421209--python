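#!/usr/bin/env python
"""Simulate the study-scale synthetic EMA cohort.

Generates 25 persons x 21 days x 6 daily prompts of raw (pre-intervention)
EMA streams and writes them, the generative person parameters, and the
latent ground truth under results/.
"""

from pathlib import Path

import jitaisim as js
from jitaisim.pipeline import params_to_frame, write_ema_csv
from jitaisim.synthetic import ground_truth_frame

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = js.RunConfig(seed=SEED)
    cohort = js.generate_cohort(cfg.n_persons, cfg.population, cfg.seed, cfg.effects)
    schedule = js.Schedule.from_config(cfg.schedule, cfg.trigger.intervention_start_day)
    records, truths = js.generate_cohort_streams(cohort, schedule, cfg.seed)

    write_ema_csv(records, OUT / "ema_raw.csv")
    params_to_frame(cohort).to_csv(OUT / "cohort_params.csv", index=False)
    ground_truth_frame(truths).to_csv(OUT / "ground_truth.csv", index=False)
    cfg.save(OUT / "config.yaml")

    completed = int(records["completed"].sum())
    print(f"simulated {cfg.n_persons} persons, {len(records)} scheduled prompts")
    print(f"completed {completed}/{len(records)} ({100 * completed / len(records):.2f}%)")
    print(f"wrote ema_raw.csv, cohort_params.csv, ground_truth.csv to {OUT}")


if __name__ == "__main__":
    main()
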