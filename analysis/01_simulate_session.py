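#!/usr/bin/env python
"""Generate the standard synthetic eyepuff session and report its contents.

Writes the event schedule, the ground-truth record, and a unit census under
results/session/.  Everything downstream (scripts 02-08) regenerates this
session deterministically from the same seed.
"""

from pathlib import Path

import pandas as pd

from affectdyn import synth

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "session"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = synth.make_event_schedule(n_trials_pre=6, n_trials_post=6,
                                         n_trials_recovery=4, seed=SEED)
    truth = synth.default_ground_truth(seed=SEED)
    schedule.write_csv(OUT / "events.csv")
    truth.to_json(OUT / "ground_truth.json")
    census = truth.units.groupby("archetype").size().rename("n_units")
    census.to_csv(OUT / "unit_census.csv")

    n_trials = len(set(schedule.trial))
    print(f"session: {len(schedule)} puff events in {n_trials} trials "
          f"({dict(pd.Series(schedule.condition).value_counts())})")
    print(f"population: {len(truth.units)} units across "
          f"{truth.units['region'].nunique()} regions")
    print(census.to_string())
    print(f"planted: {len(truth.planted_factors)} evoked factors, "
          f"{len(truth.planted_oscillations)} condition-gated oscillations, "
          f"{len(truth.coupled_pairs)} phase-coupled channel pairs")
    print(f"tau_persist by condition: {dict(truth.model_params.tau_persist)}")


if __name__ == "__main__":
    main()
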