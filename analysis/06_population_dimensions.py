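#!/usr/bin/env python
"""Single-unit population analyses: modulation screen, peri-puff response
clustering, regional composition, rise/decay timing, and the emotion-like
neural dimension.

Finding on the standard session: the screen keeps the responsive units,
clustering separates the planted archetypes, drug shortens decay (not rise)
times, and the emotion-like dimension concentrates its weight on the
planted persistent units.  Writes results/spiking/.
"""

from pathlib import Path

import numpy as np

from affectdyn import dimensions, spiking, synth
from affectdyn.core import PopulationActivity

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "spiking"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = synth.make_event_schedule(n_trials_pre=6, n_trials_post=6,
                                         n_trials_recovery=4, seed=SEED)
    truth = synth.default_ground_truth(seed=SEED)
    act = synth.simulate_population(schedule, truth, noise_sd=1.0)

    modulated = spiking.significant_modulation(act, schedule)
    print(f"modulation screen: {modulated.sum()}/{act.n_sites} units flagged")
    sub = PopulationActivity(act.rates[modulated], act.bin_width,
                             act.sites.loc[modulated].reset_index(drop=True),
                             act.t_start)

    times, traces = spiking.peri_puff_means(sub, schedule)
    labels, means = spiking.cluster_responses(traces, times, seed=SEED)
    print(f"response clustering: {len(means)} clusters "
          f"(sizes {np.bincount(labels).tolist()}), ordered by decay time")

    composition = spiking.cluster_region_composition(
        labels, sub.sites["region"].to_numpy())
    composition.to_csv(OUT / "cluster_region_composition.csv", index=False)
    n_flagged = int(composition["flagged"].sum())
    print(f"regional composition: {n_flagged} (region, cluster) cells deviate "
          "from the equal-probability null after BH")

    rows = []
    for cond in ("pre", "drug"):
        timing = spiking.rise_decay_times(sub, schedule, labels, n_boot=200,
                                          conditions=(cond,), seed=SEED)
        timing["condition"] = cond
        rows.append(timing)
    import pandas as pd
    timing = pd.concat(rows, ignore_index=True)
    timing.to_csv(OUT / "rise_decay_times.csv", index=False)
    piv = timing.pivot_table(index="region", columns="condition",
                             values=["rise_s", "decay_s"])
    print("\nregional rise/decay (s):")
    print(piv.round(3).to_string())

    emo = dimensions.emotion_dimension(act, schedule, include=modulated)
    emo.to_frame().to_csv(OUT / "emotion_dimension.csv", index=False)
    persistent = truth.units["archetype"].isin(
        ["fast_persistent", "delayed_persistent"]).to_numpy()
    top = np.argsort(-np.abs(emo.weights))[:max(int(0.1 * act.n_sites), 1)]
    overlap = np.isin(np.nonzero(persistent)[0], top).mean()
    print(f"\nemotion-like dimension: top-decile |weights| recover "
          f"{overlap:.0%} of the planted persistent units")


if __name__ == "__main__":
    main()
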