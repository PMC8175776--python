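#!/usr/bin/env python
"""Telemetry-cohort demonstration: band-specific EEG power changes.

Simulates 9 daily 5-min resting EEG segments for a 2x2 cohort in which the
knockout carries 1.5x gamma and 1.3x delta power and the drug lowers delta
by 20% in both genotypes, computes per-epoch band power (10 s epochs,
artifact screen), aggregates to the across-day average, and fits two-way
ANOVAs on absolute and relative gamma and delta power.
"""

from pathlib import Path

import pandas as pd

from fxephys import (anova_two_way, aggregate_power, simulate_eeg_cohort,
                     write_table)
from fxephys.spectral import bandpower_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

n = {(g, t): 4 for g in ("WT", "KO") for t in ("VEH", "1BAER")}
frames = []
for rec, _gt in simulate_eeg_cohort(
        n_per_group=n, days=9,
        genotype_band_multipliers={"KO": {"gamma": 1.5, "delta": 1.3}},
        treatment_band_multipliers={"1BAER": {"delta": 0.8}},
        seed=202):
    frames.append(bandpower_table(rec))
per_epoch = pd.concat(frames, ignore_index=True)
agg = aggregate_power(per_epoch)
write_table(agg, OUT / "eeg_9day_average.csv")

stat_rows = []
for response in ("gamma", "delta", "gamma_rel", "delta_rel"):
    for r in anova_two_way(agg, response=response):
        stat_rows.append({"band": response, "effect": r.comparison,
                          "F": r.statistic, "p": r.p_raw})
stats = pd.DataFrame(stat_rows)
write_table(stats, OUT / "eeg_anova.csv")

print("group-mean absolute gamma and delta power (a.u.^2), 9-day average:")
print(agg.groupby(["genotype", "treatment"])[["gamma", "delta"]]
      .mean().round(4).to_string())
for band in ("gamma", "delta"):
    sub = stats[stats.band == band].set_index("effect")
    print(f"\n{band}: p(genotype) = {sub.loc['genotype', 'p']:.2g}, "
          f"p(treatment) = {sub.loc['treatment', 'p']:.2g}")
print("-> the genotype gamma elevation and the treatment delta reduction "
      "are recovered on the across-day averages.")
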