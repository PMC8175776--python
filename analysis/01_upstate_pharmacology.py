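#!/usr/bin/env python
"""Slice-cohort demonstration: prolonged UP states and their rescue.

Simulates a 2x2 cohort of extracellular slice recordings (WT/KO x
vehicle/low-dose drug) in which the knockout carries 1.8x longer UP states
and the drug shortens them by 25%, runs threshold detection (5 Hz envelope
cutoff, 4 x RMS threshold, 200 ms / 600 ms rules) and the factorial ANOVA
on the per-slice summaries.  Writes events, summaries and the ANOVA table
under results/.
"""

from pathlib import Path

import pandas as pd

from fxephys import (DetectionParams, UpStateSimParams, anova_two_way,
                     detect_upstates, preprocess_envelope,
                     simulate_upstate_cohort, summarize_upstates, write_table)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

detection = DetectionParams(lowpass_cutoff_hz=5.0)
base = UpStateSimParams(duration_s=300.0)

rows = []
for rec, _gt in simulate_upstate_cohort(
        n_per_group=6, ko_duration_multiplier=1.8, base=base,
        treatments=("VEH", "1BAER"),
        treatment_duration_multipliers={"1BAER": 0.75}, seed=101):
    env = preprocess_envelope(rec, detection)
    s = summarize_upstates(detect_upstates(env, detection), rec.duration_s)
    rows.append({"animal_id": rec.meta["animal_id"],
                 "genotype": rec.meta["genotype"],
                 "treatment": rec.meta["treatment"],
                 "n_events": s.n_events, "mean_duration_s": s.mean_duration_s,
                 "mean_amplitude": s.mean_amplitude,
                 "freq_per_min": s.freq_per_min})
summary = pd.DataFrame(rows)
write_table(summary, OUT / "upstate_summary.csv")

stat_rows = []
for measure in ("mean_duration_s", "mean_amplitude", "freq_per_min"):
    for r in anova_two_way(summary, response=measure):
        stat_rows.append({"measure": measure, "effect": r.comparison,
                          "F": r.statistic, "df1": r.df[0], "df2": r.df[1],
                          "p": r.p_raw})
stats = pd.DataFrame(stat_rows)
write_table(stats, OUT / "upstate_anova.csv")

group_means = summary.groupby(["genotype", "treatment"])["mean_duration_s"].mean()
print("mean UP-state duration by group (s):")
print(group_means.round(3).to_string())
dur = stats[stats.measure == "mean_duration_s"].set_index("effect")
print(f"\n2-way ANOVA on duration: p(genotype) = {dur.loc['genotype', 'p']:.2g}, "
      f"p(treatment) = {dur.loc['treatment', 'p']:.2g}, "
      f"p(interaction) = {dur.loc['genotype:treatment', 'p']:.2g}")
print("-> the simulated KO prolongation and its partial drug rescue are "
      "both recovered by the detection + ANOVA path.")
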