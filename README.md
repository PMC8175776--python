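# fxephys

Analysis pipeline for preclinical Fragile X (Fmr1 knockout mouse)
electrophysiology and behavior: threshold-based UP-state detection on
extracellular slice recordings, epoch-FFT EEG band-power analysis, ordinal
audiogenic-seizure scoring, novel-object discrimination-index scoring, and
the exact nonparametric / factorial statistics used to compare
genotype × treatment groups — together with seeded synthetic-data
generators that stand in for animal recordings, so every analysis path is
testable against known ground truth.

It is written for neurophysiologists who have single-channel recordings
(EDF or plain numeric text) and tidy behavioral tables, and want the
classic slice/telemetry analysis chain as a reproducible, scriptable
pipeline rather than interactive vendor software.

## What it computes

**UP-state detection.** The raw multi-unit trace (2.5 kHz slice
recordings) is offset to zero mean, rectified and low-pass filtered
(zero-phase 4th-order Butterworth) into an activity envelope *e(t)*. With
σ̂ the robustly estimated RMS of the envelope's noise floor, the threshold
is 4σ̂; a candidate event must stay above threshold ≥ 200 ms, runs
separated by ≤ 600 ms belong to one event, and an event ends only after
the envelope stays below threshold > 600 ms. Per-slice outputs are event
count, mean duration, mean amplitude and frequency (events/min).

**EEG band power.** Cortical EEG (500 Hz telemetry) is cut into 10 s
epochs, screened for high-amplitude artifacts, and each epoch is
Fourier-transformed (Parseval-scaled periodogram). Absolute power is
summed per band — δ [0.5,4), θ [4,8), α [8,12), Σ [12,16), β [16,24),
γ [24,80) Hz — and relative power is each band's share of the six-band
total. Epochs are averaged within (animal, day), then across the 9
treatment days.

**Behavioral endpoints.** Audiogenic seizure severity is ordinal 0–4 (no
response, wild running, clonic, tonic, death), taking each animal's most
severe second-tone response; the novel-object discrimination index is
DI = (t_novel − t_familiar)/(t_novel + t_familiar); time-resolved measures
reduce to per-interval/per-block summaries plus a collapsed value.

**Statistics.** Exact Wilcoxon rank-sum (midranks; two-sided p as the
permutation-null probability of |W − E[W]| at least the observed
deviation; complete enumeration when C(n+m, n) ≤ 2×10⁶, seeded
Monte-Carlo otherwise), tie-corrected Kruskal–Wallis, two-way factorial
ANOVA with interaction (Type III sums of squares), and Benjamini–Hochberg
FDR adjustment across pairwise comparisons.

## Worked example

Simulate a slice recording with embedded UP states and detect them:

```sh
fxephys simulate-lfp --out lfp.txt --seed 3 --duration 120 --rate 1000
fxephys detect-upstates --input lfp.txt --rate 1000 --cutoff 5.0 \
    --out events.csv --summary summary.csv
```

prints

```
wrote lfp.txt (6 true events)
6 events (threshold 3.255)
```

i.e. the detection threshold settled at 3.26 a.u. (4 × the 0.81 a.u.
envelope noise floor of unit-RMS background noise) and all six embedded
events were recovered. The events CSV has one row per event
(`start_s,end_s,duration_s,amplitude`); the summary CSV holds the
per-recording aggregates.

The numbered drivers under `analysis/` run the full study-style analyses
on synthetic cohorts and write their tables under `results/`. For
example `python analysis/01_upstate_pharmacology.py` simulates a 2×2
WT/KO × vehicle/drug slice cohort (knockout UP states 1.8× longer, drug
shortening them 25%) and prints

```
mean UP-state duration by group (s):
genotype  treatment
KO        1BAER        1.966
          VEH          2.686
WT        1BAER        1.170
          VEH          1.466

2-way ANOVA on duration: p(genotype) = 9.3e-11, p(treatment) = 4.9e-06, p(interaction) = 0.018
```

— the simulated genotype prolongation and its partial pharmacological
rescue, recovered end-to-end through envelope detection and the factorial
ANOVA. `02_eeg_band_power.py`, `03_audiogenic_seizures.py` and
`04_behavior_battery.py` do the same for the EEG, seizure and behavior
arms.

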