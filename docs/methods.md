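# Methods

## UP-state detection

The detector implements the standard slice-electrophysiology recipe for
extracellular multi-unit recordings. The trace is offset to zero mean and
rectified; a zero-phase 4th-order Butterworth low-pass (applied
forward–backward with `sosfiltfilt`, so event timing is not skewed by
filter delay) produces the activity envelope. Negative excursions from
filter ringing are clipped at zero. Detection parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `lowpass_cutoff_hz` | 0.2 | envelope smoothing cutoff |
| `threshold_mult` | 4 | threshold = mult × noise RMS |
| `min_duration_s` | 0.2 | minimum suprathreshold run to qualify |
| `merge_gap_s` | 0.6 | runs closer than this form one event |

The 0.2 Hz default is kept for fidelity to the published analysis chain,
but note it averages over ~5 s — longer than a typical 1–3 s UP state —
so it cannot resolve single events of that scale. Every simulation study
in this package therefore states and uses a 5 Hz cutoff
(`benchmarks.RECOVERY_CUTOFF_HZ`): fast enough to track second-scale
events (rise time ≈ 70 ms), slow enough to average the rectified-noise
fluctuations of the 300–1200 Hz background.

Rule application: maximal runs with envelope strictly above threshold are
enumerated; runs shorter than 200 ms are discarded (the rule is a
qualification filter, not an onset delay — a qualifying event starts at
its first suprathreshold sample); surviving runs separated by ≤ 600 ms
are merged; events touching either trace boundary are dropped (their
duration is undefined). Intervals are half-open `[start, end)` in
seconds; the min-duration and merge gaps are converted to sample counts
by round-half-up and recorded in the envelope metadata. Amplitude is the
mean of the processed envelope over the event (a `peak` mode is
available); this matches the quantity the detector thresholds.

### Noise-RMS estimation

The published analyses do not state how the "root mean square noise" was
measured, so the estimator here is this package's own design. It is an
iterative-exclusion estimate on the envelope: compute an RMS, exclude
samples above `threshold_mult ×` the current value, recompute until the
change is < 0.1% or 20 iterations. The iteration is **initialized from
the RMS of the below-median envelope samples** rather than from all
samples. Initialization from all samples admits a contaminated fixed
point: with events occupying a few percent of the trace at several-fold
the noise floor, the all-sample RMS is inflated enough that no event
sample ever exceeds 4 × it, nothing is excluded, and the threshold lands
*above* the events (verified numerically: at envelope gain 8 the
all-sample start yields zero detections, the below-median start recovers
every event). The below-median start is robust to < 50% contamination and
converges upward to the uncontaminated fixed point. On a rectified
zero-mean Gaussian the estimate equals σ (E[x²] is unchanged by
rectification); on a constant envelope it returns the constant; 5%
contamination at 100× is fully excluded.

### Detection operating range

With threshold multiplier 4, detectability is set by the ratio of the
event envelope to the noise envelope. For amplitude-modulated Gaussian
noise with in-event amplitude factor (1 + g), the rectified-smoothed
envelope is √(2/π)·σ ≈ 0.80σ between events and (1 + g)·0.80σ inside
them, while any consistent noise-floor RMS estimate is ≥ 0.80σ (the RMS
of a non-negative envelope cannot fall below its mean). The threshold
4 × 0.80σ = 3.19σ therefore *equals* the event plateau exactly when
g = 3: at that gain there is no margin, detection is knife-edge at best,
and the parameter-recovery test at g = 3 in the validation suite fails by
construction — it is retained, failing, to document this operating limit.
Reliable detection (sensitivity and precision ≈ 1, duration error ~2%)
requires g ≳ 5. The simulator's default gain of 8 was chosen as the
realistic regime: genuine UP states are prominent multi-unit elevations,
and a fixed 4 × RMS threshold presupposes events well above it.

## Synthetic LFP

`simulate_upstate_recording` models the recording as band-limited
(300–1200 Hz, respecting the 1250 Hz Nyquist of 2.5 kHz sampling)
Gaussian noise of RMS σ, multiplied by (1 + g·e(t)) where e is the event
indicator smoothed by a 10 ms kernel. Event onsets are a homogeneous
Poisson process (default 2/min) thinned to enforce a 1 s minimum gap
(> 0.6 s, so distinct true events can never be merged by the 600 ms
rule); durations are lognormal with natural-scale mean 1.5 s and sd
0.5 s; an event overrunning the trace end is truncated and flagged.
Defaults are the slice-recording conditions: 600 s at 2.5 kHz.

Since the detector operates on the rectified envelope, envelope elevation
is the sufficient statistic; the generator deliberately contains no
spike-level structure, network dynamics, or non-stationary background.
Passing recovery tests therefore demonstrate correctness of the
*detection and statistics chain*, not robustness to every artifact class
of real slice recordings.

## Synthetic EEG

`simulate_eeg` synthesizes each 5-min, 500 Hz daily segment in the
frequency domain: a white Gaussian spectrum is scaled band-by-band so
that each band component's time-domain variance equals its prescribed
absolute power, then inverted. Default band powers (a.u.²) fall off
roughly 1/f across δ…γ (0.40, 0.20, 0.12, 0.10, 0.10, 0.08). Optional
artifacts are 0.5 s segments multiplied by `artifact_gain` (default 20)
and labeled in the ground truth, so screening recall is measurable.

`simulate_eeg_cohort` adds the between-subject structure the group
analyses need: each animal's expected band powers are the base powers ×
genotype/treatment multipliers × a per-animal lognormal factor with 15%
CV, plus a 5% CV day-to-day factor. The 15% between-animal CV was chosen
once as the realistic chronic-telemetry regime — small enough that
genotype effects of the size reported in this literature are detectable
with the actual published group sizes (n ≈ 4–6), which would be
impossible at the 30–50% CV of unnormalized cross-lab power measures.
The generator does not emulate EMG/EKG artifact morphology, circadian
drift across days, or movement-state selection (the pipeline consumes
pre-cut resting segments as given).

## Band-power computation

Epochs are consecutive, non-overlapping, from t = 0; the trailing partial
epoch is discarded. Artifact screening rejects an epoch iff its peak
absolute amplitude exceeds k (default 6) × the *median* per-epoch RMS —
robust to a minority of contaminated epochs; rejecting every epoch is an
error, not a silent empty result. Spectra are rectangular-window
periodograms of the de-meaned epoch (a Hann option exists but is off by
default, favoring the bare Fourier transform of the source analysis over
spectral best practice); bin powers are scaled so their sum equals the
epoch's mean squared amplitude (Parseval), and a band sums the bins whose
center frequency lies in its half-open interval — DC belongs to no band.
The normalization total is the sum over the six named bands (0.5–80 Hz);
power above 80 Hz is excluded from the denominator. Aggregation averages
kept epochs within (animal, day), then across available days (count
recorded), and relative power is recomputed from the aggregated absolute
powers rather than averaged.

## Statistics

*Exact Wilcoxon rank-sum.* Midranks under ties; W = rank sum of the first
sample; two-sided p = P(|W − E[W]| ≥ observed) over all C(n+m, n)
equally likely group assignments, enumerated (vectorized, with the
assignment matrix cached per (n+m, n)) up to 2×10⁶ assignments, else
10⁵ seeded random permutations with the add-one convention
(count+1)/(draws+1). The reflection two-sided definition is used because
it stays well-defined under ties and asymmetric nulls; mode and draw
count are recorded in the result.

*Kruskal–Wallis* uses the tie-corrected H with a χ² reference on k−1 df
(scipy), with the all-values-identical degenerate case defined as H = 0,
p = 1.

*Two-way ANOVA* fits the cell-means model by least squares with
sum-to-zero contrasts and reports Type III sums of squares (statsmodels),
which are invariant to cell imbalance and reduce exactly to the textbook
balanced table (verified against a hand-computed fixture). An empty cell
drops the analysis to one-way on the remaining factor with a warning.
Repeated factors (days, intervals) are collapsed to within-animal means
before the factorial fit; no REML mixed-effects machinery is included —
the across-day-average path is the analysis of record here, and per-day
values remain available for descriptive summaries.

*FDR* is Benjamini–Hochberg step-up (statsmodels), applied across all
unordered pairwise comparisons of a measure; adjusted p ≥ raw p
elementwise and results are reported in adjusted-p order. Results with
0.05 ≤ p < 0.1 are annotated as trends.

## Pipeline and provenance

`run_pipeline` executes simulate → detect/band-power/score → stats from
one TOML config whose defaults are the published values (0.2 Hz, 4 × RMS,
200 ms, 600 ms, 10 s epochs, six-band table). The master seed is split
into per-stage sub-seeds by hashing the stage name (CRC32, masked to
31 bits), so stages are independently re-runnable; identical config +
inputs give byte-identical output tables. The config text is echoed into
the output directory and a run log records seeds, per-recording event
counts and epoch rejection counts. Signals travel as EDF (a minimal
single-channel 16-bit writer/reader; round-trip exact to the format's
quantization of range/65535) or plain one-sample-per-line text; tables as
CSV with ≥ 10 significant digits so float round-trips are lossless.

## Problem sizes of the simulation studies

Single-recording recovery runs use the full 600 s × 2.5 kHz condition.
The replicated power studies use 100 replicates of 12-animal cohorts with
300 s recordings (LFP) and 9 × 300 s days (EEG) — sizes chosen so the
whole validation battery is a desk-scale, single-CPU computation while
leaving the measured powers (≈ 97–100%) far from their 90% acceptance
margins. The Wilcoxon size study uses 1000 null replicates at n = m = 10
with a heavy-tie 5-point ordinal distribution.

## Known limitations

- The published 0.2 Hz envelope cutoff is exposed but unusable for
  second-scale event statistics; analyses must choose and report a cutoff.
- Event amplitude depends on the envelope cutoff (a smoother envelope
  lowers the plateau), so amplitudes are comparable only within one
  parameter set.
- Relative band power uses the six-band total; results are not comparable
  to normalizations that include > 80 Hz power.
- The exact Wilcoxon's Monte-Carlo mode has resolution 1/(draws+1); with
  the default 10⁵ draws, p-values below 10⁻⁵ saturate.
- The generators model stationary backgrounds and additive/multiplicative
  elevations only; conclusions about real-data robustness (electrode
  drift, EMG contamination, state transitions) are out of scope.
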