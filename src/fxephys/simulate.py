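"""Seeded generators for synthetic LFP, EEG and behavioral cohorts.

The generators emulate the statistical structure the downstream analyses
assume, with exact ground truth attached:

* LFP with embedded UP states — amplitude-modulated band-limited Gaussian
  noise.  Since the detector operates on the rectified envelope, envelope
  elevation is the sufficient statistic; spike-level realism adds nothing
  testable.  During an event the signal is ``noise * (1 + gain)``.
* EEG with prescribed per-band power — a sum of band-limited unit-power
  Gaussian components scaled by the square root of the target band powers,
  with optional labeled high-amplitude artifact segments.
* Behavioral cohorts — ordinal audiogenic-seizure scores drawn from
  per-group multinomials and continuous measures drawn from per-group
  normals, over the 2 x k genotype-by-treatment design.

Every generator is a pure function of (params, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import GENOTYPES, TREATMENTS, RawRecording
from .spectral import DEFAULT_BANDS, BandDefinition


@dataclass
class GroundTruth:
    """Exact generative truth attached to a simulated signal or cohort."""

    events: list[tuple[float, float]] = field(default_factory=list)
    truncated_last_event: bool = False
    band_powers: dict[str, float] = field(default_factory=dict)
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    group_params: dict = field(default_factory=dict)

    def validate(self, duration_s: float) -> None:
        prev_end = -math.inf
        for start, end in self.events:
            if not (0.0 <= start < end <= duration_s):
                raise ValueError(f"event ({start}, {end}) outside [0, {duration_s})")
            if start < prev_end:
                raise ValueError("ground-truth events overlap or are unsorted")
            prev_end = end


@dataclass
class UpStateSimParams:
    """Generative parameters for a slice-style LFP recording.

    Defaults mirror the recording conditions the detector targets: 10-minute
    traces sampled at 2.5 kHz with background noise band-limited to
    300–1200 Hz.  ``gain`` is the fractional envelope elevation during an
    event (signal = noise x (1 + gain) inside events, with the event
    indicator smoothed by a 10 ms kernel); the default of 8 represents the
    strong multi-unit elevation of genuine UP states, comfortably above a
    4 x RMS detection threshold.
    """

    duration_s: float = 600.0
    rate_hz: float = 2500.0
    noise_rms: float = 1.0
    event_rate_per_min: float = 2.0
    dur_mean_s: float = 1.5
    dur_sd_s: float = 0.5
    gain: float = 8.0
    min_gap_s: float = 1.0
    seed: int = 0
    noise_band_hz: tuple[float, float] = (300.0, 1200.0)

    def validate(self) -> None:
        for name in ("duration_s", "rate_hz", "noise_rms", "event_rate_per_min",
                     "dur_mean_s", "dur_sd_s", "min_gap_s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")
        if self.min_gap_s <= 0.6:
            raise ValueError(
                "min_gap_s must exceed 0.6 s so distinct true events cannot "
                "be merged by the detector's 600 ms rule")
        expected_busy = (self.event_rate_per_min / 60.0) * (
            self.dur_mean_s + self.min_gap_s)
        if expected_busy >= 1.0:
            raise ValueError(
                "event rate x (mean duration + gap) exceeds the recording: "
                f"expected busy fraction {expected_busy:.2f} >= 1")


def _band_limited_noise(rng: np.random.Generator, n: int, rate_hz: float,
                        f_lo: float, f_hi: float, rms: float) -> np.ndarray:
    """Gaussian noise confined to [f_lo, f_hi) Hz with the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec[(freqs < f_lo) | (freqs >= f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"band [{f_lo}, {f_hi}) Hz contains no frequency bins")
    return x * (rms / sd)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_upstate_recording(
        params: UpStateSimParams) -> tuple[RawRecording, GroundTruth]:
    """Simulate one LFP trace with embedded UP states and its ground truth.

    Event onsets follow a homogeneous Poisson process thinned (rejected) to
    keep at least ``min_gap_s`` between the previous event's end and the next
    onset; durations are lognormal with the given natural-scale mean/sd.  An
    event overrunning the recording end is truncated and flagged.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))
    lam = params.event_rate_per_min / 60.0
    mu, sigma = _lognormal_params(params.dur_mean_s, params.dur_sd_s)

    events: list[tuple[float, float]] = []
    truncated = False
    t = rng.exponential(1.0 / lam)
    prev_end = -math.inf
    while t < params.duration_s:
        if t >= prev_end + params.min_gap_s:  # thinning: enforce the gap
            dur = float(rng.lognormal(mu, sigma))
            end = t + dur
            if end > params.duration_s:
                end = params.duration_s
                truncated = True
            events.append((t, end))
            prev_end = end
        t += rng.exponential(1.0 / lam)

    f_lo, f_hi = params.noise_band_hz
    f_hi = min(f_hi, 0.48 * params.rate_hz)
    noise = _band_limited_noise(rng, n, params.rate_hz, f_lo, f_hi,
                                params.noise_rms)

    indicator = np.zeros(n)
    for start, end in events:
        i0 = int(round(start * params.rate_hz))
        i1 = int(round(end * params.rate_hz))
        indicator[i0:i1] = 1.0
    kernel_n = max(1, int(round(0.010 * params.rate_hz)))
    smooth = uniform_filter1d(indicator, size=kernel_n, mode="nearest")

    samples = noise * (1.0 + params.gain * smooth)
    rec = RawRecording(samples=samples, rate_hz=params.rate_hz,
                       meta={"source": "simulate_upstate_recording",
                             "seed": params.seed})
    gt = GroundTruth(events=events, truncated_last_event=truncated)
    gt.validate(params.duration_s)
    return rec, gt


@dataclass
class EegSimParams:
    """Generative parameters for one daily resting-EEG segment.

    Defaults mirror the telemetry conditions the band-power analysis
    targets: 5-minute segments sampled at 500 Hz.  ``band_powers`` gives one
    non-negative absolute power (a.u.^2) per named band; artifacts are
    injected as 0.5 s segments with amplitude multiplied by
    ``artifact_gain`` and labeled in the ground truth.
    """

    duration_s: float = 300.0
    rate_hz: float = 500.0
    band_powers: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 0.40, "theta": 0.20, "alpha": 0.12,
                                 "sigma": 0.10, "beta": 0.10, "gamma": 0.08})
    artifact_rate_per_min: float = 0.0
    artifact_gain: float = 20.0
    artifact_duration_s: float = 0.5
    seed: int = 0
    bands: Sequence[BandDefinition] = DEFAULT_BANDS

    def validate(self) -> None:
        if not (self.duration_s > 0 and self.rate_hz > 0):
            raise ValueError("duration_s and rate_hz must be positive")
        band_names = {b.name for b in self.bands}
        for name, p in self.band_powers.items():
            if name not in band_names:
                raise ValueError(f"unknown band {name!r}")
            if p < 0:
                raise ValueError(f"negative power for band {name!r}")
        if not any(p > 0 for p in self.band_powers.values()):
            raise ValueError("at least one band power must be positive")
        for b in self.bands:
            if self.band_powers.get(b.name, 0.0) > 0 and b.f_hi > self.rate_hz / 2:
                raise ValueError(
                    f"band {b.name} upper edge {b.f_hi} Hz >= Nyquist "
                    f"{self.rate_hz / 2} Hz")
        if self.artifact_rate_per_min < 0 or self.artifact_gain < 0:
            raise ValueError("artifact parameters must be non-negative")


def simulate_eeg(params: EegSimParams) -> tuple[RawRecording, GroundTruth]:
    """Simulate an EEG trace whose per-band power follows the prescription.

    The trace is synthesized in one pass in the frequency domain: a white
    Gaussian spectrum is scaled band-by-band so each band component's
    time-domain variance equals its target power exactly, then inverted.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.rate_hz))

    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / params.rate_hz)
    # Parseval weights: interior rfft bins count twice toward the variance
    weights = np.full(freqs.size, 2.0 / n ** 2)
    weights[0] = 1.0 / n ** 2
    if n % 2 == 0:
        weights[-1] = 1.0 / n ** 2
    keep = np.zeros(freqs.size, dtype=bool)
    for band in params.bands:
        power = params.band_powers.get(band.name, 0.0)
        sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
        if power <= 0:
            continue
        var = float(np.sum(weights[sel] * np.abs(spec[sel]) ** 2))
        if var == 0:
            raise ValueError(f"band {band.name} contains no frequency bins")
        spec[sel] *= math.sqrt(power / var)
        keep |= sel
    spec[~keep] = 0.0
    signal = np.fft.irfft(spec, n)

    artifacts: list[tuple[float, float]] = []
    if params.artifact_rate_per_min > 0:
        count = rng.poisson(params.artifact_rate_per_min *
                            params.duration_s / 60.0)
        dur = params.artifact_duration_s
        for start in np.sort(rng.uniform(0, params.duration_s - dur, count)):
            i0, i1 = int(start * params.rate_hz), int((start + dur) * params.rate_hz)
            signal[i0:i1] *= params.artifact_gain
            artifacts.append((float(start), float(start + dur)))

    rec = RawRecording(samples=signal, rate_hz=params.rate_hz,
                       meta={"source": "simulate_eeg", "seed": params.seed})
    gt = GroundTruth(band_powers=dict(params.band_powers), artifacts=artifacts)
    return rec, gt


@dataclass
class CohortDesign:
    """Design of a genotype x treatment behavioral cohort.

    ``n`` maps (genotype, treatment) to group size; ``seizure_score_probs``
    gives each group's probability vector over the ordinal scores 0..4;
    ``continuous_measures`` maps measure name -> group -> (mean, sd).
    """

    n: Mapping[tuple[str, str], int]
    seizure_score_probs: Mapping[tuple[str, str], Sequence[float]] | None = None
    continuous_measures: Mapping[str, Mapping[tuple[str, str], tuple[float, float]]] = \
        field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for group, size in self.n.items():
            g, t = group
            if g not in GENOTYPES or t not in TREATMENTS:
                raise ValueError(f"illegal group {group}")
            if size < 1:
                raise ValueError(f"group {group} has n = {size} < 1")
        if self.seizure_score_probs is not None:
            for group, probs in self.seizure_score_probs.items():
                probs = np.asarray(probs, dtype=float)
                if probs.size != 5 or np.any(probs < 0):
                    raise ValueError(f"group {group}: need 5 non-negative probs")
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"group {group}: score probabilities sum to "
                        f"{probs.sum()}, not 1")
        for measure, spec in self.continuous_measures.items():
            for group, (mean, sd) in spec.items():
                if sd < 0:
                    raise ValueError(f"{measure} {group}: sd < 0")


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw a tidy behavioral dataset for the given cohort design."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    counter = 0
    for (genotype, treatment), size in design.n.items():
        ids = [f"{genotype}-{treatment}-{counter + i:03d}" for i in range(size)]
        counter += size
        if design.seizure_score_probs is not None:
            probs = np.asarray(design.seizure_score_probs[(genotype, treatment)],
                               dtype=float)
            scores = rng.choice(5, size=size, p=probs / probs.sum())
            for aid, score in zip(ids, scores):
                rows.append({"animal_id": aid, "genotype": genotype,
                             "treatment": treatment, "measure": "seizure_score",
                             "value": float(score), "index": np.nan})
        for measure, spec in design.continuous_measures.items():
            if (genotype, treatment) not in spec:
                continue
            mean, sd = spec[(genotype, treatment)]
            values = rng.normal(mean, sd, size=size)
            for aid, v in zip(ids, values):
                rows.append({"animal_id": aid, "genotype": genotype,
                             "treatment": treatment, "measure": measure,
                             "value": float(v), "index": np.nan})
    return pd.DataFrame(rows,
                        columns=["animal_id", "genotype", "treatment",
                                 "measure", "value", "index"])


# ---------------------------------------------------------------------------
# Cohort-level signal generators (drive the end-to-end demonstrations)

def simulate_upstate_cohort(
        n_per_group: int = 6,
        ko_duration_multiplier: float = 1.8,
        base: UpStateSimParams | None = None,
        treatments: Sequence[str] = ("VEH",),
        treatment_duration_multipliers: Mapping[str, float] | None = None,
        seed: int = 0,
) -> Iterator[tuple[RawRecording, GroundTruth]]:
    """Yield simulated slice recordings for a WT vs KO (x treatment) cohort.

    KO recordings get ``ko_duration_multiplier`` applied to the mean UP-state
    duration (the core excitability phenotype); optional per-treatment
    multipliers model a drug shortening events.  Each recording carries
    animal/genotype/treatment metadata and a derived sub-seed.
    """
    base = base or UpStateSimParams()
    tmult = dict(treatment_duration_multipliers or {})
    root = np.random.SeedSequence(seed)
    idx = 0
    for genotype in GENOTYPES:
        for treatment in treatments:
            for k in range(n_per_group):
                sub = int(root.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
                dur = base.dur_mean_s
                if genotype == "KO":
                    dur *= ko_duration_multiplier
                dur *= tmult.get(treatment, 1.0)
                params = UpStateSimParams(
                    duration_s=base.duration_s, rate_hz=base.rate_hz,
                    noise_rms=base.noise_rms,
                    event_rate_per_min=base.event_rate_per_min,
                    dur_mean_s=dur, dur_sd_s=base.dur_sd_s, gain=base.gain,
                    min_gap_s=base.min_gap_s, seed=sub)
                rec, gt = simulate_upstate_recording(params)
                rec.meta.update({"animal_id": f"{genotype}-{treatment}-{k:02d}",
                                 "genotype": genotype, "treatment": treatment})
                idx += 1
                yield rec, gt


def simulate_eeg_cohort(
        n_per_group: Mapping[tuple[str, str], int],
        days: int = 9,
        base_powers: Mapping[str, float] | None = None,
        genotype_band_multipliers: Mapping[str, Mapping[str, float]] | None = None,
        treatment_band_multipliers: Mapping[str, Mapping[str, float]] | None = None,
        animal_cv: float = 0.15,
        day_cv: float = 0.05,
        duration_s: float = 300.0,
        rate_hz: float = 500.0,
        seed: int = 0,
) -> Iterator[tuple[RawRecording, GroundTruth]]:
    """Yield one EEG segment per animal per day for a telemetry-style cohort.

    Each animal's expected band powers are the base powers times its
    genotype/treatment multipliers times a per-animal lognormal factor
    (CV ``animal_cv``, the dominant source of between-subject variability in
    chronic telemetry); each day adds a smaller lognormal day factor
    (CV ``day_cv``).  Recording metadata carries animal, group and day.
    """
    base_powers = dict(base_powers or EegSimParams().band_powers)
    gmult = {g: dict((genotype_band_multipliers or {}).get(g, {}))
             for g in GENOTYPES}
    tmult = {t: dict((treatment_band_multipliers or {}).get(t, {}))
             for t in TREATMENTS}
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    for (genotype, treatment), size in n_per_group.items():
        for k in range(size):
            aid = f"{genotype}-{treatment}-{k:02d}"
            animal_factor = {
                name: float(rng.lognormal(-0.5 * math.log1p(animal_cv ** 2),
                                          math.sqrt(math.log1p(animal_cv ** 2))))
                for name in base_powers}
            for day in range(1, days + 1):
                powers = {}
                for name, p in base_powers.items():
                    f = (p * gmult[genotype].get(name, 1.0)
                         * tmult[treatment].get(name, 1.0) * animal_factor[name])
                    day_factor = float(rng.lognormal(
                        -0.5 * math.log1p(day_cv ** 2),
                        math.sqrt(math.log1p(day_cv ** 2)))) if day_cv > 0 else 1.0
                    powers[name] = f * day_factor
                sub = int(root.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
                rec, gt = simulate_eeg(EegSimParams(
                    duration_s=duration_s, rate_hz=rate_hz,
                    band_powers=powers, seed=sub))
                rec.meta.update({"animal_id": aid, "genotype": genotype,
                                 "treatment": treatment, "day": day})
                yield rec, gt
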