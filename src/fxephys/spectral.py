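"""Epoch-FFT EEG band-power analysis.

The raw single-channel EEG is cut into consecutive 10 s epochs, screened
for high-amplitude artifacts, and each kept epoch is Fourier-transformed to
yield absolute power in six contiguous bands:

    delta [0.5, 4), theta [4, 8), alpha [8, 12), sigma [12, 16),
    beta [16, 24), gamma [24, 80) Hz   (half-open intervals)

Bin powers follow the Parseval convention: summed over all bins they equal
the mean squared amplitude of the de-meaned epoch.  Relative power is each
band's share of the total over the six bands (power above 80 Hz is
excluded from the denominator).  Per-epoch rows are averaged within
(animal, day) and then across treatment days for the 9-day average, with
relative power recomputed from the aggregated absolute powers.

Spectra use a plain rectangular-window periodogram by default (a Hann
window is available via ``window="hann"``); the choice trades spectral
best practice for a transform that is exactly the bare FFT of the epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import RawRecording


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band over the half-open interval [f_lo, f_hi) Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 16.0, 24.0),
    BandDefinition("gamma", 24.0, 80.0),
)


@dataclass
class Epoch:
    """One fixed-length analysis window of an EEG recording."""

    samples: np.ndarray
    rate_hz: float
    start_s: float
    kept: bool = True


def epoch_signal(rec: RawRecording, epoch_len_s: float = 10.0) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs from t = 0.

    The trailing partial epoch, if any, is discarded; a recording shorter
    than one epoch is an error.
    """
    n_per = int(round(epoch_len_s * rec.rate_hz))
    if rec.n_samples < n_per:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{epoch_len_s:.0f} s epoch")
    count = rec.n_samples // n_per
    return [Epoch(samples=rec.samples[i * n_per:(i + 1) * n_per],
                  rate_hz=rec.rate_hz, start_s=i * epoch_len_s)
            for i in range(count)]


def reject_artifacts(epochs: Sequence[Epoch], k: float = 6.0) -> list[Epoch]:
    """Flag artifact epochs: peak |amplitude| > k x median per-epoch RMS.

    The median RMS over all epochs is a robust scale reference, so a few
    contaminated epochs cannot inflate it.  Order is preserved; at least one
    epoch must survive.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    rms = np.array([math.sqrt(float(np.mean(e.samples ** 2))) for e in epochs])
    ref = float(np.median(rms))
    out = []
    for e in epochs:
        peak = float(np.max(np.abs(e.samples)))
        out.append(Epoch(samples=e.samples, rate_hz=e.rate_hz,
                         start_s=e.start_s, kept=peak <= k * ref))
    if not any(e.kept for e in out):
        raise ValueError(
            "artifact screening rejected every epoch; raise k or choose "
            "another segment")
    return out


def epoch_band_power(epoch: Epoch,
                     bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                     window: str = "rect") -> dict[str, float]:
    """Absolute power per band for one epoch (a.u.^2).

    The epoch mean is removed, the discrete Fourier transform taken, and
    bin powers scaled so their sum equals the mean squared amplitude of the
    de-meaned epoch.  A band's power is the sum over bins whose center
    frequency falls in its half-open interval; the DC bin belongs to no
    band.
    """
    x = epoch.samples - epoch.samples.mean()
    n = x.size
    nyq = epoch.rate_hz / 2.0
    for b in bands:
        if b.f_hi > nyq:
            raise ValueError(f"band {b.name} exceeds Nyquist {nyq} Hz")
    if window == "hann":
        w = np.hanning(n)
        x = x * w / math.sqrt(float(np.mean(w ** 2)))
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")

    spec = np.fft.rfft(x)
    # Parseval: sum(power) == mean(x**2); interior bins count twice
    power = (np.abs(spec) ** 2) / n ** 2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.rate_hz)

    out = {}
    for b in bands:
        sel = (freqs >= b.f_lo) & (freqs < b.f_hi)
        out[b.name] = float(power[sel].sum())
    return out


def relative_power(row: dict[str, float],
                   bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> dict[str, float]:
    """Per-band relative power: absolute / total over the named bands.

    With zero total power the relative fields are missing (NaN), not 0/0.
    """
    total = float(sum(row[b.name] for b in bands))
    out = dict(row)
    out["total"] = total
    for b in bands:
        out[f"{b.name}_rel"] = row[b.name] / total if total > 0 else float("nan")
    return out


def bandpower_table(rec: RawRecording,
                    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                    epoch_len_s: float = 10.0, artifact_k: float = 6.0,
                    window: str = "rect") -> pd.DataFrame:
    """Per-epoch band-power rows for one labeled daily recording."""
    epochs = reject_artifacts(epoch_signal(rec, epoch_len_s), k=artifact_k)
    kept = [e for e in epochs if e.kept]
    # one batched FFT over all kept epochs (identical to the per-epoch path)
    mat = np.stack([e.samples for e in kept])
    mat = mat - mat.mean(axis=1, keepdims=True)
    n = mat.shape[1]
    if window == "hann":
        w = np.hanning(n)
        mat = mat * (w / math.sqrt(float(np.mean(w ** 2))))
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    power = (np.abs(np.fft.rfft(mat, axis=1)) ** 2) / n ** 2
    power[:, 1:] *= 2.0
    if n % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate_hz)

    rows = []
    for i, e in enumerate(kept):
        row = {"animal_id": rec.meta.get("animal_id"),
               "genotype": rec.meta.get("genotype"),
               "treatment": rec.meta.get("treatment"),
               "day": rec.meta.get("day"),
               "epoch_start_s": e.start_s}
        abs_powers = {b.name: float(power[i, (freqs >= b.f_lo) &
                                             (freqs < b.f_hi)].sum())
                      for b in bands}
        row.update(relative_power(abs_powers, bands))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["kept_epochs"] = sum(e.kept for e in epochs)
    df.attrs["total_epochs"] = len(epochs)
    df.attrs["window"] = window
    return df


def aggregate_power(rows: pd.DataFrame,
                    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                    across_days: bool = True) -> pd.DataFrame:
    """Average per-epoch rows within (animal, day), then across days.

    Returns one row per animal (or per animal-day when ``across_days`` is
    False) with mean absolute powers, day count, and relative powers
    recomputed from the aggregated absolute powers.  Missing days are
    tolerated: the mean runs over available days and ``n_days`` records how
    many contributed.
    """
    if rows.empty:
        raise ValueError("no kept epochs to aggregate")
    band_cols = [b.name for b in bands]
    keys = ["animal_id", "genotype", "treatment"]
    per_day = (rows.groupby(keys + ["day"], dropna=False, sort=True)[band_cols]
               .mean().reset_index())
    if not across_days:
        out = per_day
    else:
        grouped = per_day.groupby(keys, sort=True)
        out = grouped[band_cols].mean().reset_index()
        out["n_days"] = grouped["day"].nunique().values
    rel = out[band_cols].to_numpy()
    total = rel.sum(axis=1)
    out["total"] = total
    for i, b in enumerate(bands):
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{b.name}_rel"] = np.where(total > 0, rel[:, i] / total, np.nan)
    return out
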