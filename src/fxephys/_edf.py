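"""Minimal single-channel EDF (European Data Format) writer and reader.

EDF stores signals as 16-bit integers with a per-channel linear mapping
between digital and physical units.  Only the small subset of the format
needed for single-channel telemetry-style traces is implemented: one
continuous recording, one or more channels, no annotations.  Round-trip
precision is therefore limited to (physical range) / 65535, the format's
native quantization.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def _fmt_num(value: float, width: int = 8) -> bytes:
    """Format a number into EDF's fixed-width ASCII numeric field."""
    for fmt in ("%d", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g"):
        if fmt == "%d" and value != int(value):
            continue
        s = fmt % value
        if len(s) <= width:
            return _pad(s, width)
    raise ValueError(f"cannot format {value!r} in {width} EDF header chars")


def write_edf(path: str | os.PathLike, samples: np.ndarray, rate_hz: float,
              label: str = "EEG", patient_id: str = "X",
              recording_id: str = "fxephys") -> None:
    """Write a single-channel EDF file.

    Uses 1-second data records when the trace length is a whole number of
    seconds at an integer sampling rate, otherwise a single data record
    spanning the whole trace.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    n = x.size

    if float(rate_hz).is_integer() and n % int(rate_hz) == 0:
        spr = int(rate_hz)
        n_records = n // spr
        record_dur = 1.0
    else:
        spr = n
        n_records = 1
        record_dur = n / rate_hz

    pmin, pmax = float(x.min()), float(x.max())
    if pmin == pmax:  # degenerate range; keep the mapping invertible
        pmax = pmin + max(abs(pmin), 1.0)
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    dig = np.clip(np.rint((x - pmin) * scale) + _DIG_MIN, _DIG_MIN, _DIG_MAX)
    dig = dig.astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad(recording_id, 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _fmt_num(256 + 256, 8),          # header length, 1 channel
        _pad("", 44),
        _fmt_num(n_records, 8),
        _fmt_num(record_dur, 8),
        _fmt_num(1, 4),
        # per-channel fields
        _pad(label, 16),
        _pad("", 80),                    # transducer
        _pad("uV", 8),                   # physical dimension (nominal a.u.)
        _fmt_num(pmin, 8),
        _fmt_num(pmax, 8),
        _fmt_num(_DIG_MIN, 8),
        _fmt_num(_DIG_MAX, 8),
        _pad("", 80),                    # prefiltering
        _fmt_num(spr, 8),
        _pad("", 32),
    ])
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dig.tobytes())


@dataclass
class EdfChannel:
    label: str
    rate_hz: float
    samples: np.ndarray


def read_edf(path: str | os.PathLike) -> list[EdfChannel]:
    """Read an EDF file, returning one :class:`EdfChannel` per signal."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244])
        record_dur = float(head[244:252])
        n_sig = int(head[252:256])
        sig_head = fh.read(256 * n_sig)
        labels = [sig_head[16 * i:16 * (i + 1)].decode("ascii").strip()
                  for i in range(n_sig)]
        off = 16 * n_sig + 80 * n_sig + 8 * n_sig
        pmin = [float(sig_head[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        pmax = [float(sig_head[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        dmin = [float(sig_head[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig
        dmax = [float(sig_head[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
        off += 8 * n_sig + 80 * n_sig
        spr = [int(sig_head[off + 8 * i:off + 8 * (i + 1)]) for i in range(n_sig)]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = sum(spr)
    if raw.size < per_rec * n_records:
        raise ValueError(f"{path}: EDF data shorter than header declares")
    raw = raw[:per_rec * n_records].reshape(n_records, per_rec)
    channels = []
    pos = 0
    for i in range(n_sig):
        dig = raw[:, pos:pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * gain + pmin[i]
        channels.append(EdfChannel(label=labels[i],
                                   rate_hz=spr[i] / record_dur,
                                   samples=phys))
    return channels
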