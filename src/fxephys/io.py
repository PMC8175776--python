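"""Reading and writing recordings and result tables.

All downstream analysis consumes :class:`RawRecording` (a uniformly sampled
single-channel trace with its sampling rate and animal metadata) and tidy
tables handled by :func:`read_table` / :func:`write_table`.  Signals travel
as EDF (EEG-rate traces) or plain delimited text, one sample per line
(LFP fixtures); tables as RFC-4180 CSV with "." decimals.

Conventions: times in seconds, sample indices 0-based, intervals half-open
[start, end).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _edf

GENOTYPES = ("WT", "KO")
TREATMENTS = ("VEH", "1BAER", "3BAER")

#: Column schemas for the tables the pipeline writes.
EVENT_SCHEMA = {"start_s": float, "end_s": float, "duration_s": float,
                "amplitude": float}
BEHAVIOR_SCHEMA = {"animal_id": str, "genotype": GENOTYPES,
                   "treatment": TREATMENTS, "measure": str,
                   "value": float, "index": float}


@dataclass
class RawRecording:
    """Uniformly sampled single-channel signal in arbitrary units."""

    samples: np.ndarray
    rate_hz: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if not (self.rate_hz > 0):
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        g = self.meta.get("genotype")
        if g is not None and g not in GENOTYPES:
            raise ValueError(f"illegal genotype {g!r}; expected one of {GENOTYPES}")
        t = self.meta.get("treatment")
        if t is not None and t not in TREATMENTS:
            raise ValueError(f"illegal treatment {t!r}; expected one of {TREATMENTS}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


def _sidecar_meta(path: Path) -> dict[str, Any]:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        with open(side) as fh:
            return json.load(fh)
    return {}


def read_signal(path: str | os.PathLike, rate_hz: float | None = None,
                meta: Mapping[str, Any] | None = None,
                channel: int | None = None) -> RawRecording:
    """Load a recording from EDF or delimited numeric text.

    For EDF the sampling rate always comes from the file header (an explicit
    ``rate_hz`` argument is ignored); for text files ``rate_hz`` is required.
    ``channel`` selects a signal from a multi-channel EDF; omitting it for
    such a file is an error.  Metadata is merged from a ``<file>.meta.json``
    sidecar, then from the ``meta`` argument (argument wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    merged = _sidecar_meta(path)
    merged.update(dict(meta or {}))
    merged.setdefault("source", str(path))

    if path.suffix.lower() == ".edf":
        channels = _edf.read_edf(path)
        if len(channels) > 1 and channel is None:
            raise ValueError(
                f"{path} has {len(channels)} channels; pass channel=<index>")
        ch = channels[channel or 0]
        return RawRecording(samples=ch.samples, rate_hz=ch.rate_hz, meta=merged)

    if rate_hz is None:
        raise ValueError(f"{path}: delimited text input requires rate_hz")
    try:
        data = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric entry in signal file ({exc})") from exc
    return RawRecording(samples=data, rate_hz=float(rate_hz), meta=merged)


def write_signal(rec: RawRecording, path: str | os.PathLike) -> None:
    """Write a recording as EDF (``.edf`` suffix) or one-sample-per-line text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _edf.write_edf(path, rec.samples, rec.rate_hz,
                       patient_id=str(rec.meta.get("animal_id", "X")))
    else:
        np.savetxt(path, rec.samples, fmt="%.10g")


def _as_dataframe(rows: Any, schema: Mapping[str, Any] | None = None) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows.copy()
    rows = list(rows)
    if rows:
        keys = set(rows[0])
        for r in rows:
            if set(r) != keys:
                raise ValueError("heterogeneous rows: field sets differ")
        return pd.DataFrame(rows)
    if schema is None:
        raise ValueError("empty row list requires an explicit schema")
    return pd.DataFrame({name: pd.Series(dtype=object) for name in schema})


def write_table(rows: Any, path: str | os.PathLike,
                schema: Mapping[str, Any] | None = None) -> None:
    """Write records as CSV (header row, RFC-4180 quoting, >=10 significant
    digits on floats so that read-back reproduces values to float precision)."""
    df = _as_dataframe(rows, schema)
    df.to_csv(path, index=False, float_format="%.10g")


def read_table(path: str | os.PathLike,
               schema: Mapping[str, Any] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally validating and typing it against a schema.

    ``schema`` maps column name -> type (``str``/``float``/``int``) or an
    iterable of allowed values (enumeration).  Missing columns and illegal
    enumeration values raise ``ValueError`` naming the offender.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if schema is None:
        return df
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for name, spec in schema.items():
        col = df[name]
        if spec is str:
            df[name] = col.astype(str) if len(df) else col
        elif spec in (float, int):
            try:
                df[name] = col.astype(float if spec is float else int)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: column {name!r} unparseable ({exc})") from exc
        else:  # enumeration
            allowed = set(spec)
            bad = sorted(set(col.dropna().astype(str)) - allowed)
            if bad:
                raise ValueError(
                    f"{path}: illegal value(s) {bad} in column {name!r}; "
                    f"allowed: {sorted(allowed)}")
    return df


def validate_marble_count(value: float) -> int:
    """Marble-burying raw count: integer in [0, 20] (20 marbles laid out)."""
    v = int(value)
    if v != value or not (0 <= v <= 20):
        raise ValueError(f"marble count must be an integer in [0, 20], got {value}")
    return v
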