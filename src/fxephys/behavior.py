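"""Behavioral endpoint scores.

Covers the audiogenic-seizure severity scale, the novel-object-recognition
discrimination index, and interval/block summaries for time-resolved
measures (open-field distance per 5-min interval, startle Vmax per
10-trial block), each reduced to tidy per-animal rows.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ordinal severity of each audiogenic response; the score of an animal is
#: the maximum over its observed responses (0 when none occurred).
SEIZURE_RESPONSE_SEVERITY = {
    "wild_running": 1,
    "clonic": 2,
    "tonic": 3,
    "death": 4,
}

#: Controlled vocabulary for the ``measure`` column of behavioral tables.
MEASURES = ("seizure_score", "di", "distance", "marbles", "startle_vmax",
            "time_open", "transitions", "latency_fall")


def seizure_severity(responses: Iterable[str]) -> int:
    """Ordinal 0-4 severity: the most severe response observed.

    0 = no altered behavior, 1 = wild running, 2 = clonic seizure,
    3 = tonic seizure, 4 = death.  Only second-tone responses should be
    passed in (priming-tone behavior is stored but never scored).
    """
    score = 0
    for r in responses:
        if r not in SEIZURE_RESPONSE_SEVERITY:
            raise ValueError(
                f"unknown seizure response {r!r}; expected one of "
                f"{sorted(SEIZURE_RESPONSE_SEVERITY)}")
        score = max(score, SEIZURE_RESPONSE_SEVERITY[r])
    return score


def discrimination_index(t_novel_s: float, t_familiar_s: float) -> float:
    """(novel - familiar) / (novel + familiar) exploration time, in [-1, 1].

    Positive values indicate recognition memory.  When the animal explored
    neither object the index is undefined and NaN is returned with a
    warning rather than raising.
    """
    if t_novel_s < 0 or t_familiar_s < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel_s + t_familiar_s
    if total == 0:
        warnings.warn("zero total exploration time; discrimination index "
                      "is undefined", stacklevel=2)
        return float("nan")
    return (t_novel_s - t_familiar_s) / total


def interval_summaries(times_s: Sequence[float], values: Sequence[float],
                       bin_s: float, n_bins: int, animal_id: str,
                       genotype: str, treatment: str,
                       measure: str = "distance",
                       mode: str = "total") -> pd.DataFrame:
    """Per-bin totals or means of a time-stamped series, plus the collapse.

    ``mode="total"`` sums within bins (e.g. distance per 5-min interval) and
    the collapsed row is the overall total; ``mode="mean"`` averages within
    bins (e.g. startle Vmax per block of trials, where ``times_s`` is the
    trial index) and the collapsed row is the overall mean.  The collapsed
    row has ``index`` NaN and is what FDR pairwise comparisons "collapsed
    over time" consume.
    """
    if bin_s <= 0 or n_bins < 1:
        raise ValueError("need bin_s > 0 and n_bins >= 1")
    times = np.asarray(times_s, dtype=float)
    vals = np.asarray(values, dtype=float)
    if times.size != vals.size or times.size == 0:
        raise ValueError("times and values must be equal-length, non-empty")
    if times.max() >= bin_s * n_bins:
        raise ValueError(
            f"data at t = {times.max():.3g} falls outside the requested "
            f"window of {n_bins} x {bin_s:.3g}")
    which = np.floor(times / bin_s).astype(int)
    rows = []
    for b in range(n_bins):
        sel = vals[which == b]
        if mode == "total":
            v = float(sel.sum())
        elif mode == "mean":
            v = float(sel.mean()) if sel.size else float("nan")
        else:
            raise ValueError("mode must be 'total' or 'mean'")
        rows.append({"animal_id": animal_id, "genotype": genotype,
                     "treatment": treatment, "measure": measure,
                     "value": v, "index": float(b)})
    collapsed = float(vals.sum()) if mode == "total" else float(vals.mean())
    rows.append({"animal_id": animal_id, "genotype": genotype,
                 "treatment": treatment, "measure": measure,
                 "value": collapsed, "index": float("nan")})
    return pd.DataFrame(rows)
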