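"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from fxephys.upstates import EnvelopeTrace, UpStateEvent


def brute_force_detect(env: np.ndarray, threshold: float, rate_hz: float,
                       min_duration_s: float = 0.2,
                       merge_gap_s: float = 0.6) -> list[tuple[int, int]]:
    """Literal linear-scan application of the detection rules.

    Independent of the vectorized detector: walks the envelope sample by
    sample, enumerates maximal suprathreshold runs, discards short runs,
    merges runs across small gaps, and drops boundary-touching events.
    Returns half-open sample intervals.
    """
    n = len(env)
    runs = []
    i = 0
    while i < n:
        if env[i] > threshold:
            j = i
            while j < n and env[j] > threshold:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    min_n = int(math.floor(min_duration_s * rate_hz + 0.5))
    gap_n = int(math.floor(merge_gap_s * rate_hz + 0.5))
    runs = [(s, e) for s, e in runs if e - s >= min_n]
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap_n:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if s > 0 and e < n]


def brute_force_wilcoxon_p(x, y) -> float:
    """Two-sided exact rank-sum p by explicit loop over all assignments."""
    from itertools import combinations

    from scipy.stats import rankdata
    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n, total = len(x), len(pooled)
    w_obs = sum(ranks[:n])
    e_w = n * (total + 1) / 2.0
    d_obs = abs(w_obs - e_w)
    hits = 0
    count = 0
    for idx in combinations(range(total), n):
        w = sum(ranks[i] for i in idx)
        if abs(w - e_w) >= d_obs - 1e-9:
            hits += 1
        count += 1
    return hits / count


def random_envelope(rng: np.random.Generator, n: int = 3000,
                    rate_hz: float = 100.0) -> EnvelopeTrace:
    """A positive, autocorrelated random envelope with a mid-range threshold,
    built to produce a rich mixture of runs and gaps."""
    from scipy.ndimage import uniform_filter1d
    raw = np.abs(uniform_filter1d(rng.standard_normal(n), size=25))
    thr = float(np.quantile(raw, rng.uniform(0.5, 0.95)))
    return EnvelopeTrace(env=raw, rate_hz=rate_hz, noise_rms=thr / 4.0,
                         threshold=thr)


def events_to_sample_intervals(events: list[UpStateEvent],
                               rate_hz: float) -> list[tuple[int, int]]:
    return [(int(round(e.start_s * rate_hz)), int(round(e.end_s * rate_hz)))
            for e in events]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
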