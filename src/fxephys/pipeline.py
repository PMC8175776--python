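"""End-to-end orchestration: simulate -> detect / band-power / score -> stats.

A single plain-text (TOML) config drives the run.  Every numeric default
equals the published analysis value (0.2 Hz envelope cutoff, 4 x RMS
threshold, 200 ms minimum duration, 600 ms merge gap, 10 s epochs, the
six-band table).  The master seed is split into per-stage sub-seeds by
hashing the stage name, so stages are independently reproducible;
re-running an identical config reproduces every output table
bit-identically.  The config text is echoed verbatim into the output
directory and a run log records seeds and filter counts.
"""

from __future__ import annotations

import json
import logging
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import behavior, simulate, spectral, stats, upstates
from .io import GENOTYPES, TREATMENTS, read_signal, write_signal, write_table

log = logging.getLogger("fxephys")

DEFAULT_CONFIG: dict[str, Any] = {
    "run": {"master_seed": 0},
    "detect": {"lowpass_cutoff_hz": 0.2, "threshold_mult": 4.0,
               "min_duration_s": 0.2, "merge_gap_s": 0.6},
    "bandpower": {"epoch_len_s": 10.0, "artifact_k": 6.0, "window": "rect"},
    "stats": {"test": "wilcoxon", "mc_draws": stats.MC_DRAWS},
}


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    text = ""
    if path is not None:
        text = Path(path).read_text()
        user = tomllib.loads(text)
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values)
    for section, values in (overrides or {}).items():
        cfg.setdefault(section, {}).update(values)
    cfg["_echo"] = text
    return cfg


def _detection_params(cfg: dict) -> upstates.DetectionParams:
    d = cfg.get("detect", {})
    return upstates.DetectionParams(
        lowpass_cutoff_hz=d.get("lowpass_cutoff_hz", 0.2),
        threshold_mult=d.get("threshold_mult", 4.0),
        min_duration_s=d.get("min_duration_s", 0.2),
        merge_gap_s=d.get("merge_gap_s", 0.6))


def _stage_upstates(cfg: dict, out: Path, master_seed: int) -> None:
    sec = cfg.get("upstates")
    if not sec or not sec.get("enabled", True):
        return
    seed = stage_seed(master_seed, "upstates")
    params = _detection_params(cfg)
    base = simulate.UpStateSimParams(
        duration_s=sec.get("duration_s", 600.0),
        rate_hz=sec.get("rate_hz", 2500.0),
        event_rate_per_min=sec.get("event_rate_per_min", 2.0),
        dur_mean_s=sec.get("dur_mean_s", 1.5),
        dur_sd_s=sec.get("dur_sd_s", 0.5),
        gain=sec.get("gain", 8.0))
    cohort = simulate.simulate_upstate_cohort(
        n_per_group=sec.get("n_per_group", 6),
        ko_duration_multiplier=sec.get("ko_duration_multiplier", 1.8),
        base=base, seed=seed)
    event_rows, summary_rows = [], []
    for rec, gt in cohort:
        env = upstates.preprocess_envelope(rec, params)
        events = upstates.detect_upstates(env, params)
        log.info("upstates: %s -> %d events (threshold %.3g)",
                 rec.meta["animal_id"], len(events), env.threshold)
        for e in events:
            event_rows.append({"animal_id": rec.meta["animal_id"],
                               "genotype": rec.meta["genotype"],
                               "treatment": rec.meta["treatment"],
                               "start_s": e.start_s, "end_s": e.end_s,
                               "duration_s": e.duration_s,
                               "amplitude": e.amplitude})
        s = upstates.summarize_upstates(events, rec.duration_s)
        summary_rows.append({"animal_id": rec.meta["animal_id"],
                             "genotype": rec.meta["genotype"],
                             "treatment": rec.meta["treatment"],
                             "n_events": s.n_events,
                             "mean_duration_s": s.mean_duration_s,
                             "mean_amplitude": s.mean_amplitude,
                             "freq_per_min": s.freq_per_min})
    write_table(pd.DataFrame(event_rows), out / "upstate_events.csv")
    summary = pd.DataFrame(summary_rows)
    write_table(summary, out / "upstate_summary.csv")

    stat_rows = []
    for measure in ("mean_duration_s", "mean_amplitude", "freq_per_min"):
        if summary["treatment"].nunique() >= 2:
            res = stats.anova_two_way(summary, response=measure)
        else:
            from scipy.stats import ttest_ind
            wt = summary.loc[summary.genotype == "WT", measure].dropna()
            ko = summary.loc[summary.genotype == "KO", measure].dropna()
            t, p = ttest_ind(wt, ko, equal_var=False)
            res = [stats.StatResult(method="welch_t", statistic=float(t),
                                    df=None, p_raw=float(p),
                                    comparison="genotype")]
        for r in res:
            stat_rows.append({"measure": measure, "effect": r.comparison,
                              "method": r.method, "statistic": r.statistic,
                              "p_raw": r.p_raw})
    write_table(pd.DataFrame(stat_rows), out / "upstate_stats.csv")


def _stage_eeg(cfg: dict, out: Path, master_seed: int) -> None:
    sec = cfg.get("eeg")
    if not sec or not sec.get("enabled", True):
        return
    seed = stage_seed(master_seed, "eeg")
    bp = cfg.get("bandpower", {})
    inputs = sec.get("inputs", [])
    frames = []
    if inputs:
        for item in inputs:
            path = Path(item["path"])
            if not path.exists():
                raise PipelineError(f"eeg stage: missing input file {path}")
            rec = read_signal(path, meta=item.get("meta"))
            frames.append(spectral.bandpower_table(
                rec, epoch_len_s=bp.get("epoch_len_s", 10.0),
                artifact_k=bp.get("artifact_k", 6.0),
                window=bp.get("window", "rect")))
    else:
        n = {(g, t): sec.get("n_per_group", 6)
             for g in GENOTYPES for t in sec.get("treatments", ["VEH"])}
        cohort = simulate.simulate_eeg_cohort(
            n_per_group=n, days=sec.get("days", 9),
            genotype_band_multipliers={"KO": sec.get(
                "ko_band_multipliers", {"gamma": 1.5, "delta": 1.3})},
            duration_s=sec.get("duration_s", 300.0),
            rate_hz=sec.get("rate_hz", 500.0), seed=seed)
        for rec, _gt in cohort:
            frames.append(spectral.bandpower_table(
                rec, epoch_len_s=bp.get("epoch_len_s", 10.0),
                artifact_k=bp.get("artifact_k", 6.0),
                window=bp.get("window", "rect")))
    per_epoch = pd.concat(frames, ignore_index=True)
    write_table(per_epoch, out / "bandpower_epochs.csv")
    agg = spectral.aggregate_power(per_epoch)
    write_table(agg, out / "bandpower_9day_average.csv")
    log.info("eeg: %d epochs over %d animals", len(per_epoch),
             agg["animal_id"].nunique())

    stat_rows = []
    for band in ("gamma", "delta"):
        if agg["treatment"].nunique() >= 2:
            res = stats.anova_two_way(agg, response=band)
        else:
            from scipy.stats import ttest_ind
            wt = agg.loc[agg.genotype == "WT", band]
            ko = agg.loc[agg.genotype == "KO", band]
            t, p = ttest_ind(wt, ko, equal_var=False)
            res = [stats.StatResult(method="welch_t", statistic=float(t),
                                    df=None, p_raw=float(p),
                                    comparison="genotype")]
        for r in res:
            stat_rows.append({"band": band, "effect": r.comparison,
                              "method": r.method, "statistic": r.statistic,
                              "p_raw": r.p_raw})
    write_table(pd.DataFrame(stat_rows), out / "eeg_stats.csv")


def _stage_behavior(cfg: dict, out: Path, master_seed: int) -> None:
    sec = cfg.get("behavior")
    if not sec or not sec.get("enabled", True):
        return
    seed = stage_seed(master_seed, "behavior")
    n = sec.get("n_per_group", 15)
    probs = {
        ("KO", "VEH"): sec.get("ko_veh_score_probs", [0.1, 0.1, 0.2, 0.4, 0.2]),
    }
    default_probs = sec.get("default_score_probs", [0.9, 0.1, 0.0, 0.0, 0.0])
    design = simulate.CohortDesign(
        n={(g, t): n for g in GENOTYPES for t in TREATMENTS},
        seizure_score_probs={(g, t): probs.get((g, t), default_probs)
                             for g in GENOTYPES for t in TREATMENTS},
        seed=seed)
    data = simulate.simulate_cohort(design)
    write_table(data, out / "behavior.csv")

    scores = [grp["value"].to_numpy()
              for _, grp in data[data.measure == "seizure_score"]
              .groupby(["genotype", "treatment"], sort=True)]
    kw = stats.kruskal_wallis(scores)
    pw = stats.pairwise_group_comparisons(
        data, "seizure_score", test=cfg.get("stats", {}).get("test", "wilcoxon"),
        seed=stage_seed(master_seed, "behavior_stats"))
    write_table(pw, out / "behavior_pairwise.csv")
    write_table(pd.DataFrame([{"method": kw.method, "statistic": kw.statistic,
                               "df": kw.df[0], "p_raw": kw.p_raw}]),
                out / "behavior_omnibus.csv")
    log.info("behavior: %d animals, KW H=%.3f p=%.3g",
             data["animal_id"].nunique(), kw.statistic, kw.p_raw)


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Execute the configured stages in dependency order.

    Returns the output directory.  Any stage error aborts with a
    :class:`PipelineError` naming the stage.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("run", {}).get("master_seed", 0))

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (out / "config_echo.toml").write_text(
            cfg.get("_echo") or json.dumps(
                {k: v for k, v in cfg.items() if not k.startswith("_")},
                indent=2, default=str))
        log.info("master_seed=%d", master_seed)
        for name, fn in (("upstates", _stage_upstates),
                         ("eeg", _stage_eeg),
                         ("behavior", _stage_behavior)):
            try:
                fn(cfg, out, master_seed)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{name} stage: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
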