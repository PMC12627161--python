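"""Orchestration: predictors -> RSA -> rRSA -> statistics (-> CTS).

Each stage writes its output under the configured ``out_dir``; with
``resume=True`` a stage whose output file already exists is loaded rather
than recomputed, so deleting a downstream artifact and re-running
regenerates only that stage (identically, because every stochastic step
is seeded from the config).  The final report records the config hash,
the seed, and per-stage provenance such as dropped-pair counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig
from .crosstemporal import downsample_epochs, fit_rcts
from .predictors import (
    Lexicon,
    PredictorTable,
    Taxonomy,
    build_predictor_table,
    variance_inflation_factors,
)
from .regression import (
    CONDITIONS,
    ConditionSignals,
    fit_rrsa,
    grand_average,
    predicted_condition_signals,
)
from .rsa import pairwise_rsa_series
from .stats import (
    benjamini_yekutieli,
    chance_level,
    cluster_permutation_test,
    cts_cluster_test,
    detect_windows,
    jackknife_latency_comparison,
    one_sample_t_series,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_table_stage", "signals_stage"]

CONTRASTS = ("word_specific", "semantic", "form")  # each against "unrelated"


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def build_table_stage(config: RunConfig, out_dir: Path) -> PredictorTable:
    path = out_dir / "predictors.tsv"
    if config.resume and path.exists():
        return PredictorTable.from_tsv(path)
    lexicon = Lexicon.from_tsv(config.lexicon)
    if config.taxonomy_edges is not None:
        source = Taxonomy.from_tsv(config.taxonomy_edges, config.taxonomy_wordmap)
    else:
        source = pd.read_csv(config.similarity_matrix, sep="\t", index_col=0)
    table = build_predictor_table(lexicon, source)
    table.to_tsv(path)
    # always consume the persisted (6-decimal) table so resumed and fresh
    # runs see bit-identical designs
    return PredictorTable.from_tsv(path)


def signals_stage(
    config: RunConfig, out_dir: Path, table: PredictorTable
) -> tuple[list[ConditionSignals], dict]:
    path = out_dir / "condition_signals.tsv"
    meta_path = out_dir / "signals_meta.json"
    if config.resume and path.exists() and meta_path.exists():
        return rio.load_condition_signals_tsv(path), json.loads(meta_path.read_text())
    epochs = rio.load_epochs(config.epochs_dir)
    meta: dict = {"participants": {}}
    signals = []
    betas = []
    for tensor in epochs:
        if config.channels:
            tensor = tensor.pick_channels(config.channels)
        series = pairwise_rsa_series(tensor)
        beta = fit_rrsa(series, table, fisher_z=config.fisher_z)
        signals.append(predicted_condition_signals(beta))
        betas.append(beta)
        meta["participants"][tensor.participant_id] = {
            "n_trials": tensor.n_trials,
            "n_pairs": len(series.pairs),
            "n_missing_samples": int(np.isnan(beta.beta[0]).sum()),
        }
    rio.save_condition_signals_tsv(signals, path)
    rio.save_beta_tsv(betas, out_dir / "betas.tsv")
    meta_path.write_text(json.dumps(meta, indent=2))
    return signals, meta


def _stack(signals: list[ConditionSignals]) -> dict[str, np.ndarray]:
    return {
        name: np.stack([s[name] for s in signals]) for name in CONDITIONS
    }


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    return (times >= window[0]) & (times <= window[1])


def stats_stage(
    config: RunConfig, signals: list[ConditionSignals]
) -> dict:
    rng = np.random.default_rng(config.seed)
    mean, times, n = grand_average(signals)
    chance = (
        config.chance_override
        if config.chance_override is not None
        else chance_level(mean)
    )
    stacks = _stack(signals)
    across = np.stack([s.data.mean(axis=0) for s in signals])  # participant avg over conditions
    t_series, p_series = one_sample_t_series(across, chance)
    finite = np.isfinite(p_series)
    p_adj = np.full_like(p_series, np.nan)
    if finite.any():
        p_adj[finite] = benjamini_yekutieli(p_series[finite])
    windows, envelope = detect_windows(p_adj, times, config.alpha)

    report: dict = {
        "n_participants": n,
        "chance_level": chance,
        "detected_windows": [asdict(w) for w in windows],
        "envelope": asdict(envelope) if envelope else None,
        "analysis_windows": [],
    }
    analysis_windows = [tuple(w) for w in config.windows]
    if not analysis_windows and envelope is not None:
        analysis_windows = [(envelope.start_ms, envelope.end_ms)]

    for window in analysis_windows:
        mask = _window_mask(times, window)
        wtimes = times[mask]
        entry: dict = {"window": list(window), "contrasts": {}}
        significant: dict[str, np.ndarray] = {}
        for name in CONTRASTS:
            clusters = cluster_permutation_test(
                stacks[name][:, mask],
                stacks["unrelated"][:, mask],
                threshold_t=config.threshold_t,
                n_perm=config.n_perm,
                seed=rng,
                alpha=config.alpha,
                direction=config.direction,
                times=wtimes,
            )
            entry["contrasts"][name] = [
                {
                    "start_ms": float(wtimes[c.members[0]]),
                    "end_ms": float(wtimes[c.members[-1]]),
                    "mass": c.mass,
                    "max_t": c.max_t,
                    "latency_ms": c.latency_ms,
                    "p_value": c.p_value,
                }
                for c in clusters
            ]
            if any(c.p_value <= config.alpha for c in clusters):
                significant[name] = stacks[name][:, mask]
        entry["latency_comparisons"] = {}
        names = [n_ for n_ in CONTRASTS if n_ in significant]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                result = jackknife_latency_comparison(
                    significant[a],
                    significant[b],
                    stacks["unrelated"][:, mask],
                    threshold_t=config.threshold_t,
                    n_perm=config.n_perm,
                    seed=rng,
                    times=wtimes,
                    direction=config.direction,
                )
                entry["latency_comparisons"][f"{a}_vs_{b}"] = {
                    "latency_a_ms": result.latency_a_ms,
                    "latency_b_ms": result.latency_b_ms,
                    "delta_ms": result.delta_ms,
                    "p_value": result.p_value,
                    "t_corrected": result.t_corrected,
                    "t_uncorrected": result.t_uncorrected,
                    "n_unstable": result.n_unstable,
                }
        report["analysis_windows"].append(entry)
    return report


def cts_stage(config: RunConfig, table: PredictorTable) -> dict:
    rng = np.random.default_rng(config.seed + 1)
    epochs = rio.load_epochs(config.epochs_dir)
    per_condition: dict[str, list[np.ndarray]] = {name: [] for name in CONDITIONS}
    times = None
    for tensor in epochs:
        if config.channels:
            tensor = tensor.pick_channels(config.channels)
        down = downsample_epochs(tensor, config.target_rate)
        rcts = fit_rcts(down, table)
        times = rcts.times
        for name in CONDITIONS:
            per_condition[name].append(rcts[name])
    report: dict = {"target_rate": config.target_rate, "conditions": {}}
    for name in CONDITIONS:
        stack = np.stack(per_condition[name])
        clusters = cts_cluster_test(
            stack,
            mu=0.0,
            threshold_t=config.threshold_t,
            n_perm=config.n_perm,
            seed=rng,
            n_tests=len(CONDITIONS),
            alpha=config.alpha,
            direction=config.direction,
            times=times,
        )
        report["conditions"][name] = [
            {
                "mass": c.mass,
                "max_t": c.max_t,
                "latency_row_ms": c.latency_ms,
                "latency_col_ms": c.latency_col_ms,
                "n_cells": int(c.n_members),
                "p_raw": c.p_raw,
                "p_bonferroni": c.p_value,
            }
            for c in clusters
        ]
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by *config*; returns the report.

    The report (also written to ``<out_dir>/report.json``) contains the
    predictor collinearity check, the chance level, detected windows,
    cluster tables per contrast, jack-knife latency comparisons and, when
    enabled, the cross-temporal cluster tests.
    """
    config.validate(require_inputs=True)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: dict[str, float] = {}

    table = build_table_stage(config, out_dir)
    try:
        vifs = variance_inflation_factors(table)
    except ValueError as exc:  # degenerate toy designs
        vifs = {"error": str(exc)}
    stages["predictors"] = time.time() - t0

    t1 = time.time()
    signals, signals_meta = signals_stage(config, out_dir, table)
    stages["signals"] = time.time() - t1

    t2 = time.time()
    stats_path = out_dir / "stats.json"
    if config.resume and stats_path.exists():
        stats_report = json.loads(stats_path.read_text())
    else:
        stats_report = _jsonable(stats_stage(config, signals))
        stats_path.write_text(json.dumps(stats_report, indent=2, sort_keys=True))
    stages["stats"] = time.time() - t2

    cts_report = None
    if config.run_cts:
        t3 = time.time()
        cts_path = out_dir / "cts_stats.json"
        if config.resume and cts_path.exists():
            cts_report = json.loads(cts_path.read_text())
        else:
            cts_report = _jsonable(cts_stage(config, table))
            cts_path.write_text(json.dumps(cts_report, indent=2, sort_keys=True))
        stages["cts"] = time.time() - t3

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pairs": len(table),
        "vif": _jsonable(vifs if isinstance(vifs, dict) else dict(vifs)),
        "signals_meta": signals_meta,
        "stats": stats_report,
        "cts": cts_report,
    }
    # hash of the scientific content (timings excluded): identical configs
    # must yield identical report hashes
    blob = json.dumps(_jsonable(report), sort_keys=True).encode()
    report["report_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    report["stage_seconds"] = {k: round(v, 3) for k, v in stages.items()}
    (out_dir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True)
    )
    return report
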