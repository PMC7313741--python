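"""End-to-end orchestration: simulate/ingest → preprocess → analyze.

Every run writes its tables, the decoding report and a machine-readable
manifest (config hash, seed, package versions) into the output
directory; a rerun with the same config and seed reproduces the numeric
outputs exactly.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .correlations import aggregate, correlation_table
from .io import (
    read_spike_events,
    read_trial_table,
    save_rate_tensor,
    write_spike_events,
    write_trial_table,
)
from .preprocess import balance_categories, rate_tensor, sparsity_report
from .synthetic import (
    TaskConfig,
    generate_task_sequence,
    make_default_coupling,
    sample_ensemble_activity,
)
from .validation import (
    DecoderConfig,
    causal_cv,
    decoding_error,
    divergent_trajectories,
    make_blocks,
    permutation_test,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "maybe_merge_premature"]


def maybe_merge_premature(labels: np.ndarray, threshold: float) -> np.ndarray:
    """Join the two premature categories when one is too small to decode.

    If the smaller of PC/PL holds fewer trials than ``threshold`` times
    the mean category size, both are relabeled "P" (c drops from 4 to 3)
    so every category keeps a decodable number of observations.
    """
    labels = np.asarray(labels).copy()
    counts = pd.Series(labels).value_counts()
    if "PC" not in counts or "PL" not in counts:
        return labels
    if min(counts["PC"], counts["PL"]) < threshold * counts.mean():
        labels[np.isin(labels, ["PC", "PL"])] = "P"
        logger.info("merged premature categories (c = 3)")
    return labels


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("simulate/ingest")
    if config.spikes_path is None:
        task = TaskConfig(n_trials=config.n_trials, seed=config.seed)
        trials = generate_task_sequence(task)
        coupling = make_default_coupling(n_units=config.n_units)
        spikes, counts = sample_ensemble_activity(
            trials, coupling, bin_ms=40.0, seed=config.seed + 1
        )
        write_trial_table(trials, out / "trials.csv")
        write_spike_events(spikes, out / "spikes.csv")
    else:
        spikes = read_spike_events(config.spikes_path)
        trials = read_trial_table(config.trials_path)
        counts = None
    logger.info("simulate/ingest done in %.1fs", time.time() - t0)

    t0 = _stage("preprocess")
    rt = rate_tensor(
        spikes,
        trials,
        bin_ms=config.bin_ms,
        anchor="poke",
        end_s=config.window_s,
        bandwidths_ms=config.bandwidth_ms,
    )
    if counts is not None:
        sparsity_report(counts, bin_ms=40.0).to_csv(out / "sparsity.csv", index=False)
    labels_all = trials.set_index("trial_id").loc[rt.trial_ids, "category"].to_numpy()
    labels_all = maybe_merge_premature(labels_all, config.merge_premature_threshold)
    rt_bal, labels = balance_categories(
        rt, labels_all, tolerance=config.balance_tolerance, seed=config.seed + 2
    )
    save_rate_tensor(rt_bal, out / "rates")
    logger.info("preprocess done in %.1fs", time.time() - t0)

    t0 = _stage("correlate")
    rt_corr = rate_tensor(
        spikes,
        trials,
        bin_ms=config.corr_bin_ms,
        anchor="poke",
        end_s=min(config.window_s, 1.0),
        bandwidths_ms=config.bandwidth_ms,
    )
    corr_frames = []
    for theta in (2, 3):
        for cat in np.unique(labels_all):
            subset = np.flatnonzero(labels_all == cat)
            if subset.size < 3:
                continue
            corr_frames.append(
                correlation_table(rt_corr, theta, subset, kind="raw", condition=cat)
            )
    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(out / "correlations.csv", index=False)
    aggregate(corr, mode="abs", over="bins").to_csv(out / "correlation_aggregates.csv", index=False)
    logger.info("correlate done in %.1fs", time.time() - t0)

    t0 = _stage("decode/validate")
    scheme = make_blocks(rt_bal.n_trials, block_size=min(config.block_size, rt_bal.n_trials // 2))
    reports = []
    for theta in config.thetas:
        dconf = DecoderConfig(
            theta=theta,
            lambda_grid=np.linspace(0.0, 0.5, config.lambda_grid_size),
            fixed_lambda=config.fixed_lambda,
            zscore=config.zscore,
            seed=config.seed + 3,
        )
        pred = causal_cv(rt_bal, labels, scheme, dconf)
        de = decoding_error(pred).assign(theta=theta)
        dt = divergent_trajectories(pred).assign(theta=theta)
        reports.append(de.merge(dt[["category", "DT", "mean_r_max"]], on="category"))
    report = pd.concat(reports, ignore_index=True)
    report.to_csv(out / "decoding_report.csv", index=False)
    logger.info("decode/validate done in %.1fs", time.time() - t0)

    if config.n_permutations > 0:
        t0 = _stage("permtest")
        dconf = DecoderConfig(
            theta=config.thetas[-1],
            lambda_grid=np.linspace(0.0, 0.5, config.lambda_grid_size),
            fixed_lambda=config.fixed_lambda if config.fixed_lambda is not None else 0.1,
            zscore=config.zscore,
        )
        perm = permutation_test(
            rt_bal, labels, scheme, dconf, n_perm=config.n_permutations, seed=config.seed + 4
        )
        summary = {
            k: {kk: vv for kk, vv in v.items() if kk != "null"}
            for k, v in perm.items()
            if isinstance(v, dict)
        }
        (out / "permutation.json").write_text(json.dumps(summary, indent=2))
        logger.info("permtest done in %.1fs", time.time() - t0)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {"spikespace": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
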