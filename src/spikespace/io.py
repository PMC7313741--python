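"""Columnar text I/O for spike events, trial tables, tensors and models.

Spike events and trial tables travel as headered CSV so fixtures stay
diffable; rate tensors and fitted decoders are written as ``.npy``
arrays with a JSON sidecar holding their metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RateTensor
from .synthetic import CATEGORIES, LONG_ITIS, SHORT_ITIS

logger = logging.getLogger(__name__)

__all__ = [
    "read_spike_events",
    "write_spike_events",
    "read_trial_table",
    "write_trial_table",
    "save_rate_tensor",
    "load_rate_tensor",
]

SPIKE_COLUMNS = ["unit_id", "spike_time_s"]
TRIAL_COLUMNS = [
    "trial_id",
    "t_central_poke_s",
    "t_T1_s",
    "t_T2_s",
    "t_lateral_poke_s",
    "iti_ms",
    "stimulus",
    "category",
    "predictable",
]


def write_spike_events(events: pd.DataFrame, path: str | Path) -> None:
    events[SPIKE_COLUMNS].to_csv(path, index=False)


def read_spike_events(path: str | Path) -> pd.DataFrame:
    """Validated, per-unit time-sorted spike-event table.

    Non-monotone rows are sorted with a warning; duplicate (unit, time)
    rows are deduplicated with a warning; malformed rows raise with
    their line number.
    """
    df = pd.read_csv(path)
    if list(df.columns) != SPIKE_COLUMNS:
        raise ValueError(f"{path}: expected header {','.join(SPIKE_COLUMNS)}")
    bad = df[df["spike_time_s"].isna() | df["unit_id"].isna()]
    if not bad.empty:
        raise ValueError(f"{path}: malformed row at line {bad.index[0] + 2}")
    df["unit_id"] = df["unit_id"].astype(int)
    df["spike_time_s"] = df["spike_time_s"].astype(float)
    sorted_df = df.sort_values(SPIKE_COLUMNS, kind="mergesort", ignore_index=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        logger.warning("%s: spike times not sorted; sorting", path)
    dup = sorted_df.duplicated()
    if dup.any():
        logger.warning("%s: dropping %d duplicate (unit, time) rows", path, dup.sum())
        sorted_df = sorted_df[~dup].reset_index(drop=True)
    return sorted_df


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.6f")


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Validated trial table; predictability cross-checked, lose-switch QC'd.

    The predictable flag is recomputed from the category sequence and
    must match the stored column (validation error listing trial ids
    otherwise).  A lose-switch violation — the inter-tone interval not
    repeated after a non-correct trial — only warns, since real data may
    deviate, and is recorded in the ``lose_switch_ok`` attribute.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_COLUMNS:
        raise ValueError(f"{path}: expected header {','.join(TRIAL_COLUMNS)}")
    unknown = ~df["category"].isin(CATEGORIES)
    if unknown.any():
        row = df.index[unknown][0]
        raise ValueError(
            f"{path}: unknown category {df.loc[row, 'category']!r} at row {row}"
        )
    legal = set(SHORT_ITIS) | set(LONG_ITIS)
    bad_iti = ~df["iti_ms"].isin(legal)
    if bad_iti.any():
        raise ValueError(
            f"{path}: illegal ITI values {sorted(df.loc[bad_iti, 'iti_ms'].unique())}"
        )
    df["predictable"] = df["predictable"].astype(int)

    cats = df["category"].to_numpy()
    expected = np.zeros(len(df), dtype=int)
    expected[1:] = (cats[:-1] != "C").astype(int)
    mismatch = df["predictable"].to_numpy() != expected
    if mismatch.any():
        raise ValueError(
            f"{path}: stored predictable flag contradicts categories for "
            f"trial ids {df.loc[mismatch, 'trial_id'].tolist()}"
        )
    itis = df["iti_ms"].to_numpy()
    violations = (cats[:-1] != "C") & (itis[1:] != itis[:-1])
    ok = not violations.any()
    if not ok:
        logger.warning(
            "%s: lose-switch rule violated after trials %s",
            path,
            df["trial_id"].to_numpy()[:-1][violations].tolist(),
        )
    df.attrs["lose_switch_ok"] = ok
    return df


def save_rate_tensor(rt: RateTensor, stem: str | Path) -> None:
    """Write ``<stem>.npy`` (values) and ``<stem>.json`` (metadata)."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), rt.values)
    meta = {
        "bin_ms": rt.bin_ms,
        "anchor": rt.anchor,
        "anchor_times": rt.anchor_times.tolist(),
        "unit_ids": rt.unit_ids.tolist(),
        "trial_ids": rt.trial_ids.tolist(),
        "start_s": rt.start_s,
        "zscored": rt.zscored,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta))


def load_rate_tensor(stem: str | Path) -> RateTensor:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return RateTensor(
        values=np.load(stem.with_suffix(".npy")),
        bin_ms=meta["bin_ms"],
        anchor=meta["anchor"],
        anchor_times=np.asarray(meta["anchor_times"]),
        unit_ids=np.asarray(meta["unit_ids"]),
        trial_ids=np.asarray(meta["trial_ids"]),
        start_s=meta["start_s"],
        zscored=meta["zscored"],
    )
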