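"""Spike events to smoothed, binned, aligned, balanced rate tensors.

Raw spike times are convolved with per-unit Gaussian kernels (bandwidth
chosen by a mean-integrated-squared-error cross-validation cost), the
resulting densities are integrated over 40 or 80 ms bins on a per-trial
grid anchored at a behavioral event, and the trials axis can then be
z-scored and balanced across response categories before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "RateTensor",
    "ANCHOR_COLUMNS",
    "optimize_bandwidth",
    "rate_tensor",
    "zscore",
    "balance_categories",
    "extract_periods",
    "sparsity_report",
]

#: anchor aliases accepted by :func:`rate_tensor`
ANCHOR_COLUMNS = {
    "poke": "t_central_poke_s",
    "T1": "t_T1_s",
    "T2": "t_T2_s",
    "lateral": "t_lateral_poke_s",
}

DEFAULT_BANDWIDTH_MS = 100.0
BANDWIDTH_RANGE_MS = (5.0, 500.0)


@dataclass
class RateTensor:
    """Smoothed, binned firing rates: units × bins × trials.

    ``values`` are in Hz (dimensionless after z-scoring); ``anchor_times``
    gives the per-trial time of the alignment event, and bin ``b`` covers
    ``[anchor + start_s + b*bin_ms, … + (b+1)*bin_ms)`` in session time.
    """

    values: np.ndarray
    bin_ms: float
    anchor: str
    anchor_times: np.ndarray
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    start_s: float = 0.0
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (units, bins, trials)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.unit_ids = np.asarray(self.unit_ids)
        self.trial_ids = np.asarray(self.trial_ids)
        self.anchor_times = np.asarray(self.anchor_times, dtype=float)
        if np.any(np.diff(self.trial_ids) < 0):
            raise ValueError("trials axis must be ordered by trial_id")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    def subset_trials(self, index: np.ndarray) -> "RateTensor":
        """Tensor restricted to the given positions along the trials axis."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, :, index],
            anchor_times=self.anchor_times[index],
            trial_ids=self.trial_ids[index],
        )

    def subset_units(self, index: np.ndarray) -> "RateTensor":
        index = np.asarray(index)
        return replace(self, values=self.values[index], unit_ids=self.unit_ids[index])


def _mise_cost(spikes: np.ndarray, w_s: float) -> float:
    """Leave-one-out MISE cost of a Gaussian kernel rate estimate.

    For kernel density f̂_w, the cross-validated integrated squared error
    (up to data-independent terms) is  ∫f̂² − 2/(n−1)·Σ_{i≠j}k_w(t_i−t_j),
    with ∫ k_w(·−t_i) k_w(·−t_j) = k_{w√2}(t_i − t_j) for Gaussians.
    """
    d = spikes[:, None] - spikes[None, :]
    n = len(spikes)
    k2 = np.exp(-(d**2) / (4 * w_s**2)) / (2 * np.sqrt(np.pi) * w_s)
    k1 = np.exp(-(d**2) / (2 * w_s**2)) / (np.sqrt(2 * np.pi) * w_s)
    off = ~np.eye(n, dtype=bool)
    return float(k2.sum() / n**2 - 2.0 * k1[off].sum() / (n * (n - 1)))


def optimize_bandwidth(
    spike_times: np.ndarray,
    default_ms: float = DEFAULT_BANDWIDTH_MS,
    bounds_ms: tuple[float, float] = BANDWIDTH_RANGE_MS,
    max_spikes: int = 5000,
    seed: int = 0,
) -> float:
    """Optimal Gaussian smoothing bandwidth (ms) for one unit's spikes.

    Minimizes the MISE-style cross-validation cost by bounded
    golden-section search over ``bounds_ms``.  Units with fewer than 10
    spikes fall back to ``default_ms`` with a logged warning; very long
    trains are subsampled to ``max_spikes`` for the O(n²) cost.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if t.size < 10:
        logger.warning(
            "only %d spikes: falling back to default bandwidth %.0f ms",
            t.size,
            default_ms,
        )
        return float(default_ms)
    if t.size > max_spikes:
        rng = np.random.default_rng(seed)
        t = np.sort(rng.choice(t, size=max_spikes, replace=False))
    res = minimize_scalar(
        lambda w_ms: _mise_cost(t, w_ms / 1000.0),
        bounds=(bounds_ms[0], bounds_ms[1]),
        method="bounded",
        options={"xatol": 0.5},
    )
    return float(res.x)


def _trial_end_times(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial end proxy: 150 ms past the last recorded event."""
    ev = trials[["t_central_poke_s", "t_T1_s", "t_T2_s", "t_lateral_poke_s"]]
    return np.nanmax(ev.to_numpy(dtype=float), axis=1) + 0.15


def rate_tensor(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    bin_ms: float = 40.0,
    anchor: str = "poke",
    start_s: float = 0.0,
    end_s: float | None = None,
    bandwidths_ms: dict | float | None = None,
) -> RateTensor:
    """Gaussian-smoothed spike densities binned on per-trial anchored grids.

    Each trial's grid starts at ``anchor + start_s`` and ends at
    ``anchor + end_s``; with ``end_s=None`` the end is the shortest
    retained trial span (anchor to 150 ms past its last event), so all
    trials share the bin count.  The density integral over each bin,
    divided by the bin width, gives the rate in Hz; this conserves spike
    mass exactly for the Gaussian kernel.

    ``bandwidths_ms`` may be a per-unit dict, a scalar, or None to
    optimize per unit from the pooled train.
    """
    col = ANCHOR_COLUMNS.get(anchor, anchor)
    if col not in trials.columns:
        raise ValueError(f"anchor column {col!r} not in trial table")
    anchors = trials[col].to_numpy(dtype=float)
    keep = np.isfinite(anchors)
    if not keep.all():
        logger.info(
            "dropping %d trials lacking anchor %s: %s",
            (~keep).sum(),
            anchor,
            trials.loc[~keep, "trial_id"].tolist(),
        )
    kept = trials.loc[keep].reset_index(drop=True)
    anchors = anchors[keep]

    if end_s is None:
        spans = _trial_end_times(kept) - anchors
        end_s = float(np.min(spans))
    if (end_s - start_s) < bin_ms / 1000.0:
        raise ValueError("window shorter than one bin")
    n_bins = int(np.floor((end_s - start_s) / (bin_ms / 1000.0)))

    unit_ids = np.sort(spikes["unit_id"].unique())
    bw: dict = {}
    for u in unit_ids:
        t_u = spikes.loc[spikes["unit_id"] == u, "spike_time_s"].to_numpy()
        if bandwidths_ms is None:
            bw[u] = optimize_bandwidth(t_u)
        elif np.isscalar(bandwidths_ms):
            bw[u] = float(bandwidths_ms)
        else:
            bw[u] = float(bandwidths_ms[u])

    bin_s = bin_ms / 1000.0
    edges = start_s + bin_s * np.arange(n_bins + 1)
    values = np.zeros((len(unit_ids), n_bins, len(kept)))
    for ui, u in enumerate(unit_ids):
        t_u = spikes.loc[spikes["unit_id"] == u, "spike_time_s"].to_numpy(dtype=float)
        w = bw[u] / 1000.0
        for ti, a in enumerate(anchors):
            rel = t_u - a
            near = t_u[(rel > start_s - 6 * w) & (rel < end_s + 6 * w)] - a
            if near.size == 0:
                continue
            # integral of each spike's Gaussian over each bin
            cdf = ndtr((edges[:, None] - near[None, :]) / w)
            values[ui, :, ti] = np.diff(cdf, axis=0).sum(axis=1) / bin_s
    return RateTensor(
        values=values,
        bin_ms=bin_ms,
        anchor=anchor,
        anchor_times=anchors,
        unit_ids=unit_ids,
        trial_ids=kept["trial_id"].to_numpy(),
        start_s=start_s,
    )


def zscore(
    rt: RateTensor,
    fit_trials: np.ndarray | None = None,
    params: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[RateTensor, tuple[np.ndarray, np.ndarray]]:
    """Per-unit standardization; parameters from ``fit_trials`` only.

    Means and standard deviations are estimated over bins × scoping
    trials (all trials by default) and applied to the whole tensor, so a
    held-out test set is transformed with estimation-set parameters and
    need not have mean 0 itself.  Returns the transformed tensor and the
    ``(mean, sd)`` parameters; pass ``params`` to reuse a previous fit.
    Zero-variance units are dropped with a warning.
    """
    if params is None:
        scope = rt.values if fit_trials is None else rt.values[:, :, np.asarray(fit_trials)]
        mean = scope.mean(axis=(1, 2))
        sd = scope.std(axis=(1, 2))
    else:
        mean, sd = params
    ok = sd > 1e-12 * np.maximum(np.abs(mean), 1.0)  # constant up to rounding
    if not ok.all():
        logger.warning("dropping zero-variance units: %s", rt.unit_ids[~ok].tolist())
    values = (rt.values[ok] - mean[ok, None, None]) / sd[ok, None, None]
    out = replace(rt, values=values, unit_ids=rt.unit_ids[ok], zscored=True)
    return out, (mean[ok], sd[ok])


def balance_categories(
    rt: RateTensor,
    labels: np.ndarray,
    tolerance: float = 0.10,
    seed: int = 0,
) -> tuple[RateTensor, np.ndarray]:
    """Equalize per-category trial (hence bin) counts to within ``tolerance``.

    Whole trials are discarded by seeded uniform sampling without
    replacement until every category holds at most ``(1 + tolerance)``
    times the smallest category's count; the smallest category is never
    reduced.  Keeping trials intact preserves trajectories for the
    decoder.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != rt.n_trials:
        raise ValueError("labels must have one entry per trial")
    cats, counts = np.unique(labels, return_counts=True)
    if len(cats) < 2:
        raise ValueError("need at least two categories to balance")
    for c, k in zip(cats, counts):
        if k == 0:
            raise ValueError(f"category {c!r} is empty")
    cap = int(np.floor(counts.min() * (1.0 + tolerance)))
    rng = np.random.default_rng(seed)
    keep = np.zeros(rt.n_trials, dtype=bool)
    for c in cats:
        idx = np.flatnonzero(labels == c)
        if len(idx) > cap:
            idx = np.sort(rng.choice(idx, size=cap, replace=False))
        keep[idx] = True
    index = np.flatnonzero(keep)
    return rt.subset_trials(index), labels[index]


def extract_periods(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial 150 ms windows of the three within-trial periods.

    initiation = [central poke, +150 ms]; stimulus_offset = [second tone
    onset − 100 ms, +50 ms] (absent on premature-central trials, which
    lack the second tone); choice = [lateral poke, +150 ms] (absent
    without a side poke).  Times are NaN where the anchor is absent.
    """
    poke = trials["t_central_poke_s"].to_numpy(dtype=float)
    t2 = trials["t_T2_s"].to_numpy(dtype=float)
    lat = trials["t_lateral_poke_s"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "initiation_start": poke,
            "initiation_end": poke + 0.150,
            "stimulus_offset_start": t2 - 0.100,
            "stimulus_offset_end": t2 + 0.050,
            "choice_start": lat,
            "choice_end": lat + 0.150,
        }
    )


def sparsity_report(counts: np.ndarray, bin_ms: float = 40.0) -> pd.DataFrame:
    """Fraction of bins with ≤ 1 spike per unit, with a QC flag.

    The binary-word analyses assume near-binary bins: at 40 ms every
    unit should have at least 99 % of bins carrying at most one spike.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be integer")
    frac = (counts <= 1).reshape(counts.shape[0], -1).mean(axis=1)
    qc = frac >= 0.99 if bin_ms <= 40.0 else np.ones_like(frac, dtype=bool)
    if bin_ms <= 40.0 and not qc.all():
        logger.warning("units below 99%% single-spike bins: %s", np.flatnonzero(~qc).tolist())
    return pd.DataFrame({"unit": np.arange(counts.shape[0]), "fraction_le1": frac, "qc_pass": qc})
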