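"""θ-order trial-to-trial correlation coefficients.

The pairwise Pearson noise correlation generalizes to order θ: for an
exponent vector m = (m_1 … m_n) with Σ m_i = θ and every m_i ≤ θ − 1
(so at least two units interact), the coefficient at time bin t is

    Corr(m; θ)(t) = Σ_T Π_i (x_i(t,T) − <x_i(t)>)^{m_i}
                    / Π_i ( Σ_T |x_i(t,T) − <x_i(t)>|^θ )^{m_i/θ},

with <x_i(t)> the trial average within the conditioning trial subset
(trial averages are outcome-specific, so these are "noise decision
correlations").  The denominator uses absolute central moments: the
plain power form is not real-valued for odd θ on sign-indefinite data,
while the absolute form is always real and bounds the coefficient in
[−1, 1] by Hölder's inequality.  Degenerate (zero) denominators yield
NaN and are excluded from aggregates rather than counted as zero.

Partial coefficients apply the same estimator to residuals of a per
(unit, bin) linear regression on the same bin of the preceding trial,
removing slow across-trial drift shared with the previous trial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RateTensor

__all__ = [
    "enumerate_exponent_vectors",
    "theta_correlation",
    "theta_coefficient_1bin",
    "RegressionFit",
    "regress_previous_trial",
    "partial_theta_correlation",
    "correlation_table",
    "aggregate",
    "differential_correlation",
]


def enumerate_exponent_vectors(n: int, theta: int) -> list[tuple[int, ...]]:
    """All exponent vectors of an order-θ coefficient over n units.

    Vectors m with Σ m_i = θ and m_i ∈ {0, …, θ−1}, lexicographically
    sorted.  For θ = 2 the count is n(n−1)/2 (one per unit pair); the
    cap m_i ≤ θ−1 excludes self-moments, so at least two entries are
    nonzero and every coefficient mixes at least two units.
    """
    if theta < 1 or n < 1:
        return []
    out = [
        m
        for m in itertools.product(range(theta), repeat=n)
        if sum(m) == theta
    ]
    out.sort()
    return out


def _centered(values: np.ndarray) -> np.ndarray:
    return values - values.mean(axis=-1, keepdims=True)


def theta_coefficient_1bin(values: np.ndarray, m: tuple[int, ...], theta: int) -> float:
    """Coefficient for a single bin from a (units, trials) slice."""
    m_arr = np.asarray(m, dtype=float)
    c = _centered(np.asarray(values, dtype=float))
    num = np.prod(c ** m_arr[:, None], axis=0).sum()
    moments = np.sum(np.abs(c) ** theta, axis=1)
    den = np.prod(moments ** (m_arr / theta))
    if den == 0.0:
        return np.nan
    return float(num / den)


def theta_correlation(
    rt: RateTensor | np.ndarray,
    m: tuple[int, ...],
    trial_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin order-θ coefficient for one exponent vector.

    ``rt`` is a RateTensor or a bare (units, bins, trials) array;
    ``trial_subset`` selects positions along the trials axis (the
    conditioning set whose trial averages center the data).  Returns one
    value per bin, NaN where a needed absolute moment vanishes (e.g. a
    unit constant across trials).
    """
    values = rt.values if isinstance(rt, RateTensor) else np.asarray(rt, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected (units, bins, trials)")
    if len(m) != values.shape[0]:
        raise ValueError("exponent vector length must equal the unit count")
    theta = int(sum(m))
    if any(mi < 0 or mi > theta - 1 for mi in m):
        raise ValueError("exponents must lie in {0, ..., theta-1}")
    if trial_subset is not None:
        values = values[:, :, np.asarray(trial_subset)]
    if values.shape[2] < 3:
        raise ValueError("need at least 3 trials")

    m_arr = np.asarray(m, dtype=float)
    c = values - values.mean(axis=2, keepdims=True)
    num = np.prod(c ** m_arr[:, None, None], axis=0).sum(axis=1)
    moments = np.sum(np.abs(c) ** theta, axis=2)  # units × bins
    den = np.prod(moments ** (m_arr[:, None] / theta), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0.0] = np.nan
    return out


@dataclass
class RegressionFit:
    """Per (unit, bin) OLS of the rate on the previous trial's rate."""

    b0: np.ndarray  # units × bins intercepts
    b1: np.ndarray  # units × bins slopes
    residuals: np.ndarray  # units × bins × (trials − 1)
    trial_ids: np.ndarray  # ids of the retained (current) trials


def regress_previous_trial(rt: RateTensor | np.ndarray) -> RegressionFit:
    """Least-squares adjustment of each rate on the preceding trial.

    For every unit and bin, fits x(t, T) = b1·x(t, T−1) + b0 across the
    consecutive-trial pairs and returns the residual tensor (one fewer
    trial; the first trial has no predecessor).  Constant predictors get
    b1 = 0, b0 = mean (residuals then carry the raw centered values).
    """
    values = rt.values if isinstance(rt, RateTensor) else np.asarray(rt, dtype=float)
    if values.shape[2] < 4:
        raise ValueError("need at least 3 consecutive trial pairs")
    x_prev = values[:, :, :-1]
    x_curr = values[:, :, 1:]
    mp = x_prev.mean(axis=2, keepdims=True)
    mc = x_curr.mean(axis=2, keepdims=True)
    cov = ((x_prev - mp) * (x_curr - mc)).mean(axis=2)
    var = ((x_prev - mp) ** 2).mean(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    b0 = mc[:, :, 0] - b1 * mp[:, :, 0]
    residuals = x_curr - (b1[:, :, None] * x_prev + b0[:, :, None])
    trial_ids = (
        rt.trial_ids[1:] if isinstance(rt, RateTensor) else np.arange(1, values.shape[2] + 0)
    )
    return RegressionFit(b0=b0, b1=b1, residuals=residuals, trial_ids=trial_ids)


def partial_theta_correlation(
    rt: RateTensor | np.ndarray,
    m: tuple[int, ...],
    trial_subset: np.ndarray | None = None,
) -> np.ndarray:
    """θ-order coefficient on previous-trial-regressed residuals.

    The regression is fit on all consecutive pairs of the tensor;
    ``trial_subset`` (positions in the residual tensor's trial axis)
    selects the conditioning set afterwards, mirroring
    :func:`theta_correlation`.
    """
    fit = regress_previous_trial(rt)
    return theta_correlation(fit.residuals, m, trial_subset)


def correlation_table(
    rt: RateTensor | np.ndarray,
    theta: int,
    trial_subset: np.ndarray | None = None,
    kind: str = "raw",
    condition: str = "",
) -> pd.DataFrame:
    """All order-θ coefficients of a tensor as a tidy table.

    Columns: ``order, exponent_vector, bin, condition, kind, value``.
    """
    values = rt.values if isinstance(rt, RateTensor) else np.asarray(rt, dtype=float)
    n = values.shape[0]
    func = theta_correlation if kind == "raw" else partial_theta_correlation
    rows = []
    for m in enumerate_exponent_vectors(n, theta):
        per_bin = func(rt, m, trial_subset)
        for b, v in enumerate(per_bin):
            rows.append(
                {
                    "order": theta,
                    "exponent_vector": m,
                    "bin": b,
                    "condition": condition,
                    "kind": kind,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


def aggregate(table: pd.DataFrame, mode: str = "abs", over: str = "bins") -> pd.DataFrame:
    """Summaries of a coefficient table, excluding undefined entries.

    ``mode``: "abs" averages |value|; "positive"/"negative" average the
    strictly positive/negative values only and report their fraction of
    the defined entries.  ``over`` names the grouping: "bins" groups by
    exponent vector (averaging across bins), "coefficients" by bin,
    "period"/"ensembles" pool everything.
    """
    if mode not in {"abs", "positive", "negative"}:
        raise ValueError("mode must be abs, positive or negative")
    t = table.dropna(subset=["value"])
    if t.empty:
        raise ValueError("all coefficient values are undefined")
    groups = {
        "bins": ["order", "condition", "kind", "exponent_vector"],
        "coefficients": ["order", "condition", "kind", "bin"],
        "period": ["order", "condition", "kind"],
        "ensembles": ["order", "condition", "kind"],
    }[over]

    def _summary(g: pd.DataFrame) -> pd.Series:
        v = g["value"].to_numpy()
        if mode == "abs":
            sel = np.abs(v)
            return pd.Series({"mean": sel.mean() if sel.size else np.nan, "n": sel.size})
        sel = v[v > 0] if mode == "positive" else v[v < 0]
        return pd.Series(
            {
                "mean": sel.mean() if sel.size else np.nan,
                "n": sel.size,
                "fraction": sel.size / v.size if v.size else np.nan,
            }
        )

    out = t.groupby(groups, sort=True).apply(_summary, include_groups=False).reset_index()
    return out


def differential_correlation(
    table_correct: pd.DataFrame,
    table_incorrect: pd.DataFrame,
) -> pd.DataFrame:
    """Differential correlation index between correct and incorrect trials.

    Per exponent vector j: δ+ is the mean of the strictly positive
    coefficient values on correct trials minus the same on incorrect
    trials; δ− likewise for strictly negative values; Δδ = δ+ − δ−.
    A class with no values of the requested sign contributes 0 to its
    delta, so a purely positive contrast gives Δδ = δ+ exactly.
    Both inputs must cover the same period/condition.
    """
    if table_correct.empty or table_incorrect.empty:
        raise ValueError("both correct- and incorrect-trial tables are required")

    def signed_mean(table: pd.DataFrame, positive: bool) -> pd.Series:
        t = table.dropna(subset=["value"])
        sel = t[t["value"] > 0] if positive else t[t["value"] < 0]
        means = sel.groupby("exponent_vector")["value"].mean()
        return means

    vectors = sorted(
        set(table_correct["exponent_vector"]) | set(table_incorrect["exponent_vector"])
    )
    rows = []
    for m in vectors:
        dplus = signed_mean(table_correct, True).get(m, 0.0) - signed_mean(
            table_incorrect, True
        ).get(m, 0.0)
        dminus = signed_mean(table_correct, False).get(m, 0.0) - signed_mean(
            table_incorrect, False
        ).get(m, 0.0)
        rows.append(
            {
                "exponent_vector": m,
                "delta_plus": dplus,
                "delta_minus": dminus,
                "delta_diff": dplus - dminus,
            }
        )
    return pd.DataFrame(rows)
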