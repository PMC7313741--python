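"""Causal cross-validation, decoding indexes and permutation nulls.

Decoding reliability is always evaluated *forward in time*: trials are
cut into consecutive blocks (40 trials by default), the discriminant is
fit on one block — including z-scoring and λ selection, which never see
the future — and applied frozen to every strictly later block.  With 4
blocks this yields the six folds (1,2) (1,3) (1,4) (2,3) (2,4) (3,4).

Two indexes summarize a fold: DE, the per-category fraction of
misclassified test trials (majority vote over a trial's bins, ties
counted as errors), and DT, the per-category fraction of trials whose
state-space trajectory *ends* misclassified (a divergent trajectory is
one whose last r + 1 ≥ 1 bins are all misclassified, which holds iff the
final bin is).  Chance level for a uniformly random decoder over c
balanced categories is DE = 1 − 1/c (75 % at c = 4).

Significance is assessed against a null built by shuffling the bin
order independently for each neuron within each trial — destroying
within-trial coordination while preserving every bin-value multiset —
and re-running the entire causally cross-validated pipeline on each of
the n resamples; the one-tailed p-value floor is 1/n (0.001 at the
customary n = 1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoder import (
    classify,
    fit_kernel_discriminant,
    gram_matrix,
    majority_vote,
    observations_from_tensor,
    select_lambda,
)
from .preprocess import RateTensor, zscore

logger = logging.getLogger(__name__)

__all__ = [
    "BlockScheme",
    "DecoderConfig",
    "make_blocks",
    "causal_cv",
    "decoding_error",
    "divergent_trajectories",
    "permutation_test",
    "permutation_p",
    "shuffle_bins_within_trials",
    "split_predictability",
    "predictability_decoding",
]


@dataclass
class BlockScheme:
    """Ordered partition of trials into consecutive blocks, plus folds."""

    blocks: list[np.ndarray]  # trial positions per block, time-ordered
    folds: list[tuple[int, int]]  # (train_block, test_block), test later

    def __post_init__(self) -> None:
        for tr, te in self.folds:
            if te <= tr:
                raise ValueError("every fold must test strictly later than it trains")


@dataclass
class DecoderConfig:
    """Decoding options shared by all validation entry points."""

    theta: int = 3
    lambda_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.5, 11))
    fixed_lambda: float | None = None  # bypass grid selection when set
    zscore: bool = True
    seed: int = 0


def make_blocks(n_trials: int, block_size: int = 40) -> BlockScheme:
    """Consecutive non-overlapping blocks and all strictly-later fold pairs.

    A trailing partial block is dropped with a warning.  160 trials at
    the default size give 4 blocks and 6 folds.
    """
    n_blocks = n_trials // block_size
    if n_blocks < 2:
        raise ValueError("need at least 2 full blocks")
    dropped = n_trials - n_blocks * block_size
    if dropped:
        logger.warning("dropping trailing partial block of %d trials", dropped)
    blocks = [np.arange(k * block_size, (k + 1) * block_size) for k in range(n_blocks)]
    folds = [(i, j) for i in range(n_blocks) for j in range(i + 1, n_blocks)]
    return BlockScheme(blocks=blocks, folds=folds)


def _fit_on_block(rt: RateTensor, labels, idx, config: DecoderConfig):
    sub = rt.subset_trials(idx)
    y_trials = np.asarray(labels)[idx]
    if config.zscore:
        sub, zparams = zscore(sub)
    else:
        zparams = None
    X, y, groups = observations_from_tensor(sub, y_trials)
    if config.fixed_lambda is not None:
        lam = float(config.fixed_lambda)
    else:
        lam = select_lambda(X, y, groups, config.theta, config.lambda_grid)
    K = gram_matrix(X, X, config.theta)
    model = fit_kernel_discriminant(K, y, lam, theta=config.theta, X_train=X)
    return model, zparams, sub


def causal_cv(
    rt: RateTensor,
    labels: np.ndarray,
    scheme: BlockScheme,
    config: DecoderConfig | None = None,
) -> pd.DataFrame:
    """Fit on each block, decode every strictly later block.

    Returns a per-bin prediction table with columns ``fold, train_block,
    test_block, trial, bin, true, pred``; trials are identified by their
    position in the tensor.  Folds whose training block misses a
    category are skipped with a warning.
    """
    config = config or DecoderConfig()
    labels = np.asarray(labels)
    n_cats = len(np.unique(labels))
    records = []
    models: dict[int, tuple] = {}
    for fi, (tr, te) in enumerate(scheme.folds):
        y_train = labels[scheme.blocks[tr]]
        if len(np.unique(y_train)) < n_cats:
            logger.warning("fold %d skipped: training block %d misses a category", fi, tr)
            continue
        if tr not in models:
            models[tr] = _fit_on_block(rt, labels, scheme.blocks[tr], config)
        model, zparams, _ = models[tr]
        test_idx = scheme.blocks[te]
        sub = rt.subset_trials(test_idx)
        if zparams is not None:
            sub, _ = zscore(sub, params=zparams)
        X, _, groups = observations_from_tensor(sub, labels[test_idx])
        K_new = gram_matrix(X, model.X_train, config.theta)
        pred, _post = classify(model, K_new @ model.A)
        n_bins = sub.n_bins
        records.append(
            pd.DataFrame(
                {
                    "fold": fi,
                    "train_block": tr,
                    "test_block": te,
                    "trial": test_idx[groups],
                    "bin": np.tile(np.arange(n_bins), len(test_idx)),
                    "true": labels[test_idx][groups],
                    "pred": pred,
                }
            )
        )
    if not records:
        raise ValueError("no usable folds (categories missing from every block)")
    return pd.concat(records, ignore_index=True)


def _per_trial(predictions: pd.DataFrame) -> pd.DataFrame:
    """Trial-level majority vote per fold from the bin table."""
    rows = []
    for (fold, trial), sub in predictions.groupby(["fold", "trial"], sort=True):
        vote = majority_vote(sub["pred"].to_numpy(), np.zeros(len(sub), dtype=int))
        last = sub.sort_values("bin").iloc[-1]
        wrong_run = 0
        for _, row in sub.sort_values("bin", ascending=False).iterrows():
            if row["pred"] != row["true"]:
                wrong_run += 1
            else:
                break
        rows.append(
            {
                "fold": fold,
                "trial": trial,
                "true": sub["true"].iloc[0],
                "prediction": vote["prediction"].iloc[0],
                "tie": bool(vote["tie"].iloc[0]),
                "final_bin_wrong": bool(last["pred"] != last["true"]),
                "r_max": wrong_run - 1,  # terminal misclassified run length − 1
            }
        )
    return pd.DataFrame(rows)


def decoding_error(predictions: pd.DataFrame) -> pd.DataFrame:
    """DE per category: misclassified-trial fraction, averaged over folds.

    Also reports the per-bin error rate per category.  A trial counts as
    misclassified when its bin-majority label differs from the truth or
    the vote is tied.
    """
    if predictions.empty:
        raise ValueError("empty predictions")
    trials = _per_trial(predictions)
    trials["wrong"] = (trials["prediction"] != trials["true"]) | trials["tie"]
    de = (
        trials.groupby(["true", "fold"])["wrong"].mean().groupby("true").mean().rename("DE")
    )
    bins = predictions.assign(wrong=predictions["pred"] != predictions["true"])
    de_bins = (
        bins.groupby(["true", "fold"])["wrong"].mean().groupby("true").mean().rename("DE_bins")
    )
    return pd.concat([de, de_bins], axis=1).reset_index().rename(columns={"true": "category"})


def divergent_trajectories(predictions: pd.DataFrame) -> pd.DataFrame:
    """DT per category: fraction of trials whose trajectory ends misclassified.

    A divergent trajectory has its last r + 1 ≥ 1 bins misclassified;
    existence of such an r reduces to the final bin being misclassified.
    The mean terminal run length r_max is reported alongside.
    """
    trials = _per_trial(predictions)
    dt = (
        trials.groupby(["true", "fold"])["final_bin_wrong"]
        .mean()
        .groupby("true")
        .mean()
        .rename("DT")
    )
    r = (
        trials[trials["final_bin_wrong"]]
        .groupby("true")["r_max"]
        .mean()
        .rename("mean_r_max")
    )
    out = pd.concat([dt, r], axis=1).reset_index().rename(columns={"true": "category"})
    out["mean_r_max"] = out["mean_r_max"].fillna(0.0)
    return out


def permutation_p(null: np.ndarray, observed: float) -> float:
    """One-tailed p-value, lower statistic = better.

    p = max(#{null ≤ observed}, 1) / n: an observation below every null
    sample gets the floor 1/n (0.001 at the customary n = 1000), not 0.
    """
    null = np.asarray(null)
    return max(int(np.sum(null <= observed)), 1) / len(null)


def shuffle_bins_within_trials(rt: RateTensor, rng: np.random.Generator) -> RateTensor:
    """Permute the bin order independently per (neuron, trial).

    Preserves each bin-value multiset per neuron and trial — hence rates
    and their across-trial statistics at the trial level — while
    destroying within-trial temporal coordination across neurons.
    """
    values = rt.values.copy()
    n_units, n_bins, n_trials = values.shape
    for u in range(n_units):
        for t in range(n_trials):
            values[u, :, t] = values[u, rng.permutation(n_bins), t]
    from dataclasses import replace

    return replace(rt, values=values)


def permutation_test(
    rt: RateTensor,
    labels: np.ndarray,
    scheme: BlockScheme,
    config: DecoderConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Within-trial bin-shuffle null for the causally cross-validated DE/DT.

    Each resample shuffles bin order per neuron within each trial (trial
    labels untouched) and re-runs the full causal cross-validation.  The
    test statistic is the mean DE (and DT) across categories; lower is
    better, so p = max(#{null ≤ observed}, 1) / n_perm, with floor
    1/n_perm.  Quartiles, the 1 % percentile and ±2.7·SD outlier bounds
    of the null are reported.
    """
    if n_perm < 100:
        logger.warning("n_perm = %d gives a coarse p-value floor of %.3g", n_perm, 1 / n_perm)
    config = config or DecoderConfig()
    observed_pred = causal_cv(rt, labels, scheme, config)
    obs_de = float(decoding_error(observed_pred)["DE"].mean())
    obs_dt = float(divergent_trajectories(observed_pred)["DT"].mean())

    rng = np.random.default_rng(seed)
    null_de = np.empty(n_perm)
    null_dt = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_bins_within_trials(rt, rng)
        pred = causal_cv(shuffled, labels, scheme, config)
        null_de[i] = decoding_error(pred)["DE"].mean()
        null_dt[i] = divergent_trajectories(pred)["DT"].mean()

    def summarize(obs: float, null: np.ndarray) -> dict:
        sd = null.std()
        return {
            "observed": obs,
            "null": null,
            "p": permutation_p(null, obs),
            "quartiles": np.percentile(null, [25, 50, 75]).tolist(),
            "percentile_1": float(np.percentile(null, 1)),
            "outlier_bounds": (float(null.mean() - 2.7 * sd), float(null.mean() + 2.7 * sd)),
        }

    return {"DE": summarize(obs_de, null_de), "DT": summarize(obs_dt, null_dt), "n_perm": n_perm}


def split_predictability(trials: pd.DataFrame) -> dict:
    """Correct trials by predictability, each with matched incorrect trials.

    Predictable correct trials follow an error (the stimulus repeats);
    unpredictable correct trials follow a correct choice.  For each
    condition, incorrect trials are greedily matched to the temporally
    nearest available correct trial (each incorrect trial used at most
    once), equalizing counts so both groups occupy comparable temporal
    vicinities.

    Returns ``{condition: {"correct": ids, "incorrect": ids}}`` with
    condition ∈ {"predictable", "unpredictable"}; trial ids refer to the
    ``trial_id`` column.
    """
    cats = trials["category"].to_numpy()
    pred_flag = trials["predictable"].to_numpy().astype(int)
    ids = trials["trial_id"].to_numpy()
    order = np.argsort(ids)
    cats, pred_flag, ids = cats[order], pred_flag[order], ids[order]

    incorrect_pool = list(np.flatnonzero(cats != "C"))
    out = {}
    for name, flag in (("predictable", 1), ("unpredictable", 0)):
        correct_pos = np.flatnonzero((cats == "C") & (pred_flag == flag))
        if correct_pos.size == 0:
            raise ValueError(f"no correct trials in the {name} condition")
        available = set(incorrect_pool)
        matched = []
        for cp in correct_pos:
            if not available:
                break
            nearest = min(available, key=lambda ip: (abs(ip - cp), ip))
            matched.append(nearest)
            available.discard(nearest)
        if not matched:
            raise ValueError(f"no incorrect trials available to match the {name} condition")
        k = min(len(matched), len(correct_pos))
        out[name] = {
            "correct": ids[correct_pos[:k]],
            "incorrect": ids[np.array(sorted(matched[:k]))],
        }
        incorrect_pool = [i for i in incorrect_pool if i not in set(matched[:k])]
    return out


def predictability_decoding(
    rt: RateTensor,
    trials: pd.DataFrame,
    config: DecoderConfig | None = None,
    n_blocks: int = 2,
) -> pd.DataFrame:
    """Correct-vs-incorrect DE within each predictability condition.

    Restricts the tensor to each condition's correct and matched
    incorrect trials (labels C / I), and runs a causal cross-validation
    over ``n_blocks`` consecutive blocks of the condition's trials.
    Returns one row per (condition, category) with the DE.
    """
    config = config or DecoderConfig()
    split = split_predictability(trials)
    pos_of_id = {tid: i for i, tid in enumerate(rt.trial_ids)}
    rows = []
    for cond, groups in split.items():
        sel_ids = np.concatenate([groups["correct"], groups["incorrect"]])
        lab = np.array(["C"] * len(groups["correct"]) + ["I"] * len(groups["incorrect"]))
        present = np.array([tid in pos_of_id for tid in sel_ids])
        sel_ids, lab = sel_ids[present], lab[present]
        order = np.argsort(sel_ids)  # keep temporal order for causal blocks
        sel_ids, lab = sel_ids[order], lab[order]
        idx = np.array([pos_of_id[tid] for tid in sel_ids])
        sub = rt.subset_trials(idx)
        scheme = make_blocks(sub.n_trials, block_size=sub.n_trials // n_blocks)
        pred = causal_cv(sub, lab, scheme, config)
        de = decoding_error(pred)
        for _, r in de.iterrows():
            rows.append({"condition": cond, "category": r["category"], "DE": r["DE"]})
    return pd.DataFrame(rows)
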