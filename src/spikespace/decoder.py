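"""Regularized kernel-Fisher discriminant decoding of choice outcomes.

A Fisher discriminant computed implicitly in the order-θ polynomial
feature space through the inhomogeneous multinomial kernel
k(x, x') = (1 + x·x')^θ − 1.  With gram matrix K over the l training
observations (time bins), class-mean kernel columns μ_y, their grand
mean m, within-class scatter N = K² − Σ_y l_y μ_y μ_yᵀ and between-class
scatter M = Σ_y (μ_y − m)(μ_y − m)ᵀ, the c − 1 discriminant coefficient
vectors α solve the generalized eigenproblem

    M α = ν (N + λ K + ε I) α,

taken in decreasing order of ν.  λ ∈ [0, 0.5] is a Tikhonov penalty
selected by causal cross-validation inside the training data; ε is a
small trace-scaled jitter because gram matrices of sparse low-rate data
are near-singular.  Projections F = K·A carry class-specific Gaussian
models (equal priors), giving quadratic decision boundaries in the
discriminant subspace.  At θ = 1 the whole construction reduces to
classical linear discriminant analysis.

Observations are single time bins; a trial is classified by majority
vote over its bins (ties count as misclassified).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .preprocess import RateTensor
from .state_space import multinomial_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "KernelDiscriminantModel",
    "gram_matrix",
    "class_statistics",
    "fit_kernel_discriminant",
    "orthogonalize",
    "project",
    "classify",
    "select_lambda",
    "observations_from_tensor",
    "majority_vote",
]

JITTER_SCALE = 1e-8
COV_RIDGE = 1e-6


def gram_matrix(X_rows: np.ndarray, X_cols: np.ndarray, theta: int) -> np.ndarray:
    """Kernel matrix k(x_r, x_c); symmetric PSD when both stacks coincide."""
    return multinomial_kernel(np.atleast_2d(X_rows), np.atleast_2d(X_cols), theta)


def class_statistics(K: np.ndarray, labels: np.ndarray):
    """Class-mean kernel columns, their grand mean, and within-class scatter.

    Returns ``(mu, m, N, classes, counts)`` where ``mu[:, y]`` is the mean
    of K's columns belonging to class y, ``m`` the unweighted mean of the
    class means, and ``N = K·Kᵀ − Σ_y l_y μ_y μ_yᵀ``.
    """
    K = np.asarray(K, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(classes) < 2:
        raise ValueError("every class must be nonempty and c >= 2")
    mu = np.stack([K[:, labels == y].mean(axis=1) for y in classes], axis=1)
    m = mu.mean(axis=1)
    N = K @ K.T - (mu * counts) @ mu.T
    return mu, m, N, classes, counts


@dataclass
class KernelDiscriminantModel:
    """Fitted kernel discriminant (see module docstring for the math)."""

    theta: int
    lam: float
    classes: np.ndarray
    A: np.ndarray  # l × (c−1) discriminant coefficient vectors
    eigenvalues: np.ndarray
    F: np.ndarray  # l × (c−1) training projections
    labels: np.ndarray
    class_means: np.ndarray  # c × (c−1)
    class_covs: np.ndarray  # c × (c−1) × (c−1)
    X_train: np.ndarray | None = None
    A_orth: np.ndarray | None = None
    jitter: float = 0.0

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _fix_signs(A: np.ndarray) -> np.ndarray:
    """First nonzero coefficient of each column positive (reproducibility)."""
    A = A.copy()
    for j in range(A.shape[1]):
        col = A[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            A[:, j] = -col
    return A


def _gaussians(F: np.ndarray, labels: np.ndarray, classes: np.ndarray):
    d = F.shape[1]
    means = np.zeros((len(classes), d))
    covs = np.zeros((len(classes), d, d))
    for yi, y in enumerate(classes):
        Fy = F[labels == y]
        means[yi] = Fy.mean(axis=0)
        cov = np.cov(Fy.T, bias=False).reshape(d, d) if len(Fy) > 1 else np.eye(d)
        ridge = COV_RIDGE * max(np.trace(cov) / d, 1e-30)
        covs[yi] = cov + ridge * np.eye(d)
    return means, covs


def fit_kernel_discriminant(
    K: np.ndarray,
    labels: np.ndarray,
    lam: float,
    theta: int = 1,
    X_train: np.ndarray | None = None,
) -> KernelDiscriminantModel:
    """Solve the regularized discriminant eigenproblem on a gram matrix.

    Keeps the top c − 1 generalized eigenvectors of (M, N + λK + εI),
    each normalized to αᵀ(N + λK + εI)α = 1, and fits the per-class
    Gaussians of the training projections F = K·A.  Pass ``X_train`` to
    enable kernel evaluations against new data in :func:`project`.
    """
    if lam < 0 or lam > 0.5:
        raise ValueError("lambda must lie in [0, 0.5]")
    K = np.asarray(K, dtype=float)
    labels = np.asarray(labels)
    mu, m, N, classes, _counts = class_statistics(K, labels)
    c = len(classes)
    l = K.shape[0]
    dmu = mu - m[:, None]
    M = dmu @ dmu.T
    B = N + lam * K
    eps = JITTER_SCALE * max(np.trace(B), 1e-30) / l
    B = B + eps * np.eye(l)
    try:
        w, V = eigh(M, B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"(N + lambda*K) numerically singular despite jitter; "
            f"increase lambda (got {lam})"
        ) from exc
    order = np.argsort(w)[::-1][: c - 1]
    A = _fix_signs(V[:, order])  # eigh already B-normalizes columns
    F = K @ A
    means, covs = _gaussians(F, labels, classes)
    return KernelDiscriminantModel(
        theta=theta,
        lam=lam,
        classes=classes,
        A=A,
        eigenvalues=w[order],
        F=F,
        labels=labels,
        class_means=means,
        class_covs=covs,
        X_train=None if X_train is None else np.asarray(X_train, dtype=float),
        jitter=eps,
    )


def orthogonalize(model: KernelDiscriminantModel) -> KernelDiscriminantModel:
    """Gram–Schmidt the projection columns (for Euclidean visualization).

    Finds Â with the same span as A whose projections F̂ = K·Â are
    mutually orthogonal, via a thin QR of F; numerically dependent
    columns are dropped with a warning.
    """
    Q, R = np.linalg.qr(model.F)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-10 * max(diag.max(), 1e-30)
    if not keep.all():
        logger.warning("dropping %d dependent discriminant columns", (~keep).sum())
    Rk = R[np.ix_(keep, keep)]
    model.A_orth = model.A[:, keep] @ np.linalg.inv(Rk)
    return model


def project(
    model: KernelDiscriminantModel,
    X_new: np.ndarray | None = None,
    K_new: np.ndarray | None = None,
    orthogonal: bool = False,
) -> np.ndarray:
    """Discriminant coordinates of new observations, F_new = K_new · A.

    Provide raw observations ``X_new`` (requires the model to carry its
    training observations) or a precomputed cross-kernel ``K_new`` of
    shape (new, l).
    """
    if K_new is None:
        if X_new is None or model.X_train is None:
            raise ValueError("need X_new with a stored training set, or K_new")
        K_new = gram_matrix(np.atleast_2d(X_new), model.X_train, model.theta)
    K_new = np.asarray(K_new, dtype=float)
    if K_new.shape[1] != model.A.shape[0]:
        raise ValueError("cross-kernel width must equal the training size")
    A = model.A_orth if orthogonal else model.A
    if A is None:
        raise ValueError("call orthogonalize() before projecting orthogonally")
    return K_new @ A


def classify(model: KernelDiscriminantModel, F_new: np.ndarray):
    """Equal-prior Gaussian classification of projected observations.

    Returns ``(predicted labels, posterior matrix)`` with posteriors
    normalized across classes; the prediction maximizes the
    class-conditional Gaussian density (Bayes rule with equal priors).
    """
    F_new = np.atleast_2d(np.asarray(F_new, dtype=float))
    logp = np.zeros((F_new.shape[0], model.n_classes))
    d = F_new.shape[1]
    for yi in range(model.n_classes):
        cov = model.class_covs[yi]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("class covariance not positive definite")
        diff = F_new - model.class_means[yi]
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        logp[:, yi] = -0.5 * (maha + logdet + d * np.log(2 * np.pi))
    shifted = logp - logp.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    return model.classes[np.argmax(logp, axis=1)], post


def observations_from_tensor(rt: RateTensor, trial_labels: np.ndarray):
    """Flatten a rate tensor into per-bin observations.

    Returns ``(X, y, groups)``: X is (trials·bins, units) with each
    trial's bins consecutive and in time order, y repeats the trial
    label over its bins, groups holds the trial position index.
    """
    n_units, n_bins, n_trials = rt.values.shape
    X = rt.values.transpose(2, 1, 0).reshape(n_trials * n_bins, n_units)
    y = np.repeat(np.asarray(trial_labels), n_bins)
    groups = np.repeat(np.arange(n_trials), n_bins)
    return X, y, groups


def majority_vote(pred: np.ndarray, groups: np.ndarray):
    """Trial labels by majority over bin predictions; ties → None.

    Returns a DataFrame (group, prediction, tie); tied trials carry their
    plurality label but are flagged, and callers count them as
    misclassified.
    """
    df = pd.DataFrame({"group": groups, "pred": pred})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        counts = sub["pred"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        rows.append({"group": g, "prediction": winners[0], "tie": len(winners) > 1})
    return pd.DataFrame(rows)


def _mean_category_error(pred_trials: pd.DataFrame, true_by_group: dict) -> float:
    truths = pred_trials["group"].map(true_by_group)
    wrong = (pred_trials["prediction"] != truths) | pred_trials["tie"]
    per_cat = wrong.groupby(truths.values).mean()
    return float(per_cat.mean())


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    theta: int,
    grid: np.ndarray,
) -> float:
    """Pick λ by a causal split of the estimation data.

    Trials (groups) are split in time order into an earlier fitting half
    and a later validation half; for each grid value the discriminant is
    fit on the earlier half and scored by mean per-category trial error
    on the later half.  Ties break toward the larger λ (stronger
    regularization).  The grid must lie within [0, 0.5] with at most
    1000 points.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if grid.size > 1000 or grid.min() < 0 or grid.max() > 0.5:
        raise ValueError("grid must be <= 1000 points within [0, 0.5]")
    if grid.size == 1:
        return float(grid[0])

    uniq = np.unique(groups)
    half = len(uniq) // 2
    fit_groups = set(uniq[:half])
    fit_mask = np.isin(groups, list(fit_groups))
    val_mask = ~fit_mask
    # a category missing from either half makes validation ill-posed
    for part in (y[fit_mask], y[val_mask]):
        if len(np.unique(part)) < len(np.unique(y)):
            logger.warning("lambda selection split lost a category; using full grid median")
            return float(np.sort(grid)[grid.size // 2])

    K_fit = gram_matrix(X[fit_mask], X[fit_mask], theta)
    K_val = gram_matrix(X[val_mask], X[fit_mask], theta)
    true_by_group = dict(
        pd.DataFrame({"g": groups[val_mask], "y": y[val_mask]}).drop_duplicates("g").values
    )
    best = (np.inf, -np.inf)
    for lam in np.sort(grid):
        model = fit_kernel_discriminant(K_fit, y[fit_mask], lam, theta=theta)
        pred, _ = classify(model, K_val @ model.A)
        de = _mean_category_error(majority_vote(pred, groups[val_mask]), true_by_group)
        if de <= best[0]:  # ties toward larger lambda (grid is ascending)
            best = (de, lam)
    return float(best[1])
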