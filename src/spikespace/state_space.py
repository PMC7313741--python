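"""Polynomial state spaces for higher-order ensemble interactions.

An order-``theta`` state space augments the n-dimensional space of unit
firing rates with axes for every product of rates up to total degree
``theta``.  A point x ∈ R^n maps to the feature vector

    phi(theta, x)_j = sqrt(theta! / (i0! i1! ... in!)) * x1^i1 ... xn^in,

indexed by exponent tuples (i0, i1, ..., in) with i0 < theta and
sum_k i_k = theta (i0 absorbs the slack degree).  The scaling makes the
map reproduce the inhomogeneous multinomial kernel exactly:

    phi(theta, x) . phi(theta, x') = (1 + x . x')^theta - 1,

so classifiers can work either in the explicit feature space or, for
high dimensions, through Gram matrices of kernel evaluations alone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "state_space_dim",
    "FeatureMapSpec",
    "feature_map",
    "multinomial_kernel",
    "normalized_coordinates",
    "coordinate_correlation_identity",
]

#: explicit feature maps above this dimension are refused
DEFAULT_DIM_CAP = 10**6


def state_space_dim(n: int, theta: int) -> int:
    """Dimension of the order-``theta`` state space of an ``n``-unit ensemble.

    Equals ``binomial(n + theta, n) - 1``: the number of monomials in n
    variables of total degree between 1 and theta.
    """
    if n < 1 or theta < 1:
        raise ValueError("n and theta must be >= 1")
    return math.comb(n + theta, n) - 1


def _exponent_tuples(n: int, theta: int) -> list[tuple[int, ...]]:
    """Unit-exponent tuples (i1..in), total degree 1..theta, in stable order.

    Graded ordering: ascending total degree; within a degree, tuples with
    more interacting units (cross terms) come before pure powers, then
    lexicographic.  Stability of this bijection is required for model
    serialization.
    """
    out: list[tuple[int, ...]] = []
    for degree in range(1, theta + 1):
        tuples = [
            t
            for t in itertools.product(range(degree + 1), repeat=n)
            if sum(t) == degree
        ]
        tuples.sort(key=lambda t: (-sum(1 for e in t if e > 0), tuple(-e for e in t)))
        out.extend(tuples)
    return out


@dataclass(frozen=True)
class FeatureMapSpec:
    """Index map and multinomial scalings of an explicit feature map."""

    n_units: int
    theta: int
    exponents: tuple[tuple[int, ...], ...] = field(init=False)
    coefficients: np.ndarray = field(init=False)  # sqrt multinomial weights

    def __post_init__(self) -> None:
        exps = _exponent_tuples(self.n_units, self.theta)
        coeffs = np.array(
            [
                math.factorial(self.theta)
                / (math.factorial(self.theta - sum(e)) * math.prod(map(math.factorial, e)))
                for e in exps
            ],
            dtype=float,
        )
        object.__setattr__(self, "exponents", tuple(exps))
        object.__setattr__(self, "coefficients", np.sqrt(coeffs))

    @property
    def dimension(self) -> int:
        return len(self.exponents)

    def index_of(self, exponent: tuple[int, ...]) -> int:
        return self.exponents.index(tuple(exponent))


def feature_map(
    x: np.ndarray, theta: int, *, dim_cap: int = DEFAULT_DIM_CAP
) -> np.ndarray:
    """Explicit order-``theta`` feature vector(s) of rate vector(s) ``x``.

    ``x`` may be a single vector (n,) or a stack (m, n); the result has the
    feature dimension D = C(n+theta, n) - 1 as last axis.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    n = X.shape[1]
    D = state_space_dim(n, theta)
    if D > dim_cap:
        raise ValueError(
            f"feature dimension {D} exceeds cap {dim_cap}; "
            "use the kernelized path (multinomial_kernel) instead"
        )
    spec = FeatureMapSpec(n, theta)
    cols = [
        spec.coefficients[j]
        * np.prod(X ** np.asarray(e, dtype=float), axis=1)
        for j, e in enumerate(spec.exponents)
    ]
    phi = np.stack(cols, axis=1)
    return phi[0] if single else phi


def multinomial_kernel(x: np.ndarray, x2: np.ndarray, theta: int) -> np.ndarray:
    """Inhomogeneous multinomial kernel k(x, x') = (1 + x.x')^theta - 1.

    Accepts single vectors or stacks; with stacks (a, n) and (b, n) it
    returns the (a, b) kernel matrix.  For theta = 1 this is the plain dot
    product, so downstream discriminants reduce to linear ones.
    """
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape[-1] != x2.shape[-1]:
        raise ValueError("inputs must share their trailing (unit) dimension")
    if x.ndim == 1 and x2.ndim == 1:
        return (1.0 + x @ x2) ** theta - 1.0
    dots = np.atleast_2d(x) @ np.atleast_2d(x2).T
    return (1.0 + dots) ** theta - 1.0


def normalized_coordinates(phi: np.ndarray, spec: FeatureMapSpec) -> np.ndarray:
    """Divide each coordinate by its multinomial coefficient.

    The result contains the pure monomials x1^i1 ... xn^in, whose trial
    averages are the raw cross-moments entering the correlation
    coefficients.
    """
    phi = np.asarray(phi, dtype=float)
    return phi / spec.coefficients


def coordinate_correlation_identity(
    values: np.ndarray, theta: int, *, atol_zscore: float = 1e-8
) -> dict:
    """Check the link between state-space coordinates and correlations.

    ``values`` is a (units, trials) array of z-scored data for a single
    time bin (mean 0 across trials per unit).  For every full-degree cross
    coordinate of the normalized map (exponent tuple with i0 = 0, each
    unit exponent < theta and at least two units involved), the sum over
    trials of the coordinate equals the numerator of the theta-order
    correlation coefficient with the same exponent vector; dividing by the
    absolute-central-moment denominator must reproduce the coefficient.

    Returns a report dict with the maximum absolute discrepancy.
    """
    from .correlations import enumerate_exponent_vectors, theta_coefficient_1bin

    V = np.asarray(values, dtype=float)
    if V.ndim != 2:
        raise ValueError("values must be (units, trials)")
    n, n_trials = V.shape
    if np.max(np.abs(V.mean(axis=1))) > atol_zscore:
        raise ValueError("input must be z-scored (per-unit mean 0 across trials)")

    spec = FeatureMapSpec(n, theta)
    phi = feature_map(V.T, theta)  # (trials, D)
    phi_norm = phi / spec.coefficients  # pure monomials

    denom_moments = np.sum(np.abs(V) ** theta, axis=1)  # per unit

    discrepancies = []
    n_checked = 0
    for m in enumerate_exponent_vectors(n, theta):
        j = spec.index_of(m)
        numerator = phi_norm[:, j].sum()
        denominator = float(np.prod(denom_moments ** (np.asarray(m) / theta)))
        if denominator == 0.0:
            continue
        coord_side = numerator / denominator
        corr_side = theta_coefficient_1bin(V, m, theta)
        discrepancies.append(abs(coord_side - corr_side))
        n_checked += 1
    return {
        "theta": theta,
        "n_coefficients": n_checked,
        "max_discrepancy": max(discrepancies) if discrepancies else 0.0,
    }
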