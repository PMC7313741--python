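"""Trial-structured synthetic spike trains with controlled interactions.

Stands in for small orbitofrontal-ensemble recordings during a two-tone
interval-discrimination task.  The generator has two layers:

* a behavioral layer producing trial sequences of the lose-switch task
  (the inter-tone interval is redrawn after correct choices and repeated
  after any incorrect choice, which makes post-error trials predictable);

* a spiking layer drawing, for each 40 ms bin of a trial, a binary
  spike word for the whole ensemble from an exponential-family
  distribution over {0,1}^n with bias, pairwise and triplet terms

      P(s) ∝ exp( Σ_i h_i s_i + Σ_{i<j} J_ij s_i s_j
                  + Σ_{i<j<k} G_ijk s_i s_j s_k ),

  enumerated exactly (n ≤ 12), so every moment the analysis estimates
  has a closed-form oracle.  Interaction strength depends on the trial's
  response category and predictability through per-condition gains.

One spike at most is placed per unit per generator bin, uniformly
jittered within the bin, which enforces the binary-ish sparsity regime
(≥ 99 % of 40 ms bins carry ≤ 1 spike) by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "CATEGORIES",
    "TaskConfig",
    "CouplingSpec",
    "PatternDistribution",
    "generate_task_sequence",
    "exact_pattern_distribution",
    "moments_from_distribution",
    "oracle_theta_coefficient",
    "sample_ensemble_activity",
    "calibrate_coupling",
    "category_triplet_supports",
    "make_default_coupling",
]

#: response categories: correct; missed/false-alarm; premature-central;
#: premature-lateral
CATEGORIES = ("C", "M", "PC", "PL")

SHORT_ITIS = (50, 100, 150, 200)
LONG_ITIS = (350, 400, 450, 500)
DELAYS = (50, 100, 150, 200, 250, 300)

MAX_ENUM_UNITS = 12


@dataclass
class TaskConfig:
    """Parameters of the interval-discrimination task simulation.

    ``policy`` maps each stimulus difficulty ("short"/"long") to the
    probability of each response category; the animal model is a
    memoryless categorical draw (the analyses condition on categories,
    not on learning dynamics).
    """

    n_trials: int = 160
    short_itis: tuple[int, ...] = SHORT_ITIS
    long_itis: tuple[int, ...] = LONG_ITIS
    delay_values: tuple[int, ...] = DELAYS
    tone_ms: float = 50.0
    policy: dict = field(
        default_factory=lambda: {
            "short": {"C": 0.25, "M": 0.25, "PC": 0.25, "PL": 0.25},
            "long": {"C": 0.25, "M": 0.25, "PC": 0.25, "PL": 0.25},
        }
    )
    seed: int = 20160

    def validate(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 (predictability undefined)")
        if not set(self.short_itis) <= set(SHORT_ITIS):
            raise ValueError(f"short_itis must be a subset of {SHORT_ITIS}")
        if not set(self.long_itis) <= set(LONG_ITIS):
            raise ValueError(f"long_itis must be a subset of {LONG_ITIS}")
        for difficulty, probs in self.policy.items():
            if set(probs) != set(CATEGORIES):
                raise ValueError(f"policy[{difficulty!r}] must cover {CATEGORIES}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"policy[{difficulty!r}] probabilities sum to {total}, not 1"
                )


def generate_task_sequence(config: TaskConfig) -> pd.DataFrame:
    """Simulate a trial sequence of the lose-switch interval task.

    Returns a trial table with per-trial event times (seconds, on a
    common session clock), the inter-tone interval, stimulus class,
    response category and the derived predictability flag (1 iff the
    preceding outcome was non-correct, so the stimulus is a repeat).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    all_itis = tuple(config.short_itis) + tuple(config.long_itis)

    rows = []
    t_poke = 0.0
    prev_iti: int | None = None
    prev_correct: bool | None = None
    for trial_id in range(config.n_trials):
        if prev_correct is False:
            iti = prev_iti  # lose-switch: repeat the stimulus after errors
        else:
            iti = int(rng.choice(all_itis))
        stimulus = "short" if iti in SHORT_ITIS else "long"
        predictable = int(prev_correct is False)
        category = str(rng.choice(CATEGORIES, p=[config.policy[stimulus][c] for c in CATEGORIES]))

        delay_s = float(rng.choice(config.delay_values)) / 1000.0
        tone_s = config.tone_ms / 1000.0
        t_t1 = t_poke + delay_s
        t_t2 = np.nan
        t_lateral = np.nan
        if category != "PC":  # premature-central trials end before the 2nd tone
            t_t2 = t_t1 + tone_s + iti / 1000.0
            if category == "PL":
                t_lateral = t_t2 + float(rng.uniform(0.0, 0.05))
            else:  # C and M (false alarms) reach a side socket
                t_lateral = t_t2 + tone_s + float(rng.uniform(0.2, 0.6))
        rows.append(
            {
                "trial_id": trial_id,
                "t_central_poke_s": t_poke,
                "t_T1_s": t_t1,
                "t_T2_s": t_t2,
                "t_lateral_poke_s": t_lateral,
                "iti_ms": iti,
                "stimulus": stimulus,
                "category": category,
                "predictable": predictable,
            }
        )
        prev_iti = iti
        prev_correct = category == "C"
        # reward / white-noise epoch then a pause before self-initiation
        t_poke += 4.5 + float(rng.uniform(0.0, 1.5))
    return pd.DataFrame(rows)


@dataclass
class CouplingSpec:
    """Exponential-family interaction parameters of an ensemble.

    ``h`` are per-unit biases, ``J`` pairwise terms (symmetric, zero
    diagonal; only the upper triangle is read), ``G`` triplet terms keyed
    by sorted unit triples.  ``condition_gains`` maps a trial condition
    ``(category, predictable)`` to multiplicative gains ``(g_h, g_J,
    g_G)``.  ``condition_h_offsets`` optionally adds a per-condition bias
    vector (used to hold mean rates fixed while interactions vary) and
    ``condition_h_jitter_sd`` adds trial-to-trial bias jitter emulating
    behavioral heterogeneity within a category.
    """

    n_units: int
    h: np.ndarray
    J: np.ndarray
    G: dict[tuple[int, int, int], float]
    condition_gains: dict[tuple[str, int], tuple[float, float, float]]
    condition_h_offsets: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    condition_h_jitter_sd: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_units > MAX_ENUM_UNITS:
            raise ValueError(
                f"n_units = {self.n_units} exceeds {MAX_ENUM_UNITS}; "
                "exact enumeration refused"
            )
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.h.shape != (self.n_units,):
            raise ValueError("h must have shape (n_units,)")
        if self.J.shape != (self.n_units, self.n_units):
            raise ValueError("J must have shape (n_units, n_units)")
        if np.any(np.diag(self.J) != 0.0):
            raise ValueError("J must have a zero diagonal (no self terms)")
        for triple in self.G:
            if len(set(triple)) != 3 or tuple(sorted(triple)) != tuple(triple):
                raise ValueError(f"G key {triple} must be a sorted triple of distinct units")

    def effective_parameters(self, condition: tuple[str, int]):
        """(h, J, G) with the condition's gains and offsets applied."""
        if condition not in self.condition_gains:
            raise KeyError(f"condition {condition} absent from condition_gains")
        g_h, g_j, g_g = self.condition_gains[condition]
        h = g_h * self.h
        if condition in self.condition_h_offsets:
            h = h + np.asarray(self.condition_h_offsets[condition], dtype=float)
        J = g_j * self.J
        G = {t: g_g * v for t, v in self.G.items()}
        return h, J, G


@dataclass
class PatternDistribution:
    """Exact distribution over the 2^n binary spike words of an ensemble."""

    n_units: int
    probabilities: np.ndarray
    log_partition: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (2**self.n_units,):
            raise ValueError("probabilities must have length 2**n_units")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = p

    @property
    def words(self) -> np.ndarray:
        """(2^n, n) array of binary words, word w = bits of its index."""
        return _words(self.n_units)


def _words(n: int) -> np.ndarray:
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(float)


def _energies(n: int, h: np.ndarray, J: np.ndarray, G: dict) -> np.ndarray:
    W = _words(n)
    E = W @ h
    E += 0.5 * np.einsum("wi,ij,wj->w", W, np.triu(J, 1) + np.triu(J, 1).T, W)
    for (i, j, k), g in G.items():
        E += g * W[:, i] * W[:, j] * W[:, k]
    return E


def exact_pattern_distribution(
    coupling: CouplingSpec, condition: tuple[str, int]
) -> PatternDistribution:
    """Enumerate P(s) ∝ exp(h·s + Σ J s s + Σ G s s s) for one condition."""
    h, J, G = coupling.effective_parameters(condition)
    E = _energies(coupling.n_units, h, J, G)
    logZ = float(logsumexp(E))
    return PatternDistribution(coupling.n_units, np.exp(E - logZ), logZ)


def moments_from_distribution(dist: PatternDistribution, order: int) -> pd.DataFrame:
    """Exact raw and central moments for all exponent vectors up to ``order``.

    Rows are exponent vectors m (one integer per unit) with
    1 ≤ Σ m_i ≤ order; columns hold E[Π s_i^{m_i}] (raw) and
    E[Π (s_i − p_i)^{m_i}] (central), computed by full summation.
    """
    if order > dist.n_units:
        raise ValueError("order cannot exceed n_units")
    W = dist.words
    p = dist.probabilities
    means = p @ W
    centered = W - means
    rows = []
    for total in range(1, order + 1):
        for m in itertools.product(range(total + 1), repeat=dist.n_units):
            if sum(m) != total:
                continue
            m_arr = np.asarray(m, dtype=float)
            raw = float(p @ np.prod(W**m_arr, axis=1))
            central = float(p @ np.prod(centered**m_arr, axis=1))
            rows.append({"exponents": m, "order": total, "raw": raw, "central": central})
    return pd.DataFrame(rows)


def oracle_theta_coefficient(
    dist: PatternDistribution, m: tuple[int, ...], theta: int | None = None
) -> float:
    """Population value of the order-θ correlation coefficient.

    Numerator E[Π (s_i − p_i)^{m_i}]; denominator Π E[|s_i − p_i|^θ]^{m_i/θ}
    (absolute central moments, matching the estimator's convention).
    Sample coefficients computed from draws of ``dist`` converge to this
    value as the number of draws grows.
    """
    m_arr = np.asarray(m, dtype=float)
    theta = int(m_arr.sum()) if theta is None else theta
    W = dist.words
    p = dist.probabilities
    centered = W - p @ W
    num = float(p @ np.prod(centered**m_arr, axis=1))
    abs_mom = p @ np.abs(centered) ** theta  # per unit
    den = float(np.prod(abs_mom ** (m_arr / theta)))
    if den == 0.0:
        return np.nan
    return num / den


def sample_ensemble_activity(
    trials: pd.DataFrame,
    coupling: CouplingSpec,
    bin_ms: float = 40.0,
    seed: int = 0,
    duration_s: float = 1.8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ensemble spike trains for every trial of a trial table.

    Each trial contributes ``duration_s / bin_ms`` generator bins starting
    at its central poke; each bin's binary word is an independent draw
    from the trial condition's exact pattern distribution, and each spike
    is jittered uniformly within its bin.  Randomness is split into one
    child stream per trial from the single ``seed`` so per-trial draws
    are independent and reproducible.

    Returns the spike-event table (columns ``unit_id, spike_time_s``) and
    the exact (units × bins × trials) spike-count tensor.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n = coupling.n_units
    n_bins = int(round(duration_s * 1000.0 / bin_ms))
    n_trials = len(trials)
    counts = np.zeros((n, n_bins, n_trials), dtype=np.int64)

    conditions = list(zip(trials["category"], trials["predictable"].astype(int)))
    for cond in set(conditions):
        if cond not in coupling.condition_gains:
            raise KeyError(f"condition {cond} absent from condition_gains")
    base_params = {c: coupling.effective_parameters(c) for c in set(conditions)}

    streams = np.random.SeedSequence(seed).spawn(n_trials)
    events_unit: list[np.ndarray] = []
    events_time: list[np.ndarray] = []
    bin_s = bin_ms / 1000.0
    pokes = trials["t_central_poke_s"].to_numpy(dtype=float)
    for ti, (cond, ss) in enumerate(zip(conditions, streams)):
        rng = np.random.default_rng(ss)
        h, J, G = base_params[cond]
        sd = coupling.condition_h_jitter_sd.get(cond, 0.0)
        if sd > 0.0:
            h = h + rng.normal(0.0, sd, size=n)
        E = _energies(n, h, J, G)
        probs = np.exp(E - logsumexp(E))
        idx = rng.choice(2**n, size=n_bins, p=probs)
        words = ((idx[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int64)  # bins × units
        counts[:, :, ti] = words.T
        b, u = np.nonzero(words)
        if b.size:
            t = pokes[ti] + (b + rng.uniform(size=b.size)) * bin_s
            events_unit.append(u)
            events_time.append(t)
    if events_unit:
        events = pd.DataFrame(
            {
                "unit_id": np.concatenate(events_unit),
                "spike_time_s": np.concatenate(events_time),
            }
        ).sort_values(["unit_id", "spike_time_s"], kind="mergesort", ignore_index=True)
    else:
        events = pd.DataFrame({"unit_id": np.array([], int), "spike_time_s": np.array([], float)})
    return events, counts


def _pair_indices(n: int) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def calibrate_coupling(
    n_units: int,
    G: dict[tuple[int, int, int], float],
    target_mean: float,
    target_pair: float,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve for (h, J) matching first and second raw moments given fixed G.

    Finds the maximum-entropy member of the family with the prescribed
    triplet terms whose per-unit firing probability equals ``target_mean``
    and per-pair joint probability equals ``target_pair``; this decouples
    interaction order from rate so that conditions differing only in G
    differ only in third-and-higher-order statistics.  Convex dual
    (log-partition minus linear term) minimized with exact gradients.
    """
    pairs = _pair_indices(n_units)
    W = _words(n_units)
    pair_feats = np.stack([W[:, i] * W[:, j] for i, j in pairs], axis=1)
    targets = np.concatenate(
        [np.full(n_units, target_mean), np.full(len(pairs), target_pair)]
    )
    G_energy = np.zeros(2**n_units)
    for (i, j, k), g in G.items():
        G_energy += g * W[:, i] * W[:, j] * W[:, k]

    def objective(params):
        h, j = params[:n_units], params[n_units:]
        E = W @ h + pair_feats @ j + G_energy
        logZ = logsumexp(E)
        p = np.exp(E - logZ)
        moments = np.concatenate([p @ W, p @ pair_feats])
        return logZ - params @ targets, moments - targets

    x0 = np.concatenate(
        [np.full(n_units, float(np.log(target_mean / (1 - target_mean)))), np.zeros(len(pairs))]
    )
    res = minimize(objective, x0, jac=True, method="L-BFGS-B", tol=tol,
                   options={"maxiter": 2000})
    if not res.success and np.max(np.abs(objective(res.x)[1])) > 1e-6:
        raise RuntimeError(f"coupling calibration failed: {res.message}")
    h = res.x[:n_units]
    J = np.zeros((n_units, n_units))
    for (i, j), v in zip(pairs, res.x[n_units:]):
        J[i, j] = J[j, i] = v
    return h, J


def category_triplet_supports(n_units: int) -> dict[str, list[tuple[int, int, int]]]:
    """Which unit triples each response category couples.

    Correct trials engage every triple of the ensemble; each incorrect
    category engages only the triples inside its own 4-unit subnetwork
    (overlapping windows), so categories differ in *which* triplets
    correlate — a signature visible to an order-3 decoder but invisible
    to first- and second-order statistics once rates and pairwise
    moments are matched.
    """
    if n_units < 6:
        raise ValueError("need at least 6 units for distinct category supports")
    subnets = {
        "M": tuple(range(4)),
        "PC": tuple(range(n_units - 4, n_units)),
        "PL": (0, 1, n_units - 2, n_units - 1),
    }
    out = {"C": list(itertools.combinations(range(n_units), 3))}
    for cat, units in subnets.items():
        out[cat] = list(itertools.combinations(sorted(units), 3))
    return out


def make_default_coupling(
    n_units: int = 6,
    target_mean: float = 0.15,
    pair_corr: float = 0.06,
    g_correct: float = 1.5,
    g_incorrect: float = 2.2,
    g_unpredictable_correct: float = -1.2,
    incorrect_jitter_sd: float = 0.25,
    predictability_dependence: bool = True,
) -> CouplingSpec:
    """Default study-condition ensemble: outcome-dependent triplet coupling.

    All conditions share identical first- and second-order statistics
    (``target_mean`` spike probability per 40 ms bin, weak positive
    pairwise correlation ``pair_corr``), enforced per condition by
    moment-matching calibration of (h, J).  Conditions differ only in
    their triplet structure (see :func:`category_triplet_supports`):
    correct trials couple every triple at ``g_correct``, each incorrect
    category couples its own subnetwork's triples at ``g_incorrect``.

    With ``predictability_dependence`` (the default), unpredictable
    correct trials instead carry ``g_unpredictable_correct`` on all
    triples — a negative coupling that suppresses the triple-coincidence
    excess — and every condition except predictable-correct adds
    trial-to-trial bias jitter (``incorrect_jitter_sd``) emulating the
    behavioral heterogeneity of non-rewarded responses.  Without it, all
    conditions of a category share that category's coupling and no
    jitter is applied ("triplet-structured" data for order sweeps).
    """
    p = target_mean
    q = p * p + pair_corr * p * (1 - p)
    supports = category_triplet_supports(n_units)

    cond_G: dict[tuple[str, int], dict] = {}
    for cat in CATEGORIES:
        for pred in (0, 1):
            if cat == "C" and pred == 0 and predictability_dependence:
                G = {t: g_unpredictable_correct for t in supports["C"]}
            elif cat == "C":
                G = {t: g_correct for t in supports["C"]}
            else:
                G = {t: g_incorrect for t in supports[cat]}
            cond_G[(cat, pred)] = G

    gains: dict[tuple[str, int], tuple[float, float, float]] = {}
    offsets: dict[tuple[str, int], np.ndarray] = {}
    jitter: dict[tuple[str, int], float] = {}
    cond_J: dict[tuple[str, int], np.ndarray] = {}
    cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for cond, G in cond_G.items():
        key = tuple(sorted(G.items()))
        if key not in cache:
            cache[key] = calibrate_coupling(n_units, G, p, q)
        h_c, J_c = cache[key]
        gains[cond] = (0.0, 1.0, 1.0)  # h supplied wholly via the offset
        offsets[cond] = h_c
        cond_J[cond] = J_c
        if predictability_dependence and cond != ("C", 1):
            jitter[cond] = incorrect_jitter_sd
    ref = ("C", 1)
    return _CalibratedCouplingSpec(
        n_units=n_units,
        h=np.zeros(n_units),
        J=cond_J[ref],
        G=cond_G[ref],
        condition_gains=gains,
        condition_h_offsets=offsets,
        condition_h_jitter_sd=jitter,
        condition_J=cond_J,
        condition_G=cond_G,
    )


@dataclass
class _CalibratedCouplingSpec(CouplingSpec):
    """CouplingSpec with per-condition (J, G) from moment-matching.

    The public gain/offset fields remain valid; the per-condition tables
    override J (to hold pairwise moments fixed while G varies) and G
    (category-specific triplet supports).
    """

    condition_J: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    condition_G: dict[tuple[str, int], dict] = field(default_factory=dict)

    def effective_parameters(self, condition):
        h, J, G = super().effective_parameters(condition)
        if condition in self.condition_J:
            J = self.condition_J[condition]
        if condition in self.condition_G:
            G = dict(self.condition_G[condition])
        return h, J, G
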