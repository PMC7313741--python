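# Methods

This note documents the models, estimators and numerical choices in
`spikespace`, and what the synthetic test bed does and does not show.

## θ-order correlation coefficients

For units i = 1…n with smoothed rates x_i(t, T) (time bin t, trial T),
an exponent vector m with Σ m_i = θ and m_i ∈ {0, …, θ−1} defines

    Corr(m; θ)(t) = Σ_T Π_i (x_i(t,T) − ⟨x_i(t)⟩)^{m_i}
                    / Π_i ( Σ_T |x_i(t,T) − ⟨x_i(t)⟩|^θ )^{m_i/θ}.

Trial averages ⟨x_i(t)⟩ are taken within the conditioning trial subset
(one response category at a time), so these are noise correlations at
fixed behavioral outcome.  The cap m_i ≤ θ−1 excludes pure
self-moments; at θ = 2 the definition is exactly the Pearson
coefficient across trials.

**Denominator convention.** A power-form denominator
(Σ_T (x−⟨x⟩)^θ)^{m_i/θ} is not real-valued for odd θ when the centered
sum is negative.  We use absolute central moments, which are always
real and give |Corr| ≤ 1 by Hölder's inequality.  Coefficients are
signed; the sign carries the direction of the shared fluctuation.

**Degenerate cases.** A zero denominator (e.g. a unit constant across
the conditioning trials) yields NaN, and NaNs are excluded from every
aggregate — including the positive/negative sign fractions — rather
than being counted as zeros, which would bias those fractions.

**Partial coefficients** apply the same estimator to residuals of a
per-(unit, bin) ordinary least-squares regression of x(t, T) on
x(t, T−1).  This removes components predictable from the immediately
preceding trial (slow drift, lose-switch stimulus carry-over).

**Differential correlation.** For each coefficient, δ+ (δ−) is the
mean of its strictly positive (negative) values on correct trials
minus the same on incorrect trials, aggregated over a trial period;
Δδ = δ+ − δ−.  A sign class with no members contributes 0.

## State spaces, kernel, and the coordinate–correlation link

The order-θ state space has one axis per monomial x₁^{i₁}…x_n^{i_n}
of total degree 1…θ; its dimension is D = C(n+θ, n) − 1.  The feature
map scales each coordinate by √(θ!/(i₀!·i₁!…i_n!)) (i₀ absorbs the
slack degree), which makes

    φ(θ, x)·φ(θ, x′) = (1 + x·x′)^θ − 1

hold exactly — the inhomogeneous multinomial kernel.  Coordinates are
ordered by ascending degree, cross terms before pure powers, then
lexicographically; the bijection is fixed so serialized models are
stable.  Dividing coordinates by their scaling recovers pure
monomials, and for per-(unit, bin) centered data the sum over trials
of such a cross coordinate equals the numerator of the correlation
coefficient with the matching exponent vector; dividing by the
absolute-moment denominator reproduces the coefficient exactly.  The
package verifies this identity numerically (`coordinate_correlation_identity`)
for any θ, under the same normalization the estimator uses.

## Decoder

Observations are single time bins.  With gram matrix K (l × l) over a
training block, indicator-derived class means μ_y = K·1_y / l_y, grand
mean m = (1/c) Σ μ_y, within-class scatter N = K·Kᵀ − Σ l_y μ_y μ_yᵀ
and between-class scatter M = Σ (μ_y − m)(μ_y − m)ᵀ, the discriminant
vectors are the top c−1 generalized eigenvectors of

    M α = ν (N + λK + εI) α,

normalized to αᵀ(N + λK + εI)α = 1.  The alternative normalization
αᵀ Σ_y (μ_y − m) = 1 sometimes written for this program is degenerate —
Σ_y (μ_y − m) vanishes identically by the definition of m — so the
standard eigenproblem convention is used, as this package's own choice.
Eigenvector signs are fixed (first nonzero coefficient positive).

* ε = 1e-8 · trace(N + λK)/l: gram matrices of sparse, low-rate data
  are near-singular; the jitter scale tracks the problem's magnitude.
* Class models in the projected (c−1)-space are Gaussians with
  class-specific covariances (ridge 1e-6 × mean variance), equal
  priors; class-specific covariances give quadratic boundaries, so the
  θ=1 decoder matches classical LDA in its projection exactly but can
  differ from it on isolated boundary points.
* λ ∈ [0, 0.5] is selected on the training block only: trials are
  split in time order, the earlier half fits, the later half scores,
  ties break toward stronger regularization.  Empirically the
  validation error is nearly flat in λ over [0, 0.5] for these problem
  sizes (N dominates λK numerically); replicated experiments therefore
  fix λ = 0.1 and spend the compute on replicates instead.
* Trial-level labels are the majority vote over the trial's bin
  predictions; ties count as misclassified.  Likelihood pooling across
  bins would be more efficient (it roughly triples the recoverable
  accuracy on the synthetic test bed) but the per-bin vote is kept as
  the primary index because it makes DE a direct per-observation
  error rate; per-bin DE is reported alongside.

## Causal validation and the permutation null

Blocks of 40 consecutive trials; every (train, test) pair with the
test block strictly later is a fold (six folds at 160 trials).
Z-scoring parameters and λ come from the training block alone.  DE is
the per-category misclassified-trial fraction averaged over folds; DT
is the fraction of trials whose final bin is misclassified (a
"divergent trajectory" requires the last r+1 ≥ 1 bins wrong, which
reduces to the endpoint condition; the terminal run length is also
reported).  Chance DE for c balanced categories is 1 − 1/c.

The null model shuffles the bin order independently per neuron within
each trial: per-trial rate content is preserved exactly, while
within-bin coincidences across neurons — the carrier of θ-order
information — are destroyed.  p = max(#{null ≤ observed}, 1)/n, floor
1/n (0.001 at n = 1000); the (k+1)/(n+1) convention is deliberately
not used so the floor matches 1/n exactly.

Predictable trials are those following a non-correct outcome (the
stimulus repeats).  For correct-vs-incorrect comparisons within a
predictability condition, incorrect trials are greedily matched to the
temporally nearest available correct trial, one use each, equalizing
counts and temporal vicinity.

## Synthetic test bed

**Task.** Self-initiated trials; a 50 ms tone after a 50–300 ms delay
(50 ms steps); an inter-tone interval from {50,100,150,200} (short) or
{350,400,450,500} ms (long); response categories C (correct), M
(missed/false-alarm), PC (premature central, no second tone), PL
(premature lateral).  The behavioral policy is a per-difficulty
categorical draw (default ¼ each, so ~40 trials per category in a
160-trial session); after any non-correct trial the ITI repeats.
There is no learning or drift — the analyses condition on categories,
not on acquisition dynamics.

**Spiking.** Within each 40 ms generator bin the ensemble emits a
binary word s ∈ {0,1}^n drawn from
P(s) ∝ exp(Σ h_i s_i + Σ J_ij s_i s_j + Σ G_ijk s_i s_j s_k),
enumerated exactly for n ≤ 12.  One spike at most per unit per bin,
uniformly jittered within the bin — so ≥ 99 % of 40 ms bins carry ≤ 1
spike by construction.  All randomness descends from one seed through
per-trial child streams.

**Study conditions (defaults).** Every condition is calibrated by a
convex moment-matching solve of (h, J) to the same per-unit spike
probability (0.15 per 40 ms bin, ≈ 3.8 Hz) and the same pairwise
correlation (0.06), so conditions differ only at third order:
correct trials couple *all* triples (G = 1.5); each incorrect category
couples only the triples inside its own 4-unit subnetwork (G = 2.2);
with predictability dependence enabled, unpredictable-correct trials
instead carry G = −1.2 on all triples (negative coupling saturates
near zero triplet correlation in the sparse regime — there is little
triple-coincidence probability left to remove, a genuine property of
sparse binary words) and all conditions except predictable-correct add
per-trial bias jitter (SD 0.25) emulating the heterogeneity of
non-rewarded behaviors.  The rate is above the sub-2 Hz floor some
units show in vivo because at ~1 Hz triple coincidences are too rare
(≪ 1 per trial) for any per-trial decoder — the test bed must express
the structure it claims to plant.

**What the generator does not emulate:** within-trial rate dynamics
(event-locked transients), learning, interactions above third order,
bursting/refractoriness, and LFP.  Passing tests show the estimators
recover planted interaction structure under stationary,
condition-dependent coupling; they do not certify behavior on
nonstationary real recordings.

## Preprocessing choices

* Gaussian spike-density estimation integrates the kernel exactly over
  each bin (mass-conserving).  Bandwidths can be optimized per unit by
  a least-squares cross-validation (MISE) cost with golden-section
  search over 5–500 ms; units with < 10 spikes keep a 100 ms default.
  On *stationary* synthetic trains the MISE optimum is the upper
  bound (maximal smoothing is correct for a constant rate), which
  destroys the within-bin coincidences the decoder needs, so the
  pipeline defaults to a fixed 8 ms bandwidth — bins then retain their
  near-binary identity.  On temporally structured trains the optimizer
  finds interior minima and matches a grid search.
* Decoding uses 80 ms bins over the first 1.6 s of each trial (40 ms
  bins and finer windows behave consistently but quadruple the gram
  sizes); correlation analyses use 40 ms bins over the first second.
* Category balancing discards whole trials by seeded uniform sampling
  until every category holds ≤ 1.1× the smallest count; trials stay
  intact for trajectory analyses.  The two premature categories merge
  into one (c = 3) when the smaller falls below half the mean category
  size.
* Z-scoring is per unit over bins × trials of the estimation set only,
  applied with those parameters to test data.

## Problem sizes used in the shipped experiments

Order sweep: 10 sessions × 160 trials, 6 units, θ ∈ {1,2,3,4}, 40-trial
blocks, fixed λ = 0.1.  Predictability contrast: 12 sessions, per-
condition two-block causal split, paired t-test across sessions.
Correlation contrast: 3 sessions × 400 trials, incorrect trials
subsampled to the correct count (the |r| noise floor scales as 1/√T,
so unequal counts alone create spurious gaps).  Permutation checks:
100 resamples on an 80-trial session, plus 10 small-scale repeats for
null-rank uniformity.  These sizes trade replicate count against
session length at fixed compute; the qualitative contrasts are stable
across the seeds exercised in the test suite.

## Known limitations

* The coefficient estimator is biased upward in |·| at small trial
  counts (noise floor ≈ (π/2)^{1/2}/√T for θ = 2); compare conditions
  only at matched counts.
* The majority-vote trial rule discards per-bin evidence weights;
  absolute DEs on weak-signal data sit far above the Bayes-optimal
  pooled-likelihood error.
* λ has little numerical leverage in [0, 0.5] because the within-class
  term N = K·Kᵀ dominates; regularization is effectively carried by
  the trace-scaled jitter.
* Exact enumeration limits the generator to n ≤ 12 units; the
  estimators themselves have no such limit.
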