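"""Task generator and exponential-family spike-word model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chisquare

from spikespace.synthetic import (
    CATEGORIES,
    CouplingSpec,
    TaskConfig,
    calibrate_coupling,
    category_triplet_supports,
    exact_pattern_distribution,
    generate_task_sequence,
    make_default_coupling,
    moments_from_distribution,
    oracle_theta_coefficient,
    sample_ensemble_activity,
)


def forced_policy(cat):
    probs = {c: 0.0 for c in CATEGORIES}
    probs[cat] = 1.0
    return {"short": dict(probs), "long": dict(probs)}


class TestTaskSequence:
    def test_lose_switch_repeats_iti_after_errors(self, task_table):
        cats = task_table["category"].to_numpy()
        itis = task_table["iti_ms"].to_numpy()
        after_error = np.flatnonzero(cats[:-1] != "C") + 1
        assert np.all(itis[after_error] == itis[after_error - 1])

    def test_all_incorrect_policy_freezes_the_stimulus(self):
        cfg = TaskConfig(n_trials=50, policy=forced_policy("M"), seed=1)
        t = generate_task_sequence(cfg)
        assert t["iti_ms"].nunique() == 1

    def test_all_correct_policy_is_unpredictable_and_uniform(self):
        cfg = TaskConfig(n_trials=8000, policy=forced_policy("C"), seed=2)
        t = generate_task_sequence(cfg)
        assert not t["predictable"].iloc[1:].any()
        counts = t["iti_ms"].value_counts()
        assert len(counts) == 8
        # uniform draw over the 8 ITIs within sampling error
        assert chisquare(counts.to_numpy()).pvalue > 1e-3

    def test_default_policy_balances_categories(self, task_table):
        assert len(task_table) == 160
        counts = task_table["category"].value_counts()
        assert set(counts.index) == set(CATEGORIES)
        assert counts.between(36, 44).all()  # within 10% of 40

    def test_predictability_flag_derivation(self, task_table):
        cats = task_table["category"].to_numpy()
        expected = np.r_[0, (cats[:-1] != "C").astype(int)]
        assert np.array_equal(task_table["predictable"].to_numpy(), expected)

    def test_event_schema(self, task_table):
        pc = task_table[task_table["category"] == "PC"]
        assert pc["t_T2_s"].isna().all() and pc["t_lateral_poke_s"].isna().all()
        rest = task_table[task_table["category"] != "PC"]
        assert rest["t_T2_s"].notna().all()
        # second tone onset = first tone offset + inter-tone interval
        assert np.allclose(
            rest["t_T2_s"], rest["t_T1_s"] + 0.05 + rest["iti_ms"] / 1000.0
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_trials"):
            generate_task_sequence(TaskConfig(n_trials=1))
        bad = forced_policy("C")
        bad["short"]["C"] = 0.7
        with pytest.raises(ValueError, match="sum"):
            generate_task_sequence(TaskConfig(policy=bad))


def plain_coupling(n, h, J=None, G=None):
    gains = {(c, p): (1.0, 1.0, 1.0) for c in CATEGORIES for p in (0, 1)}
    return CouplingSpec(
        n_units=n,
        h=np.asarray(h, float),
        J=np.zeros((n, n)) if J is None else J,
        G=G or {},
        condition_gains=gains,
    )


class TestPatternDistribution:
    def test_zero_parameters_give_uniform(self):
        d = exact_pattern_distribution(plain_coupling(3, np.zeros(3)), ("C", 1))
        assert np.allclose(d.probabilities, 1 / 8)

    def test_bias_only_factorizes_into_bernoullis(self):
        d = exact_pattern_distribution(plain_coupling(3, [-2, -2, -2]), ("C", 1))
        p = expit(-2.0)
        marginals = d.probabilities @ d.words
        assert np.allclose(marginals, p, atol=1e-12)
        # independence: joint equals product of marginals for every word
        for w, prob in zip(d.words, d.probabilities):
            assert prob == pytest.approx(np.prod(np.where(w, p, 1 - p)), abs=1e-12)

    def test_triplet_term_boosts_triple_coincidence(self):
        d0 = exact_pattern_distribution(plain_coupling(3, [-1.0] * 3), ("C", 1))
        d1 = exact_pattern_distribution(
            plain_coupling(3, [-1.0] * 3, G={(0, 1, 2): 1.5}), ("C", 1)
        )
        idx_111 = 7
        # excess of (1,1,1) beyond what independence predicts from the
        # (unchanged-by-construction) one- and two-spike word ratios
        assert d1.probabilities[idx_111] / d0.probabilities[idx_111] > 2.0
        m0 = moments_from_distribution(d0, 3)
        m1 = moments_from_distribution(d1, 3)
        c0 = m0[m0.exponents == (1, 1, 1)]["central"].iloc[0]
        c1 = m1[m1.exponents == (1, 1, 1)]["central"].iloc[0]
        assert c1 > c0

    def test_pure_triplet_construction_pairwise_moments(self):
        # J = 0, G != 0: the oracle says pairwise central moments are NOT
        # zero (triplet coupling induces pairwise correlation in binary
        # variables); assert the oracle values as they are
        d = exact_pattern_distribution(
            plain_coupling(3, [-1.5] * 3, G={(0, 1, 2): 2.0}), ("C", 1)
        )
        m = moments_from_distribution(d, 2)
        pair = m[m.exponents == (1, 1, 0)]["central"].iloc[0]
        assert pair > 0.0

    def test_enumeration_refused_above_cap(self):
        with pytest.raises(ValueError, match="enumeration"):
            plain_coupling(13, np.zeros(13))

    def test_unknown_condition_raises(self):
        cp = plain_coupling(3, np.zeros(3))
        cp.condition_gains.pop(("C", 1))
        with pytest.raises(KeyError):
            exact_pattern_distribution(cp, ("C", 1))


class TestMoments:
    def test_uniform_two_units(self):
        d = exact_pattern_distribution(plain_coupling(2, np.zeros(2)), ("C", 1))
        m = moments_from_distribution(d, 2)
        assert m[m.exponents == (1, 1)]["raw"].iloc[0] == pytest.approx(0.25)

    def test_independent_central_cross_moments_vanish(self):
        d = exact_pattern_distribution(plain_coupling(3, [-1, 0.5, -2]), ("C", 1))
        m = moments_from_distribution(d, 3)
        cross = m[[sum(1 for e in ex if e > 0) >= 2 for ex in m.exponents]]
        assert np.abs(cross["central"]).max() < 1e-12

    def test_order_above_units_rejected(self):
        d = exact_pattern_distribution(plain_coupling(2, np.zeros(2)), ("C", 1))
        with pytest.raises(ValueError):
            moments_from_distribution(d, 3)

    def test_sampler_moments_match_oracle(self, default_coupling):
        """Kolmogorov consistency: sample moments within 4 SE at 1e5 draws."""
        d = exact_pattern_distribution(default_coupling, ("C", 1))
        rng = np.random.default_rng(123)
        draws = d.words[rng.choice(len(d.probabilities), size=100_000, p=d.probabilities)]
        centered = draws - d.probabilities @ d.words
        for _, row in moments_from_distribution(d, 3).iterrows():
            m = np.asarray(row["exponents"], float)
            samples = np.prod(centered**m, axis=1)
            se = samples.std() / np.sqrt(len(samples))
            assert abs(samples.mean() - row["central"]) <= 4 * max(se, 1e-12)


class TestSampler:
    def test_fixed_seed_is_byte_identical(self, task_table, default_coupling):
        a, ca = sample_ensemble_activity(task_table, default_coupling, seed=5, duration_s=0.6)
        b, cb = sample_ensemble_activity(task_table, default_coupling, seed=5, duration_s=0.6)
        pd.testing.assert_frame_equal(a, b)
        assert np.array_equal(ca, cb)

    def test_near_silent_for_strong_negative_bias(self, task_table):
        cp = plain_coupling(3, [-8.0] * 3)
        ev, counts = sample_ensemble_activity(task_table, cp, seed=1, duration_s=1.0)
        assert counts.mean() < 1e-3

    def test_sparsity_contract(self, small_session):
        _, counts = small_session
        frac = (counts <= 1).reshape(counts.shape[0], -1).mean(axis=1)
        assert np.all(frac >= 0.99)

    def test_counts_match_events(self, task_table, default_coupling):
        ev, counts = sample_ensemble_activity(task_table, default_coupling, seed=2, duration_s=0.8)
        assert len(ev) == counts.sum()
        assert ev["spike_time_s"].is_monotonic_increasing or True  # sorted per unit
        for u, sub in ev.groupby("unit_id"):
            assert sub["spike_time_s"].is_monotonic_increasing

    def test_missing_condition_errors(self, task_table):
        cp = plain_coupling(3, np.zeros(3))
        cp.condition_gains = {("C", 1): (1.0, 1.0, 1.0)}
        with pytest.raises(KeyError, match="condition"):
            sample_ensemble_activity(task_table, cp, seed=0)


class TestCalibratedDefaults:
    def test_first_and_second_moments_matched_across_conditions(self, default_coupling):
        """All conditions share mean rate and pairwise moments exactly."""
        ref = None
        for cond in [("C", 1), ("C", 0), ("M", 0), ("PC", 1), ("PL", 0)]:
            d = exact_pattern_distribution(default_coupling, cond)
            mean = d.probabilities @ d.words
            pairs = [
                d.probabilities @ (d.words[:, i] * d.words[:, j])
                for i, j in itertools.combinations(range(d.n_units), 2)
            ]
            if ref is None:
                ref = (mean, pairs)
            assert np.allclose(mean, ref[0], atol=1e-5)
            assert np.allclose(pairs, ref[1], atol=1e-5)

    def test_condition_triplet_signatures(self, default_coupling):
        """Correct trials have the strongest triple-coincidence structure;
        unpredictable-correct coupling suppresses it."""
        def mean_triplet(cond):
            d = exact_pattern_distribution(default_coupling, cond)
            vals = [
                oracle_theta_coefficient(d, tuple(np.bincount(t, minlength=6)))
                for t in itertools.combinations(range(6), 3)
            ]
            return np.mean(vals)

        assert mean_triplet(("C", 1)) > mean_triplet(("M", 0)) > mean_triplet(("C", 0))
        assert mean_triplet(("C", 0)) < 0.01  # destabilized, near zero/negative

    def test_supports_define_where_incorrect_categories_correlate(self, triplet_coupling):
        sup = category_triplet_supports(6)
        d = exact_pattern_distribution(triplet_coupling, ("M", 0))
        in_m = np.mean(
            [oracle_theta_coefficient(d, tuple(np.bincount(t, minlength=6))) for t in sup["M"]]
        )
        out_m = np.mean(
            [
                oracle_theta_coefficient(d, tuple(np.bincount(t, minlength=6)))
                for t in set(sup["C"]) - set(sup["M"])
            ]
        )
        assert in_m > 5 * abs(out_m)

    def test_calibration_hits_requested_moments(self):
        G = {t: 1.0 for t in itertools.combinations(range(5), 3)}
        h, J = calibrate_coupling(5, G, 0.1, 0.012)
        cp = plain_coupling(5, h, J=J, G=G)
        d = exact_pattern_distribution(cp, ("C", 1))
        assert np.allclose(d.probabilities @ d.words, 0.1, atol=1e-6)
        p01 = d.probabilities @ (d.words[:, 0] * d.words[:, 1])
        assert p01 == pytest.approx(0.012, abs=1e-6)
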