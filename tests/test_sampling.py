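"""Decoding-engine unit and property tests.

Expected values are closed forms (softmax arithmetic, renormalization
by hand) or come from the exhaustive path-enumeration oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldcensus.sampling import (
    BackgroundModel,
    SamplingParams,
    Vocabulary,
    apply_repetition_penalty,
    apply_temperature,
    empirical_distribution,
    enumerate_sequence_distribution,
    filter_top_k,
    filter_top_p,
    generate_autoregressive,
    generate_background,
    generate_gibbs_lr,
    gibbs_defaults,
    sample_next_token,
    total_variation,
    transform_distribution,
)
from foldcensus.synthetic import STOP_TOKEN, make_toy_markov_model


class TestTemperature:
    def test_symmetric_logits_stay_uniform(self):
        for T in (0.1, 1.0, 7.3):
            np.testing.assert_allclose(
                apply_temperature(np.array([2.5, 2.5]), T), [0.5, 0.5]
            )

    def test_closed_form_softmax(self):
        np.testing.assert_allclose(
            apply_temperature(np.array([math.log(2), 0.0]), 1.0),
            [2 / 3, 1 / 3],
            atol=1e-12,
        )

    def test_high_temperature_flattens_to_uniform(self):
        # softmax([5,0,-5]/T) deviates from uniform by ~ 5/(3T)
        out = apply_temperature(np.array([5.0, 0.0, -5.0]), 1000.0)
        assert np.all(np.abs(out - 1 / 3) < 2e-3)
        out = apply_temperature(np.array([5.0, 0.0, -5.0]), 10_000.0)
        assert np.all(np.abs(out - 1 / 3) < 1e-3)

    def test_low_temperature_concentrates_on_argmax(self):
        out = apply_temperature(np.array([1.0, 0.5, 0.0]), 1e-3)
        assert out[0] > 0.999

    @given(
        logits=st.lists(
            st.floats(-20, 20), min_size=2, max_size=8
        ),
        temperature=st.floats(0.05, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_preserves_ranking_and_normalizes(self, logits, temperature):
        logits = np.asarray(logits)
        out = apply_temperature(logits, temperature)
        assert abs(out.sum() - 1) < 1e-9
        order_in = np.argsort(logits, kind="stable")
        assert np.all(np.diff(out[order_in]) > -1e-12)

    def test_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            apply_temperature(np.array([0.0, 1.0]), 0.0)
        with pytest.raises(ValueError):
            apply_temperature(np.array([0.0, 1.0]), -1.0)


class TestTopKTopP:
    def test_top1_is_argmax(self):
        np.testing.assert_allclose(
            filter_top_k(np.array([0.5, 0.3, 0.2]), 1), [1, 0, 0]
        )

    def test_full_pool_is_identity(self):
        probs = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(filter_top_k(probs, 3), probs)

    def test_hand_renormalization(self):
        np.testing.assert_allclose(
            filter_top_k(np.array([0.5, 0.3, 0.2]), 2), [0.625, 0.375, 0]
        )

    def test_k_out_of_range(self):
        for k in (0, 4):
            with pytest.raises(ValueError):
                filter_top_k(np.array([0.5, 0.3, 0.2]), k)

    def test_nucleus_identity_at_p1(self):
        probs = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(filter_top_p(probs, 1.0), probs)

    def test_nucleus_cumulative_prefix(self):
        np.testing.assert_allclose(
            filter_top_p(np.array([0.5, 0.3, 0.2]), 0.6), [0.625, 0.375, 0]
        )

    def test_nucleus_degenerate_distribution(self):
        np.testing.assert_allclose(
            filter_top_p(np.array([1.0, 0.0, 0.0]), 0.01), [1, 0, 0]
        )

    def test_nucleus_rejects_bad_p(self):
        for p in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                filter_top_p(np.array([0.5, 0.5]), p)

    @given(
        probs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
        k1=st.integers(1, 8),
        k2=st.integers(1, 8),
    )
    @settings(max_examples=100, deadline=None)
    def test_pool_size_monotone_in_k(self, probs, k1, k2):
        probs = np.asarray(probs)
        probs = probs / probs.sum()
        k1, k2 = sorted((min(k1, probs.size), min(k2, probs.size)))
        s1 = np.count_nonzero(filter_top_k(probs, k1))
        s2 = np.count_nonzero(filter_top_k(probs, k2))
        assert s1 <= s2


class TestRepetitionPenalty:
    def test_identity_at_penalty_one(self):
        logits = np.array([1.2, -0.4, 0.0])
        np.testing.assert_array_equal(
            apply_repetition_penalty(logits, {0, 1}, 1.0), logits
        )

    def test_positive_logit_divided(self):
        out = apply_repetition_penalty(np.array([1.2, 0.5]), {0}, 1.2)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == 0.5

    def test_negative_logit_multiplied(self):
        out = apply_repetition_penalty(np.array([-1.0, 0.5]), {0}, 1.2)
        assert out[0] == pytest.approx(-1.2)

    def test_rejects_penalty_below_one(self):
        with pytest.raises(ValueError):
            apply_repetition_penalty(np.array([0.0]), {0}, 0.9)


class TestTransformChain:
    def test_neutral_chain_is_identity(self, uniform_model, neutral_params):
        probs = uniform_model.next_token_probs(())
        out = transform_distribution(probs, set(), neutral_params)
        assert np.max(np.abs(out - probs)) < 1e-9

    def test_neutral_chain_identity_on_skewed_distribution(self, neutral_params):
        probs = np.array([0.6, 0.25, 0.1, 0.05])
        out = transform_distribution(probs, set(), neutral_params)
        assert np.max(np.abs(out - probs)) < 1e-9

    def test_temperature_widens_support_never_shrinks(self, two_mode_model):
        probs = two_mode_model.next_token_probs(())
        supports = []
        for T in (0.5, 1.0, 2.0, 5.0):
            params = SamplingParams(
                temperature=T, top_k=None, top_p=1.0, repetition_penalty=1.0
            )
            supports.append(
                np.count_nonzero(transform_distribution(probs, set(), params))
            )
        assert all(a <= b for a, b in zip(supports, supports[1:]))


class TestSampling:
    def test_deterministic_model_always_argmax(self, constant_model_factory):
        model = constant_model_factory(["A", "C", STOP_TOKEN], 2, 0)
        rng = np.random.default_rng(0)
        params = SamplingParams(top_k=None, repetition_penalty=1.0)
        assert all(
            sample_next_token(model, (), params, rng) == 0 for _ in range(20)
        )

    def test_uniform_draw_frequencies(self, uniform_model, neutral_params):
        # per-symbol frequency of the first draw over many sequences
        rng = np.random.default_rng(7)
        n = 20_000
        draws = np.array(
            [
                sample_next_token(uniform_model, (), neutral_params, rng)
                for _ in range(n)
            ]
        )
        freqs = np.bincount(draws, minlength=3) / n
        assert np.all(np.abs(freqs - 1 / 3) < 0.02)


class TestGenerateAutoregressive:
    def test_stop_first_gives_empty_sequences(self, constant_model_factory):
        model = constant_model_factory(["A", "C", STOP_TOKEN], 2, 2)
        params = SamplingParams(top_k=None, repetition_penalty=1.0)
        records = generate_autoregressive(model, params, 5, seed=0)
        assert all(r.sequence == "" for r in records)

    def test_multiresidue_token_truncation(self, constant_model_factory):
        # 40 tokens x 3 residues = 120, truncated to the 100-residue cap
        model = constant_model_factory(["ACD", STOP_TOKEN], 1, 0)
        params = SamplingParams(
            top_k=None, repetition_penalty=1.0, max_tokens=40, max_residues=100
        )
        records = generate_autoregressive(model, params, 3, seed=0)
        assert all(len(r.sequence) == 100 for r in records)
        assert records[0].sequence == ("ACD" * 40)[:100]

    def test_matches_enumeration_oracle(self, uniform_model, neutral_params):
        records = generate_autoregressive(uniform_model, neutral_params, 30_000, seed=3)
        exact = enumerate_sequence_distribution(uniform_model, neutral_params, 4)
        assert abs(sum(exact.values()) - 1) < 1e-9
        tv = total_variation(exact, empirical_distribution(records))
        assert tv < 0.02

    def test_fixed_seed_bit_identical(self, two_mode_model):
        params = SamplingParams(top_k=None, max_tokens=6)
        a = generate_autoregressive(two_mode_model, params, 50, seed=9)
        b = generate_autoregressive(two_mode_model, params, 50, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        c = generate_autoregressive(two_mode_model, params, 50, seed=10)
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_top_k_beyond_vocabulary_is_interface_error(self, uniform_model):
        params = SamplingParams(top_k=950)
        with pytest.raises(ValueError):
            generate_autoregressive(uniform_model, params, 1, seed=0)

    def test_records_echo_params(self, uniform_model, neutral_params):
        records = generate_autoregressive(uniform_model, neutral_params, 2, seed=0)
        assert records[0].params is neutral_params


class _MaskedStopAt:
    """Masked model: probability 1 on 'A' before the stop position,
    probability 1 on STOP at it."""

    def __init__(self, stop_at, max_residues=100):
        self.vocabulary = Vocabulary(["A", STOP_TOKEN], 1)
        self.stop_at = stop_at

    def next_token_probs(self, context):
        return self.masked_probs((None,), 0)

    def masked_probs(self, template, position):
        if position == self.stop_at:
            return np.array([0.0, 1.0])
        return np.array([1.0, 0.0])


class TestGenerateGibbs:
    def test_all_A_template_fill(self):
        model = _MaskedStopAt(stop_at=10**9)
        records = generate_gibbs_lr(model, gibbs_defaults(seed=0), 2)
        assert all(r.sequence == "A" * 100 for r in records)

    def test_forced_stop_at_position_51_gives_length_50(self):
        model = _MaskedStopAt(stop_at=50)  # 0-based: the 51st position
        records = generate_gibbs_lr(model, gibbs_defaults(seed=0), 2)
        assert all(len(r.sequence) == 50 for r in records)

    def test_position_independent_marginals(self):
        class Marginals:
            vocabulary = Vocabulary(["A", "C", "D", STOP_TOKEN], 3)

            def next_token_probs(self, context):
                return np.array([0.5, 0.3, 0.2, 0.0])

            def masked_probs(self, template, position):
                return np.array([0.5, 0.3, 0.2, 0.0])

        records = generate_gibbs_lr(
            Marginals(), gibbs_defaults(seed=4, max_residues=20), 3000
        )
        mat = np.array([[ord(c) for c in r.sequence] for r in records])
        for col in range(20):
            freq_a = np.mean(mat[:, col] == ord("A"))
            assert abs(freq_a - 0.5) < 0.03

    def test_model_without_masked_mode_rejected(self, uniform_model, constant_model_factory):
        model = constant_model_factory(["A", STOP_TOKEN], 1, 0)
        with pytest.raises(TypeError):
            generate_gibbs_lr(model, gibbs_defaults(), 1)


class TestBackground:
    def test_one_hot_abundances(self):
        probs = np.zeros(20)
        probs[5] = 1.0  # 'G'
        bg = BackgroundModel(probs, length=5)
        records = generate_background(bg, 4, seed=0)
        assert all(r.sequence == "GGGGG" for r in records)

    def test_uniform_residue_frequencies(self):
        bg = BackgroundModel(np.full(20, 0.05), length=100)
        records = generate_background(bg, 5000, seed=1)
        joined = "".join(r.sequence for r in records)
        counts = np.array([joined.count(c) for c in "ACDEFGHIKLMNPQRSTVWY"])
        freqs = counts / counts.sum()
        assert np.all(np.abs(freqs - 0.05) < 0.005)

    def test_alphabet_closure(self):
        bg = BackgroundModel(np.full(20, 0.05), length=50)
        records = generate_background(bg, 200, seed=2)
        assert not any(set(r.sequence) & set("BJOUXZ") for r in records)
        assert all(len(r.sequence) == 50 for r in records)


class TestEnumeration:
    def test_deterministic_chain_single_sequence(self, neutral_params):
        model = make_toy_markov_model(4, "chain")
        dist = enumerate_sequence_distribution(model, neutral_params, 6)
        assert dist == {"ACD": pytest.approx(1.0)}

    def test_two_token_uniform_no_stop(self, constant_model_factory):
        class Coin:
            vocabulary = Vocabulary(["A", "C", STOP_TOKEN], 2)

            def next_token_probs(self, context):
                return np.array([0.5, 0.5, 0.0])

        params = SamplingParams(top_k=None, repetition_penalty=1.0, max_tokens=3)
        dist = enumerate_sequence_distribution(Coin(), params, 3)
        assert len(dist) == 8
        assert all(p == pytest.approx(1 / 8) for p in dist.values())

    def test_probability_conservation(self, two_mode_model, neutral_params):
        dist = enumerate_sequence_distribution(two_mode_model, neutral_params, 4)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_path_budget_enforced(self, uniform_model, neutral_params):
        with pytest.raises(ValueError):
            enumerate_sequence_distribution(uniform_model, neutral_params, 20)


class TestVocabulary:
    def test_rejects_duplicates_and_bad_tokens(self):
        with pytest.raises(ValueError):
            Vocabulary(["A", "A", STOP_TOKEN], 2)
        with pytest.raises(ValueError):
            Vocabulary(["A", "X"], 0)  # X outside the 20-letter alphabet
        with pytest.raises(ValueError):
            Vocabulary(["A", STOP_TOKEN], 5)

    def test_decode_skips_stop(self):
        v = Vocabulary(["AC", "D", STOP_TOKEN], 2)
        assert v.decode([0, 2, 1]) == "ACD"
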