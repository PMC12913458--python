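import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdyn import ConfigError, LabelSequence
from microdyn.dynamics import (complexity_vector, dfa_exponent,
                               fo_derivatives, graph_features,
                               higher_order_vector, hurst_exponent,
                               lz76_phrase_count, lz_complexity, mean_iti,
                               ngram_entropy, permutation_entropy, plv_sync,
                               sample_entropy, transition_entropy)
from microdyn.dynamics import _log_spaced_sizes
from microdyn.schema import (complexity_feature_names,
                             higher_order_feature_names)

import oracles

label_seqs = st.lists(st.integers(0, 3), min_size=10, max_size=200).map(np.array)


class TestSampleEntropy:
    def test_constant_sequence_is_perfectly_regular(self):
        assert sample_entropy(np.zeros(50)) == 0.0

    def test_alternating_sequence_is_perfectly_regular(self):
        x = np.tile([0, 1], 50)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_iid_symbols_are_irregular(self, rng):
        x = rng.integers(0, 4, size=2000)
        assert sample_entropy(x) > 0.5

    @given(seq=st.lists(st.integers(0, 3), min_size=10, max_size=150))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_discrete_fast_path_matches_template_oracle(self, seq):
        x = np.array(seq)
        ours = sample_entropy(x)
        ref = oracles.sampen_direct(x)
        if np.isnan(ref):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_continuous_path_matches_template_oracle(self, rng):
        x = rng.normal(size=300)
        assert sample_entropy(x) == pytest.approx(oracles.sampen_direct(x),
                                                  abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), m=2)


class TestPermutationEntropy:
    def test_monotone_sequence_has_single_pattern(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_iid_continuous_approaches_log_6(self, rng):
        x = rng.normal(size=10_000)
        assert permutation_entropy(x, m=3) == pytest.approx(np.log(6),
                                                            rel=0.05)

    def test_tied_alternation_gives_two_patterns(self):
        x = np.array([1, 2] * 50, dtype=float)
        assert permutation_entropy(x, m=3) == pytest.approx(np.log(2),
                                                            abs=1e-12)

    @given(seq=st.lists(st.integers(0, 5), min_size=5, max_size=100))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_exhaustive_pattern_counter(self, seq):
        x = np.array(seq, dtype=float)
        assert permutation_entropy(x) == pytest.approx(
            oracles.permen_direct(x), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            permutation_entropy(np.array([1.0, 2.0]), m=3)


class TestDfa:
    def test_white_noise_exponent_near_half(self):
        x = np.random.default_rng(42).standard_normal(4096)
        assert dfa_exponent(x) == pytest.approx(0.5, abs=0.1)

    def test_random_walk_exponent_near_three_halves(self):
        steps = np.random.default_rng(42).standard_normal(4096)
        assert dfa_exponent(np.cumsum(steps)) == pytest.approx(1.5, abs=0.15)

    def test_scale_invariance_exact(self, rng):
        x = rng.normal(size=512)
        assert dfa_exponent(3.7 * x) == pytest.approx(dfa_exponent(x),
                                                      abs=1e-12)

    def test_matches_naive_per_segment_oracle(self, rng):
        x = rng.normal(size=500)
        sizes = _log_spaced_sizes(4, len(x) // 4, 16)
        assert dfa_exponent(x) == pytest.approx(
            oracles.dfa_direct(x, sizes), abs=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigError):
            dfa_exponent(np.arange(32.0))


class TestLempelZiv:
    def test_binary_example_matches_stepwise_parser(self):
        s = np.array([int(c) for c in "0001101001000101"])
        c = lz76_phrase_count(s)
        assert c == oracles.lz76_direct(s.tolist())
        assert lz_complexity(s) == pytest.approx(c * 4 / 16)

    def test_constant_sequence_has_two_phrases(self):
        s = np.zeros(16, dtype=int)
        assert lz76_phrase_count(s) == 2
        assert lz_complexity(s) == pytest.approx(0.5)

    def test_random_beats_periodic(self, rng):
        random = rng.integers(0, 4, size=5000)
        periodic = np.tile([0, 1], 2500)
        assert lz_complexity(random) > lz_complexity(periodic)

    @given(seq=st.lists(st.integers(0, 3), min_size=1, max_size=80))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_matches_stepwise_parser(self, seq):
        assert lz76_phrase_count(np.array(seq)) == oracles.lz76_direct(seq)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ConfigError):
            lz76_phrase_count(np.array([], dtype=int))


class TestHurst:
    def test_white_noise_near_half(self):
        x = np.random.default_rng(42).standard_normal(4096)
        assert hurst_exponent(x) == pytest.approx(0.5, abs=0.15)

    def test_persistent_ar1_above_0_6(self):
        rng = np.random.default_rng(0)
        x = np.empty(4096)
        x[0] = 0.0
        for t in range(1, 4096):
            x[t] = 0.9 * x[t - 1] + rng.standard_normal()
        assert hurst_exponent(x) > 0.6

    def test_scale_invariance(self, rng):
        x = rng.normal(size=512)
        assert hurst_exponent(2.5 * x) == pytest.approx(hurst_exponent(x),
                                                        abs=1e-12)

    def test_constant_input_is_nan(self):
        assert np.isnan(hurst_exponent(np.full(256, 3.0)))

    def test_matches_naive_rs_oracle(self, rng):
        x = rng.normal(size=500)
        sizes = _log_spaced_sizes(8, len(x) // 2, 16)
        assert hurst_exponent(x) == pytest.approx(
            oracles.hurst_rs_direct(x, sizes), abs=1e-6)


class TestComplexityVector:
    def _seq(self, rng, n=2048):
        return LabelSequence(labels=rng.integers(0, 4, size=n), fs=128.0, K=4)

    def test_exactly_15_named_features(self, rng):
        out = complexity_vector(self._seq(rng))
        assert list(out) == complexity_feature_names()
        assert len(out) == 15

    def test_constant_sequence_sampen_zero_at_all_scales(self):
        seq = LabelSequence(labels=np.zeros(1024, dtype=int), fs=128.0, K=4)
        out = complexity_vector(seq)
        for scale in (1, 2, 4):
            assert out[f"sampen_s{scale}"] == 0.0

    def test_scale_one_equals_direct_calls(self, rng):
        seq = self._seq(rng)
        out = complexity_vector(seq)
        assert out["sampen_s1"] == sample_entropy(seq.flat)
        assert out["lzc_s1"] == lz_complexity(seq.flat)
        assert out["dfa_s1"] == dfa_exponent(seq.flat)


class TestTransitionEntropy:
    def test_deterministic_cycle_has_zero_entropy(self):
        seq = np.tile([0, 1, 2, 3], 25)
        assert transition_entropy(seq, K=4) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_approaches_4_log_4(self, rng):
        seq = rng.integers(0, 4, size=100_000)
        assert transition_entropy(seq, K=4) == pytest.approx(4 * np.log(4),
                                                             abs=0.01)

    def test_single_state_sequence_has_zero_entropy(self):
        assert transition_entropy(np.zeros(10, dtype=int), K=4) == 0.0


class TestMeanIti:
    def test_examples(self):
        assert mean_iti(np.array([0, 0, 1, 1, 0, 0])) == pytest.approx(2.0)
        assert mean_iti(np.array([0, 1, 0, 1, 0])) == pytest.approx(1.0)

    def test_constant_sequence_is_nan(self):
        assert np.isnan(mean_iti(np.zeros(10, dtype=int)))


class TestNgramEntropy:
    def test_constant_sequence(self):
        assert ngram_entropy(np.zeros(10, dtype=int)) == 0.0

    def test_period_three_cycle(self):
        seq = np.tile([0, 1, 2], 31)[:92]
        assert ngram_entropy(seq, n=3) == pytest.approx(np.log(3), abs=1e-12)

    @given(seq=st.lists(st.integers(0, 1), min_size=3, max_size=100))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_relabeling_invariance(self, seq):
        seq = np.array(seq)
        shifted = seq + 2  # states {2, 3} instead of {0, 1}
        assert ngram_entropy(seq) == pytest.approx(ngram_entropy(shifted),
                                                   abs=1e-12)

    @given(seq=label_seqs)
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_dictionary_counting_oracle(self, seq):
        assert ngram_entropy(seq) == pytest.approx(
            oracles.ngram_entropy_direct(seq), abs=1e-9)


class TestPlv:
    def test_constant_sequence_convention(self):
        assert plv_sync(np.full(64, 2)) == 1.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            v = plv_sync(rng.integers(0, 4, size=256))
            assert 0.0 <= v <= 1.0

    def test_pure_tone_phase_sweeps_uniformly(self):
        t = np.arange(1024)
        x = np.sin(2 * np.pi * 8 * t / 1024)  # integer number of cycles
        assert plv_sync(x) < 0.1


class TestFoDerivatives:
    def test_uniform_occupancy_gives_zeros(self):
        seq = np.tile([0, 1, 2, 3], 25)
        out = fo_derivatives(seq, K=4)
        assert list(out.values()) == pytest.approx([0.0, 0.0, 0.0])

    def test_linear_occupancy_profile(self):
        seq = np.concatenate([np.full(10, 0), np.full(20, 1),
                              np.full(30, 2), np.full(40, 3)])
        out = fo_derivatives(seq, K=4)
        assert list(out.values()) == pytest.approx([0.1, 0.1, 0.1])

    @given(seq=label_seqs)
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_telescoping_sum(self, seq):
        out = fo_derivatives(seq, K=4)
        fo0 = np.mean(seq == 0)
        fo3 = np.mean(seq == 3)
        assert sum(out.values()) == pytest.approx(fo3 - fo0, abs=1e-12)


class TestGraphFeatures:
    def test_full_transition_graph(self, rng):
        seq = rng.integers(0, 4, size=2000)
        density, _, _ = graph_features(seq, K=4)
        assert density == 1.0

    def test_directed_cycle(self):
        seq = np.tile([0, 1, 2, 3], 25)
        density, avg_degree, clustering = graph_features(seq, K=4)
        assert density == pytest.approx(4 / 12)
        assert avg_degree == pytest.approx(2.0)
        assert clustering == 0.0

    def test_single_state_graph_is_empty(self):
        density, avg_degree, clustering = graph_features(
            np.zeros(10, dtype=int), K=4)
        assert (density, avg_degree, clustering) == (0.0, 0.0, 0.0)


class TestHigherOrderVector:
    def _seq(self, rng):
        return LabelSequence(labels=rng.integers(0, 4, size=2000), fs=128.0,
                             K=4)

    def test_exactly_10_named_features(self, rng):
        out = higher_order_vector(self._seq(rng))
        assert list(out) == higher_order_feature_names()
        assert len(out) == 10

    def test_cfc_mock_only_behind_flag(self, rng):
        seq = self._seq(rng)
        base = higher_order_vector(seq)
        with_cfc = higher_order_vector(seq, include_cfc=True, cfc_seed=1)
        assert not any(k.startswith("cfc_") for k in base)
        assert sum(k.startswith("cfc_") for k in with_cfc) == 4
        again = higher_order_vector(seq, include_cfc=True, cfc_seed=1)
        assert with_cfc == again

    def test_time_shuffling_changes_iti_not_full_graph_density(self, rng):
        seq = self._seq(rng)
        shuffled = LabelSequence(labels=rng.permutation(seq.flat), fs=128.0,
                                 K=4)
        a = higher_order_vector(seq)
        b = higher_order_vector(shuffled)
        assert a["graph_density"] == b["graph_density"] == 1.0
        assert a["mean_inter_transition_interval"] != \
            b["mean_inter_transition_interval"]

    def test_deterministic(self, rng):
        seq = self._seq(rng)
        assert higher_order_vector(seq) == higher_order_vector(seq)
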