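"""Conditional-emission HMM engine: likelihood, decoding, training,
sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flexmotif as fm
from flexmotif.hmm import TrainConfig, baum_welch, encode, sample

from conftest import enum_posterior, random_hmm, random_seq


def uniform_one_state():
    return fm.ConditionalEmissionHMM(np.ones(1), np.ones((1, 1)),
                                     np.full((1, 4, 4), 0.25))


class TestLikelihood:
    def test_uniform_closed_form(self):
        # one state, unconditional uniform emissions: P = (1/4)^3
        assert fm.log_likelihood(uniform_one_state(), "ACG") == \
            pytest.approx(np.log(1 / 64), abs=1e-12)

    def test_first_symbol_conditioned_on_sentinel(self):
        em = np.tile(np.array([[0.7, 0.1, 0.1, 0.1],
                               [0.4, 0.2, 0.2, 0.2],
                               [0.25, 0.25, 0.25, 0.25],
                               [0.1, 0.3, 0.3, 0.3]]), (1, 1, 1))
        h = fm.ConditionalEmissionHMM(np.ones(1), np.ones((1, 1)), em)
        assert fm.log_likelihood(h, "A", sentinel="A") == \
            pytest.approx(np.log(0.7), abs=1e-12)
        assert fm.log_likelihood(h, "A", sentinel="T") == \
            pytest.approx(np.log(0.1), abs=1e-12)

    def test_matches_enumeration_on_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            h = random_hmm(rng, int(rng.integers(2, 5)))
            seq = random_seq(rng, int(rng.integers(1, 7)))
            ll_ref, _ = enum_posterior(h, seq)
            assert fm.log_likelihood(h, seq) == pytest.approx(ll_ref,
                                                              abs=1e-10)

    def test_invalid_residue_rejected(self):
        with pytest.raises(fm.HMMError):
            fm.log_likelihood(uniform_one_state(), "ACXG")

    def test_long_sequence_is_stable(self):
        rng = np.random.default_rng(0)
        h = random_hmm(rng, 3)
        ll = fm.log_likelihood(h, random_seq(rng, 100_000))
        assert np.isfinite(ll)


class TestPosterior:
    def test_one_state_identity(self):
        gamma = fm.posterior_decode(uniform_one_state(), "ACGT")
        np.testing.assert_allclose(gamma, 1.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            h = random_hmm(rng, int(rng.integers(2, 5)))
            seq = random_seq(rng, int(rng.integers(2, 8)))
            _, g_ref = enum_posterior(h, seq)
            g = fm.posterior_decode(h, seq)
            np.testing.assert_allclose(g, g_ref, atol=1e-10)
            np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 4), st.integers(2, 5), st.integers(0, 10_000))
    def test_enumeration_property(self, n_states, length, seed):
        rng = np.random.default_rng(seed)
        h = random_hmm(rng, n_states)
        seq = random_seq(rng, length)
        _, g_ref = enum_posterior(h, seq)
        np.testing.assert_allclose(fm.posterior_decode(h, seq), g_ref,
                                   atol=1e-10)

    def test_impossible_state_gets_zero(self):
        # state 1 can only emit A: gamma is 0 there wherever a C appears
        em = np.stack([np.full((4, 4), 0.25),
                       np.tile([1.0, 0, 0, 0], (4, 1))])
        h = fm.ConditionalEmissionHMM([0.5, 0.5],
                                      [[0.5, 0.5], [0.5, 0.5]], em)
        gamma = fm.posterior_decode(h, "ACA")
        assert gamma[1, 1] == 0.0
        assert gamma[0, 1] > 0 and gamma[2, 1] > 0

    def test_matches_unconditional_hmm_implementation(self):
        # order-0 degenerate case cross-checked against hmmlearn
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        n = 3
        pi = rng.dirichlet(np.ones(n))
        A = rng.dirichlet(np.ones(n), n)
        B = rng.dirichlet(np.ones(4), n)            # unconditional emissions
        ours = fm.ConditionalEmissionHMM(
            pi, A, np.repeat(B[:, None, :], 4, axis=1))
        ref = hmmlearn.CategoricalHMM(n_components=n)
        ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, A, B
        seq = random_seq(rng, 40)
        obs = encode(seq).reshape(-1, 1)
        np.testing.assert_allclose(fm.posterior_decode(ours, seq),
                                   ref.predict_proba(obs), atol=1e-9)
        assert fm.log_likelihood(ours, seq) == pytest.approx(
            ref.score(obs), abs=1e-9)


class TestBaumWelch:
    def test_trace_monotone_and_fixed_point(self, cre_pfm):
        gen = fm.build_tffm(cre_pfm, "order1")
        # data drawn from the init model itself: near a fixed point
        seqs = [sample(gen.hmm, 101, seed=500 + i)[0] for i in range(80)]
        trained, trace = baum_welch(gen.hmm, seqs,
                                    TrainConfig(max_iterations=15))
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-9)
        # total gain stays at the noise-fitting scale (~ #free params / 2
        # nats), tiny next to the ~137 nats/sequence likelihood itself
        n_params = gen.hmm.emissions.size + gen.hmm.transitions.size
        assert trace[-1] - trace[0] < n_params
        assert diffs[-1] < diffs[0]

    def test_structural_zeros_preserved(self, cre_pfm):
        gen = fm.build_tffm(cre_pfm, "order1")
        ds = fm.simulate_dataset(fm.SimConfig(n_sequences=50,
                                              planted_model=gen, seed=6))
        trained, _ = baum_welch(gen.hmm, [s.residues for s in ds.sequences],
                                TrainConfig(max_iterations=5))
        assert np.all(trained.transitions[gen.hmm.transitions == 0] == 0)
        assert np.all(trained.initial[gen.hmm.initial == 0] == 0)
        assert np.all(trained.transitions >= 0)
        assert np.all(trained.emissions >= 0)

    def test_frozen_and_tied_parameters(self, cre_pfm):
        det = fm.build_tffm(cre_pfm, "detailed")
        ds = fm.simulate_dataset(fm.SimConfig(n_sequences=40,
                                              planted_model=det, seed=8))
        seqs = [s.residues for s in ds.sequences]
        trained, _ = det.train(seqs, TrainConfig(max_iterations=3))
        np.testing.assert_array_equal(trained.hmm.emissions,
                                      det.hmm.emissions)
        zero = fm.build_tffm(cre_pfm, "order0")
        trained0, _ = zero.train(seqs, TrainConfig(max_iterations=3))
        for s in range(trained0.hmm.n_states):
            rows = trained0.hmm.emissions[s]
            np.testing.assert_allclose(rows - rows[0][None, :], 0.0,
                                       atol=1e-12)

    def test_empty_and_all_n_rejected(self):
        h = uniform_one_state()
        with pytest.raises(fm.HMMError):
            baum_welch(h, [])
        with pytest.raises(fm.HMMError):
            baum_welch(h, ["NNNN"])


class TestSampling:
    def test_deterministic_cycle(self):
        # two states on a strict cycle with indicator emissions: ACACAC...
        em = np.zeros((2, 4, 4))
        em[0, :, 0] = 1.0           # state 0 emits A
        em[1, :, 1] = 1.0           # state 1 emits C
        h = fm.ConditionalEmissionHMM([1, 0], [[0, 1], [1, 0]], em)
        seq, path = sample(h, 6, seed=0)
        assert seq == "ACACAC"
        np.testing.assert_array_equal(path, [0, 1, 0, 1, 0, 1])

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        h = random_hmm(rng, 3)
        seq1, path1 = sample(h, 200, seed=4)
        seq2, path2 = sample(h, 200, seed=4)
        assert seq1 == seq2
        np.testing.assert_array_equal(path1, path2)

    def test_dinucleotide_frequencies_match_model(self):
        table = np.array([[0.5, 0.2, 0.2, 0.1],
                          [0.1, 0.4, 0.1, 0.4],
                          [0.3, 0.3, 0.2, 0.2],
                          [0.25, 0.25, 0.25, 0.25]])
        h = fm.ConditionalEmissionHMM(np.ones(1), np.ones((1, 1)),
                                      table[None])
        seq, _ = sample(h, 100_000, seed=13)
        codes = encode(seq)
        counts = np.zeros((4, 4))
        np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
        freq = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, table, atol=0.01)

    def test_length_validated(self):
        with pytest.raises(fm.HMMError):
            sample(uniform_one_state(), 0, seed=0)


class TestValidation:
    @pytest.mark.parametrize("field,breaker", [
        ("initial", lambda a: a * 1.1),
        ("transitions", lambda a: a + 0.05),
        ("emissions", lambda a: np.clip(a - 0.05, 0, 1)),
    ])
    def test_non_stochastic_tables_rejected(self, field, breaker):
        rng = np.random.default_rng(2)
        h = random_hmm(rng, 2)
        kwargs = {"initial": h.initial, "transitions": h.transitions,
                  "emissions": h.emissions}
        kwargs[field] = breaker(kwargs[field])
        with pytest.raises(fm.HMMError):
            fm.ConditionalEmissionHMM(**kwargs)
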