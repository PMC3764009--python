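"""Benchmarking protocol: splitting, backgrounds, ROC, statistics."""

import numpy as np
import pytest

import flexmotif as fm
from flexmotif.hmm import TrainConfig, encode

from conftest import mixed_pfm, random_seq


def mann_whitney_auc(fg, bg):
    """Independent oracle: AUC as the tie-corrected pairwise-comparison
    probability P(fg > bg) + 0.5 P(fg == bg)."""
    fg, bg = np.asarray(fg), np.asarray(bg)
    wins = (fg[:, None] > bg[None, :]).sum()
    ties = (fg[:, None] == bg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(fg) * len(bg))


class TestMakePlan:
    def test_benchmark_scale_layout(self):
        rng = np.random.default_rng(0)
        plan = fm.make_plan(rng.random(1800), init_size=600, k=10, seed=1)
        assert len(plan.init_set) == 600
        for train, test in plan.folds:
            assert len(test) == 120 and len(train) == 1080
            assert not set(train) & set(test)
            assert not set(train) & set(plan.init_set)
        all_tests = np.concatenate([t for _, t in plan.folds])
        assert len(np.unique(all_tests)) == 1200

    def test_init_set_is_top_signal(self):
        signals = np.arange(700, dtype=float)
        plan = fm.make_plan(signals, init_size=600, k=10, seed=0)
        assert set(plan.init_set) == set(range(100, 700))

    def test_ties_resolved_by_input_order(self):
        signals = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        plan = fm.make_plan(signals, init_size=2, k=2, seed=0)
        assert set(plan.init_set) == {0, 1}

    def test_zero_init_two_folds(self):
        plan = fm.make_plan(np.arange(10.0), init_size=0, k=2, seed=3)
        assert sorted(len(t) for _, t in plan.folds) == [5, 5]

    def test_too_small_rejected(self):
        with pytest.raises(fm.EvaluationError):
            fm.make_plan(np.arange(100.0), init_size=600, k=10, seed=0)


class TestBackgrounds:
    def test_markov_background_learns_homopolymer(self):
        chain = fm.markov_background(["A" * 500])
        seqs = fm.sample_markov_background(chain, 5, [100], seed=1)
        frac_a = sum(s.count("A") for s in seqs) / 500
        assert frac_a > 0.95

    def test_dinucleotide_frequencies_recovered(self):
        rng = np.random.default_rng(5)
        train = [random_seq(rng, 2000) for _ in range(10)]
        chain = fm.markov_background(train)
        sampled = fm.sample_markov_background(chain, 1, [100_000], seed=2)[0]
        codes = encode(sampled)
        counts = np.zeros((4, 4))
        np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
        freq = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, chain.emissions[0], atol=0.01)

    def test_seed_reproducibility(self):
        chain = fm.markov_background(["ACGTACGTAC" * 50])
        a = fm.sample_markov_background(chain, 3, [50, 60, 70], seed=7)
        assert a == fm.sample_markov_background(chain, 3, [50, 60, 70], seed=7)

    def test_empty_training_rejected(self):
        with pytest.raises(fm.EvaluationError):
            fm.markov_background([])


class TestGcMatching:
    def test_pool_equals_foreground_gives_permutation(self):
        rng = np.random.default_rng(9)
        fg = [random_seq(rng, 50) for _ in range(30)]
        out = fm.gc_matched_subsample(list(fg), fg, seed=1)
        assert sorted(out) == sorted(fg)

    def test_only_matching_bin_used(self):
        fg = ["GGCC" * 5]                       # 100% GC
        pool = ["GGCC" * 5, "GCGC" * 5, "AATT" * 5, "ATAT" * 5]
        out = fm.gc_matched_subsample(pool, fg, seed=0)
        assert out[0] in pool[:2]

    def test_exhausted_bin_raises(self):
        fg = ["GGCC", "GGCC"]
        pool = ["CCGG", "AATT"]
        with pytest.raises(fm.EvaluationError, match="exhausted"):
            fm.gc_matched_subsample(pool, fg, seed=0)

    def test_output_size_matches_foreground(self):
        rng = np.random.default_rng(10)
        fg = [random_seq(rng, 40) for _ in range(12)]
        pool = fg * 3
        assert len(fm.gc_matched_subsample(pool, fg, seed=2)) == 12


class TestRocAuc:
    def test_perfect_separation(self):
        assert fm.roc_auc([1.0] * 5, [0.0] * 7).auc == pytest.approx(1.0)

    def test_identical_distributions(self):
        scores = [0.1, 0.4, 0.4, 0.9]
        assert fm.roc_auc(scores, scores).auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            fg = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0],
                            rng.integers(2, 20))
            bg = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0],
                            rng.integers(2, 20))
            res = fm.roc_auc(fg, bg)
            assert res.auc == pytest.approx(mann_whitney_auc(fg, bg),
                                            abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(22)
        res = fm.roc_auc(rng.random(50), rng.random(40))
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(1 - res.specificity) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(fm.EvaluationError):
            fm.roc_auc([], [1.0])


class TestCompareMethods:
    def test_identical_columns(self):
        col = np.linspace(0.6, 0.9, 10)
        res = fm.compare_methods(np.stack([col, col], axis=1), ["a", "b"])
        assert res.p_values[("a", "b")] == pytest.approx(1.0)
        np.testing.assert_allclose(res.ratio_to_best, 1.0)
        assert res.similar_to_best.all()

    def test_dominating_column_significant(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0.6, 0.85, 20)
        res = fm.compare_methods(np.stack([a, a + 0.05], axis=1), ["a", "b"])
        assert res.p_values[("a", "b")] < 0.01

    def test_ratio_similarity_threshold(self):
        res = fm.compare_methods(np.array([[0.90, 0.95]] * 6), ["a", "b"])
        assert res.ratio_to_best[0, 0] == pytest.approx(0.90 / 0.95)
        assert not res.similar_to_best[0, 0]
        assert res.similar_to_best[0, 1]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(32)
        table = rng.uniform(0.5, 1.0, (12, 3))
        r1 = fm.compare_methods(table, ["a", "b", "c"])
        r2 = fm.compare_methods(table[:, ::-1], ["c", "b", "a"])
        for pair, p in r1.p_values.items():
            assert r2.p_values[pair] == pytest.approx(p, abs=1e-12)


class TestSignalScoreCorrelation:
    def test_monotone_scores_give_rho_one(self):
        signals = np.arange(100.0)
        scores = signals ** 2 + 1
        res = fm.signal_score_correlation(signals, scores)
        assert res.rho == pytest.approx(1.0)
        assert res.slope_pvalue < 1e-6

    def test_independent_scores_flat(self):
        rng = np.random.default_rng(41)
        res = fm.signal_score_correlation(rng.random(400), rng.random(400))
        assert abs(res.rho) < 0.5
        assert res.slope_pvalue > 0.05

    def test_constant_scores_degenerate(self):
        res = fm.signal_score_correlation(np.arange(40.0), np.ones(40))
        assert res.degenerate and res.rho == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(fm.EvaluationError):
            fm.signal_score_correlation(np.arange(10.0), np.arange(10.0))


@pytest.fixture(scope="module")
def tiny_dataset():
    pfm = mixed_pfm("TGACGTCA")
    gen = fm.build_tffm(pfm, "order1")
    ds = fm.simulate_dataset(fm.SimConfig(n_sequences=120,
                                          planted_model=gen, seed=51))
    return ds, pfm


class TestCrossValidate:

    def test_reproducible_given_seed(self, tiny_dataset):
        ds, pfm = tiny_dataset
        seqs = [s.residues for s in ds.sequences]
        kwargs = dict(method="order1", init_size=20, k=5, seed=3,
                      train_config=TrainConfig(max_iterations=3))
        r1 = fm.crossvalidate(seqs, ds.signals, pfm, **kwargs)
        r2 = fm.crossvalidate(seqs, ds.signals, pfm, **kwargs)
        assert r1.pooled.auc == r2.pooled.auc
        assert r1.fold_aucs == r2.fold_aucs

    def test_background_equal_to_foreground_is_chance(self, tiny_dataset):
        ds, pfm = tiny_dataset
        seqs = [s.residues for s in ds.sequences]
        # %GC-matched subsampling from the foreground itself returns a
        # permutation of it: identical score multisets, AUC 0.5
        res = fm.crossvalidate(seqs, ds.signals, pfm, method="order1",
                               background=seqs, init_size=20, k=5, seed=3,
                               train_config=TrainConfig(max_iterations=2))
        # 100 pooled scores: AUC sampling s.d. ~0.04, so allow ~3 s.d.
        assert res.pooled.auc == pytest.approx(0.5, abs=0.12)

    def test_pwm_method_runs_without_training(self, tiny_dataset):
        ds, pfm = tiny_dataset
        seqs = [s.residues for s in ds.sequences]
        res = fm.crossvalidate(seqs, ds.signals, pfm, method="pwm",
                               init_size=20, k=5, seed=3)
        assert 0.5 < res.pooled.auc <= 1.0
        assert len(res.fg_scores) == 100
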