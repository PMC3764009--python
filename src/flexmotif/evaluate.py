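"""Benchmarking protocol: cross-validation, background construction,
ROC/AUC, method-comparison statistics and score-signal correlation.

The protocol mirrors how ChIP-seq motif models are usually assessed: the
top-signal peaks form an initialization set used only to seed the models
(here, the PFM the harness supplies stands in for a de-novo motif found in
those peaks); the remaining peaks are split 10-fold, a model is trained on
each fold's training sequences, every test sequence (foreground and an
equally sized background) gets its best-hit score, and the threshold sweep
over those scores yields a ROC curve.  Two background constructions are
provided: %GC-matched subsampling from a user-supplied candidate pool, and
sampling from a one-state first-order Markov chain estimated from the
training sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .hmm import ConditionalEmissionHMM, TrainConfig, _sample_with_rng, encode
from .models import TFFM, FlexEdit, PositionFrequencyMatrix, apply_flex_edit, \
    build_tffm
from .pwm import build_pwm, pwm_best_hit
from .scan import best_hit, pocc


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

@dataclass
class CrossValPlan:
    """Index layout for initialization + k-fold cross-validation.

    ``init_set`` holds the indices of the top-signal sequences (used only to
    seed models); ``folds`` partitions the remainder into (train, test)
    pairs with train 9x test for the default k=10."""

    init_set: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]


def make_plan(signal_values, init_size: int = 600, k: int = 10,
              seed: int = 0) -> CrossValPlan:
    """Top ``init_size`` signals (ties by input order) form the init set;
    the rest is shuffled by ``seed`` and split into k folds."""
    signals = np.asarray(signal_values, dtype=float)
    n = len(signals)
    if n < init_size + k:
        raise EvaluationError(f"{n} sequences < init_size + k = "
                              f"{init_size + k}")
    order = np.argsort(-signals, kind="stable")     # ties keep input order
    init_set = np.sort(order[:init_size])
    rest = np.sort(order[init_size:])
    rng = np.random.default_rng(seed)
    rest = rest[rng.permutation(len(rest))]
    test_sets = np.array_split(rest, k)
    folds = [(np.sort(np.concatenate(test_sets[:i] + test_sets[i + 1:])),
              np.sort(test_sets[i]))
             for i in range(k)]
    return CrossValPlan(init_set, folds)


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------

def markov_background(train_seqs: list[str],
                      pseudocount: float = 1.0) -> ConditionalEmissionHMM:
    """One-state first-order chain estimated from all adjacent nucleotide
    pairs of the training sequences."""
    if not train_seqs:
        raise EvaluationError("empty training set for background estimation")
    counts = np.zeros((4, 4))
    for s in train_seqs:
        codes = encode(s)
        codes = codes[codes < 4]
        if len(codes) >= 2:
            np.add.at(counts, (codes[:-1], codes[1:]), 1.0)
    counts += pseudocount
    table = counts / counts.sum(axis=1, keepdims=True)
    return ConditionalEmissionHMM(np.ones(1), np.ones((1, 1)),
                                  table[None, :, :], ["bg"])


def sample_markov_background(generator: ConditionalEmissionHMM, n: int,
                             lengths, seed: int) -> list[str]:
    """``n`` sequences with the requested lengths from the background chain."""
    lengths = list(lengths)
    if len(lengths) == 1:
        lengths = lengths * n
    if len(lengths) != n:
        raise EvaluationError("need one length per requested sequence")
    rng = np.random.default_rng(seed)
    return [_sample_with_rng(generator, L, rng, 0)[0] for L in lengths]


def gc_fraction(residues: str) -> float:
    acgt = sum(residues.count(c) for c in "ACGT")
    return (residues.count("G") + residues.count("C")) / max(acgt, 1)


def gc_matched_subsample(pool: list, foreground: list, seed: int,
                         bin_width: float = 0.01) -> list:
    """One pool sequence per foreground sequence from the same %GC bin
    (1-percentage-point bins), sampled without replacement."""
    def res(x):
        return x if isinstance(x, str) else x.residues

    def gc_bin(x):
        return int(np.floor(gc_fraction(res(x)) / bin_width + 1e-9))

    rng = np.random.default_rng(seed)
    bins: dict[int, list[int]] = {}
    for i, s in enumerate(pool):
        bins.setdefault(gc_bin(s), []).append(i)
    for b in bins.values():
        rng.shuffle(b)
    out = []
    for s in foreground:
        b = gc_bin(s)
        if not bins.get(b):
            raise EvaluationError(
                f"%GC bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}) "
                "exhausted in the background pool")
        out.append(pool[bins[b].pop()])
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(fg_scores, bg_scores) -> ROCResult:
    """ROC by threshold sweep over the observed scores (tied scores grouped
    at one threshold) and trapezoidal AUC; foreground above threshold counts
    as a true positive."""
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if len(fg) == 0 or len(bg) == 0:
        raise EvaluationError("both score lists must be non-empty")
    y = np.concatenate([np.ones(len(fg)), np.zeros(len(bg))])
    scores = np.concatenate([fg, bg])
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, sensitivity=tpr,
                     specificity=1.0 - fpr, auc=auc)


# ---------------------------------------------------------------------------
# Cross-validated discrimination
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    fold_rocs: list[ROCResult]
    pooled: ROCResult
    fg_scores: dict[int, float]     # original sequence index -> test score
    models: list = field(default_factory=list)

    @property
    def fold_aucs(self) -> list[float]:
        return [r.auc for r in self.fold_rocs]


def _model_scorer(method: str, seed_pfm: PositionFrequencyMatrix,
                  edits: list[FlexEdit], train_seqs: list[str],
                  train_config: TrainConfig | None, score: str):
    """Build + train one fold's model; return (model, per-sequence scorer)."""
    if method == "pwm":
        model = build_pwm(seed_pfm)
        return model, lambda s: pwm_best_hit(model, s).score
    model = build_tffm(seed_pfm, method)
    for e in edits:
        model = apply_flex_edit(model, e)
    clean = [s for s in train_seqs if "N" not in s]
    model, _ = model.train(clean, train_config)
    if score == "pocc":
        return model, lambda s: pocc(model, s)
    return model, lambda s: best_hit(model, s).score


def crossvalidate(sequences: list[str], signals, seed_pfm,
                  method: str = "order1", edits: list[FlexEdit] | None = None,
                  background: str | list[str] = "markov",
                  score: str = "best_hit", init_size: int = 600, k: int = 10,
                  seed: int = 0, train_config: TrainConfig | None = None,
                  keep_models: bool = False) -> CrossValResult:
    """Full protocol for one method on one dataset.

    ``method`` is a TFFM kind or ``"pwm"``; ``background`` is either
    ``"markov"`` (one-state first-order chain fitted per fold) or a
    candidate pool for %GC-matched subsampling.  Per-fold ROC curves plus a
    pooled ROC over the concatenated fold scores are returned; foreground
    test scores are kept per original index for score-signal analysis."""
    edits = edits or []
    seqs = [s if isinstance(s, str) else s.residues for s in sequences]
    plan = make_plan(signals, init_size=init_size, k=k, seed=seed)
    init = set(plan.init_set.tolist())
    fold_rocs = []
    all_fg, all_bg = [], []
    fg_scores: dict[int, float] = {}
    models = []
    for f, (train_idx, test_idx) in enumerate(plan.folds):
        assert not (set(train_idx) | set(test_idx)) & init
        train = [seqs[i] for i in train_idx]
        test = [seqs[i] for i in test_idx]
        model, scorer = _model_scorer(method, seed_pfm, edits, train,
                                      train_config, score)
        if isinstance(background, str) and background == "markov":
            chain = markov_background(train)
            bg = sample_markov_background(chain, len(test),
                                          [len(t) for t in test],
                                          seed=seed * 1000 + f)
        else:
            bg = [b if isinstance(b, str) else b.residues
                  for b in gc_matched_subsample(list(background), test,
                                                seed=seed * 1000 + f)]
        fg_s = [scorer(s) for s in test]
        bg_s = [scorer(s) for s in bg]
        for i, v in zip(test_idx, fg_s):
            fg_scores[int(i)] = float(v)
        fold_rocs.append(roc_auc(fg_s, bg_s))
        all_fg.extend(fg_s)
        all_bg.extend(bg_s)
        if keep_models:
            models.append(model)
    pooled = roc_auc(all_fg, all_bg)
    return CrossValResult(fold_rocs, pooled, fg_scores, models)


# ---------------------------------------------------------------------------
# Method comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    methods: list[str]
    p_values: dict[tuple[str, str], float]       # BH-corrected, symmetric
    ratio_to_best: np.ndarray                    # datasets x methods
    similar_to_best: np.ndarray                  # ratio >= threshold


def compare_methods(auc_table: np.ndarray, methods: list[str],
                    similarity_threshold: float = 0.95) -> MethodComparison:
    """Pairwise Wilcoxon signed-rank tests on per-dataset AUC differences,
    Benjamini-Hochberg corrected across pairs, plus the per-dataset
    ratio-to-best table with its similarity flag."""
    table = np.asarray(auc_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != len(methods):
        raise EvaluationError("auc_table must be datasets x methods")
    if len(methods) < 2:
        raise EvaluationError("need at least two methods")
    pairs = [(i, j) for i in range(len(methods))
             for j in range(i + 1, len(methods))]
    raw = []
    for i, j in pairs:
        diff = table[:, i] - table[:, j]
        if np.allclose(diff, 0.0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(table[:, i], table[:, j]).pvalue))
    corrected = multipletests(raw, method="fdr_bh")[1] if pairs else []
    p_values = {}
    for (i, j), p in zip(pairs, corrected):
        p_values[(methods[i], methods[j])] = float(p)
        p_values[(methods[j], methods[i])] = float(p)
    best = table.max(axis=1, keepdims=True)
    ratio = np.where(best > 0, table / np.where(best > 0, best, 1), 1.0)
    return MethodComparison(list(methods), p_values, ratio,
                            ratio >= similarity_threshold)


@dataclass
class SignalScoreCorrelation:
    rho: float
    slope: float
    slope_pvalue: float
    bin_medians: np.ndarray
    degenerate: bool = False


def signal_score_correlation(signals, scores,
                             n_bins: int = 20) -> SignalScoreCorrelation:
    """Spearman correlation between signal-percentile rank and the median
    prediction score within each 5-percentile bin, plus the OLS slope
    p-value on the same points.

    Binning by percentile smooths the per-peak scatter so the monotone
    trend (if any) is visible.  Constant scores are degenerate: rho is
    reported as 0 with the flag set."""
    signals = np.asarray(signals, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(signals) != len(scores) or len(signals) < n_bins:
        raise EvaluationError(f"need >= {n_bins} paired observations")
    order = np.argsort(signals, kind="stable")
    groups = np.array_split(order, n_bins)
    medians = np.array([np.median(scores[g]) for g in groups])
    ranks = np.arange(1, n_bins + 1, dtype=float)
    if np.allclose(medians, medians[0]):
        return SignalScoreCorrelation(0.0, 0.0, 1.0, medians, degenerate=True)
    rho = float(stats.spearmanr(ranks, medians).statistic)
    reg = stats.linregress(ranks, medians)
    return SignalScoreCorrelation(rho, float(reg.slope), float(reg.pvalue),
                                  medians)
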