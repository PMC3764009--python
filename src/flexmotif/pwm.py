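"""Log-odds position weight matrix baseline.

Weights are ``log2((p + pc) / (b + pc))`` for PFM probability ``p``,
background frequency ``b`` and pseudocount ``pc``; a window's score is the
plain sum of its per-position weights, maximized over positions and strands.
"""

from __future__ import annotations

import numpy as np

from .hmm import encode
from .io_formats import NucleotideSequence, revcomp
from .models import ModelError, PositionFrequencyMatrix
from .scan import Hit, ScanError

UNIFORM_BG = np.full(4, 0.25)


class PWM:
    """L x 4 log-odds weights plus the background used to build them."""

    def __init__(self, weights: np.ndarray, background: np.ndarray,
                 name: str = "pwm"):
        self.weights = np.asarray(weights, dtype=float)
        self.background = np.asarray(background, dtype=float)
        self.name = name
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ModelError("PWM weights must be L x 4")
        if not np.all(np.isfinite(self.weights)):
            raise ModelError("PWM weights must be finite")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


def build_pwm(pfm: PositionFrequencyMatrix,
              background: np.ndarray | None = None,
              pseudocount: float | None = None) -> PWM:
    """Log-odds matrix from a PFM.

    The default pseudocount is 0.01 and the default background uniform.  A
    zero PFM entry with zero pseudocount would give an infinite weight and
    is rejected."""
    bg = UNIFORM_BG if background is None else np.asarray(background, float)
    if not np.isclose(bg.sum(), 1.0, atol=1e-9) or np.any(bg <= 0):
        raise ModelError("background must be a positive probability vector")
    pc = 0.01 if pseudocount is None else float(pseudocount)
    if pc < 0:
        raise ModelError("pseudocount must be >= 0")
    if pc == 0 and np.any(pfm.probs == 0):
        raise ModelError("zero PFM entry requires a positive pseudocount")
    weights = np.log2((pfm.probs + pc) / (bg[None, :] + pc))
    return PWM(weights, bg, name=pfm.name)


def window_scores(pwm: PWM, residues: str) -> np.ndarray:
    """Score of every window start on the given strand.  ``N`` positions
    contribute the background expectation of their column."""
    codes = encode(residues.upper())
    L = pwm.length
    T = len(codes)
    if T < L:
        raise ScanError(f"sequence length {T} shorter than PWM length {L}")
    col_expect = (pwm.weights * pwm.background[None, :]).sum(axis=1)
    per_pos = np.empty((T, L))
    for i in range(L):
        w = np.append(pwm.weights[i], col_expect[i])    # code 4 = N
        per_pos[:, i] = w[codes]
    starts = T - L + 1
    return np.array([per_pos[s:s + L, :].diagonal().sum()
                     for s in range(starts)])


def pwm_best_hit(pwm: PWM, seq, both_strands: bool = True) -> Hit:
    """Maximal windowed log-odds sum over all positions and both strands;
    ties broken by smaller forward start, then + strand."""
    if isinstance(seq, NucleotideSequence):
        ident, residues = seq.identifier, seq.residues
    else:
        ident, residues = "seq", str(seq).upper()
    L = pwm.length
    T = len(residues)
    fwd = window_scores(pwm, residues)
    candidates = [(-fwd[s], s, 0, "+") for s in range(len(fwd))]
    if both_strands:
        rev = window_scores(pwm, revcomp(residues))
        # rc window starting at s covers forward interval [T-L-s, T-s)
        candidates += [(-rev[s], T - L - s, 1, "-") for s in range(len(rev))]
    neg, start, _, strand = min(candidates)
    site = residues[start:start + L]
    if strand == "-":
        site = revcomp(site)
    return Hit(ident, start, start + L, strand, float(-neg), site)
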