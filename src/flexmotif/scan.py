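"""Scoring sequences with a TFFM.

The score of a site ending at position ``t`` is the posterior probability
(from forward-backward decoding) of being in a *final matching state* at
``t``.  Sequences are scanned on both strands: the reverse strand is scored
by scanning the reverse complement with the same model and mapping the
resulting intervals back to forward coordinates; models are never
reverse-complemented.

For flexible-length models the width of the site ending at ``t`` is taken
from the most probable state path ending in a final state there (Viterbi
backtrack), as the posterior alone does not determine where the site began.

The probability of occupancy (Pocc) aggregates the per-position scores into
the probability that at least one site is present anywhere in the sequence:
``Pocc = 1 - prod_t (1 - P_t)``, the product running over both strands by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hmm import posterior_decode, viterbi, viterbi_path_ending_at
from .io_formats import NucleotideSequence, revcomp
from .models import TFFM


class ScanError(ValueError):
    pass


@dataclass
class Hit:
    """The best-scoring predicted site of one sequence.

    start/end are 0-based half-open on the forward coordinate system; the
    site sequence is reported on the hit's strand."""

    identifier: str
    start: int
    end: int
    strand: str
    score: float
    site: str

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class HitTrack:
    """Per-position, per-strand posterior probabilities of a site ending
    there.

    ``plus[t]`` is the probability that a forward-strand site ends at
    position ``t``.  ``minus[i]`` is the probability of a reverse-strand
    site whose forward-strand interval starts at ``i`` (i.e. whose
    reverse-complement reading ends there).  Width arrays give the site
    width associated with each score (constant for fixed-length models).
    """

    identifier: str
    plus: np.ndarray
    minus: np.ndarray | None
    widths_plus: np.ndarray
    widths_minus: np.ndarray | None

    def scores(self) -> np.ndarray:
        """All per-position scores across the populated strands."""
        if self.minus is None:
            return self.plus
        return np.concatenate([self.plus, self.minus])


def _residues(seq) -> tuple[str, str]:
    if isinstance(seq, NucleotideSequence):
        return seq.identifier, seq.residues
    return "seq", str(seq).upper()


def _strand_scores(model: TFFM, residues: str) -> tuple[np.ndarray, np.ndarray]:
    """Final-state posterior and site width per position, in the scanned
    orientation."""
    gamma = posterior_decode(model.hmm, residues)
    finals = sorted(model.final_states)
    scores = gamma[:, finals].sum(axis=1)
    T = len(residues)
    lo, hi = model.length_range
    widths = np.full(T, lo, dtype=np.int64)
    if lo != hi:
        delta, psi = viterbi(model.hmm, residues)
        sub = delta[:, finals]
        for t in range(T):
            if not np.isfinite(sub[t]).any():
                widths[t] = 0
                continue
            s = finals[int(np.argmax(sub[t]))]
            path = viterbi_path_ending_at(model.hmm, delta, psi, t, s)
            w = 0
            for state in path[::-1]:
                if state in model.match_states:
                    w += 1
                else:
                    break
            widths[t] = w
    return scores, widths


def hit_track(model: TFFM, seq, both_strands: bool = True) -> HitTrack:
    """Posterior site-end probabilities at every position, on both strands
    unless ``both_strands`` is false."""
    ident, residues = _residues(seq)
    if len(residues) < model.length_range[0]:
        raise ScanError(f"sequence {ident!r} shorter than the minimum motif "
                        f"width {model.length_range[0]}")
    plus, w_plus = _strand_scores(model, residues)
    minus = w_minus = None
    if both_strands:
        rc_scores, rc_widths = _strand_scores(model, revcomp(residues))
        # rc position t maps to forward coordinate T-1-t
        minus = rc_scores[::-1].copy()
        w_minus = rc_widths[::-1].copy()
    return HitTrack(ident, plus, minus, w_plus, w_minus)


def best_hit(model: TFFM, seq, both_strands: bool = True) -> Hit:
    """The maximal-score site over all positions and strands.

    Ties are broken by smaller forward start, then by the + strand."""
    ident, residues = _residues(seq)
    track = hit_track(model, seq, both_strands=both_strands)
    T = len(residues)
    lo, _ = model.length_range
    candidates = []   # (-score, start, strand_rank, end, strand)
    for t in range(T):
        w = int(track.widths_plus[t]) or lo
        if t + 1 - w < 0:      # a site of width w cannot end here
            continue
        candidates.append((-track.plus[t], t + 1 - w, 0, t + 1, "+"))
    if track.minus is not None:
        for i in range(T):
            w = int(track.widths_minus[i]) or lo
            if i + w > T:
                continue
            candidates.append((-track.minus[i], i, 1, i + w, "-"))
    if not candidates:
        raise ScanError(f"no admissible site position in {ident!r}")
    neg_score, start, _, end, strand = min(candidates)
    site = residues[start:end]
    if strand == "-":
        site = revcomp(site)
    return Hit(ident, start, end, strand, float(-neg_score), site)


def pocc(model: TFFM, seq, both_strands: bool = True) -> float:
    """Probability of occupancy: 1 - prod_t (1 - P_t) over the per-position
    site-end posteriors (both strands included by default)."""
    track = hit_track(model, seq, both_strands=both_strands)
    p = np.clip(track.scores(), 0.0, 1.0)
    return float(1.0 - np.exp(np.log1p(-p).sum())) if np.all(p < 1) else 1.0


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_hits_bed(hits: list[Hit], path: str | Path,
                   chrom_of: dict[str, str] | None = None) -> None:
    """BED6: chrom (the sequence identifier unless remapped), start, end,
    name, score (posterior), strand."""
    with open(path, "w") as out:
        for i, h in enumerate(hits):
            chrom = (chrom_of or {}).get(h.identifier, h.identifier)
            out.write(f"{chrom}\t{h.start}\t{h.end}\thit{i + 1}"
                      f"\t{h.score:.6f}\t{h.strand}\n")


def write_hits_table(hits: list[Hit], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("sequence\tstart\tend\tstrand\tscore\tsite\n")
        for h in hits:
            out.write(f"{h.identifier}\t{h.start}\t{h.end}\t{h.strand}"
                      f"\t{h.score:.6f}\t{h.site}\n")


def write_track(track: HitTrack, path: str | Path) -> None:
    """Wiggle-like text: position, forward-strand score, reverse-strand
    score (empty when single-stranded)."""
    with open(path, "w") as out:
        out.write(f"# track {track.identifier}\n")
        out.write("position\tplus\tminus\n")
        for t in range(len(track.plus)):
            m = "" if track.minus is None else f"{track.minus[t]:.6g}"
            out.write(f"{t}\t{track.plus[t]:.6g}\t{m}\n")
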