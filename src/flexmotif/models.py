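"""Motif models: position frequency matrices and TFFM topologies.

A TFFM (transcription factor flexible model) wraps a conditional-emission
HMM with motif bookkeeping.  Three topologies are supported:

* ``order0`` -- one background state plus one state per motif position, all
  with unconditional (row-tied) emissions: a PFM expressed as an HMM.
* ``order1`` -- same state layout, but each state's emissions may depend on
  the previously observed nucleotide.  At initialization the four conditional
  rows of each match state are identical (the seed PFM row); dinucleotide
  dependencies emerge only through training.
* ``detailed`` -- every order-1 state is decomposed into four
  nucleotide-specific states with indicator emissions (frozen); dinucleotide
  dependencies, including the probability of *starting* a site after a given
  background nucleotide, live entirely in the transitions.

Flexible-length edits (gap insertion, skippable position, alternative core,
flexible edge) rewire transitions declaratively and apply uniformly to all
three topologies: an edit touches state *groups* (one state per group for
order0/order1, four for detailed), so the same edit list yields the same
width range everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import (ConditionalEmissionHMM, TrainConfig, baum_welch, encode)

KINDS = ("order0", "order1", "detailed")


class ModelError(ValueError):
    pass


@dataclass
class PositionFrequencyMatrix:
    """L x 4 per-position nucleotide probabilities (rows sum to 1)."""

    probs: np.ndarray
    name: str = "pfm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or len(self.probs) < 1:
            raise ModelError(f"PFM must be L x 4, got {self.probs.shape}")
        if np.any(self.probs < 0):
            raise ModelError("PFM entries must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("PFM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def pfm_from_sites(sites: list[str], pseudocount: float = 0.0,
                   name: str = "pfm") -> PositionFrequencyMatrix:
    """Column nucleotide frequencies of equal-length aligned sites:
    probs[i][n] = (count + pseudocount) / (N + 4 * pseudocount)."""
    if not sites:
        raise ModelError("no sites given")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ModelError("sites must all have equal length")
    counts = np.zeros((L, 4))
    for s in sites:
        codes = encode(s)
        if np.any(codes > 3):
            raise ModelError("sites may not contain N")
        counts[np.arange(L), codes] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PositionFrequencyMatrix(probs, name=name)


@dataclass
class FlexEdit:
    """A declarative flexible-length edit.

    kind:
      * ``gap_insert``    -- positions (p,): a spacer state inserted between
                             motif positions p and p+1, used with the given
                             branch probability; widths (L, L+1).
      * ``skip_position`` -- positions (p,): position p kept with the branch
                             probability, skipped otherwise; widths (L-1, L).
      * ``alternative_core`` -- positions (start, end): a parallel variant of
                             that span (emissions from ``alt_pfm``), the
                             original path taken with the branch probability.
      * ``flexible_edge`` -- positions (p,): the motif may end at position p
                             with the branch probability.
    """

    kind: str
    positions: tuple[int, ...]
    prob: float
    alt_pfm: "PositionFrequencyMatrix | None" = None

    def __post_init__(self) -> None:
        if self.kind not in ("gap_insert", "skip_position",
                             "alternative_core", "flexible_edge"):
            raise ModelError(f"unknown edit kind {self.kind!r}")
        if not 0.0 < self.prob < 1.0:
            raise ModelError("branch probability must be strictly in (0, 1)")


@dataclass
class TFFM:
    """A conditional-emission HMM plus motif bookkeeping."""

    kind: str
    hmm: ConditionalEmissionHMM
    match_map: dict[int, list[int]]          # motif position (1..L) -> states
    final_states: set[int]
    length_range: tuple[int, int]
    match_states: set[int] = field(default_factory=set)
    edits: list[FlexEdit] = field(default_factory=list)
    name: str = "tffm"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ModelError(f"unknown model kind {self.kind!r}")
        if not self.final_states:
            raise ModelError("final_states must be non-empty")
        if not self.match_states:
            self.match_states = {s for ss in self.match_map.values() for s in ss}
        self.hmm.validate()

    @property
    def motif_length(self) -> int:
        return max(self.match_map)

    @property
    def is_flexible(self) -> bool:
        return self.length_range[0] != self.length_range[1]

    def frozen_tags(self) -> set[str]:
        """Parameters never re-estimated: the indicator emissions of a
        detailed model are definitional."""
        if self.kind == "detailed":
            return {"emissions"}
        return set()

    def tied_rows(self) -> set[int]:
        """States whose conditional emission rows stay identical (order-0)."""
        if self.kind == "order0":
            return set(range(self.hmm.n_states))
        return set()

    def train(self, seqs: list[str], config: TrainConfig | None = None,
              ) -> tuple["TFFM", list[float]]:
        """Baum-Welch on full-length sequences; returns the trained model and
        the log-likelihood trace."""
        trained, trace = baum_welch(self.hmm, seqs, config,
                                    frozen=self.frozen_tags(),
                                    tied_rows=self.tied_rows())
        out = TFFM(self.kind, trained, dict(self.match_map),
                   set(self.final_states), self.length_range,
                   set(self.match_states), list(self.edits), self.name)
        return out, trace


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

DEFAULT_BG_TO_MOTIF = 1.0 / 101.0   # ~one site expected per 101-nt window


def build_tffm(pfm: PositionFrequencyMatrix, kind: str,
               bg_to_motif_prob: float = DEFAULT_BG_TO_MOTIF,
               name: str | None = None) -> TFFM:
    """Initialize a TFFM of the requested topology from a seed PFM."""
    if kind not in KINDS:
        raise ModelError(f"unknown model kind {kind!r}")
    if not 0.0 < bg_to_motif_prob < 1.0:
        raise ModelError("bg_to_motif_prob must be in (0, 1)")
    name = name or f"{pfm.name}_{kind}"
    if kind == "detailed":
        return _build_detailed(pfm, bg_to_motif_prob, name)
    return _build_chain(pfm, kind, bg_to_motif_prob, name)


def _build_chain(pfm: PositionFrequencyMatrix, kind: str, p: float,
                 name: str) -> TFFM:
    L = pfm.length
    n = L + 1
    pi = np.zeros(n)
    pi[0] = 1.0 - p
    pi[1] = p
    A = np.zeros((n, n))
    A[0, 0] = 1.0 - p
    A[0, 1] = p
    for i in range(1, L):
        A[i, i + 1] = 1.0
    A[L, 0] = 1.0
    em = np.empty((n, 4, 4))
    em[0] = 0.25
    for i in range(1, n):
        em[i] = np.tile(pfm.probs[i - 1], (4, 1))
    labels = ["bg"] + [f"m{i}" for i in range(1, n)]
    hmm = ConditionalEmissionHMM(pi, A, em, labels)
    return TFFM(kind, hmm, {i: [i] for i in range(1, n)}, {L}, (L, L),
                name=name)


def _build_detailed(pfm: PositionFrequencyMatrix, p: float, name: str) -> TFFM:
    L = pfm.length
    n = 4 * (L + 1)        # 4 background states + 4 per position
    nt = "ACGT"

    def bg(m): return m
    def st(i, m): return 4 * i + m      # position i (1..L), nucleotide m

    pi = np.zeros(n)
    A = np.zeros((n, n))
    for m in range(4):
        pi[bg(m)] = (1.0 - p) / 4.0
        for m2 in range(4):
            A[bg(m), bg(m2)] = (1.0 - p) / 4.0
            A[bg(m), st(1, m2)] = p * pfm.probs[0, m2]
            A[st(L, m), bg(m2)] = 0.25
        pi[st(1, m)] = p * pfm.probs[0, m]
        for i in range(1, L):
            for m2 in range(4):
                A[st(i, m), st(i + 1, m2)] = pfm.probs[i, m2]
    em = np.zeros((n, 4, 4))
    for m in range(4):
        em[bg(m), :, m] = 1.0
        for i in range(1, L + 1):
            em[st(i, m), :, m] = 1.0
    labels = [f"bg.{nt[m]}" for m in range(4)]
    for i in range(1, L + 1):
        labels += [f"m{i}.{nt[m]}" for m in range(4)]
    hmm = ConditionalEmissionHMM(pi, A, em, labels)
    match_map = {i: [st(i, m) for m in range(4)] for i in range(1, L + 1)}
    return TFFM("detailed", hmm, match_map, set(match_map[L]), (L, L),
                name=name)


# ---------------------------------------------------------------------------
# Flexible-length edits
# ---------------------------------------------------------------------------

def _bg_states(model: TFFM) -> list[int]:
    return sorted(set(range(model.hmm.n_states)) - model.match_states)


def _group_dist(model: TFFM, src: list[int], dst: list[int]) -> np.ndarray:
    """Per-source-state distribution over dst, renormalized; rows that give
    dst zero mass fall back to the group-average row."""
    sub = model.hmm.transitions[np.ix_(src, dst)]
    tot = sub.sum(axis=1, keepdims=True)
    avg = sub.sum(axis=0)
    avg = avg / avg.sum() if avg.sum() > 0 else np.full(len(dst), 1 / len(dst))
    out = np.where(tot > 0, sub / np.where(tot > 0, tot, 1), avg[None, :])
    return out


def _grown(model: TFFM, extra: int, extra_em: np.ndarray,
           extra_labels: list[str]) -> ConditionalEmissionHMM:
    """Return a copy of the model's HMM with `extra` appended states."""
    h = model.hmm
    n = h.n_states
    pi = np.concatenate([h.initial, np.zeros(extra)])
    A = np.zeros((n + extra, n + extra))
    A[:n, :n] = h.transitions
    # appended rows are filled by the caller before validation
    em = np.concatenate([h.emissions, extra_em], axis=0)
    hmm = object.__new__(ConditionalEmissionHMM)
    hmm.initial, hmm.transitions, hmm.emissions = pi, A, em
    hmm.state_labels = list(h.state_labels) + extra_labels
    return hmm


def apply_flex_edit(model: TFFM, edit: FlexEdit) -> TFFM:
    """Return a new TFFM with the edit applied; the input is not mutated."""
    L = model.motif_length
    for p in edit.positions:
        if not 1 <= p <= L:
            raise ModelError(f"edit position {p} outside motif 1..{L}")
    touched = {p for e in model.edits for p in e.positions}
    if touched & set(edit.positions):
        raise ModelError(f"positions {sorted(touched & set(edit.positions))} "
                         "already edited")
    if edit.kind == "skip_position":
        out = _edit_skip(model, edit)
    elif edit.kind == "gap_insert":
        out = _edit_gap(model, edit)
    elif edit.kind == "flexible_edge":
        out = _edit_edge(model, edit)
    else:
        out = _edit_alt_core(model, edit)
    out.edits = model.edits + [edit]
    out.hmm.validate()
    return out


def _edit_skip(model: TFFM, edit: FlexEdit) -> TFFM:
    (p,) = edit.positions
    if p < 2 or p >= model.motif_length:
        raise ModelError("skip_position needs an interior position (2..L-1)")
    h = model.hmm.copy()
    prev = model.match_map[p - 1]
    cur = model.match_map[p]
    nxt = model.match_map[p + 1]
    dist_next = _group_dist(model, cur, nxt)    # what follows the skipped slot
    jump = dist_next.mean(axis=0)
    for k, u in enumerate(prev):
        h.transitions[u, cur] *= edit.prob
        h.transitions[u, nxt] += (1.0 - edit.prob) * jump
    lo, hi = model.length_range
    return TFFM(model.kind, h, dict(model.match_map), set(model.final_states),
                (lo - 1, hi), set(model.match_states), name=model.name)


def _edit_gap(model: TFFM, edit: FlexEdit) -> TFFM:
    (p,) = edit.positions
    if p >= model.motif_length:
        raise ModelError("gap_insert needs a position before the last one")
    cur = model.match_map[p]
    nxt = model.match_map[p + 1]
    dist_next = _group_dist(model, cur, nxt)
    if model.kind == "detailed":
        extra = 4
        extra_em = np.zeros((4, 4, 4))
        for m in range(4):
            extra_em[m, :, m] = 1.0
        extra_labels = [f"m{p}gap.{c}" for c in "ACGT"]
    else:
        extra = 1
        extra_em = np.full((1, 4, 4), 0.25)
        extra_labels = [f"m{p}gap"]
    n0 = model.hmm.n_states
    gap = list(range(n0, n0 + extra))
    h = _grown(model, extra, extra_em, extra_labels)
    h.transitions[:n0, :n0] = model.hmm.transitions
    for k, u in enumerate(cur):
        h.transitions[u, nxt] = model.hmm.transitions[u, nxt] * (1.0 - edit.prob)
        h.transitions[u, gap] = edit.prob / extra    # uniform spacer entry
    for g in gap:
        h.transitions[g, nxt] = dist_next.mean(axis=0)
    h.validate()
    lo, hi = model.length_range
    mm = dict(model.match_map)
    return TFFM(model.kind, h, mm, set(model.final_states), (lo, hi + 1),
                set(model.match_states) | set(gap), name=model.name)


def _edit_edge(model: TFFM, edit: FlexEdit) -> TFFM:
    (p,) = edit.positions
    if p >= model.motif_length:
        raise ModelError("flexible_edge needs a position before the last one")
    h = model.hmm.copy()
    cur = model.match_map[p]
    last = model.match_map[model.motif_length]
    bg = _bg_states(model)
    exit_dist = _group_dist(model, last, bg)   # how the motif re-enters bg
    row = exit_dist.mean(axis=0)
    for u in cur:
        h.transitions[u, :] *= (1.0 - edit.prob)
        h.transitions[u, bg] += edit.prob * row
    lo, hi = model.length_range
    return TFFM(model.kind, h, dict(model.match_map),
                set(model.final_states) | set(cur), (min(lo, p), hi),
                set(model.match_states), name=model.name)


def _edit_alt_core(model: TFFM, edit: FlexEdit) -> TFFM:
    if len(edit.positions) != 2:
        raise ModelError("alternative_core needs (start, end) positions")
    start, end = edit.positions
    if start > end:
        raise ModelError("alternative_core start must be <= end")
    span = end - start + 1
    if edit.alt_pfm is None or edit.alt_pfm.length != span:
        raise ModelError(f"alternative_core needs alt_pfm of length {span}")
    alt = edit.alt_pfm.probs
    per = 4 if model.kind == "detailed" else 1
    extra = per * span
    n0 = model.hmm.n_states
    if model.kind == "detailed":
        extra_em = np.zeros((extra, 4, 4))
        for j in range(span):
            for m in range(4):
                extra_em[4 * j + m, :, m] = 1.0
        extra_labels = [f"m{start + j}alt.{c}" for j in range(span)
                        for c in "ACGT"]
    else:
        extra_em = np.stack([np.tile(alt[j], (4, 1)) for j in range(span)])
        extra_labels = [f"m{start + j}alt" for j in range(span)]
    h = _grown(model, extra, extra_em, extra_labels)
    h.transitions[:n0, :n0] = model.hmm.transitions

    def alt_group(j):          # 0-based within the span
        return list(range(n0 + per * j, n0 + per * (j + 1)))

    entry_src = (model.match_map[start - 1] if start > 1 else _bg_states(model))
    orig_first = model.match_map[start]
    # split the entry mass: original span with prob, variant with 1-prob
    for u in entry_src:
        mass = h.transitions[u, orig_first].sum()
        h.transitions[u, orig_first] *= edit.prob
        if model.kind == "detailed":
            h.transitions[u, alt_group(0)] = (1.0 - edit.prob) * mass * alt[0]
        else:
            h.transitions[u, alt_group(0)] = (1.0 - edit.prob) * mass
    # chain within the variant span
    for j in range(span - 1):
        for m, u in enumerate(alt_group(j)):
            if model.kind == "detailed":
                h.transitions[u, alt_group(j + 1)] = alt[j + 1]
            else:
                h.transitions[u, alt_group(j + 1)] = 1.0
    # exit: variant end behaves like the original end of the span
    orig_last = model.match_map[end]
    exit_row = model.hmm.transitions[orig_last, :].mean(axis=0)
    exit_row = exit_row / exit_row.sum()
    full = np.zeros(h.n_states)
    full[:n0] = exit_row
    for u in alt_group(span - 1):
        h.transitions[u, :] = full
    h.validate()
    finals = set(model.final_states)
    if end == model.motif_length:
        finals |= set(alt_group(span - 1))
    mm = dict(model.match_map)
    new_match = set(model.match_states) | set(range(n0, n0 + extra))
    return TFFM(model.kind, h, mm, finals, model.length_range, new_match,
                name=model.name)
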