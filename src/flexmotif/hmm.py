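"""Discrete hidden Markov machinery over the DNA alphabet with first-order
conditional emissions.

Every state carries a 4x4 emission table ``e_s(n | m)``: the probability of
emitting nucleotide ``n`` given that the *previously observed* nucleotide was
``m``.  Because the conditioning is on the observed symbol (not the hidden
state), the forward/backward recursions stay standard -- the emission term at
step ``t`` is simply looked up with the pair ``(seq[t-1], seq[t])``.  A fixed
sentinel nucleotide (``A`` by default) conditions the first position so the
likelihood is defined from position one.

States whose four conditional rows are identical behave exactly like an
ordinary unconditional-emission HMM state; order-0 motif models are expressed
that way and kept row-tied during training.

Numerics use per-position scaling (Rabiner-style), stable for sequences up to
~1e5 nt.  ``N`` residues emit with the uniform marginal probability 0.25 in
every state, and conditioning on an ``N`` uses the mean of the four rows, so
likelihoods remain defined during scanning; training rejects sequences
containing ``N`` upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
DEFAULT_SENTINEL = "A"

_PROB_ATOL = 1e-9


class HMMError(ValueError):
    """Invalid model, parameters or input sequence."""


def encode(residues: str) -> np.ndarray:
    """Map a DNA string (A/C/G/T/N, upper case) to integer codes 0..4."""
    try:
        return np.fromiter((NT_INDEX[c] for c in residues), dtype=np.int64,
                           count=len(residues))
    except KeyError as exc:
        raise HMMError(f"invalid residue {exc.args[0]!r}; expected A/C/G/T/N")


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[int(c)] for c in codes)


@dataclass
class ConditionalEmissionHMM:
    """HMM with per-state emissions conditioned on the previous observed
    nucleotide.

    Parameters
    ----------
    initial : (n,) array
        Start distribution pi over states.
    transitions : (n, n) array
        Row-stochastic transition matrix A.
    emissions : (n, 4, 4) array
        ``emissions[s, m, n] = P(emit n | state s, previous observed m)``.
        A state with four identical rows has order-0 (unconditional)
        emissions.
    state_labels : list of str, optional
        Human-readable labels, used by model serialization.
    """

    initial: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    state_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        if not self.state_labels:
            self.state_labels = [f"s{i}" for i in range(self.n_states)]
        self.validate()

    @property
    def n_states(self) -> int:
        return self.initial.shape[0]

    def validate(self) -> None:
        n = self.n_states
        if self.transitions.shape != (n, n):
            raise HMMError(f"transition matrix shape {self.transitions.shape} "
                           f"does not match {n} states")
        if self.emissions.shape != (n, 4, 4):
            raise HMMError(f"emission tensor shape {self.emissions.shape} "
                           f"!= ({n}, 4, 4)")
        if len(self.state_labels) != n:
            raise HMMError("state label count does not match state count")
        for name, arr, axis in (("initial", self.initial, None),
                                ("transition", self.transitions, 1),
                                ("emission", self.emissions, 2)):
            if np.any(arr < -_PROB_ATOL):
                raise HMMError(f"negative {name} probability")
            sums = arr.sum() if axis is None else arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=_PROB_ATOL):
                raise HMMError(f"{name} probabilities do not sum to 1 "
                               f"(max deviation {np.max(np.abs(sums - 1)):.3g})")

    def copy(self) -> "ConditionalEmissionHMM":
        return ConditionalEmissionHMM(self.initial.copy(),
                                      self.transitions.copy(),
                                      self.emissions.copy(),
                                      list(self.state_labels))

    # -- emission lookup ---------------------------------------------------

    def _emission_lookup(self) -> np.ndarray:
        """(n, 5, 5) table extending emissions to the N code: an observed N
        emits with probability 0.25 in every state, and conditioning on N
        averages the four conditional rows."""
        n = self.n_states
        ext = np.empty((n, 5, 5))
        ext[:, :4, :4] = self.emissions
        ext[:, 4, :4] = self.emissions.mean(axis=1)
        ext[:, :, 4] = 0.25
        return ext


@dataclass
class TrainConfig:
    """Baum-Welch settings.

    pseudocount is added to every *non-structural-zero* expected count before
    renormalization; structural zeros (parameters exactly 0 at initialization)
    define the topology and are never resurrected.  Training stops when the
    mean per-sequence log-likelihood improves by less than ``ll_tolerance``
    or after ``max_iterations`` rounds.
    """

    pseudocount: float = 1e-4
    max_iterations: int = 100
    ll_tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise HMMError("pseudocount must be > 0")
        if self.max_iterations < 1:
            raise HMMError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Batched scaled forward/backward.  Sequences of one common length form a
# batch (axis 0); all recursions are vectorized over the batch and states.
# ---------------------------------------------------------------------------

def _emission_terms(hmm: ConditionalEmissionHMM, obs: np.ndarray,
                    sentinel: int) -> np.ndarray:
    """(B, T, n) emission probabilities for a batch of encoded sequences."""
    prev = np.empty_like(obs)
    prev[:, 0] = sentinel
    prev[:, 1:] = obs[:, :-1]
    ext = hmm._emission_lookup()            # (n, 5, 5)
    # em[b, t, s] = ext[s, prev[b,t], obs[b,t]]
    return ext[:, prev, obs].transpose(1, 2, 0)


def _forward(hmm, em):
    """Scaled forward pass.  Returns (alpha, scale) with
    alpha: (B, T, n) scaled so each alpha[b, t] sums to 1,
    scale: (B, T) normalization constants."""
    B, T, n = em.shape
    alpha = np.empty((B, T, n))
    scale = np.empty((B, T))
    a = hmm.initial[None, :] * em[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] <= 0):
        raise HMMError("sequence has zero probability under the model")
    alpha[:, 0, :] = a / scale[:, 0, None]
    A = hmm.transitions
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ A) * em[:, t, :]
        scale[:, t] = a.sum(axis=1)
        if np.any(scale[:, t] <= 0):
            raise HMMError("sequence has zero probability under the model")
        alpha[:, t, :] = a / scale[:, t, None]
    return alpha, scale


def _backward(hmm, em, scale):
    B, T, n = em.shape
    beta = np.empty((B, T, n))
    beta[:, T - 1, :] = 1.0
    A = hmm.transitions
    for t in range(T - 2, -1, -1):
        beta[:, t, :] = ((beta[:, t + 1, :] * em[:, t + 1, :]) @ A.T)
        beta[:, t, :] /= scale[:, t + 1, None]
    return beta


def _batch(seqs: list[np.ndarray]) -> dict[int, tuple[np.ndarray, list[int]]]:
    """Group encoded sequences by length -> (stacked array, original indices)."""
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    return {L: (np.stack([seqs[i] for i in idx]), idx)
            for L, idx in groups.items()}


def log_likelihood(hmm: ConditionalEmissionHMM, residues: str,
                   sentinel: str = DEFAULT_SENTINEL) -> float:
    """Natural-log probability of a sequence under the model.

    The first position's emission is conditioned on the sentinel nucleotide;
    termination is free (no end state)."""
    obs = _check_seq(residues)
    em = _emission_terms(hmm, obs[None, :], NT_INDEX[sentinel])
    _, scale = _forward(hmm, em)
    return float(np.log(scale).sum())


def posterior_decode(hmm: ConditionalEmissionHMM, residues: str,
                     sentinel: str = DEFAULT_SENTINEL) -> np.ndarray:
    """Posterior state probabilities gamma[t, s] = P(state s at t | seq)."""
    obs = _check_seq(residues)
    em = _emission_terms(hmm, obs[None, :], NT_INDEX[sentinel])
    alpha, scale = _forward(hmm, em)
    beta = _backward(hmm, em, scale)
    gamma = alpha[0] * beta[0]
    return gamma / gamma.sum(axis=1, keepdims=True)


def _check_seq(residues: str) -> np.ndarray:
    if len(residues) < 1:
        raise HMMError("empty sequence")
    return encode(residues)


def viterbi(hmm: ConditionalEmissionHMM, residues: str,
            sentinel: str = DEFAULT_SENTINEL) -> np.ndarray:
    """Backpointer table of the most probable state path.

    Returns (delta, psi): delta[t, s] is the max log joint probability of a
    path ending in state s at t; psi[t, s] the arg max predecessor."""
    obs = _check_seq(residues)
    em = _emission_terms(hmm, obs[None, :], NT_INDEX[sentinel])[0]
    T, n = em.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transitions)
        logem = np.log(em)
        delta = np.full((T, n), -np.inf)
        psi = np.zeros((T, n), dtype=np.int64)
        delta[0] = np.log(hmm.initial) + logem[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA          # (from, to)
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(n)] + logem[t]
    return delta, psi


def viterbi_path_ending_at(hmm, delta, psi, t: int, state: int) -> np.ndarray:
    """Backtrack the most probable path over positions 0..t that ends in
    ``state`` at position t."""
    path = np.empty(t + 1, dtype=np.int64)
    path[t] = state
    for u in range(t, 0, -1):
        path[u - 1] = psi[u, path[u]]
    return path


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def baum_welch(hmm: ConditionalEmissionHMM, seqs: list[str],
               config: TrainConfig | None = None,
               frozen: set[str] | None = None,
               tied_rows: set[int] | None = None,
               sentinel: str = DEFAULT_SENTINEL,
               ) -> tuple[ConditionalEmissionHMM, list[float]]:
    """Expectation-maximization estimation of all free parameters.

    Parameters
    ----------
    frozen : set of tags
        ``"initial"``, ``"transitions"``, ``"emissions"`` freeze whole
        parameter groups; ``"emissions:<i>"`` freezes the emission table of
        state ``i`` (used for the indicator emissions of detailed models).
    tied_rows : set of state indices
        States whose four conditional emission rows are kept identical
        (order-0 states): expected counts are pooled over the previous
        nucleotide before renormalization.

    Returns the trained model and the per-iteration total log-likelihood
    trace (non-decreasing up to numerical slack).  Structural zeros -- any
    probability exactly 0 in the input model -- are preserved.
    """
    config = config or TrainConfig()
    frozen = frozen or set()
    tied_rows = tied_rows or set()
    if not seqs:
        raise HMMError("empty training set")
    encoded = []
    for s in seqs:
        obs = _check_seq(s)
        if np.all(obs == 4):
            raise HMMError("all-N sequence cannot be used for training")
        encoded.append(obs)
    sent = NT_INDEX[sentinel]

    model = hmm.copy()
    n = model.n_states
    init_mask = model.initial > 0
    trans_mask = model.transitions > 0
    emit_mask = model.emissions > 0
    emit_frozen = np.zeros(n, dtype=bool)
    for tag in frozen:
        if tag.startswith("emissions:"):
            emit_frozen[int(tag.split(":", 1)[1])] = True
    if "emissions" in frozen:
        emit_frozen[:] = True

    batches = _batch(encoded)
    trace: list[float] = []
    n_total = len(encoded)
    for _ in range(config.max_iterations):
        ll = 0.0
        init_counts = np.zeros(n)
        trans_counts = np.zeros((n, n))
        # emission counts indexed (prev 0..4, cur 0..4, state); N slots are
        # accumulated but discarded (training sequences exclude N upstream,
        # but stray Ns must not corrupt the ACGT table).
        emit_counts = np.zeros((5, 5, n))
        A = model.transitions
        for L, (obs, _) in batches.items():
            prev = np.empty_like(obs)
            prev[:, 0] = sent
            prev[:, 1:] = obs[:, :-1]
            em = _emission_terms(model, obs, sent)
            alpha, scale = _forward(model, em)
            beta = _backward(model, em, scale)
            ll += float(np.log(scale).sum())
            gamma = alpha * beta                      # (B, T, n), rows sum 1
            gamma /= gamma.sum(axis=2, keepdims=True)
            init_counts += gamma[:, 0, :].sum(axis=0)
            for t in range(L - 1):
                # xi_t summed over the batch
                right = (em[:, t + 1, :] * beta[:, t + 1, :]
                         / scale[:, t + 1, None])     # (B, n)
                trans_counts += (alpha[:, t, :].T @ right) * A
            for t in range(L):
                np.add.at(emit_counts, (prev[:, t], obs[:, t]), gamma[:, t, :])
        trace.append(ll)
        if len(trace) > 1 and (trace[-1] - trace[-2]) / n_total < config.ll_tolerance:
            break

        pc = config.pseudocount
        if "initial" not in frozen:
            c = np.where(init_mask, init_counts + pc, 0.0)
            model.initial = c / c.sum()
        if "transitions" not in frozen:
            c = np.where(trans_mask, trans_counts + pc, 0.0)
            rows = c.sum(axis=1, keepdims=True)
            model.transitions = np.where(rows > 0, c / np.where(rows > 0, rows, 1),
                                         model.transitions)
        ec = emit_counts[:4, :4, :].transpose(2, 0, 1)   # (n, prev, cur)
        new_em = model.emissions.copy()
        for s in range(n):
            if emit_frozen[s]:
                continue
            c = ec[s]
            if s in tied_rows:
                c = np.repeat(c.sum(axis=0, keepdims=True), 4, axis=0)
            c = np.where(emit_mask[s], c + pc, 0.0)
            rows = c.sum(axis=1, keepdims=True)
            new_em[s] = np.where(rows > 0, c / np.where(rows > 0, rows, 1),
                                 model.emissions[s])
        model.emissions = new_em
        model.validate()
    return model, trace


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample(hmm: ConditionalEmissionHMM, length: int, seed: int,
           sentinel: str = DEFAULT_SENTINEL) -> tuple[str, np.ndarray]:
    """Draw one sequence of the given length from the generative process.

    The first emission is conditioned on the sentinel nucleotide.  Returns
    the residue string and the hidden state path."""
    if length < 1:
        raise HMMError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_with_rng(hmm, length, rng, NT_INDEX[sentinel])


def _sample_with_rng(hmm: ConditionalEmissionHMM, length: int,
                     rng: np.random.Generator, sentinel: int,
                     start_state: int | None = None,
                     ) -> tuple[str, np.ndarray]:
    states = np.empty(length, dtype=np.int64)
    obs = np.empty(length, dtype=np.int64)
    n = hmm.n_states
    s = (rng.choice(n, p=hmm.initial) if start_state is None else start_state)
    prev = sentinel
    for t in range(length):
        states[t] = s
        x = rng.choice(4, p=hmm.emissions[s, prev])
        obs[t] = x
        prev = x
        if t + 1 < length:
            s = rng.choice(n, p=hmm.transitions[s])
    return decode(obs), states
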