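"""Shared fixtures and independent oracles.

The enumeration oracle computes likelihoods and posteriors by explicit
summation over every hidden-state path; it shares no code with the scaled
forward-backward implementation it is used to check.
"""


import numpy as np
import pytest

import flexmotif as fm
from flexmotif.hmm import encode


def enum_posterior(hmm, residues, sentinel=0):
    """(log-likelihood, gamma) by exhaustive path enumeration (vectorized)."""
    obs = encode(residues)
    T, n = len(obs), hmm.n_states
    prev = np.concatenate([[sentinel], obs[:-1]])
    idx = np.indices((n,) * T).reshape(T, -1)
    p = hmm.initial[idx[0]] * hmm.emissions[idx[0], prev[0], obs[0]]
    for t in range(1, T):
        p = p * hmm.transitions[idx[t - 1], idx[t]] \
              * hmm.emissions[idx[t], prev[t], obs[t]]
    total = p.sum()
    gamma = np.stack([np.bincount(idx[t], weights=p, minlength=n)
                      for t in range(T)]) / total
    return np.log(total), gamma


def random_hmm(rng, n_states):
    """A random valid conditional-emission HMM."""
    return fm.ConditionalEmissionHMM(
        rng.dirichlet(np.ones(n_states)),
        rng.dirichlet(np.ones(n_states), n_states),
        rng.dirichlet(np.ones(4), (n_states, 4)))


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), length))


def mixed_pfm(consensus, weight=0.9):
    """A PFM that puts ``weight`` on the consensus base per position and
    spreads the rest uniformly (weight 0.9 gives ~1.5 bits/position)."""
    hard = fm.pfm_from_sites([consensus])
    return fm.PositionFrequencyMatrix(weight * hard.probs + (1 - weight) * 0.25)


def enumerate_site_widths(model, cap=50):
    """All match-path widths reachable from the background, by walking the
    transition graph (small models only)."""
    bg = sorted(set(range(model.hmm.n_states)) - model.match_states)
    A = model.hmm.transitions
    entries = [s for s in model.match_states
               if any(A[b, s] > 0 for b in bg)]
    widths = set()
    frontier = [(s, 1) for s in entries]
    seen = set(frontier)
    while frontier:
        s, w = frontier.pop()
        if w > cap:
            continue
        for s2 in range(model.hmm.n_states):
            if A[s, s2] <= 0:
                continue
            if s2 in model.match_states:
                item = (s2, w + 1)
                if item not in seen:
                    seen.add(item)
                    frontier.append(item)
            else:
                widths.add(w)
    return widths


@pytest.fixture
def cre_pfm():
    """A 12-bit, 8-position palindromic motif (CRE-like consensus)."""
    return mixed_pfm("TGACGTCA")


@pytest.fixture
def stat_pfm():
    """An 11-position motif with two half-sites, used for flexible edits."""
    return mixed_pfm("TTCCTAGGAAC")
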