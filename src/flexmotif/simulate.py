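"""Synthetic peak-like datasets with known ground truth.

Each simulated "peak" is a 101-nt summit-centred window drawn from a
first-order Markov background chain; with a configurable probability, one
binding site sampled from a known generative motif model (a PFM or a TFFM,
including flexible-width variants with their branch probabilities) is
written over the window at a drawn position and strand.  A signal value is
attached to every window through a monotone map from the planted site's
generative log-probability, emulating the ChIP enrichment values that
accompany real peaks and giving the score-signal trend real data shows.

The default background has human-like composition: ~41% GC with mild CpG
depletion (the conditional probability of G after C is far below its
marginal), which makes %GC-matched background construction meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import ConditionalEmissionHMM, _sample_with_rng, decode, encode
from .io_formats import NucleotideSequence, revcomp
from .models import TFFM, PositionFrequencyMatrix


class SimulationError(ValueError):
    pass


# Row m -> distribution of the next nucleotide (A, C, G, T); GC ~ 41%,
# G-after-C suppressed to ~5%.
HUMAN_LIKE_BACKGROUND = np.array([
    [0.32, 0.18, 0.23, 0.27],    # after A
    [0.33, 0.25, 0.05, 0.37],    # after C  (CpG depletion)
    [0.28, 0.21, 0.25, 0.26],    # after G
    [0.22, 0.20, 0.25, 0.33],    # after T
])


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``signal_scale`` and ``signal_noise_sd`` define the signal model
    ``signal = exp(a * (logp - w * ln(1/4)) + noise)``: a positive monotone
    map of the planted site's generative log-probability (centred on the
    uniform-sequence baseline so stronger-than-random sites get signal > 1),
    with lognormal noise."""

    n_sequences: int
    planted_model: "TFFM | PositionFrequencyMatrix"
    window_length: int = 101
    background: np.ndarray = field(
        default_factory=lambda: HUMAN_LIKE_BACKGROUND.copy())
    planting_probability: float = 1.0
    strand_probability: float = 0.5     # probability of the + strand
    site_position: str = "uniform"      # or "gaussian"
    site_position_sd: float = 10.0
    signal_scale: float = 0.5
    signal_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4, 4) or \
                not np.allclose(self.background.sum(axis=1), 1, atol=1e-9):
            raise SimulationError("background must be a 4x4 stochastic table")
        if not 0.0 <= self.planting_probability <= 1.0:
            raise SimulationError("planting_probability must be in [0, 1]")
        wmax = (self.planted_model.length_range[1]
                if isinstance(self.planted_model, TFFM)
                else self.planted_model.length)
        if wmax > self.window_length:
            raise SimulationError(f"motif width {wmax} exceeds the "
                                  f"{self.window_length}-nt window")


@dataclass
class PlantedSite:
    """Ground-truth annotation of one planted site (window coordinates)."""

    seq_index: int
    start: int
    end: int
    strand: str
    width: int
    strength: float       # generative log-probability of the site

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class SimulatedDataset:
    sequences: list[NucleotideSequence]
    truth: list[PlantedSite]
    signals: np.ndarray
    config: SimConfig


def _sample_site_pfm(pfm: PositionFrequencyMatrix, rng) -> tuple[str, float]:
    codes = [rng.choice(4, p=row) for row in pfm.probs]
    logp = float(sum(np.log(pfm.probs[i, c]) for i, c in enumerate(codes)))
    return decode(np.array(codes)), logp


def _sample_site_tffm(model: TFFM, rng, prev: int) -> tuple[str, float]:
    """Walk the motif sub-chain from its entry until it returns to the
    background, emitting conditioned on the previously seen nucleotide."""
    h = model.hmm
    bg = sorted(set(range(h.n_states)) - model.match_states)
    entry = h.transitions[bg, :].sum(axis=0)
    entry[bg] = 0.0
    if entry.sum() <= 0:
        raise SimulationError("model has no background-to-motif entry")
    entry /= entry.sum()
    s = rng.choice(h.n_states, p=entry)
    logp = float(np.log(entry[s]))     # path probability given site entry
    codes = []
    while True:
        p_emit = h.emissions[s, prev]
        x = rng.choice(4, p=p_emit)
        logp += float(np.log(p_emit[x]))
        codes.append(x)
        prev = x
        row = h.transitions[s]
        s2 = rng.choice(h.n_states, p=row)
        if s2 not in model.match_states:
            break
        logp += float(np.log(row[s2]))
        s = s2
    return decode(np.array(codes)), logp


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate windows, plant sites, and derive signals; fully reproducible
    from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    chain = ConditionalEmissionHMM(np.ones(1), np.ones((1, 1)),
                                   config.background[None, :, :], ["bg"])
    W = config.window_length
    seqs: list[NucleotideSequence] = []
    truth: list[PlantedSite] = []
    signals = np.empty(config.n_sequences)
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    wmax = (config.planted_model.length_range[1]
            if isinstance(config.planted_model, TFFM)
            else config.planted_model.length)
    for i in range(config.n_sequences):
        window, _ = _sample_with_rng(chain, W, rng, 0)
        planted = rng.random() < config.planting_probability
        codes = encode(window)
        strand = "+" if rng.random() < config.strand_probability else "-"
        # draw the start for the widest variant so every width fits
        if config.site_position == "gaussian":
            center = (W - wmax) / 2.0
            start = int(np.clip(round(rng.normal(center,
                                                 config.site_position_sd)),
                                0, W - wmax))
        else:
            start = int(rng.integers(0, W - wmax + 1))
        if isinstance(config.planted_model, TFFM):
            # condition the site's first emission on the base that precedes
            # it in its own reading direction (sentinel A at a window edge)
            if strand == "+":
                prev = int(codes[start - 1]) if start > 0 else 0
            else:
                after = start + wmax
                prev = comp[int(codes[after])] if after < W else 0
            site, logp = _sample_site_tffm(config.planted_model, rng, prev)
        else:
            site, logp = _sample_site_pfm(config.planted_model, rng)
        w = len(site)
        if planted:
            insert = revcomp(site) if strand == "-" else site
            window = window[:start] + insert + window[start + w:]
            truth.append(PlantedSite(i, start, start + w, strand, w, logp))
            strength = logp
        else:
            # unplanted windows: enrichment reflects how motif-like the
            # window's own background sequence happens to be
            sub = codes[start:start + w]
            prev = np.concatenate([[0], sub[:-1]])
            strength = float(np.log(
                config.background[prev, sub]).sum())
        baseline = w * np.log(0.25)
        signals[i] = float(np.exp(
            config.signal_scale * (strength - baseline)
            + rng.normal(0.0, config.signal_noise_sd)))
        seqs.append(NucleotideSequence(f"peak{i + 1}", window))
    return SimulatedDataset(seqs, truth, signals, config)


# ---------------------------------------------------------------------------
# Writers: FASTA + truth BED + signal table + faux narrowPeak
# ---------------------------------------------------------------------------

def write_truth_bed(ds: SimulatedDataset, path) -> None:
    with open(path, "w") as out:
        for site in ds.truth:
            out.write(f"peak{site.seq_index + 1}\t{site.start}\t{site.end}"
                      f"\tsite\t{site.strength:.4f}\t{site.strand}\n")


def write_signal_table(ds: SimulatedDataset, path) -> None:
    with open(path, "w") as out:
        out.write("sequence\tsignal\n")
        for s, v in zip(ds.sequences, ds.signals):
            out.write(f"{s.identifier}\t{v:.6g}\n")


def write_narrowpeak(ds: SimulatedDataset, path,
                     spacing: int = 1000) -> None:
    """Faux narrowPeak on a synthetic contig: window i occupies
    [i*spacing, i*spacing + W) with its summit at the window centre."""
    W = ds.config.window_length
    with open(path, "w") as out:
        for i, (s, v) in enumerate(zip(ds.sequences, ds.signals)):
            start = i * spacing
            out.write(f"synth\t{start}\t{start + W}\t{s.identifier}\t0\t."
                      f"\t{v:.6g}\t-1\t-1\t{W // 2}\n")
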