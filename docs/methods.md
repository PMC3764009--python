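# Methods

## The model

A binding motif of length L is represented as a hidden Markov model over
the DNA alphabet in which every state carries a conditional emission table
e_s(n | m): the probability of emitting nucleotide n given that the
previously **observed** nucleotide was m. Because the conditioning is on
the observed symbol rather than on a hidden quantity, the forward and
backward recursions keep their standard form — the emission term at
position t is looked up with the pair (x_{t-1}, x_t) — and all the usual
HMM guarantees (EM monotonicity, posterior normalization) carry over
unchanged. A fixed sentinel nucleotide (A) conditions the first position so
the likelihood is defined from position one; it is exposed as a parameter
but its effect is confined to position one of a scan.

Three topologies share this engine:

* **order0** — one background state plus one match state per position, all
  with row-tied (unconditional) emissions. This is exactly a PFM whose
  columns are estimated by Baum–Welch instead of from an alignment, and it
  serves to separate "better model" from "better training" in comparisons.
* **order1** — the same layout with free conditional emissions. At
  initialization the four conditional rows of each match state are set
  equal to the seed PFM column, i.e. no dependency is assumed;
  dinucleotide structure is learned, not seeded.
* **detailed** — each order-1 state is split into four nucleotide-specific
  states emitting their nucleotide with probability 1. Emissions are
  definitional indicators and are frozen during training; dependencies —
  including the probability of *entering* the motif after a given
  background nucleotide, which the order-1 topology cannot express — live
  entirely in the transitions. Four background states are used so that the
  background context is itself nucleotide-resolved.

Transition structure at build time: background self-loop 1 − p, background
to first match position p, consecutive match transitions 1, last position
back to background 1. The entry probability p defaults to 1/101 so that
one site per 101-nt window is expected at initialization; it is
re-estimated during training. The initial state distribution mirrors the
background/entry split so sites touching the window edge are not excluded.

## Training

Baum–Welch with per-position scaling; sequences are grouped by length and
each group's forward/backward pass is vectorized over the batch, which is
what keeps training on a thousand 101-nt windows in the seconds range.
Defaults (declared here, tunable in `TrainConfig`):

* pseudocount 1e-4, added to every expected count whose parameter was
  non-zero at initialization. Parameters exactly zero at initialization
  are structural — they define the topology — and are never resurrected.
* stopping when the mean per-sequence log-likelihood improves by less than
  1e-4 nats, or after 100 iterations.
* order-0 models keep their conditional rows tied by pooling expected
  emission counts over the previous-nucleotide index before
  renormalization; detailed models freeze all emission tables.

Sequences containing N are excluded from training. During scanning an N
emits with probability 0.25 in every state and conditioning on an N uses
the mean of the four conditional rows, so likelihoods stay defined on
real-world sequence.

## Scanning and occupancy

The score at position t (per strand) is the posterior probability of being
in a final match state at t, from forward–backward. The reverse strand is
handled by scanning the reverse complement with the same model and mapping
intervals back to forward coordinates; the model itself is never
reverse-complemented. The best hit is the maximal score over positions and
strands, ties broken by smaller start then the + strand. For
flexible-width models, the width of the site ending at t is read off the
most probable state path ending in a final state there (one Viterbi pass
plus a backtrack); for fixed-width models it is L by construction.

Occupancy is aggregated as Pocc = 1 − Π_t (1 − P_t), treating the
per-position end-of-site posteriors as approximately independent binding
opportunities; the product runs over both strands by default
(`both_strands=False` restricts it). This is the probabilistic counterpart
of "at least one site is present" and is monotone in every P_t, never
below the best-hit score.

## Flexible-width edits

Edits are declarative and operate on state *groups* (one state per motif
position for order0/order1, four for detailed), so an edit list produces
the same width range on every topology:

* `skip_position(p, q)` — position p is used with probability q, bypassed
  with 1 − q; widths (L−1, L).
* `gap_insert(p, q)` — a uniform-emission spacer between p and p+1 entered
  with probability q; widths (L, L+1).
* `alternative_core(a, b, q, alt_pfm)` — a parallel variant of the span
  a..b; the original path is taken with probability q; width unchanged.
* `flexible_edge(p, q)` — the motif may end at p with probability q, whose
  states join the final set; widths (p, L).

Branch probabilities are ordinary transitions and are re-estimated by
Baum–Welch, which is how a planted 0.7/0.3 width mixture is recovered from
unlabeled sequence.

## Benchmarking protocol

`make_plan` reserves the top-signal peaks (default 600) for seeding only
and shuffles the remainder into 10 folds (train = 9 test folds). Per fold
the model is initialized from the seed PFM, trained on the training
sequences, and both the test foreground and an equal-size background are
scored by best hit (or Pocc). Backgrounds: a one-state first-order Markov
chain estimated with pseudocount 1 from the fold's training sequences, or
a %GC-matched subsample (1-percentage-point bins, without replacement)
from a user-supplied candidate pool. ROC curves come from the threshold
sweep over observed scores with tied scores grouped; AUC is the trapezoid
integral, and the pooled AUC over concatenated fold scores is the headline
number (per-fold AUCs are also reported, since fold aggregation is
otherwise a free choice). Pairwise method differences use the Wilcoxon
signed-rank test on per-dataset AUCs with Benjamini–Hochberg correction;
all-zero differences report p = 1. The score–signal trend bins peaks into
twenty 5-percentile groups by signal and correlates the group rank with
the median prediction score (Spearman), with an OLS slope p-value on the
same 20 points; constant scores are flagged degenerate with rho 0.

The PWM baseline uses log2((p + c)/(b + c)) log-odds with uniform
background and pseudocount 0.01 by default, summed over a window and
maximized over positions and strands; N columns contribute their
background expectation.

## Synthetic data

`simulate_dataset` emulates summit-centred ChIP-seq peak windows: 101-nt
sequences from a first-order background chain with human-like composition
(≈41% GC, G-after-C suppressed to ≈5% to mimic CpG depletion — the table
is in `simulate.HUMAN_LIKE_BACKGROUND`), one site per window planted with
configurable probability, position (uniform, or Gaussian around the
centre) and strand. Sites are drawn from the generative model itself —
including flexible-width branches — with the first emission conditioned on
the base that actually precedes the site in its reading direction, so the
planted data match the model's own generative process exactly. Signal
values follow signal = exp(a·(log p − w·ln ¼) + ε), a monotone map of the
site's generative log-probability centred on the uniform-sequence
baseline, with lognormal noise (a = 0.5, sd 0.3); unplanted windows take
the analogous value from their own background subsequence, so enrichment
tracks motif-likeness in both cases.

What the generator does **not** emulate: read-level coverage and
peak-calling artifacts, mappability structure, co-factor motifs, copy
number, or inter-peak correlation. Passing tests therefore demonstrate
correctness of the algorithms and recoverability under the model's own
assumptions, not performance on any particular real dataset.

Benchmark problem sizes were chosen to make the statistics stable while
keeping a full run in the minutes range: 500 windows for discrimination
(pooled AUC s.e. ≈ 0.01 at AUC 0.95), 1000 for parameter and mixture
recovery (per-entry s.e. ≈ 0.015).

## Numerical choices and edge cases

* Scaled (not log-space) forward–backward; stable to sequence length 1e5.
* Model JSON serialization is exact for float64; round-trips are
  identities to 1e-12 and invalid tables (row sums off by more than 1e-9)
  are rejected on load.
* Coordinates are 0-based half-open everywhere (BED convention); summit
  windows are [summit − 50, summit + 51). Peaks without a summit (−1) are
  skipped with a warning; windows crossing a contig edge are clipped and
  flagged.
* Cross-validation ties at the init-set boundary resolve by input order;
  the shuffle of the remainder is seeded.
* Information content is Σ_i (2 + Σ_n P_i(n) log2 P_i(n)) bits with
  0·log 0 = 0, computed from marginals propagated from a uniform
  distribution ahead of position one. Logos: the summary logo scales
  letter heights by P·IC per position; the dense logo draws each
  conditional row probability-scaled with cell opacity 0.1 + 0.9·P_{i−1}(m)
  (the floor is a legibility choice, not semantics). Logos are defined
  only for fixed-width, unedited topologies.

## Known limitations

* Flexible edits compose only at distinct positions; editing the same
  position twice is rejected rather than merged.
* The detailed topology's conditional tables are only identifiable where
  the previous position actually varies; columns following a
  near-consensus base are dominated by their initialization plus
  pseudocount, which is why recovery is stated as a mean absolute error.
* Where to place gaps/skips must be specified by the user; the framework
  does not search for variable-length structure automatically.
* Scanning is O(T·n_states²) per sequence and strand; genome-scale
  scanning would want a dedicated streaming implementation.
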