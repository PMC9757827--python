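# Methods

## The scoring model

`methylcall` calls 5-methylcytosine (5mC) in CpG context at the read level
from nanopore-style signal. For each read and each *CpG group* (a cluster of
CG dinucleotides closer than `group_distance` bp), it evaluates two
haplotypes of the reference window around the group — the unmethylated
sequence and the sequence with every CpG cytosine replaced by M — under a
profile HMM, and reports the log-likelihood ratio

    LLR = log P(events | methylated) − log P(events | unmethylated),

with positive values supporting methylation. Evidence enters through a k-mer
current model: every k-mer `x` (k = 6 by default, alphabet {A,C,G,T,M}) has
an expected current `μ_x` and spread `σ_x`; an observed event with mean `e`
is scored by the Gaussian density `N(e; c·μ_x + s, (v·σ_x)²)` where
`(s, c, v)` are the read's shift/scale/var calibration parameters.

### State layout and recurrences

The scored haplotype of K k-mers becomes K *blocks* of three state columns,
in the fixed order KMER_SKIP, BAD_EVENT, MATCH. `fm[row][3b + state]` is the
log-probability of the alignment ending at event `row` (row 0 = no events
consumed) in that state of block `b`:

- **MATCH(r, b)** — Gaussian emission of event r at k-mer b, times the
  log-sum of all three states at (r−1, b−1) with a *step* transition and all
  three at (r−1, b) with a *stay* transition.
- **BAD_EVENT(r, b)** — a flat emission penalty (`p_bad_emit`, default 0.01)
  times the log-sum of the states at (r−1, b): the event is consumed but
  unexplained.
- **KMER_SKIP(r, b)** — the log-sum of the states at (r, b−1), same row: the
  k-mer is traversed without consuming an event.

Transition probabilities are shared across source states: `p_stay = 0.1`,
`p_skip = 0.01`, `p_bad = 0.01`, `p_step = 1 − p_stay − p_skip − p_bad`.
These are order-of-magnitude typical for nanopore event streams and are
exposed in `TransitionParams`; the calling accuracy is insensitive to factors
of a few in either direction because both haplotypes pay the same transition
costs.

**Boundary and termination.** Row 0 seeds MATCH of block 0 with log 1 = 0
and fills the row-0 KMER_SKIP chain so leading k-mers may be skipped before
the first event; all other row-0 entries are −∞. After the last block of
every event row r ≥ 1 the termination score accumulates
`fm[r][last block, MATCH] + lp_end` with `lp_end = log p_step` — a *soft*
end: the alignment may end before all events are consumed. The accumulated
value is the returned log-likelihood. Termination only from MATCH (not from
BAD_EVENT/KMER_SKIP) and the absence of explicit flanking blocks are
deliberate simplifications. A consequence of the soft end worth knowing:
appending trailing garbage events can raise the log-likelihood by a sliver
(early-terminating paths keep their mass); both haplotypes are affected
identically, so the LLR is unaffected in practice.

### Two-phase parallel fill

MATCH and BAD_EVENT of row r read only row r−1, so they are block-independent
(*phase A*); KMER_SKIP chains along row r and is inherently sequential
(*phase B*). `ParallelFiller` assigns contiguous block chunks to worker
threads; per row, every worker computes phase A on its chunk, a barrier
synchronizes, worker 0 alone scans the KMER_SKIP chain and accumulates
termination, a second barrier releases the next row. Every cell is computed
by the same kernel with a fixed `add_log` operand order (step terms from
states 0,1,2 of the left block, then stay terms from states 0,1,2; numpy's
elementwise `logaddexp` evaluates identically regardless of chunking), so the
parallel fill is **bit-identical** to the serial one for any worker count —
the property the test suite enforces with exact float equality. The pool is
portable threads with an explicit per-row barrier; any backend honouring the
same phase/barrier contract (e.g. a GPU kernel) could be dropped in.

### Numerical choices

All arithmetic is double precision in natural-log space; −∞ is the floating
infinity, never a sentinel. `add_log(a, b) = max + log1p(exp(−|a−b|))`
(numpy `logaddexp`), commutative, with −∞ as identity. A group window with
no CpG yields byte-identical haplotypes and an LLR of exactly 0 by
construction (the second fill is skipped). Degenerate inputs (no events,
haplotype shorter than k, unknown k-mer) are rejected with `ValueError` /
`KeyError`.

## Upstream stages

These three stages are simple, fully specified stand-ins for the heavily
engineered equivalents in production pipelines; they feed the HMM and
exercise the executor, and are *not* re-implementations of the originals.

**Event detection** — a two-window change-point detector: at each boundary
candidate the Welch t-statistic between the `window` (default 4) samples on
each side is computed; boundaries are local maxima above `threshold`
(default 4.0) at least `min_event_len` (default 3) samples apart. Events
tile the signal; each carries its segment mean and stdv. With 4-sample
windows the statistic has Student-t tails (~6 df), so occasional spurious
boundaries on pure noise are expected; the HMM's stay transitions absorb the
resulting fragmentation.

**Event alignment** — a banded Viterbi-style DP over (event, k-mer) cells
with stay/step/skip moves priced by the transition log-probabilities and
Gaussian emissions. The band (default 100 cells) is fixed and centred on the
ideal diagonal scaled by `n_events / n_kmers`; adaptive band movement is out
of scope. The skip move is handled by a vectorized running maximum of
`dp[j′] − j′·log p_skip`, ties broken toward fewer skips. Alignment runs
under a method-of-moments pre-scaling (match mean/spread of event currents
to the window's model levels); a collapsed band raises `AlignmentError` and
drops the read with a warning.

**Calibration** — ordinary least squares of aligned event means on model
level means gives `scale` and `shift`; `var` is the residual standard
deviation over the mean model σ of the used k-mers, floored at 0.01. A
design with fewer than two distinct model means returns identity scaling
with a warning. Drift is carried but fixed at 0.

## Pipelined executor

Reads are partitioned into batches of `batch_size`; each batch traverses the
four stages (event detection, alignment, calibration, methylation scoring)
in order. Concurrency is governed by two mechanisms:

- a **window semaphore** of `batch_count` (default 3) bounding the number of
  batches in flight between stage-1 entry and stage-4 exit (data loading is
  a stage-0 producer outside the window accounting);
- a **per-stage turnstile** admitting batches one at a time, in batch-id
  order (a batch waits until the previous batch has left the stage).

One coordinating thread runs per in-flight batch. Stage functions are pure
per-batch transformations, so the concatenated, batch-ordered call stream is
identical to a serial run regardless of window size, thread count or
scheduling; the final call list is additionally sorted by
(chrom, start, read_name) and floats are printed with fixed formatting, so
the output TSV is byte-reproducible. A stage failure marks its batch failed,
the batch passes through the remaining stages as a no-op so the pipeline
drains, and the CLI exits nonzero. Every stage enter/exit is recorded in a
trace (exportable as TSV); `max_concurrency` sweeps the trace's event order.

With four stages and a window of three, the steady-state schedule keeps
three batches in flight (the window bound is the binding constraint, which
is how the executor realizes the "three concurrent batches" schedule rather
than deriving it from stage/resource structure).

## Synthetic data generator

The generator is the package's reference experiment; its defaults are the
study conditions the tests and the acceptance script use:

| parameter | default | meaning |
|---|---|---|
| `n_reads` / `read_length` / `ref_length` | 50 / 2000 bp / 12000 bp | reads sample random reference windows |
| `cpg_density` | 0.02 /bp | CG dinucleotides planted in a CG-free background (site count is Binomial) |
| `methylation_rate` | 0.5 | Bernoulli per (read, CpG cluster); clusters use the caller's 10 bp rule so group truth is homogeneous |
| `p_stay` / `p_skip` / `p_bad` | 0.1 / 0.01 / 0.01 | generative stay/skip/outlier behaviour, mirroring the HMM |
| `noise_sd` | 1.0 pA | event-mean and sample noise |
| `m_shift` | 4.0 pA | constant level offset of M-containing k-mers |
| scaling truth | shift 10, scale 1.2, var 1 | affine distortion the pipeline must recover |
| dwell | 5–20 samples/event | uniform |

The synthetic pore model draws per-k-mer levels uniformly in [60, 120] pA
(σ in [1.0, 2.5] pA) and gives every M-substituted variant the canonical
level plus `m_shift`. Everything is deterministic under the seed, including
file bytes (gzip written with zeroed mtime).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: basecalling errors (read sequences equal their
reference window, so alignment coordinates are exact), within-read current
drift, realistic dwell-time distributions, per-k-mer methylation level
differences (real models differ per k-mer; a constant shift gives a
controllable effect size), and reverse-strand reads (the caller supports
them; the generator emits forward-strand only).

## Problem sizes used in tests and the acceptance script

Oracle equivalence uses 500 (tests) / 200 (script) random instances of at
most 4 events × 4 blocks, where exhaustive path enumeration is exact and
fast; parallel/serial bit-equivalence uses 200 instances up to 20 events ×
12 blocks across worker counts {1, 2, 8}; end-to-end checks run the default
50-read generator conditions (~1600–1700 (read, group) calls) across window
sizes {1, 3, 6} and worker counts {1, 4}. These sizes make the whole suite
run in a couple of minutes while leaving every check at full strength.

## Known limitations

- Non-CpG motifs (GpC, dam/dcm), duplex/strand-merged calls, and FAST5/POD5
  ingestion are out of scope; raw signal arrives via the plain-text signal
  table.
- The aligner's fixed band can clip the optimum for reads whose event count
  deviates grossly from the k-mer count; the bandwidth is configurable.
- Transition parameters are global, not estimated per read.
- The soft-end termination choice (MATCH-only, every row) is one defensible
  reading of the recurrence family this HMM belongs to; alternatives
  (last-row-only termination, termination from all states) would change
  absolute likelihoods slightly but largely cancel in the ratio.
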