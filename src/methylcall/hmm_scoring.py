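"""Profile-HMM methylation scoring: block-structured forward fill.

The scored haplotype of K k-mers is laid out as K *blocks* of three state
columns each, in the fixed order ``KMER_SKIP, BAD_EVENT, MATCH``.  Cell
``fm[row][3*b + s]`` holds the log-probability of the alignment ending at
event ``row`` (row 0 is the "no events consumed" boundary row) in state
``s`` of block ``b``.  The dependency structure is:

* MATCH(row, b)      <- all states of (row-1, b-1) by a *step* and of
                        (row-1, b) by a *stay*, times a Gaussian emission;
* BAD_EVENT(row, b)  <- all states of (row-1, b), times a flat bad-event
                        emission penalty;
* KMER_SKIP(row, b)  <- all states of (row, b-1), same row: the k-mer is
                        traversed without consuming an event.

Because MATCH and BAD_EVENT read only the previous row, they are
block-independent and may be filled concurrently (phase A).  KMER_SKIP
chains along the current row and is filled by a single left-to-right scan
(phase B).  ``hmm_fill_parallel`` realizes exactly this two-phase schedule
with a worker pool and a per-row barrier and is bit-identical to
``hmm_fill_serial`` because every cell is computed by the same kernel with
a fixed ``add_log`` operand order.

After the last block of each event row, the termination score accumulates
``fm[row][last block, MATCH] + lp_end`` (a "soft" end: the alignment may
end before all events are consumed).  The accumulated end score is the
returned log-likelihood.
"""

from __future__ import annotations

import logging
import math
import threading
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .model_types import (
    CpGGroup,
    Event,
    MethylationCall,
    PoreModel,
    ScalingParams,
    make_methylated_haplotype,
    reverse_complement,
)

logger = logging.getLogger(__name__)

# State layout inside one block.
KMER_SKIP = 0
BAD_EVENT = 1
MATCH = 2
NUM_STATES = 3

NEG_INF = float("-inf")
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def add_log(a: float, b: float) -> float:
    """Stable log-space addition: log(exp(a) + exp(b)).

    Computed as max + log1p(exp(-|a-b|)); commutative; -inf is the identity
    element.  The same ufunc is used elementwise in the vectorized fill so
    that scalar and vector paths produce identical floats.
    """
    return float(np.logaddexp(a, b))


@dataclass(frozen=True)
class TransitionParams:
    """Transition probabilities of the scoring HMM.

    From any state the walk stays in the same block with ``p_stay``
    (emitting another event from the same k-mer), skips the next k-mer with
    ``p_skip`` (no event), emits an unexplained event with ``p_bad``, and
    otherwise steps to the next k-mer: ``p_step = 1 - p_stay - p_skip -
    p_bad``.  ``p_bad_emit`` is the flat emission probability of a bad
    event (a penalty, not a density).  ``lp_end`` defaults to ``log
    p_step``: terminating costs one step transition.
    """

    p_stay: float = 0.1
    p_skip: float = 0.01
    p_bad: float = 0.01
    p_bad_emit: float = 0.01

    def __post_init__(self):
        for name in ("p_stay", "p_skip", "p_bad", "p_bad_emit"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.p_step <= 0.0:
            raise ValueError("p_stay + p_skip + p_bad must be < 1")

    @property
    def p_step(self) -> float:
        return 1.0 - self.p_stay - self.p_skip - self.p_bad

    @property
    def lp_stay(self) -> float:
        return math.log(self.p_stay)

    @property
    def lp_skip(self) -> float:
        return math.log(self.p_skip)

    @property
    def lp_bad(self) -> float:
        return math.log(self.p_bad)

    @property
    def lp_step(self) -> float:
        return math.log(self.p_step)

    @property
    def lp_bad_emit(self) -> float:
        return math.log(self.p_bad_emit)

    @property
    def lp_end(self) -> float:
        return self.lp_step


DEFAULT_TRANSITIONS = TransitionParams()


@dataclass
class ProbabilityMatrix:
    """The filled forward matrix and its accumulated termination score."""

    fm: np.ndarray
    n_block: int
    end_score: float

    @property
    def n_row(self) -> int:
        return self.fm.shape[0]


@dataclass(frozen=True)
class ScoreResult:
    log_lik: float


def lp_emit_match(
    event: Event, kmer: str, model: PoreModel, scaling: ScalingParams
) -> float:
    """Log Gaussian density of the event mean under the scaled k-mer level."""
    mu, sd = model.lookup(kmer)
    smu = scaling.scale * mu + scaling.shift
    ssd = scaling.var * sd
    z = (event.mean - smu) / ssd
    return -0.5 * z * z - math.log(ssd) - _HALF_LOG_2PI


def scaled_levels(
    kmers: list[str], model: PoreModel, scaling: ScalingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled (mean, stdv) arrays for a k-mer sequence."""
    mu = np.array([model.level_mean(km) for km in kmers])
    sd = np.array([model.level_stdv(km) for km in kmers])
    return scaling.scale * mu + scaling.shift, scaling.var * sd


def emission_matrix(
    events: list[Event],
    kmers: list[str],
    model: PoreModel,
    scaling: ScalingParams,
) -> np.ndarray:
    """Matrix of match-emission log densities, shape (n_events, n_kmers)."""
    smu, ssd = scaled_levels(kmers, model, scaling)
    x = np.array([e.mean for e in events])
    z = (x[:, None] - smu[None, :]) / ssd[None, :]
    return -0.5 * z * z - np.log(ssd)[None, :] - _HALF_LOG_2PI


def _haplotype_kmers(haplotype: str, k: int) -> list[str]:
    if len(haplotype) < k:
        raise ValueError(
            f"haplotype of length {len(haplotype)} is shorter than k={k}"
        )
    return [haplotype[i : i + k] for i in range(len(haplotype) - k + 1)]


def _phase_a_chunk(
    prev_row: np.ndarray,
    emit_row: np.ndarray,
    trans: TransitionParams,
    n_block: int,
    lo: int,
    hi: int,
) -> tuple[np.ndarray, np.ndarray]:
    """MATCH and BAD_EVENT values for blocks [lo, hi) of the current row.

    Reads only the previous row, so chunks are independent.  The add_log
    chain order is fixed: step terms from block b-1 (states 0, 1, 2), then
    stay terms from block b (states 0, 1, 2); the bad chain uses states
    0, 1, 2 of block b.  Elementwise ufunc evaluation makes the result
    independent of how blocks are chunked across workers.
    """
    prev = prev_row.reshape(n_block, NUM_STATES)
    chunk = prev[lo:hi]
    if lo == 0:
        prev_shift = np.vstack(
            [np.full((1, NUM_STATES), NEG_INF), prev[: hi - 1]]
        )
    else:
        prev_shift = prev[lo - 1 : hi - 1]
    n = hi - lo
    acc = np.full(n, NEG_INF)
    for s in range(NUM_STATES):
        acc = np.logaddexp(acc, prev_shift[:, s] + trans.lp_step)
    for s in range(NUM_STATES):
        acc = np.logaddexp(acc, chunk[:, s] + trans.lp_stay)
    match = emit_row[lo:hi] + acc

    accb = np.full(n, NEG_INF)
    for s in range(NUM_STATES):
        accb = np.logaddexp(accb, chunk[:, s] + trans.lp_bad)
    bad = trans.lp_bad_emit + accb
    return match, bad


def _phase_b(row: np.ndarray, trans: TransitionParams, n_block: int) -> None:
    """Left-to-right KMER_SKIP scan of one row (in place).

    KMER_SKIP of block 0 has no predecessor block and stays -inf.
    """
    for b in range(1, n_block):
        off = NUM_STATES * (b - 1)
        acc = np.logaddexp(row[off + KMER_SKIP], row[off + BAD_EVENT])
        acc = np.logaddexp(acc, row[off + MATCH])
        row[NUM_STATES * b + KMER_SKIP] = acc + trans.lp_skip


def _init_matrix(
    n_events: int, n_block: int, trans: TransitionParams
) -> np.ndarray:
    """Row 0 boundary: MATCH of block 0 is seeded with lp_start = 0 and the
    KMER_SKIP chain lets leading k-mers be skipped before the first event."""
    fm = np.full((n_events + 1, NUM_STATES * n_block), NEG_INF)
    fm[0, NUM_STATES * 0 + MATCH] = 0.0
    _phase_b(fm[0], trans, n_block)
    return fm


def _validate_fill_args(events, haplotype, model):
    if len(events) < 1:
        raise ValueError("at least one event is required")
    if not haplotype:
        raise ValueError("empty haplotype")
    return _haplotype_kmers(haplotype, model.k)


def hmm_fill_serial(
    events: list[Event],
    haplotype: str,
    model: PoreModel,
    scaling: ScalingParams,
    trans: TransitionParams = DEFAULT_TRANSITIONS,
) -> tuple[ProbabilityMatrix, ScoreResult]:
    """Reference forward fill: first row to last, first block to last."""
    kmers = _validate_fill_args(events, haplotype, model)
    n_block = len(kmers)
    n_events = len(events)
    emit = emission_matrix(events, kmers, model, scaling)
    fm = _init_matrix(n_events, n_block, trans)
    end = NEG_INF
    last_match = NUM_STATES * (n_block - 1) + MATCH
    for r in range(1, n_events + 1):
        match, bad = _phase_a_chunk(fm[r - 1], emit[r - 1], trans, n_block, 0, n_block)
        fm[r, MATCH::NUM_STATES] = match
        fm[r, BAD_EVENT::NUM_STATES] = bad
        _phase_b(fm[r], trans, n_block)
        end = add_log(end, fm[r, last_match] + trans.lp_end)
    return ProbabilityMatrix(fm=fm, n_block=n_block, end_score=end), ScoreResult(end)


class ParallelFiller:
    """Persistent worker pool realizing the two-phase fill contract.

    Each worker owns a contiguous chunk of blocks.  Per row: phase A — every
    worker fills MATCH and BAD_EVENT of its blocks concurrently (these read
    only the previous row); barrier; phase B — worker 0 alone scans the
    KMER_SKIP chain left to right and accumulates the termination score;
    barrier; next row.  The result is bit-identical to the serial fill.

    The pool is reusable across fills (``fill`` may be called repeatedly)
    and must be closed, or used as a context manager.
    """

    def __init__(self, workers: int):
        if workers < 1:
            raise ValueError("workers must be >= 1")
        self.workers = workers
        self._barrier = threading.Barrier(workers)
        self._start = threading.Barrier(workers + 1)
        self._done = threading.Barrier(workers + 1)
        self._task = None
        self._shutdown = False
        self._error: Optional[BaseException] = None
        self._threads = [
            threading.Thread(target=self._loop, args=(w,), daemon=True)
            for w in range(workers)
        ]
        for t in self._threads:
            t.start()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False

    def close(self):
        if self._shutdown:
            return
        self._shutdown = True
        try:
            self._start.wait(timeout=5)
        except threading.BrokenBarrierError:
            pass
        for t in self._threads:
            t.join(timeout=5)

    def _loop(self, wid: int):
        while True:
            try:
                self._start.wait()
            except threading.BrokenBarrierError:
                return
            if self._shutdown:
                return
            try:
                self._run_worker(wid)
            except BaseException as exc:  # pragma: no cover - defensive
                self._error = exc
                self._barrier.abort()
            try:
                self._done.wait()
            except threading.BrokenBarrierError:
                return

    def _run_worker(self, wid: int):
        fm, emit, trans, n_block, bounds, end_box = self._task
        lo, hi = bounds[wid], bounds[wid + 1]
        n_events = emit.shape[0]
        last_match = NUM_STATES * (n_block - 1) + MATCH
        for r in range(1, n_events + 1):
            if hi > lo:
                match, bad = _phase_a_chunk(
                    fm[r - 1], emit[r - 1], trans, n_block, lo, hi
                )
                fm[r, NUM_STATES * lo + MATCH : NUM_STATES * hi : NUM_STATES] = match
                fm[r, NUM_STATES * lo + BAD_EVENT : NUM_STATES * hi : NUM_STATES] = bad
            self._barrier.wait()
            if wid == 0:
                _phase_b(fm[r], trans, n_block)
                end_box[0] = add_log(end_box[0], fm[r, last_match] + trans.lp_end)
            self._barrier.wait()

    def fill(
        self,
        events: list[Event],
        haplotype: str,
        model: PoreModel,
        scaling: ScalingParams,
        trans: TransitionParams = DEFAULT_TRANSITIONS,
    ) -> tuple[ProbabilityMatrix, ScoreResult]:
        kmers = _validate_fill_args(events, haplotype, model)
        n_block = len(kmers)
        emit = emission_matrix(events, kmers, model, scaling)
        fm = _init_matrix(len(events), n_block, trans)
        # Contiguous block chunks, one per worker (some may be empty).
        bounds = np.linspace(0, n_block, self.workers + 1).astype(int)
        end_box = [NEG_INF]
        if self._barrier.broken:
            self._barrier.reset()
        self._task = (fm, emit, trans, n_block, bounds, end_box)
        self._start.wait()
        self._done.wait()
        self._task = None
        if self._error is not None:
            exc, self._error = self._error, None
            raise exc
        end = end_box[0]
        return (
            ProbabilityMatrix(fm=fm, n_block=n_block, end_score=end),
            ScoreResult(end),
        )


def hmm_fill_parallel(
    events: list[Event],
    haplotype: str,
    model: PoreModel,
    scaling: ScalingParams,
    trans: TransitionParams = DEFAULT_TRANSITIONS,
    workers: int = 1,
) -> tuple[ProbabilityMatrix, ScoreResult]:
    """Two-phase parallel fill; bit-identical to :func:`hmm_fill_serial`."""
    with ParallelFiller(workers) as pool:
        return pool.fill(events, haplotype, model, scaling, trans)


FillFn = Callable[..., tuple[ProbabilityMatrix, ScoreResult]]


def score_cpg_group(
    group: CpGGroup,
    events: list[Event],
    model: PoreModel,
    scaling: ScalingParams,
    trans: TransitionParams = DEFAULT_TRANSITIONS,
    fill: FillFn = hmm_fill_serial,
    read_name: str = "",
) -> Optional[MethylationCall]:
    """Score one CpG group: methylated vs unmethylated log-likelihood ratio.

    The scored sequence is the reference forward strand of the group window;
    for reverse-strand reads the events are scored against the reverse
    complement, whose CpGs (the motif is palindromic) are then M-marked.
    Returns None (with a logged warning) when the group has no events.
    """
    if group.event_range is None:
        logger.warning(
            "CpG group %s:%d-%d has no event range; call suppressed",
            group.chrom,
            group.group_start,
            group.group_end,
        )
        return None
    first, last = group.event_range
    ev = events[first : last + 1]
    if not ev:
        logger.warning(
            "CpG group %s:%d-%d covers no events; call suppressed",
            group.chrom,
            group.group_start,
            group.group_end,
        )
        return None
    seq = group.sequence
    if group.strand == "-":
        seq = reverse_complement(seq)
    hap_m = make_methylated_haplotype(seq)
    _, unmeth = fill(ev, seq, model, scaling, trans)
    if hap_m == seq:
        meth = unmeth  # no CpG in window: identical haplotypes, ratio 0 exactly
    else:
        _, meth = fill(ev, hap_m, model, scaling, trans)
    return MethylationCall(
        chrom=group.chrom,
        strand=group.strand,
        start=group.group_start,
        end=group.group_end + 2,
        read_name=read_name,
        log_lik_ratio=meth.log_lik - unmeth.log_lik,
        log_lik_methylated=meth.log_lik,
        log_lik_unmethylated=unmeth.log_lik,
        num_motifs=group.num_motifs,
        sequence=group.sequence,
    )
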