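"""Upstream pipeline stages: event detection, event-to-k-mer alignment and
per-read calibration.

These are deliberately simple, well-specified stand-ins for the heavily
engineered equivalents in production nanopore tools: a two-window t-statistic
segmenter, a fixed-band dynamic-programming event aligner (the adaptive band
movement of full ABEA is not reproduced) and a least-squares affine
calibration fit.  They are sufficient to feed the scoring HMM and to
exercise the pipelined executor end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .model_types import Event, EventAlignment, PoreModel, ScalingParams
from .hmm_scoring import TransitionParams, DEFAULT_TRANSITIONS, scaled_levels

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SegmentationParams:
    """Two-window change-point detector settings.

    ``window`` samples on each side of a candidate boundary feed a Welch
    t-statistic; boundaries are local maxima of the statistic above
    ``threshold``, at least ``min_event_len`` samples apart.
    """

    window: int = 4
    threshold: float = 4.0
    min_event_len: int = 3

    def __post_init__(self):
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.min_event_len < 1:
            raise ValueError("min_event_len must be >= 1")


@dataclass(frozen=True)
class BandParams:
    """Width (in k-mer cells) of the fixed diagonal band of the aligner."""

    bandwidth: int = 100

    def __post_init__(self):
        if self.bandwidth < 3:
            raise ValueError("bandwidth must be >= 3")


class AlignmentError(RuntimeError):
    """Raised when the banded aligner has no reachable final cell."""


def detect_events(signal, params: SegmentationParams = SegmentationParams()) -> list[Event]:
    """Segment a raw current trace into events at sudden level changes.

    Returns events that tile the signal without overlap; each carries the
    sample mean and (population) standard deviation of its segment.  A
    signal shorter than ``2 * window`` yields an empty list.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    w = params.window
    if n <= 2 * w:
        return []
    sw = np.lib.stride_tricks.sliding_window_view(signal, w)
    means = sw.mean(axis=1)
    varis = sw.var(axis=1)
    # Boundary candidates i in [w, n-w]: left window [i-w, i), right [i, i+w).
    idx = np.arange(w, n - w + 1)
    m_l, m_r = means[idx - w], means[idx]
    v_l, v_r = varis[idx - w], varis[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m_r - m_l) / np.sqrt((v_l + v_r) / w)
    t[np.isnan(t)] = 0.0  # flat on both sides and equal means

    peaks = (t[1:-1] > t[:-2]) & (t[1:-1] >= t[2:]) & (t[1:-1] > params.threshold)
    candidates = idx[1:-1][peaks]
    # Handle infinities (zero variance, different means): always boundaries.
    boundaries = [0]
    for i in candidates:
        if i - boundaries[-1] >= params.min_event_len:
            boundaries.append(int(i))
    boundaries.append(n)

    events = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = signal[a:b]
        events.append(
            Event(
                start_sample=a,
                length=b - a,
                mean=float(seg.mean()),
                stdv=float(seg.std()),
            )
        )
    return events


def _band_limits(n_events: int, n_kmers: int, bandwidth: int):
    """Per-row [lo, hi] k-mer bounds of a band centred on the ideal diagonal."""
    if n_events > 1:
        centers = np.round(
            np.arange(n_events) * (n_kmers - 1) / (n_events - 1)
        ).astype(int)
    else:
        centers = np.zeros(n_events, dtype=int)
    half = bandwidth // 2
    lo = np.clip(centers - half, 0, n_kmers - 1)
    hi = np.clip(centers + half, 0, n_kmers - 1)
    return lo, hi


def align_events(
    events: list[Event],
    sequence: str,
    model: PoreModel,
    scaling: ScalingParams,
    params: BandParams = BandParams(),
    trans: TransitionParams = DEFAULT_TRANSITIONS,
) -> EventAlignment:
    """Banded Viterbi-style alignment of events to the k-mers of a sequence.

    Moves are stay (one more event on the same k-mer), step (next k-mer) and
    skip (k-mer traversed without an event); match emissions are the scaled
    Gaussian log densities, moves are priced with the log transition
    probabilities.  Cells outside a fixed band around the ideal diagonal are
    pruned.  The traceback assigns every event to exactly one k-mer and is
    monotone in both indices.
    """
    if not events:
        raise ValueError("at least one event is required")
    k = model.k
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    kmers = [sequence[i : i + k] for i in range(len(sequence) - k + 1)]
    n_e, n_k = len(events), len(kmers)
    smu, ssd = scaled_levels(kmers, model, scaling)
    x = np.array([e.mean for e in events])
    lo, hi = _band_limits(n_e, n_k, params.bandwidth)
    jidx = np.arange(n_k, dtype=float)

    lp_stay, lp_step, lp_skip = trans.lp_stay, trans.lp_step, trans.lp_skip

    def emit_row(i, a, b):
        z = (x[i] - smu[a : b + 1]) / ssd[a : b + 1]
        return -0.5 * z * z - np.log(ssd[a : b + 1]) - _HALF_LOG_2PI

    # Per-row backpointers: step-choice flags (band-compact) and, per row,
    # the skip-extended argmax of the *previous* row (full length).
    steps: list[np.ndarray] = [np.zeros(0, dtype=bool)]
    args: list[np.ndarray] = [np.zeros(0, dtype=np.int32)]

    a, b = int(lo[0]), int(hi[0])
    dp_prev = np.full(n_k, NEG_INF)
    dp_prev[a : b + 1] = emit_row(0, a, b) + jidx[a : b + 1] * lp_skip
    m_prev, arg_prev = _running_skip_max(dp_prev, a, lp_skip, jidx)

    for i in range(1, n_e):
        a, b = int(lo[i]), int(hi[i])
        args.append(arg_prev)
        dp = np.full(n_k, NEG_INF)
        stay = dp_prev[a : b + 1] + lp_stay
        step = np.full(b - a + 1, NEG_INF)
        lo_s = max(a, 1)
        step[lo_s - a :] = m_prev[lo_s - 1 : b] + lp_step
        choice_step = step > stay
        dp[a : b + 1] = emit_row(i, a, b) + np.where(choice_step, step, stay)
        steps.append(choice_step)
        dp_prev = dp
        m_prev, arg_prev = _running_skip_max(dp_prev, a, lp_skip, jidx)

    a, b = int(lo[-1]), int(hi[-1])
    finals = dp_prev[a : b + 1] + (n_k - 1 - jidx[a : b + 1]) * lp_skip
    if not np.isfinite(finals).any():
        raise AlignmentError("banded alignment failed: no reachable final cell")
    j = int(a + np.argmax(finals))

    pairs: list[tuple[int, int]] = []
    for i in range(n_e - 1, -1, -1):
        pairs.append((i, j))
        if i == 0:
            break
        if steps[i][j - int(lo[i])]:
            # step: predecessor is the skip-extended argmax of the previous
            # row at k-mer j-1.
            j = int(args[i][j - 1])
        # else stay: same j
    pairs.reverse()
    return EventAlignment(pairs=pairs)


def _running_skip_max(dp, a, lp_skip, jidx):
    """Skip-extended running maximum from column ``a`` to the end:
    ``m[j] = max_{j' <= j} dp[j'] + (j - j') * lp_skip`` with the attaining
    ``j'`` (ties broken toward the larger, i.e. fewer skips)."""
    n_k = len(dp)
    m = np.full(n_k, NEG_INF)
    arg = np.zeros(n_k, dtype=np.int32)
    shifted = dp[a:] - jidx[a:] * lp_skip
    racc = np.maximum.accumulate(shifted)
    m[a:] = racc + jidx[a:] * lp_skip
    hits = np.where(shifted >= racc, np.arange(a, n_k), a)
    arg[a:] = np.maximum.accumulate(hits)
    return m, arg


def calibrate(
    events: list[Event],
    alignment: EventAlignment,
    sequence: str,
    model: PoreModel,
    var_floor: float = 0.01,
) -> ScalingParams:
    """Least-squares affine calibration of event means against model levels.

    Fits ``event_mean = scale * level_mean + shift`` over the aligned
    (event, k-mer) pairs; ``var`` is the residual standard deviation divided
    by the mean model level stdv of the used k-mers, floored at
    ``var_floor``.  A degenerate design (fewer than two distinct model
    means) returns identity scaling with a warning.
    """
    k = model.k
    kmers = [sequence[i : i + k] for i in range(len(sequence) - k + 1)]
    xs, ys, sds = [], [], []
    for e_idx, k_idx in alignment.pairs:
        mu, sd = model.lookup(kmers[k_idx])
        xs.append(mu)
        ys.append(events[e_idx].mean)
        sds.append(sd)
    x = np.array(xs)
    y = np.array(ys)
    if len(np.unique(x)) < 2:
        logger.warning("degenerate calibration fit (all model means equal); "
                       "returning identity scaling")
        return ScalingParams()
    design = np.column_stack([x, np.ones_like(x)])
    (scale, shift), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (scale * x + shift)
    var = float(np.std(resid)) / float(np.mean(sds))
    return ScalingParams(shift=float(shift), scale=float(scale),
                         var=max(var, var_floor))


def moment_scaling(events: list[Event], kmers_mu: np.ndarray) -> ScalingParams:
    """Method-of-moments pre-scaling used before alignment: match the mean
    and spread of event currents to the model level distribution."""
    ev = np.array([e.mean for e in events])
    mu_sd = float(np.std(kmers_mu))
    ev_sd = float(np.std(ev))
    if mu_sd <= 0 or ev_sd <= 0:
        return ScalingParams()
    scale = ev_sd / mu_sd
    shift = float(np.mean(ev)) - scale * float(np.mean(kmers_mu))
    return ScalingParams(shift=shift, scale=scale)
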