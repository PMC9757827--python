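"""End-to-end wiring: build the four per-batch stage functions and run the
pipelined caller over a set of reads.

Stage 1 segments each read's raw signal into events; stage 2 aligns events
to the k-mers of the read's mapped reference window (after a
method-of-moments pre-scaling); stage 3 refines the per-read scaling by
least squares on the alignment; stage 4 groups the window's CpG sites and
scores each group's methylated-vs-unmethylated log-likelihood ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import hmm_scoring, stages
from .hmm_scoring import (
    DEFAULT_TRANSITIONS,
    ParallelFiller,
    TransitionParams,
    hmm_fill_serial,
    score_cpg_group,
)
from .model_types import PoreModel, Read, group_cpg_sites
from .pipeline_executor import (
    Batch,
    PipelineConfig,
    PipelineRun,
    make_batches,
    run_pipeline,
)
from .stages import AlignmentError, BandParams, SegmentationParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallParams:
    """Knobs of the calling workflow (exclusive of executor settings)."""

    group_distance: int = 10
    flank: int = 5
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    band: BandParams = field(default_factory=BandParams)
    transitions: TransitionParams = field(default_factory=TransitionParams)
    engine: str = "serial"  # "serial" | "parallel"

    def __post_init__(self):
        if self.engine not in ("serial", "parallel"):
            raise ValueError("engine must be 'serial' or 'parallel'")


def _window_sequence(read: Read, reference: dict[str, str]) -> str:
    chrom_seq = reference[read.mapped_chrom]
    return chrom_seq[read.mapped_start : read.window_end].upper()


def make_stage_fns(
    reference: dict[str, str],
    model: PoreModel,
    params: CallParams = CallParams(),
    workers: int = 1,
    filler: Optional[ParallelFiller] = None,
):
    """The four stage callables, closing over the reference and pore model.

    ``filler`` (a reusable :class:`ParallelFiller`) is used for scoring when
    ``params.engine == "parallel"``; the caller owns its lifecycle.
    """

    def stage_detect(batch: Batch) -> None:
        for read in batch.reads:
            if read.signal is None:
                logger.warning("read %s has no signal; dropped", read.read_id)
                continue
            ev = stages.detect_events(read.signal, params.segmentation)
            if not ev:
                logger.warning("read %s produced no events; dropped", read.read_id)
                continue
            batch.events[read.read_id] = ev

    def stage_align(batch: Batch) -> None:
        for read in batch.reads:
            ev = batch.events.get(read.read_id)
            if not ev:
                continue
            window = _window_sequence(read, reference)
            if read.mapped_strand == "-":
                from .model_types import reverse_complement

                window = reverse_complement(window)
            k = model.k
            kmers_mu = np.array(
                [
                    model.level_mean(window[i : i + k])
                    for i in range(len(window) - k + 1)
                ]
            )
            pre = stages.moment_scaling(ev, kmers_mu)
            try:
                aln = stages.align_events(ev, window, model, pre, params.band,
                                          params.transitions)
            except AlignmentError as exc:
                logger.warning("read %s: %s; dropped", read.read_id, exc)
                continue
            batch.alignments[read.read_id] = aln

    def stage_calibrate(batch: Batch) -> None:
        for read in batch.reads:
            aln = batch.alignments.get(read.read_id)
            if aln is None:
                continue
            window = _window_sequence(read, reference)
            if read.mapped_strand == "-":
                from .model_types import reverse_complement

                window = reverse_complement(window)
            batch.scalings[read.read_id] = stages.calibrate(
                batch.events[read.read_id], aln, window, model
            )

    def stage_score(batch: Batch) -> None:
        fill = hmm_fill_serial
        if params.engine == "parallel" and filler is not None:
            fill = filler.fill
        for read in batch.reads:
            aln = batch.alignments.get(read.read_id)
            if aln is None:
                continue
            ev = batch.events[read.read_id]
            scaling = batch.scalings[read.read_id]
            window = _window_sequence(read, reference)
            groups = group_cpg_sites(
                window,
                read.mapped_start,
                chrom=read.mapped_chrom,
                strand=read.mapped_strand,
                group_distance=params.group_distance,
                flank=params.flank,
                k=model.k,
            )
            kmer_events = aln.kmer_to_events()
            for group in groups:
                _attach_event_range(group, read, kmer_events, model.k,
                                    len(window))
                call = score_cpg_group(
                    group,
                    ev,
                    model,
                    scaling,
                    params.transitions,
                    fill=fill,
                    read_name=read.read_id,
                )
                if call is not None:
                    batch.calls.append(call)

    return (stage_detect, stage_align, stage_calibrate, stage_score)


def _attach_event_range(group, read, kmer_events, k, window_len) -> None:
    """Set group.event_range to the events aligned to the group's k-mers.

    The group sequence spans window offsets [seq_lo, seq_hi); its k-mers are
    the window k-mer indices [seq_lo, seq_hi - k].  For reverse-strand reads
    the window (and the alignment) is in reverse-complement orientation, so
    the offsets are mirrored.
    """
    seq_lo = group.seq_start - read.mapped_start
    seq_hi = seq_lo + len(group.sequence)
    if group.strand == "-":
        seq_lo, seq_hi = window_len - seq_hi, window_len - seq_lo
    j_lo, j_hi = seq_lo, seq_hi - k
    hit_events = [
        e
        for j in range(j_lo, j_hi + 1)
        for e in kmer_events.get(j, ())
    ]
    group.event_range = (min(hit_events), max(hit_events)) if hit_events else None


def call_methylation(
    reads: list[Read],
    reference: dict[str, str],
    model: PoreModel,
    params: CallParams = CallParams(),
    config: PipelineConfig = PipelineConfig(),
) -> PipelineRun:
    """Run the full pipelined caller; calls are returned sorted by
    (chrom, start, read_name) so output is reproducible."""
    batches = make_batches(reads, config.batch_size)
    filler = None
    try:
        if params.engine == "parallel":
            filler = ParallelFiller(config.threads)
        stage_fns = make_stage_fns(reference, model, params,
                                   workers=config.threads, filler=filler)
        run = run_pipeline(batches, config, stage_fns)
    finally:
        if filler is not None:
            filler.close()
    run.calls.sort(key=lambda c: (c.chrom, c.start, c.read_name))
    return run
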