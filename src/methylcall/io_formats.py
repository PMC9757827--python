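"""Readers and writers for the formats the caller touches.

Reads arrive as FASTQ (optionally gzipped), alignments as BAM/SAM,
the reference as FASTA, and per-read raw signal as a *signal table*: a
two-column tab-separated text file ``read_id <TAB> s1,s2,...`` standing in
for a raw-signal container.  Calls leave as a tab-separated table with the
column layout downstream methylation scripts already consume.
"""

from __future__ import annotations

import gzip
import logging
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO

from .model_types import MethylationCall, PoreModel, Read

logger = logging.getLogger(__name__)

CALLS_TSV_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path) -> dict[str, str]:
    """read_id -> sequence from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")}


def load_reference(path) -> dict[str, str]:
    """chrom -> sequence from a FASTA file."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def read_signal_table(path) -> dict[str, np.ndarray]:
    """read_id -> raw sample array from the tab-separated signal table."""
    signals: dict[str, np.ndarray] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                read_id, samples = line.split("\t")
                arr = np.array([float(x) for x in samples.split(",")])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed signal-table record"
                ) from exc
            if read_id in signals:
                raise ValueError(f"{path}:{lineno}: duplicate read_id {read_id!r}")
            if arr.size < 1:
                raise ValueError(f"{path}:{lineno}: empty signal for {read_id!r}")
            signals[read_id] = arr
    return signals


def write_signal_table(signals: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for read_id in signals:
            samples = ",".join(f"{x:.4f}" for x in signals[read_id])
            fh.write(f"{read_id}\t{samples}\n")


def read_alignments(bam_path) -> dict[str, tuple[str, int, int, str]]:
    """read_id -> (chrom, start, end, strand) from primary BAM/SAM records;
    unmapped, secondary and supplementary records are skipped (counted)."""
    skipped = 0
    out: dict[str, tuple[str, int, int, str]] = {}
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            out[rec.query_name] = (
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                strand,
            )
    if skipped:
        logger.info("skipped %d unmapped/secondary/supplementary records", skipped)
    return out


def read_inputs(reads_path, bam_path, ref_path, signals_path) -> Iterator[Read]:
    """Join FASTQ, BAM and signal-table records by read name into Reads.

    Reads missing an alignment or a signal are skipped with a warning
    counter; the reference is validated to contain every mapped chromosome.
    """
    sequences = read_fastq(reads_path)
    alignments = read_alignments(bam_path)
    signals = read_signal_table(signals_path)
    reference = load_reference(ref_path)
    n_no_aln = n_no_signal = 0
    for read_id, seq in sequences.items():
        if read_id not in alignments:
            n_no_aln += 1
            continue
        if read_id not in signals:
            logger.warning("read %s has no signal record; skipped", read_id)
            n_no_signal += 1
            continue
        chrom, start, end, strand = alignments[read_id]
        if chrom not in reference:
            raise ValueError(f"mapped chromosome {chrom!r} absent from reference")
        yield Read(
            read_id=read_id,
            sequence=seq,
            signal=signals[read_id],
            mapped_chrom=chrom,
            mapped_start=start,
            mapped_strand=strand,
            mapped_end=end,
        )
    if n_no_aln or n_no_signal:
        logger.info(
            "excluded reads: %d without primary alignment, %d without signal",
            n_no_aln,
            n_no_signal,
        )


def write_calls_tsv(calls: Iterable[MethylationCall], out_path) -> int:
    """Write calls as a tab-separated table; returns the row count.

    Callers should pass calls ordered by (chrom, start, read_name); floats
    are printed with fixed 2-decimal formatting and ``num_calling_strands``
    is the constant 1 (no duplex calling).
    """
    n = 0
    with open(out_path, "w") as fh:
        fh.write("\t".join(CALLS_TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.strand}\t{c.start}\t{c.end}\t{c.read_name}\t"
                f"{c.log_lik_ratio:.2f}\t{c.log_lik_methylated:.2f}\t"
                f"{c.log_lik_unmethylated:.2f}\t1\t{c.num_motifs}\t{c.sequence}\n"
            )
            n += 1
    return n


def read_calls_tsv(path) -> list[MethylationCall]:
    """Parse a calls table written by :func:`write_calls_tsv`."""
    calls = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CALLS_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected calls header {header!r}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                MethylationCall(
                    chrom=f[0],
                    strand=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    read_name=f[4],
                    log_lik_ratio=float(f[5]),
                    log_lik_methylated=float(f[6]),
                    log_lik_unmethylated=float(f[7]),
                    num_motifs=int(f[9]),
                    sequence=f[10],
                )
            )
    return calls
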