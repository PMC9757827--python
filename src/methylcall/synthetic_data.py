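"""Synthetic fixtures with the statistical structure the scoring HMM assumes.

The generator emulates a nanopore-style experiment end to end: a reference
with CG dinucleotides planted at a controlled density, per-read per-CpG
methylation truth, a k-mer Gaussian pore model with distinct entries for
M-substituted k-mers, and event-level signal produced by walking the
haplotype k-mer by k-mer with stay/skip/bad-event behaviour, affine
scaling, and Gaussian current noise.  Everything is deterministic under a
fixed seed.

What it does *not* emulate: basecalling errors (read sequences equal their
reference window), within-read drift, realistic dwell-time distributions,
or per-k-mer methylation shifts (M raises the level by one constant).
"""

from __future__ import annotations

import gzip
import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .model_types import (
    Event,
    PoreModel,
    Read,
    ScalingParams,
    enumerate_m_variants,
    find_cg_sites,
    make_methylated_haplotype,
)
from .hmm_scoring import TransitionParams

CHROM_NAME = "chrSim"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's reference study
    conditions."""

    seed: int = 42
    n_reads: int = 50
    read_length: int = 2000
    ref_length: int = 12000
    cpg_density: float = 0.02
    methylation_rate: float = 0.5
    p_stay: float = 0.1
    p_skip: float = 0.01
    p_bad: float = 0.01
    noise_sd: float = 1.0
    m_shift: float = 4.0
    shift: float = 10.0
    scale: float = 1.2
    var: float = 1.0
    k: int = 6
    dwell_min: int = 5
    dwell_max: int = 20
    group_distance: int = 10

    def __post_init__(self):
        for name in ("cpg_density", "methylation_rate", "p_stay", "p_skip", "p_bad"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def scaling(self) -> ScalingParams:
        return ScalingParams(shift=self.shift, scale=self.scale, var=self.var)


def make_pore_model(k: int = 6, m_shift: float = 4.0, seed: int = 0) -> PoreModel:
    """Synthetic k-mer Gaussian model over {A,C,G,T} plus M variants.

    Level means are drawn uniformly in [60, 120] pA and stdvs in
    [1.0, 2.5] pA per canonical k-mer; every M-substituted variant that can
    occur in a methylated haplotype gets the canonical mean plus ``m_shift``.
    """
    rng = np.random.default_rng(seed)
    table: dict[str, tuple[float, float]] = {}
    for bases in itertools.product("ACGT", repeat=k):
        kmer = "".join(bases)
        mean = float(rng.uniform(60.0, 120.0))
        stdv = float(rng.uniform(1.0, 2.5))
        table[kmer] = (mean, stdv)
    for kmer in list(table):
        mean, stdv = table[kmer]
        for variant in enumerate_m_variants(kmer):
            table[variant] = (mean + m_shift, stdv)
    return PoreModel(k, table)


def simulate_reference(config: SimConfig, rng=None) -> tuple[str, list[int]]:
    """Random reference with CG dinucleotides planted at the requested
    density; the background is CG-free so the planted sites are exactly the
    CG occurrences.  Returns (sequence, CG site positions)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.ref_length
    bases = "ACGT"
    chars = []
    prev = ""
    for _ in range(n):
        choices = bases if prev != "C" else "ACT"
        c = choices[rng.integers(len(choices))]
        chars.append(c)
        prev = c
    mask = rng.random(n) < config.cpg_density
    sites = []
    i = 0
    while i < n - 1:
        if mask[i] and (not sites or i - sites[-1] >= 2):
            # planting C,G cannot create a CG across either edge: the pair
            # (i-1, i) ends in C and (i+1, i+2) starts with G
            chars[i], chars[i + 1] = "C", "G"
            sites.append(i)
            i += 2
        else:
            i += 1
    seq = "".join(chars)
    return seq, find_cg_sites(seq)


def cluster_sites(sites: list[int], group_distance: int) -> list[list[int]]:
    """Cluster CG positions at most ``group_distance`` apart (same rule as
    the caller's grouping, so per-cluster truth is homogeneous per group)."""
    clusters: list[list[int]] = []
    for s in sites:
        if clusters and s - clusters[-1][-1] <= group_distance:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    return clusters


def simulate_read_signal(
    ref_window: str,
    methylation: dict[int, bool],
    model: PoreModel,
    config: SimConfig,
    rng,
    read_id: str = "read0",
    chrom: str = CHROM_NAME,
    mapped_start: int = 0,
) -> tuple[Read, list[Event], np.ndarray]:
    """Generate one read's events and raw signal from a reference window.

    ``methylation`` maps window offsets of CG sites to truth flags; the
    walked haplotype uses the M-substituted model entry at methylated
    sites.  Per k-mer the walk emits ``1 + Geometric`` events (stay rate
    ``p_stay``), skips the k-mer with ``p_skip``, and injects a
    uniform-outlier bad event with ``p_bad``.  Event means are
    ``Normal(scale * level + shift, noise_sd)``; the raw trace concatenates
    per-event constant segments plus sample noise.
    """
    chars = list(ref_window)
    for off, flag in methylation.items():
        if flag and ref_window[off : off + 2] == "CG":
            chars[off] = "M"
    haplotype = "".join(chars)
    k = model.k
    scaling = config.scaling
    level_lo = 60.0 * scaling.scale + scaling.shift - 20.0
    level_hi = 120.0 * scaling.scale + scaling.shift + 20.0

    events: list[Event] = []
    segments: list[np.ndarray] = []
    cursor = 0

    def emit(mean: float):
        nonlocal cursor
        length = int(rng.integers(config.dwell_min, config.dwell_max + 1))
        if config.noise_sd > 0:
            samples = mean + rng.normal(0.0, config.noise_sd, length)
        else:
            samples = np.full(length, mean)
        events.append(
            Event(start_sample=cursor, length=length, mean=float(mean),
                  stdv=config.noise_sd)
        )
        segments.append(samples)
        cursor += length

    for j in range(len(haplotype) - k + 1):
        if config.p_skip > 0 and rng.random() < config.p_skip:
            continue
        kmer = haplotype[j : j + k]
        mu = model.level_mean(kmer)
        n_events = 1
        if config.p_stay > 0:
            n_events += int(rng.geometric(1.0 - config.p_stay)) - 1
        for _ in range(n_events):
            level = scaling.scale * mu + scaling.shift
            mean = level if config.noise_sd == 0 else float(
                rng.normal(level, config.noise_sd)
            )
            emit(mean)
        if config.p_bad > 0 and rng.random() < config.p_bad:
            emit(float(rng.uniform(level_lo, level_hi)))

    signal = (
        np.concatenate(segments) if segments else np.zeros(0)
    )
    read = Read(
        read_id=read_id,
        sequence=ref_window,
        signal=signal,
        mapped_chrom=chrom,
        mapped_start=mapped_start,
        mapped_strand="+",
        mapped_end=mapped_start + len(ref_window),
    )
    return read, events, signal


def simulate_dataset(config: SimConfig = SimConfig()):
    """Full in-memory dataset: reference, model, reads and methylation truth.

    Returns (reference_seq, model, reads, truth) where truth maps
    ``(chrom, cg_position, read_id) -> methylated flag``; methylation state
    is drawn once per (read, CpG cluster) so groups are homogeneous.
    """
    rng = np.random.default_rng(config.seed)
    reference, _ = simulate_reference(config, rng)
    model = make_pore_model(config.k, config.m_shift,
                            seed=int(rng.integers(2**31)))
    reads: list[Read] = []
    truth: dict[tuple[str, int, str], bool] = {}
    max_start = max(0, config.ref_length - config.read_length)
    for r in range(config.n_reads):
        start = int(rng.integers(0, max_start + 1)) if max_start else 0
        window = reference[start : start + config.read_length]
        sites = find_cg_sites(window)
        flags: dict[int, bool] = {}
        for cluster in cluster_sites(sites, config.group_distance):
            flag = bool(rng.random() < config.methylation_rate)
            for off in cluster:
                flags[off] = flag
        read_id = f"simread_{r:04d}"
        read, _, _ = simulate_read_signal(
            window, flags, model, config, rng,
            read_id=read_id, mapped_start=start,
        )
        reads.append(read)
        for off, flag in flags.items():
            truth[(CHROM_NAME, start + off, read_id)] = flag
    return reference, model, reads, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def emit_fixture_set(config: SimConfig, out_dir) -> dict:
    """Write the full fixture file set and return a manifest.

    Files: reference FASTA, reads FASTQ.gz, alignments BAM, signal table
    TSV, methylation-truth TSV, plus the pore model table.  Identical
    configs produce byte-identical files (the gzip stream is written with a
    zeroed timestamp).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, model, reads, truth = simulate_dataset(config)

    ref_path = out / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{CHROM_NAME}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")

    fastq_path = out / "reads.fastq.gz"
    with open(fastq_path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
            for read in reads:
                rec = f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
                fh.write(rec.encode())

    bam_path = out / "alignments.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": CHROM_NAME, "LN": len(reference)}],
    }
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for read in reads:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.sequence
            seg.flag = 0 if read.mapped_strand == "+" else 16
            seg.reference_id = 0
            seg.reference_start = read.mapped_start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, len(read.sequence))]
            bam.write(seg)

    signals_path = out / "signals.tsv"
    from .io_formats import write_signal_table

    write_signal_table({r.read_id: r.signal for r in reads}, signals_path)

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tposition\tread_id\tmethylated\n")
        for (chrom, pos, read_id), flag in sorted(truth.items()):
            fh.write(f"{chrom}\t{pos}\t{read_id}\t{int(flag)}\n")

    model_path = out / "pore_model.tsv"
    model.to_file(model_path)

    files = {
        "reference": ref_path,
        "reads": fastq_path,
        "alignments": bam_path,
        "signals": signals_path,
        "truth": truth_path,
        "pore_model": model_path,
    }
    manifest = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "files": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_truth_table(path) -> dict[tuple[str, int, str], bool]:
    truth = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, read_id, flag = line.split()
            truth[(chrom, int(pos), read_id)] = bool(int(flag))
    return truth


def random_hmm_instance(
    rng,
    max_events: int = 4,
    max_blocks: int = 4,
    k: int = 3,
):
    """A small random scoring-HMM instance for oracle cross-checks.

    Returns (events, haplotype, model, scaling, trans): a random k-mer
    model, a random haplotype of ``n_blocks + k - 1`` bases, and events
    drawn loosely around the haplotype's scaled levels.
    """
    n_events = int(rng.integers(1, max_events + 1))
    n_blocks = int(rng.integers(1, max_blocks + 1))
    model = make_pore_model(k=k, m_shift=4.0, seed=int(rng.integers(2**31)))
    bases = "ACGT"
    haplotype = "".join(bases[rng.integers(4)] for _ in range(n_blocks + k - 1))
    scaling = ScalingParams(
        shift=float(rng.uniform(-5, 5)),
        scale=float(rng.uniform(0.8, 1.3)),
        var=float(rng.uniform(0.7, 1.5)),
    )
    kmers = [haplotype[i : i + k] for i in range(n_blocks)]
    events = []
    cursor = 0
    for i in range(n_events):
        kmer = kmers[int(rng.integers(n_blocks))]
        level = scaling.scale * model.level_mean(kmer) + scaling.shift
        mean = float(rng.normal(level, 2.0))
        length = int(rng.integers(3, 10))
        events.append(Event(start_sample=cursor, length=length, mean=mean, stdv=1.0))
        cursor += length
    trans = TransitionParams(
        p_stay=float(rng.uniform(0.05, 0.3)),
        p_skip=float(rng.uniform(0.005, 0.05)),
        p_bad=float(rng.uniform(0.005, 0.05)),
    )
    return events, haplotype, model, scaling, trans
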