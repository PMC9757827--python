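"""Shared domain types for signal-level CpG methylation calling.

Conventions used throughout the package:

* All genomic coordinates are 0-based; intervals are half-open ``[start, end)``.
* Currents (event means, pore-model levels) are in picoamps.
* The methylated base 5-methylcytosine is written ``M``, so haplotypes are
  strings over the alphabet ``{A, C, G, T, M}``.
* Probabilities are carried in natural-log space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
HAPLOTYPE_ALPHABET = frozenset("ACGTM")

_COMPLEMENT = str.maketrans("ACGTM", "TGCAM")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA/haplotype string (M is self-complementary
    here only as a placeholder; reverse-strand methylation is handled by
    re-marking CpGs after complementing)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class PoreModel:
    """k-mer current model: expected level mean and stdv per k-mer.

    The table covers every k-mer over {A,C,G,T} plus, for each k-mer with a
    cytosine in CpG context, the variant(s) with that cytosine replaced by M.
    """

    def __init__(self, k: int, table: dict[str, tuple[float, float]]):
        if k < 1:
            raise ValueError("k must be >= 1")
        for kmer, (mean, stdv) in table.items():
            if len(kmer) != k:
                raise ValueError(f"k-mer {kmer!r} does not have length {k}")
            if stdv <= 0:
                raise ValueError(f"k-mer {kmer!r} has non-positive level_stdv")
        self.k = k
        self.table = dict(table)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.table

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, kmer: str) -> tuple[float, float]:
        try:
            return self.table[kmer]
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} not present in the pore model") from None

    def level_mean(self, kmer: str) -> float:
        return self.lookup(kmer)[0]

    def level_stdv(self, kmer: str) -> float:
        return self.lookup(kmer)[1]

    def to_file(self, path) -> None:
        """Write the model as a whitespace-delimited text table with header."""
        with open(path, "w") as fh:
            fh.write("kmer\tlevel_mean\tlevel_stdv\n")
            for kmer in sorted(self.table):
                mean, stdv = self.table[kmer]
                fh.write(f"{kmer}\t{mean:.6f}\t{stdv:.6f}\n")

    @classmethod
    def from_file(cls, path) -> "PoreModel":
        table: dict[str, tuple[float, float]] = {}
        with open(path) as fh:
            header = fh.readline().split()
            if header[:3] != ["kmer", "level_mean", "level_stdv"]:
                raise ValueError(
                    f"{path}: expected header 'kmer level_mean level_stdv', got {header!r}"
                )
            for line in fh:
                if not line.strip():
                    continue
                kmer, mean, stdv = line.split()[:3]
                table[kmer] = (float(mean), float(stdv))
        if not table:
            raise ValueError(f"{path}: empty pore model")
        k = len(next(iter(table)))
        return cls(k, table)


@dataclass(frozen=True)
class ScalingParams:
    """Per-read affine calibration mapping model currents onto the read.

    An event drawn from k-mer ``x`` is modelled as
    ``Normal(scale * level_mean(x) + shift, (var * level_stdv(x))**2)``.
    ``drift`` (picoamps per sample) is carried for completeness but unused
    by default.
    """

    shift: float = 0.0
    scale: float = 1.0
    var: float = 1.0
    drift: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.var <= 0:
            raise ValueError("var must be > 0")


IDENTITY_SCALING = ScalingParams()


@dataclass(frozen=True)
class Event:
    """One segment of the raw current trace: a putative single k-mer residency."""

    start_sample: int
    length: int
    mean: float
    stdv: float

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if self.stdv < 0:
            raise ValueError("event stdv must be >= 0")


@dataclass
class Read:
    """A sequenced read joined with its raw signal and primary alignment."""

    read_id: str
    sequence: str
    signal: Optional[np.ndarray] = None
    mapped_chrom: str = ""
    mapped_start: int = 0
    mapped_strand: str = "+"
    mapped_end: Optional[int] = None

    def __post_init__(self):
        if self.mapped_start < 0:
            raise ValueError("mapped_start must be >= 0")
        if self.signal is not None and len(self.signal) and not self.sequence:
            raise ValueError("read with signal must have a sequence")

    @property
    def window_end(self) -> int:
        """End of the mapped reference window (falls back to read length)."""
        if self.mapped_end is not None:
            return self.mapped_end
        return self.mapped_start + len(self.sequence)


@dataclass
class EventAlignment:
    """Monotone mapping of event indices to k-mer indices."""

    pairs: list[tuple[int, int]]

    def __post_init__(self):
        prev_e, prev_k = -1, -1
        for e, k in self.pairs:
            if e < prev_e or k < prev_k:
                raise ValueError("event alignment must be monotone in both indices")
            prev_e, prev_k = e, k

    def kmer_to_events(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for e, k in self.pairs:
            out.setdefault(k, []).append(e)
        return out


@dataclass
class CpGGroup:
    """A cluster of nearby CG dinucleotides scored jointly by one HMM matrix.

    ``group_start``/``group_end`` are the reference positions of the first and
    last CG in the group (start of each dinucleotide).  ``sequence`` is the
    reference subsequence including flanks, starting at ``seq_start``.
    """

    chrom: str
    group_start: int
    group_end: int
    num_motifs: int
    sequence: str
    seq_start: int
    strand: str = "+"
    event_range: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if self.group_start > self.group_end:
            raise ValueError("group_start must be <= group_end")
        if self.event_range is not None and self.event_range[0] > self.event_range[1]:
            raise ValueError("event_range first index must be <= last index")


@dataclass(frozen=True)
class MethylationCall:
    """Per (read, CpG group) log-likelihood-ratio call.

    ``log_lik_ratio = log_lik_methylated - log_lik_unmethylated`` (natural
    log); positive values support methylation.
    """

    chrom: str
    strand: str
    start: int
    end: int
    read_name: str
    log_lik_ratio: float
    log_lik_methylated: float
    log_lik_unmethylated: float
    num_motifs: int
    sequence: str


def make_methylated_haplotype(sequence: str) -> str:
    """Replace every cytosine in CpG context by M.

    The input may already contain M (which has no CpG context and passes
    through unchanged), so the function is idempotent.  Any character outside
    {A,C,G,T,M} is rejected.
    """
    bad = set(sequence) - HAPLOTYPE_ALPHABET
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT(M) characters: {sorted(bad)!r}"
        )
    return sequence.replace("CG", "MG")


def find_cg_sites(sequence: str) -> list[int]:
    """Offsets of every CG dinucleotide start in ``sequence``."""
    out = []
    start = 0
    while True:
        i = sequence.find("CG", start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def group_cpg_sites(
    ref_window: str,
    window_start: int = 0,
    *,
    chrom: str = "",
    strand: str = "+",
    group_distance: int = 10,
    flank: int = 5,
    k: int = 6,
) -> list[CpGGroup]:
    """Cluster the CG sites of a reference window into scoring groups.

    CG dinucleotides whose start positions are at most ``group_distance``
    apart are merged into one group.  Each group's sequence spans
    ``[first CG - flank, last CG + 2 + flank)`` clipped to the window, so
    that with ``flank = k - 1`` every k-mer overlapping a CpG lies inside
    the scored subsequence.
    """
    if group_distance < 0 or flank < 0:
        raise ValueError("group_distance and flank must be >= 0")
    if len(ref_window) < k:
        return []
    sites = find_cg_sites(ref_window)
    if not sites:
        return []
    clusters: list[list[int]] = [[sites[0]]]
    for s in sites[1:]:
        if s - clusters[-1][-1] <= group_distance:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    groups = []
    for cluster in clusters:
        first, last = cluster[0], cluster[-1]
        lo = max(0, first - flank)
        hi = min(len(ref_window), last + 2 + flank)
        groups.append(
            CpGGroup(
                chrom=chrom,
                group_start=window_start + first,
                group_end=window_start + last,
                num_motifs=len(cluster),
                sequence=ref_window[lo:hi],
                seq_start=window_start + lo,
                strand=strand,
            )
        )
    return groups


def enumerate_m_variants(kmer: str) -> list[str]:
    """All M-substituted variants of an ACGT k-mer that can occur in a
    methylated haplotype.

    A cytosine is substitutable when its CpG context is possible: the next
    base within the k-mer is G, or the cytosine is the last base (the G then
    lies just outside the k-mer).
    """
    k = len(kmer)
    eligible = [
        i
        for i, c in enumerate(kmer)
        if c == "C" and (i == k - 1 or kmer[i + 1] == "G")
    ]
    variants = []
    for r in range(1, len(eligible) + 1):
        for subset in itertools.combinations(eligible, r):
            chars = list(kmer)
            for i in subset:
                chars[i] = "M"
            variants.append("".join(chars))
    return variants
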