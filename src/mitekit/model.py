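"""Core genomic data model shared by every pipeline stage.

All coordinates are 0-based half-open on the forward strand; the only place
1-based inclusive coordinates appear is GFF3 text at the I/O boundary.
``N`` is the only ambiguity symbol carried internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A single assembled sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id}: non-ACGTN symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.contig_id}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with its exon structure (introns are the gaps between exons)."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = ex.end


@dataclass
class MITECandidate:
    """A putative MITE: TIR-bounded, TSD-flanked element found de novo.

    ``interval`` spans the element only (TIR..internal..TIR); the TSD copies
    sit immediately outside it on both flanks.
    """

    interval: GenomicInterval
    tir_length: int
    tir_mismatches: int
    tsd_seq: str
    sequence: str = ""

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)

    @property
    def score(self) -> float:
        return self.tir_length + self.tsd_len - self.tir_mismatches


@dataclass
class MITEFamily:
    """A cluster of candidates with a curated seed and superfamily label."""

    family_id: str
    members: list[MITECandidate]
    seed: MITECandidate | None = None
    consensus: str = ""
    superfamily: str = "unknown"


@dataclass
class MITEHit:
    """One genome-scan occurrence of a family (full-length or fragment)."""

    hit_id: str
    family_id: str
    superfamily: str
    interval: GenomicInterval
    identity_to_seed: float
    kimura_divergence: float
    full_length: bool
    score: float


@dataclass
class TruthRecord:
    """One planted element from the synthetic generator (acceptance oracle)."""

    element_id: str
    family_id: str
    superfamily: str
    interval: GenomicInterval
    tsd_seq: str
    tir_length: int
    planted_k: float
    species_id: str = ""
    locus_id: str = ""
    locus_class: str = ""


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)
    spec: object = None

    def __post_init__(self):
        ids = [r.element_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate element_id in truth set")

    def intervals(self, contig_id: str | None = None) -> list[GenomicInterval]:
        ivs = [r.interval for r in self.records]
        if contig_id is not None:
            ivs = [iv for iv in ivs if iv.contig_id == contig_id]
        return sorted(ivs)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of (start, end) pairs on one contig, sorted and merged."""
    pairs = sorted((iv.start, iv.end) if isinstance(iv, GenomicInterval) else tuple(iv)
                   for iv in intervals)
    merged: list[list[int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(p) for p in merged]
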