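"""Genome-wide recovery of all copies of each family from its seed.

A k-mer seeded (k=11, both strands) local-alignment search: anchor matches
of the seed against an indexed contig define candidate windows, each window
is aligned with a gapped local aligner (match +1, mismatch -1, gap open -4,
extend -1), and hits are retained when their Kimura two-parameter divergence
from the seed is at most ``max_divergence`` (default 0.15) and their score
reaches ``min_score`` (default 50, roughly the shortest admissible perfect
50 bp hit — a calibration constant, not an equivalence claim with any
external masker's cutoff). Low-complexity hits dominated by a single
dinucleotide are dropped unless the family is Micron, whose copies
legitimately sit in microsatellite context.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import KmerIndex, local_search, make_aligner
from .clock import k2p_from_counts
from .model import Contig, GenomicInterval, MITEHit, merge_intervals, revcomp

_SCAN_ALIGNER = make_aligner("local", 1.0, -1.0, -4.0, -1.0)


@dataclass
class LandscapeSummary:
    """The four landscape indices of a masked genome."""

    proportion_of_genome: float   # percent of bases covered (merged)
    density_per_mb: float         # copies per Mb
    mean_length: float            # bp
    family_count: int


def _dinucleotide_fraction(seq: str) -> float:
    """Fraction of the sequence explained by its most frequent dinucleotide."""
    if len(seq) < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        counts[d] = counts.get(d, 0) + 1
    best = max(counts.values())
    return min(1.0, 2.0 * best / len(seq))


def scan(genome: list[Contig], seed_library,
         max_divergence: float = 0.15, min_score: float = 50.0,
         k: int = 11, full_length_coverage: float = 0.9,
         low_complexity_frac: float = 0.8) -> list[MITEHit]:
    """All occurrences of the seed library in the genome.

    ``seed_library`` is a list of (family_id, superfamily, seed_sequence).
    Per-family overlapping hits are merged; cross-family conflicts (overlap
    >50% of the shorter hit) resolve to the highest score. ``full_length``
    marks hits covering at least 90% of the seed with both ends present.
    """
    if not seed_library:
        raise ValueError("empty seed library")
    raw: list[MITEHit] = []
    counter = 0
    for contig in genome:
        index = KmerIndex(contig.sequence, k)
        for family_id, superfamily, seed in seed_library:
            for strand, query in (("+", seed), ("-", revcomp(seed))):
                for hit in local_search(query, contig.sequence, index,
                                        _SCAN_ALIGNER, min_score,
                                        pad=100):
                    st = hit.stats
                    dist = k2p_from_counts(st.transitions, st.transversions,
                                           st.matches + st.mismatches)
                    if not dist.valid or dist.K > max_divergence:
                        continue
                    if hit.target_end - hit.target_start < 50:
                        continue
                    hit_seq = contig.sequence[hit.target_start:hit.target_end]
                    if (superfamily != "Micron"
                            and _dinucleotide_fraction(hit_seq) > low_complexity_frac):
                        continue
                    qlen = len(query)
                    span = st.query_end - st.query_start
                    full = (span >= full_length_coverage * qlen
                            and st.query_start <= 5 and st.query_end >= qlen - 5)
                    counter += 1
                    raw.append(MITEHit(
                        hit_id=f"hit{counter}",
                        family_id=family_id, superfamily=superfamily,
                        interval=GenomicInterval(contig.id, hit.target_start,
                                                 hit.target_end,
                                                 "." if strand == "+" else "-"),
                        identity_to_seed=st.identity,
                        kimura_divergence=dist.K,
                        full_length=full, score=hit.score))
    merged = _merge_per_family(raw)
    resolved = _resolve_cross_family(merged)
    resolved.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                                 h.interval.end))
    for i, h in enumerate(resolved, start=1):
        h.hit_id = f"hit{i}"
    return resolved


def _merge_per_family(hits: list[MITEHit]) -> list[MITEHit]:
    """Union overlapping same-family hits; the best-scoring hit represents."""
    out: list[MITEHit] = []
    by_key: dict[tuple, list[MITEHit]] = {}
    for h in hits:
        by_key.setdefault((h.family_id, h.interval.contig_id), []).append(h)
    for (family_id, contig_id), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.interval.start, h.interval.end))
        cluster: list[MITEHit] = []
        end = -1
        for h in group + [None]:
            if h is not None and (not cluster or h.interval.start < end):
                cluster.append(h)
                end = max(end, h.interval.end)
                continue
            if cluster:
                rep = max(cluster, key=lambda x: x.score)
                start = min(x.interval.start for x in cluster)
                stop = max(x.interval.end for x in cluster)
                out.append(MITEHit(
                    hit_id=rep.hit_id, family_id=family_id,
                    superfamily=rep.superfamily,
                    interval=GenomicInterval(contig_id, start, stop,
                                             rep.interval.strand),
                    identity_to_seed=rep.identity_to_seed,
                    kimura_divergence=rep.kimura_divergence,
                    full_length=rep.full_length, score=rep.score))
            if h is not None:
                cluster = [h]
                end = h.interval.end
            else:
                cluster = []
    return out


def _resolve_cross_family(hits: list[MITEHit]) -> list[MITEHit]:
    """Drop hits overlapped >50% (of the shorter) by a better-scoring hit."""
    ranked = sorted(hits, key=lambda h: (-h.score, h.interval.contig_id,
                                         h.interval.start, h.family_id))
    kept: list[MITEHit] = []
    for h in ranked:
        ok = True
        for other in kept:
            ov = h.interval.overlap(other.interval)
            if ov > 0.5 * min(h.interval.length, other.interval.length):
                ok = False
                break
        if ok:
            kept.append(h)
    return kept


def summarize_landscape(hits: list[MITEHit],
                        genome: list[Contig]) -> LandscapeSummary:
    """Proportion, density/Mb, mean length and family number of a hit set.

    Proportion uses merged masked bases; density counts copies.
    """
    genome_bp = sum(c.length for c in genome)
    if genome_bp == 0:
        raise ValueError("empty genome")
    masked = 0
    by_contig: dict[str, list] = {}
    for h in hits:
        by_contig.setdefault(h.interval.contig_id, []).append(h.interval)
    for intervals in by_contig.values():
        masked += sum(e - s for s, e in merge_intervals(intervals))
    n = len(hits)
    return LandscapeSummary(
        proportion_of_genome=100.0 * masked / genome_bp,
        density_per_mb=n / (genome_bp / 1e6),
        mean_length=(sum(h.interval.length for h in hits) / n) if n else 0.0,
        family_count=len({h.family_id for h in hits}))


def seed_library_from_families(families) -> list[tuple]:
    """(family_id, superfamily, seed_sequence) triples for ``scan``."""
    lib = []
    for fam in families:
        if fam.seed is None:
            raise ValueError(f"family {fam.family_id} has no seed")
        lib.append((fam.family_id, fam.superfamily, fam.seed.sequence))
    return lib
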