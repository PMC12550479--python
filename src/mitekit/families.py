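"""Clustering of MITE candidates into families.

Follows the annotation pipeline's family rules: greedy centroid clustering
at 80% global identity (identity = matching columns / alignment columns
including terminal gaps, the iddef-1 definition), a minimum of three copies
per family, collapse of members that share their 50 bp flanking context
(elements that transposed do not carry their flanks with them, so identical
flanks mean the same individual was found twice), a <100 bp positional
merge of two detection sources, and deterministic seed selection by TSD/TIR
completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import global_identity
from .model import Contig, MITECandidate, MITEFamily


@dataclass
class ClusterParams:
    identity_threshold: float = 0.8
    flank_len: int = 50
    flank_identity_collapse: float = 0.8
    merge_tolerance: int = 100
    min_copies: int = 3

    def __post_init__(self):
        for name in ("identity_threshold", "flank_identity_collapse"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


def cluster(candidates: list[MITECandidate],
            params: ClusterParams | None = None):
    """Greedy centroid clustering by decreasing length.

    A candidate joins the first centroid whose global identity reaches the
    threshold, otherwise founds a new centroid. Families below the copy
    minimum are dissolved into singletons.

    Returns (families, singletons).
    """
    params = params or ClusterParams()
    ordered = sorted(candidates,
                     key=lambda c: (-len(c.sequence), c.interval.contig_id,
                                    c.interval.start))
    centroids: list[str] = []
    clusters: list[list[MITECandidate]] = []
    for cand in ordered:
        for i, centroid in enumerate(centroids):
            if global_identity(centroid, cand.sequence) >= params.identity_threshold:
                clusters[i].append(cand)
                break
        else:
            centroids.append(cand.sequence)
            clusters.append([cand])
    families: list[MITEFamily] = []
    singletons: list[MITECandidate] = []
    n = 0
    for members in clusters:
        if len(members) >= params.min_copies:
            n += 1
            members = sorted(members, key=lambda c: (c.interval.contig_id,
                                                     c.interval.start))
            families.append(MITEFamily(family_id=f"FAM{n}", members=members))
        else:
            singletons.extend(members)
    singletons.sort(key=lambda c: (c.interval.contig_id, c.interval.start))
    return families, singletons


def _flanks(cand: MITECandidate, seqs: dict[str, str], flank_len: int) -> str:
    seq = seqs[cand.interval.contig_id]
    s, e = cand.interval.start, cand.interval.end
    return seq[max(0, s - flank_len):s] + seq[e:e + flank_len]


def flank_distinctness_filter(family: MITEFamily, genome: list[Contig],
                              params: ClusterParams | None = None) -> MITEFamily:
    """Collapse members whose 50 bp flank context is not distinct.

    Members whose concatenated left+right flanks align at or above the
    collapse identity are the same individual annotated twice (e.g. a tandem
    duplication); the higher-scoring member represents the group. Collapse is
    transitive. Members with no flank sequence at all (both at contig edges)
    are never auto-collapsed.
    """
    params = params or ClusterParams()
    seqs = {c.id: c.sequence for c in genome}
    members = family.members
    flanks = [_flanks(m, seqs, params.flank_len) for m in members]
    parent = list(range(len(members)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if not flanks[i] or not flanks[j]:
                continue
            if global_identity(flanks[i], flanks[j]) >= params.flank_identity_collapse:
                parent[find(j)] = find(i)
    groups: dict[int, list[MITECandidate]] = {}
    for i, m in enumerate(members):
        groups.setdefault(find(i), []).append(m)
    kept = [max(g, key=lambda m: (m.score, -m.interval.start))
            for g in groups.values()]
    kept.sort(key=lambda m: (m.interval.contig_id, m.interval.start))
    return MITEFamily(family_id=family.family_id, members=kept,
                      seed=family.seed, consensus=family.consensus,
                      superfamily=family.superfamily)


def merge_annotation_sets(set_a: list[MITECandidate],
                          set_b: list[MITECandidate],
                          tolerance: int = 100) -> list[MITECandidate]:
    """Merge two detection outputs on the same genome.

    Records whose starts and ends each differ by less than ``tolerance`` bp
    on the same contig are the same element; the one with stricter boundary
    evidence (longer TIR, then longer TSD) wins. Everything else passes
    through. Matching is greedy in coordinate order; each record matches at
    most once.
    """
    out: list[MITECandidate] = []
    used_b = [False] * len(set_b)
    b_sorted = sorted(range(len(set_b)),
                      key=lambda i: (set_b[i].interval.contig_id,
                                     set_b[i].interval.start))
    for a in sorted(set_a, key=lambda c: (c.interval.contig_id,
                                          c.interval.start)):
        match = None
        for bi in b_sorted:
            if used_b[bi]:
                continue
            b = set_b[bi]
            if b.interval.contig_id != a.interval.contig_id:
                continue
            if (abs(a.interval.start - b.interval.start) < tolerance
                    and abs(a.interval.end - b.interval.end) < tolerance):
                match = bi
                break
        if match is None:
            out.append(a)
        else:
            used_b[match] = True
            b = set_b[match]
            keys = ((a.tir_length, a.tsd_len), (b.tir_length, b.tsd_len))
            out.append(a if keys[0] >= keys[1] else b)
    for bi, b in enumerate(set_b):
        if not used_b[bi]:
            out.append(b)
    out.sort(key=lambda c: (c.interval.contig_id, c.interval.start,
                            c.interval.end))
    return out


def select_seed(family: MITEFamily) -> MITECandidate:
    """The member with the most complete TSD and TIR.

    Maximises (tsd_len, tir_length, -tir_mismatches); remaining ties are
    broken by the smallest mean divergence to the other members, then the
    leftmost coordinate.
    """
    if not family.members:
        raise ValueError("empty family")
    best_key = max((m.tsd_len, m.tir_length, -m.tir_mismatches)
                   for m in family.members)
    tied = [m for m in family.members
            if (m.tsd_len, m.tir_length, -m.tir_mismatches) == best_key]
    if len(tied) == 1:
        return tied[0]

    def mean_div(m):
        others = [o for o in family.members if o is not m]
        if not others:
            return 0.0
        return sum(1.0 - global_identity(m.sequence, o.sequence)
                   for o in others) / len(others)

    tied.sort(key=lambda m: (mean_div(m), m.interval.contig_id,
                             m.interval.start))
    return tied[0]


def build_families(candidates: list[MITECandidate], genome: list[Contig],
                   params: ClusterParams | None = None):
    """cluster -> flank collapse -> copy-count filter -> seed selection."""
    params = params or ClusterParams()
    families, singletons = cluster(candidates, params)
    final: list[MITEFamily] = []
    for fam in families:
        fam = flank_distinctness_filter(fam, genome, params)
        if len(fam.members) >= params.min_copies:
            fam.seed = select_seed(fam)
            final.append(fam)
        else:
            singletons.extend(fam.members)
    singletons.sort(key=lambda c: (c.interval.contig_id, c.interval.start))
    return final, singletons
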