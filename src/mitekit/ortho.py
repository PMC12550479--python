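"""Shared vs species-specific MITE insertion sites across related genomes.

Each full-length element is extended by 1 kb of flanking sequence on both
sides (truncated at contig ends) and searched against the other species'
genomes with a gapped local aligner (+2/-3, gap open -5 extend -2,
BLASTN-like). Hits are kept at E-value < 1e-9 (classical ungapped
Karlin-Altschul parameters lambda=0.625, K=0.41, m = query length,
n = target genome length) and identity > 80%; hits within 1 kb of each
other on the target merge into one locus region.

A species' status is *shared* when one region covers essentially the whole
query including the element; *specific-absent* (an empty site) when both
flanks are recovered nearly contiguously while the element itself is not;
anything else is *unresolved*. A locus is shared when every non-reference
species is shared, species-specific when every one shows the empty site,
and ambiguous otherwise. Unresolved species states keep a locus out of both
headline counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (KmerIndex, evalue_score_threshold,
                    karlin_altschul_evalue, local_search, make_aligner)
from .model import Contig, GenomicInterval, merge_intervals

_ORTHO_ALIGNER = make_aligner("local", 2.0, -3.0, -5.0, -2.0)

# artifact constants of the locus rules (the method text gives none)
SHARED_QUERY_COVER = 0.95
SHARED_ELEMENT_COVER = 0.80
SPECIFIC_FLANK_COVER = 0.80
SPECIFIC_ELEMENT_COVER = 0.20
LOCUS_MERGE_BP = 1000


@dataclass
class OrthoQuery:
    """A reference element plus up to 1 kb of flank on each side."""

    locus_id: str
    reference_species: str
    element_interval: GenomicInterval
    query_seq: str
    left_flank_len: int
    right_flank_len: int

    @property
    def element_len(self) -> int:
        return self.element_interval.length

    @property
    def element_span(self) -> tuple[int, int]:
        """Element position inside query_seq coordinates."""
        return (self.left_flank_len, self.left_flank_len + self.element_len)


def build_query(element_interval: GenomicInterval, genome: list[Contig],
                flank_len: int = 1000, locus_id: str = "",
                reference_species: str = "ref") -> OrthoQuery:
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    seqs = {c.id: c.sequence for c in genome}
    seq = seqs[element_interval.contig_id]
    s, e = element_interval.start, element_interval.end
    left = max(0, s - flank_len)
    right = min(len(seq), e + flank_len)
    return OrthoQuery(locus_id=locus_id, reference_species=reference_species,
                      element_interval=element_interval,
                      query_seq=seq[left:right],
                      left_flank_len=s - left, right_flank_len=right - e)


@dataclass
class HomologyHit:
    contig_id: str
    target_start: int
    target_end: int
    identity: float
    e_value: float
    score: float
    # residue-to-residue aligned block pairs (query side, target side)
    query_blocks: list = field(default_factory=list)
    target_blocks: list = field(default_factory=list)


@dataclass
class LocusRegion:
    """Homology hits within 1 kb of each other on the target."""

    contig_id: str
    start: int
    end: int
    hits: list

    def query_coverage_intervals(self):
        ivs = []
        for h in self.hits:
            ivs.extend(h.query_blocks)
        return merge_intervals(ivs) if ivs else []


def search_homologs(query: OrthoQuery, target_genome: list[Contig],
                    evalue_max: float = 1e-9, min_identity: float = 0.8,
                    k: int = 13, min_anchors: int = 4) -> list[LocusRegion]:
    """Filtered local hits of the query in one genome, merged into regions."""
    n_total = sum(c.length for c in target_genome)
    m = len(query.query_seq)
    # Seed windows from the flanks only: the element itself recurs
    # genome-wide and would spray windows over every family copy, none of
    # which can satisfy the flank-coverage rules. Score floor = the score
    # at which the E-value filter would reject the hit anyway.
    es, ee = query.element_span
    seed_query = (query.query_seq[:es] + "N" * (ee - es)
                  + query.query_seq[ee:])
    min_score = max(40.0, evalue_score_threshold(evalue_max, m, n_total))
    hits: list[HomologyHit] = []
    for contig in target_genome:
        index = KmerIndex(contig.sequence, k)
        for lh in local_search(query.query_seq, contig.sequence, index,
                               _ORTHO_ALIGNER, min_score=min_score,
                               pad=200, seed_query=seed_query,
                               min_anchors=min_anchors):
            ev = karlin_altschul_evalue(lh.score, m, n_total)
            ident = lh.stats.aligned_identity
            if ev >= evalue_max or ident <= min_identity:
                continue
            hits.append(HomologyHit(
                contig_id=contig.id, target_start=lh.target_start,
                target_end=lh.target_end, identity=ident, e_value=ev,
                score=lh.score, query_blocks=list(lh.query_blocks),
                target_blocks=list(lh.target_blocks)))
    regions: list[LocusRegion] = []
    by_contig: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for cid in sorted(by_contig):
        group = sorted(by_contig[cid], key=lambda h: (h.target_start,
                                                      h.target_end))
        cluster: list[HomologyHit] = []
        end = None
        for h in group + [None]:
            if h is not None and (end is None or h.target_start < end + LOCUS_MERGE_BP):
                cluster.append(h)
                end = max(end or h.target_end, h.target_end)
                continue
            if cluster:
                regions.append(LocusRegion(
                    contig_id=cid,
                    start=min(x.target_start for x in cluster),
                    end=max(x.target_end for x in cluster), hits=cluster))
            if h is not None:
                cluster, end = [h], h.target_end
    return regions


@dataclass
class OrthoLocus:
    locus_id: str
    reference_species: str
    reference_interval: GenomicInterval
    per_species_status: dict
    classification: str
    copies: int


def _covered(intervals, lo, hi) -> int:
    """Bases of [lo, hi) covered by the merged interval list."""
    total = 0
    for s, e in intervals:
        total += max(0, min(e, hi) - max(s, lo))
    return total


def _species_status(query: OrthoQuery, regions: list[LocusRegion]) -> str:
    es, ee = query.element_span
    qlen = len(query.query_seq)
    for region in regions:
        cov = region.query_coverage_intervals()
        total_cov = _covered(cov, 0, qlen) / qlen
        elem_cov = _covered(cov, es, ee) / max(1, ee - es)
        if total_cov >= SHARED_QUERY_COVER and elem_cov >= SHARED_ELEMENT_COVER:
            return "shared"
    for region in regions:
        cov = region.query_coverage_intervals()
        left_cov = (_covered(cov, 0, es) / es) if es else 1.0
        right_cov = (_covered(cov, ee, qlen) / (qlen - ee)) if qlen > ee else 1.0
        elem_cov = _covered(cov, es, ee) / max(1, ee - es)
        if not (left_cov >= SPECIFIC_FLANK_COVER
                and right_cov >= SPECIFIC_FLANK_COVER
                and elem_cov < SPECIFIC_ELEMENT_COVER):
            continue
        # target-side images of the two flanks must be near-contiguous
        left_img_end = right_img_start = None
        for h in region.hits:
            for (q0, q1), (t0, t1) in zip(h.query_blocks, h.target_blocks):
                if q0 < es:  # block touches the left flank
                    left_img_end = t1 if left_img_end is None else max(left_img_end, t1)
                if q1 > ee:  # block touches the right flank
                    right_img_start = t0 if right_img_start is None else min(right_img_start, t0)
        if left_img_end is None or right_img_start is None:
            continue
        if right_img_start - left_img_end < LOCUS_MERGE_BP:
            return "specific_absent"
    return "unresolved"


def classify_locus(query: OrthoQuery,
                   regions_per_species: dict[str, list[LocusRegion]]) -> OrthoLocus:
    """Combine per-species statuses into the locus classification."""
    statuses = {sp: _species_status(query, regions)
                for sp, regions in sorted(regions_per_species.items())}
    values = list(statuses.values())
    if values and all(v == "shared" for v in values):
        cls = "shared"
    elif values and all(v == "specific_absent" for v in values):
        cls = "species_specific"
    else:
        cls = "ambiguous"
    copies = 1 + sum(v == "shared" for v in values)
    return OrthoLocus(locus_id=query.locus_id,
                      reference_species=query.reference_species,
                      reference_interval=query.element_interval,
                      per_species_status=statuses, classification=cls,
                      copies=copies)


def classify_loci(queries: list[OrthoQuery],
                  target_genomes: dict[str, list[Contig]],
                  evalue_max: float = 1e-9,
                  min_identity: float = 0.8) -> list[OrthoLocus]:
    """Classify every query against every non-reference genome.

    Loci whose element is recovered everywhere come out shared and are
    thereby excluded from the specific-site call of the remaining loci, so
    no site is counted twice.
    """
    out = []
    for q in queries:
        regions = {sp: search_homologs(q, genome, evalue_max, min_identity)
                   for sp, genome in target_genomes.items()
                   if sp != q.reference_species}
        out.append(classify_locus(q, regions))
    return out


def polymorphism_matrix(loci: list[OrthoLocus], species: list[str],
                        tree_newick: str | None = None):
    """Presence/absence matrix and, with a tree, per-node insertion counts.

    The matrix row order follows ``loci``; a locus is present in its
    reference species and in every target species with shared status. When a
    Newick tree (branch lengths in My) is given, each locus maps to the most
    recent common ancestor of the species possessing it, and per-node counts
    are also expressed per My of the node's stem branch.

    Returns (DataFrame, node_table DataFrame or None).
    """
    rows = {}
    for locus in loci:
        presence = {}
        for sp in species:
            if sp == locus.reference_species:
                presence[sp] = 1
            else:
                presence[sp] = int(locus.per_species_status.get(sp) == "shared")
        rows[locus.locus_id] = presence
    matrix = pd.DataFrame.from_dict(rows, orient="index")[species]

    if tree_newick is None:
        return matrix, None
    import dendropy

    tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    tree.is_rooted = True
    labels = {t.label for t in tree.taxon_namespace}
    missing = set(species) - labels
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    node_counts: dict[int, dict] = {}
    for locus_id, presence in rows.items():
        present = [sp for sp, v in presence.items() if v]
        taxa = [t for t in tree.taxon_namespace if t.label in present]
        node = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
            tree.find_node_with_taxon_label(present[0])
        key = id(node)
        if key not in node_counts:
            leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
            stem = node.edge.length if node.edge.length else np.nan
            node_counts[key] = {"node": "+".join(leaves), "stem_my": stem,
                                "loci": 0}
        node_counts[key]["loci"] += 1
    table = pd.DataFrame(sorted(node_counts.values(),
                                key=lambda r: r["node"]))
    table["loci_per_my"] = table["loci"] / table["stem_my"]
    return matrix, table
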