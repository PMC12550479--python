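"""Gene-context assignment of MITE hits and binned flank densities.

Every hit is represented by the midpoint of its interval and assigned with
precedence exon > intron > flank > intergenic. Flanks extend 5000 bp from
the gene boundary and are subdivided into 500 bp bins (bin 0 adjacent to
the gene); upstream/downstream are strand-aware, i.e. upstream is 5' of the
gene on its own strand. The midpoint rule sidesteps boundary-straddling
ambiguity; ``mode="any-overlap"`` instead assigns by the best-precedence
region the interval touches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import GeneModel, MITEHit

FLANK_BP = 5000
BIN_BP = 500
N_BINS = FLANK_BP // BIN_BP
# "promoter" for gene grouping: upstream bins 0-3 (0-2000 bp)
PROMOTER_BINS = (0, 1, 2, 3)

REGIONS = ("exon", "intron", "upstream", "downstream", "intergenic")
_PRECEDENCE = {"exon": 0, "intron": 1, "upstream": 2, "downstream": 2,
               "intergenic": 3}


@dataclass
class RegionAssignment:
    hit_id: str
    region: str                 # exon | intron | upstream | downstream | intergenic
    gene_id: str | None
    distance_to_gene: int       # bp; 0 iff genic
    bin_index: int | None       # in [0, 9] iff flank region

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        flank = self.region in ("upstream", "downstream")
        if flank != (self.bin_index is not None):
            raise ValueError("bin_index set iff region is a flank")
        if flank and self.bin_index < 0:
            raise ValueError("bin_index out of range")
        if (self.distance_to_gene == 0) != (self.region in ("exon", "intron")):
            raise ValueError("distance 0 iff genic")


def _classify_point(pos: int, gene: GeneModel, flank_bp: int):
    """(region, distance) of a single position relative to one gene.

    Distance is 0 inside the gene, else 1 for the base immediately flanking
    the boundary, counting outward. Returns None beyond the flank.
    """
    gs, ge = gene.interval.start, gene.interval.end
    if gs <= pos < ge:
        for ex in gene.exons:
            if ex.start <= pos < ex.end:
                return "exon", 0
        return "intron", 0
    if pos < gs:
        dist = gs - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - ge + 1
        side = "downstream" if gene.strand == "+" else "upstream"
    if dist >= flank_bp:
        return None
    return side, dist


def _assign_point(hit_id: str, pos: int, contig_id: str,
                  genes: list[GeneModel], flank_bp: int,
                  bin_bp: int) -> RegionAssignment:
    best = None  # (precedence, distance, is_downstream, gene_index, region, gene)
    for gi, gene in enumerate(genes):
        if gene.interval.contig_id != contig_id:
            continue
        res = _classify_point(pos, gene, flank_bp)
        if res is None:
            continue
        region, dist = res
        # nearer boundary wins among flank candidates; tie -> upstream side
        key = (_PRECEDENCE[region], dist, region == "downstream", gi)
        if best is None or key < best[0]:
            best = (key, region, dist, gene)
    if best is None:
        return RegionAssignment(hit_id, "intergenic", None, -1, None)
    _, region, dist, gene = best
    bin_index = dist // bin_bp if region in ("upstream", "downstream") else None
    return RegionAssignment(hit_id, region, gene.gene_id, dist, bin_index)


def assign_regions(hits: list[MITEHit], genes: list[GeneModel],
                   mode: str = "midpoint", flank_bp: int = FLANK_BP,
                   bin_bp: int = BIN_BP) -> list[RegionAssignment]:
    """Region class of every hit relative to the gene models.

    ``mode="midpoint"`` (default) classifies the interval midpoint;
    ``mode="any-overlap"`` classifies every base of the interval and keeps
    the highest-precedence result (nearest gene within precedence).
    """
    if flank_bp <= 0 or bin_bp <= 0 or flank_bp % bin_bp:
        raise ValueError("flank_bp must be a positive multiple of bin_bp")
    if mode not in ("midpoint", "any-overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for h in hits:
        iv = h.interval
        if mode == "midpoint":
            mid = (iv.start + iv.end - 1) // 2
            out.append(_assign_point(h.hit_id, mid, iv.contig_id,
                                     genes, flank_bp, bin_bp))
        else:
            best = None
            for pos in (iv.start, (iv.start + iv.end - 1) // 2, iv.end - 1):
                a = _assign_point(h.hit_id, pos, iv.contig_id,
                                  genes, flank_bp, bin_bp)
                key = (_PRECEDENCE[a.region], a.distance_to_gene)
                if best is None or key < best[0]:
                    best = (key, a)
            out.append(best[1])
    return out


def binned_density(assignments: list[RegionAssignment],
                   normalize: bool = False, flank_bp: int = FLANK_BP,
                   bin_bp: int = BIN_BP) -> dict:
    """Counts per region class and per flank bin.

    With ``normalize``, counts are divided by the number of assigned hits
    and by the bin width in kb, yielding unit densities whose between-bin
    ratios equal those of the raw counts.
    """
    n_bins = flank_bp // bin_bp
    region_counts = {r: 0 for r in REGIONS}
    upstream = [0] * n_bins
    downstream = [0] * n_bins
    for a in assignments:
        region_counts[a.region] += 1
        if a.region == "upstream":
            upstream[a.bin_index] += 1
        elif a.region == "downstream":
            downstream[a.bin_index] += 1
    if not normalize:
        return {"regions": region_counts, "upstream_bins": upstream,
                "downstream_bins": downstream}
    total = max(1, len(assignments))
    scale = 1.0 / (total * (bin_bp / 1000.0))
    return {"regions": {r: c / total for r, c in region_counts.items()},
            "upstream_bins": [c * scale for c in upstream],
            "downstream_bins": [c * scale for c in downstream]}


def group_genes_by_insertion(assignments: list[RegionAssignment],
                             genes: list[GeneModel]) -> dict:
    """Gene id sets with a MITE in the promoter, intron or downstream region.

    Promoter means upstream bins 0-3 (0-2000 bp). Each region also gets a
    complement set (genes without such an insertion); sets may overlap
    across regions.
    """
    all_ids = {g.gene_id for g in genes}
    groups = {"promoter": set(), "intron": set(), "downstream": set(),
              "exon": set()}
    for a in assignments:
        if a.gene_id is None:
            continue
        if a.region == "upstream" and a.bin_index in PROMOTER_BINS:
            groups["promoter"].add(a.gene_id)
        elif a.region in groups:
            groups[a.region].add(a.gene_id)
    out = {}
    for region, ids in groups.items():
        out[region] = ids
        out[f"no_{region}"] = all_ids - ids
    return out
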