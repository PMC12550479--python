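import pytest

from mitekit.genes import (RegionAssignment, assign_regions, binned_density,
                           group_genes_by_insertion)
from mitekit.model import GeneModel, GenomicInterval, MITEHit


def _gene(gid, s, e, strand="+", exons=None, cid="c1"):
    exons = exons or [(s, e)]
    return GeneModel(gene_id=gid, interval=GenomicInterval(cid, s, e, strand),
                     exons=[GenomicInterval(cid, a, b, strand)
                            for a, b in exons], strand=strand)


def _hit(hid, s, e, cid="c1"):
    return MITEHit(hit_id=hid, family_id="F", superfamily="hAT",
                   interval=GenomicInterval(cid, s, e, "."),
                   identity_to_seed=1.0, kimura_divergence=0.0,
                   full_length=True, score=10.0)


GENE = _gene("g1", 20_000, 24_000,
             exons=[(20_000, 21_000), (23_000, 24_000)])


def _one(hit, genes=(GENE,), **kw):
    (a,) = assign_regions([hit], list(genes), **kw)
    return a


def test_assignment_invariants():
    with pytest.raises(ValueError):
        RegionAssignment("h", "promoter", None, 1, None)
    with pytest.raises(ValueError):
        RegionAssignment("h", "upstream", "g", 5, None)   # flank needs bin
    with pytest.raises(ValueError):
        RegionAssignment("h", "exon", "g", 3, None)       # genic => dist 0


def test_exon_intron_midpoint():
    assert _one(_hit("h", 20_400, 20_600)).region == "exon"
    a = _one(_hit("h", 21_900, 22_100))
    assert a.region == "intron" and a.distance_to_gene == 0
    assert a.gene_id == "g1"


def test_flank_distance_and_bins():
    # midpoint 19_999: 1 bp upstream of a + gene -> bin 0
    a = _one(_hit("h", 19_949, 20_050))
    assert (a.region, a.bin_index, a.distance_to_gene) == ("upstream", 0, 1)
    # midpoint 700 bp out -> bin 1
    b = _one(_hit("h", 19_250, 19_350))
    assert (b.region, b.bin_index) == ("upstream", 1)
    # 6000 bp out -> beyond the 5 kb flank -> intergenic
    c = _one(_hit("h", 13_950, 14_050))
    assert c.region == "intergenic" and c.gene_id is None
    assert c.distance_to_gene == -1 and c.bin_index is None


def test_strand_mirror_property():
    minus = _gene("g1", 20_000, 24_000, strand="-",
                  exons=[(20_000, 21_000), (23_000, 24_000)])
    left = _hit("h", 19_949, 20_050)     # left of the gene
    right = _hit("h", 24_050, 24_150)    # right of the gene
    assert _one(left).region == "upstream"
    assert _one(left, genes=[minus]).region == "downstream"
    assert _one(right).region == "downstream"
    assert _one(right, genes=[minus]).region == "upstream"


def test_downstream_distance_one_based():
    a = _one(_hit("h", 23_950, 24_051))   # midpoint 24_000, first base out
    assert (a.region, a.distance_to_gene, a.bin_index) == ("downstream", 1, 0)


def test_precedence_exon_over_flank():
    g2 = _gene("g2", 20_500, 26_000)      # overlaps g1's exon region
    a = _one(_hit("h", 20_400, 20_600), genes=[GENE, g2])
    assert a.region == "exon" and a.gene_id == "g1"


def test_tie_prefers_upstream():
    # midpoint equidistant: 1 bp upstream of g2 and 1 bp downstream of g1
    g1 = _gene("g1", 10_000, 12_000)
    g2 = _gene("g2", 12_001, 14_000)
    a = _one(_hit("h", 12_000, 12_002), genes=[g1, g2])  # midpoint 12_000
    assert a.region == "upstream" and a.gene_id == "g2"


def test_any_overlap_mode():
    # straddles the exon boundary; midpoint is upstream, an end is exonic
    h = _hit("h", 19_900, 20_020)
    assert _one(h).region == "upstream"
    assert _one(h, mode="any-overlap").region == "exon"
    with pytest.raises(ValueError):
        assign_regions([h], [GENE], mode="nearest")
    with pytest.raises(ValueError):
        assign_regions([h], [GENE], flank_bp=5000, bin_bp=300)


def test_binned_density_counts_and_normalization():
    hits = [_hit("a", 19_949, 20_050), _hit("b", 19_250, 19_350),
            _hit("c", 20_400, 20_600), _hit("d", 100, 200)]
    asn = assign_regions(hits, [GENE])
    d = binned_density(asn)
    assert d["regions"]["exon"] == 1
    assert d["regions"]["intergenic"] == 1
    assert d["upstream_bins"][0] == 1 and d["upstream_bins"][1] == 1
    n = binned_density(asn, normalize=True)
    assert n["upstream_bins"][0] == pytest.approx(n["upstream_bins"][1])
    assert n["regions"]["exon"] == pytest.approx(0.25)


def test_group_genes_by_insertion():
    g2 = _gene("g2", 60_000, 62_000)
    hits = [_hit("a", 19_949, 20_050),    # upstream bin 0 -> promoter of g1
            _hit("b", 21_900, 22_100),    # intron of g1
            _hit("c", 15_400, 15_500)]    # upstream bin 9 -> not promoter
    asn = assign_regions(hits, [GENE, g2])
    groups = group_genes_by_insertion(asn, [GENE, g2])
    assert groups["promoter"] == {"g1"}
    assert groups["intron"] == {"g1"}
    assert groups["no_promoter"] == {"g2"}
    assert groups["exon"] == set()
    assert groups["no_exon"] == {"g1", "g2"}
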