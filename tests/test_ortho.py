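import numpy as np
import pytest

from mitekit.model import Contig, GenomicInterval
from mitekit.ortho import (OrthoLocus, build_query, classify_loci,
                           classify_locus, polymorphism_matrix,
                           search_homologs)
from mitekit.simulate import mutate_k80
from tests.conftest import make_element, random_background

RNG = np.random.default_rng(42)
BG = random_background(RNG, 12_000)
ELEM = make_element(RNG, 300, 14)
INS = 6000


def _ref_genome():
    seq = BG[:INS] + "TA" + ELEM + "TA" + BG[INS:]
    return [Contig(id="chr1", sequence=seq)], GenomicInterval(
        "chr1", INS + 2, INS + 2 + len(ELEM), ".")


def _target(present: bool, flank_k: float = 0.02, seed: int = 0):
    rng = np.random.default_rng(seed)
    bg = mutate_k80(BG, flank_k, 2.0, rng)
    if present:
        seq = bg[:INS] + "TA" + mutate_k80(ELEM, 0.02, 2.0, rng) + "TA" + bg[INS:]
    else:
        seq = bg
    return [Contig(id="chr1", sequence=seq)]


def test_build_query_flank_truncation():
    genome, iv = _ref_genome()
    q = build_query(iv, genome, flank_len=1000, locus_id="L1")
    assert (q.left_flank_len, q.right_flank_len) == (1000, 1000)
    assert q.element_span == (1000, 1000 + 300)
    near_start = GenomicInterval("chr1", 100, 400, ".")
    q2 = build_query(near_start, genome, flank_len=1000)
    assert q2.left_flank_len == 100
    with pytest.raises(ValueError):
        build_query(iv, genome, flank_len=0)


def test_search_homologs_finds_the_locus():
    genome, iv = _ref_genome()
    q = build_query(iv, genome, flank_len=1000, locus_id="L1",
                    reference_species="ref")
    regions = search_homologs(q, _target(True, seed=1))
    assert len(regions) == 1
    r = regions[0]
    assert r.start <= INS and r.end >= INS + 304
    cov = r.query_coverage_intervals()
    covered = sum(e - s for s, e in cov)
    assert covered >= 0.95 * len(q.query_seq)


@pytest.mark.parametrize("presences,expected", [
    ((True, True), "shared"),
    ((False, False), "species_specific"),
    ((True, False), "ambiguous"),
])
def test_classify_loci_combinations(presences, expected):
    genome, iv = _ref_genome()
    q = build_query(iv, genome, flank_len=1000, locus_id="L1",
                    reference_species="ref")
    targets = {f"sp{i + 1}": _target(p, seed=i + 2)
               for i, p in enumerate(presences)}
    (locus,) = classify_loci([q], targets)
    assert locus.classification == expected
    want = ["shared" if p else "specific_absent" for p in presences]
    assert [locus.per_species_status[f"sp{i + 1}"] for i in range(2)] == want
    assert locus.copies == 1 + sum(presences)


def test_diverged_flanks_become_unresolved():
    """Status degrades to unresolved, not to a wrong call, as flanks decay."""
    genome, iv = _ref_genome()
    q = build_query(iv, genome, flank_len=1000, locus_id="L1",
                    reference_species="ref")
    (locus,) = classify_loci([q], {"spX": _target(False, flank_k=0.60,
                                                  seed=9)})
    assert locus.per_species_status["spX"] == "unresolved"
    assert locus.classification == "ambiguous"


def _locus(lid, ref, statuses, cls):
    return OrthoLocus(locus_id=lid, reference_species=ref,
                      reference_interval=GenomicInterval("chr1", 0, 100, "."),
                      per_species_status=statuses, classification=cls,
                      copies=1 + sum(v == "shared" for v in statuses.values()))


def test_polymorphism_matrix_and_tree_nodes():
    species = ["sp1", "sp2", "sp3"]
    loci = [
        _locus("L1", "sp1", {"sp2": "shared", "sp3": "shared"}, "shared"),
        _locus("L2", "sp1", {"sp2": "shared", "sp3": "specific_absent"},
               "ambiguous"),
        _locus("L3", "sp2", {"sp1": "specific_absent",
                             "sp3": "specific_absent"}, "species_specific"),
    ]
    tree = "((sp1:1.0,sp2:1.0):2.0,sp3:3.0);"
    matrix, nodes = polymorphism_matrix(loci, species, tree)
    assert matrix.loc["L1"].tolist() == [1, 1, 1]
    assert matrix.loc["L2"].tolist() == [1, 1, 0]
    assert matrix.loc["L3"].tolist() == [0, 1, 0]
    by_node = dict(zip(nodes["node"], nodes["loci"]))
    assert by_node["sp1+sp2"] == 1          # L2 -> MRCA(sp1, sp2)
    assert by_node["sp1+sp2+sp3"] == 1      # L1 -> root
    assert by_node["sp2"] == 1              # L3 -> leaf
    row = nodes[nodes["node"] == "sp1+sp2"].iloc[0]
    assert row["loci_per_my"] == pytest.approx(1 / 2.0)


def test_polymorphism_matrix_missing_species_error():
    loci = [_locus("L1", "sp1", {"sp2": "shared"}, "shared")]
    with pytest.raises(ValueError, match="missing"):
        polymorphism_matrix(loci, ["sp1", "sp2"], "(sp1:1,spZ:1);")


def test_scenario_round_trip():
    """Generator truth agrees with the classifier on a seeded scenario."""
    from mitekit.simulate import SimulationSpec, generate_ortholog_scenario
    spec = SimulationSpec(seed=7, genome_length=40_000, n_families=2)
    genomes, truth = generate_ortholog_scenario(spec, n_species=2,
                                                shared_fraction=0.5,
                                                n_loci=4)
    refs = [r for r in truth.records if r.species_id == "sp1"]
    queries = [build_query(r.interval, genomes["sp1"], flank_len=1000,
                           locus_id=r.locus_id, reference_species="sp1")
               for r in refs]
    loci = classify_loci(queries, genomes)
    want = {r.locus_id: ("shared" if r.locus_class == "shared"
                         else "species_specific") for r in refs}
    got = {l.locus_id: l.classification for l in loci}
    assert got == want
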