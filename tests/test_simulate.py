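import numpy as np
import pytest

from mitekit.model import revcomp
from mitekit.simulate import (ConstantAge, MixtureAge, SimulationSpec,
                              UniformAge, draw_tsd, family_masters,
                              generate_gene_models, generate_genome,
                              generate_mirna_set, generate_ortholog_scenario,
                              mutate_k80, random_dna)

SMALL = dict(genome_length=120_000, n_families=4, copies_per_family=6)


def test_spec_validation():
    with pytest.raises(ValueError):
        SimulationSpec(gc_content=0.0)
    with pytest.raises(ValueError):
        SimulationSpec(genome_length=0)
    with pytest.raises(ValueError):
        SimulationSpec(superfamily_mix={"hAT": 0.5})
    with pytest.raises(ValueError):
        SimulationSpec(kappa=-1)


def test_age_models():
    rng = np.random.default_rng(0)
    assert np.all(ConstantAge(0.07).draw(rng, 5) == 0.07)
    u = UniformAge(0.1, 0.2).draw(rng, 1000)
    assert u.min() >= 0.1 and u.max() <= 0.2
    m = MixtureAge([(1.0, ConstantAge(0.03))]).draw(rng, 10)
    assert np.all(m == 0.03)


def test_mutate_k80_zero_and_n():
    rng = np.random.default_rng(1)
    assert mutate_k80("ACGTACGT", 0.0, 2.0, rng) == "ACGTACGT"
    out = mutate_k80("N" * 50, 0.5, 2.0, rng)
    assert out == "N" * 50


def test_mutate_k80_divergence_calibrated():
    """Observed p-distance matches the K80 expectation within 2%."""
    rng = np.random.default_rng(2)
    n = 200_000
    seq = random_dna(rng, n)
    k, kappa = 0.15, 2.0
    out = mutate_k80(seq, k, kappa, rng)
    diffs = sum(a != b for a, b in zip(seq, out))
    a_t = k * kappa / (kappa + 2)
    b_t = k / (kappa + 2)
    p = 0.25 + 0.25 * np.exp(-4 * b_t) - 0.5 * np.exp(-2 * (a_t + b_t))
    q = 0.5 - 0.5 * np.exp(-4 * b_t)
    assert diffs / n == pytest.approx(p + q, abs=0.02)


def test_draw_tsd_signatures():
    rng = np.random.default_rng(3)
    for _ in range(20):
        assert draw_tsd("Tc1/Mariner", rng) == "TA"
        assert draw_tsd("Micron", rng) == "TA"
        assert draw_tsd("PIF/Harbinger", rng) in ("TAA", "TTA")
        assert len(draw_tsd("hAT", rng)) == 8
        assert len(draw_tsd("Mutator", rng)) in (9, 10)
        assert len(draw_tsd("CACTA", rng)) in (2, 3)
    with pytest.raises(ValueError):
        draw_tsd("LINE", rng)


def test_generate_genome_deterministic():
    spec = SimulationSpec(seed=5, **SMALL)
    g1, t1 = generate_genome(spec)
    g2, t2 = generate_genome(SimulationSpec(seed=5, **SMALL))
    assert [c.sequence for c in g1] == [c.sequence for c in g2]
    assert t1.records == t2.records


def test_generate_genome_truth_is_exact():
    """At K=0 the sequence under each truth interval IS the family master,
    with the recorded TSD duplicated immediately outside it."""
    spec = SimulationSpec(seed=8, age_model=ConstantAge(0.0), **SMALL)
    contigs, truth = generate_genome(spec)
    masters = {m.family_id: m for m in family_masters(spec)}
    seqs = {c.id: c.sequence for c in contigs}
    assert len(truth.records) == spec.n_families * spec.copies_per_family
    for r in truth.records:
        s = seqs[r.interval.contig_id]
        elem = s[r.interval.start:r.interval.end]
        assert elem == masters[r.family_id].element
        t = len(r.tsd_seq)
        assert s[r.interval.start - t:r.interval.start] == r.tsd_seq
        assert s[r.interval.end:r.interval.end + t] == r.tsd_seq
        w = r.tir_length
        assert elem[-w:] == revcomp(elem[:w])


def test_generate_genome_micron_context():
    spec = SimulationSpec(seed=4, n_families=3, copies_per_family=4,
                          genome_length=80_000, age_model=ConstantAge(0.0),
                          superfamily_mix={"Micron": 1.0})
    contigs, truth = generate_genome(spec)
    s = contigs[0].sequence
    for r in truth.records:
        left = s[r.interval.start - 14:r.interval.start - 2]
        assert left == "TA" * 6   # microsatellite run outside the TSD


def test_generate_genome_min_gap_respected():
    spec = SimulationSpec(seed=9, **SMALL)
    _, truth = generate_genome(spec)
    recs = truth.records
    for a, b in zip(recs, recs[1:]):
        if a.interval.contig_id == b.interval.contig_id:
            assert b.interval.start - a.interval.end >= 0


def test_ortholog_scenario_counts_and_presence():
    spec = SimulationSpec(seed=7, genome_length=120_000, n_families=3)
    genomes, truth = generate_ortholog_scenario(spec, n_species=3,
                                                shared_fraction=0.3,
                                                n_loci=20)
    assert set(genomes) == {"sp1", "sp2", "sp3"}
    by_locus = {}
    for r in truth.records:
        by_locus.setdefault(r.locus_id, []).append(r)
    shared = [l for l, rs in by_locus.items()
              if rs[0].locus_class == "shared"]
    specific = [l for l, rs in by_locus.items()
                if rs[0].locus_class == "specific"]
    assert len(shared) == round(0.3 * 20)
    assert len(shared) + len(specific) == 20
    for l in shared:
        assert {r.species_id for r in by_locus[l]} == {"sp1", "sp2", "sp3"}
    for l in specific:
        assert len(by_locus[l]) == 1


def test_ortholog_scenario_rejects_bad_args():
    spec = SimulationSpec(seed=7, genome_length=120_000)
    with pytest.raises(ValueError):
        generate_ortholog_scenario(spec, n_species=1)
    with pytest.raises(ValueError):
        generate_ortholog_scenario(spec, shared_fraction=1.5)


def test_gene_models_well_formed():
    spec = SimulationSpec(seed=6, **SMALL)
    contigs, _ = generate_genome(spec)
    genes = generate_gene_models(contigs, 8, seed=6)
    assert len(genes) == 8
    lengths = {c.id: c.length for c in contigs}
    prev_end = {}
    for g in genes:
        assert 0 <= g.interval.start < g.interval.end <= lengths[g.interval.contig_id]
        assert g.interval.start >= prev_end.get(g.interval.contig_id, 0)
        prev_end[g.interval.contig_id] = g.interval.end
        for e in g.exons:
            assert g.interval.start <= e.start < e.end <= g.interval.end


def test_mirna_set_labels_and_homology():
    spec = SimulationSpec(seed=3, age_model=ConstantAge(0.0), **SMALL)
    contigs, truth = generate_genome(spec)
    pres, labels = generate_mirna_set(contigs, truth, n_from_mite=5,
                                      n_background=4, seed=3)
    assert sum(labels.values()) == 5
    assert len(labels) == 9
    seqs = {c.id: c.sequence for c in contigs}
    by_fam = {}
    for r in truth.records:
        by_fam.setdefault(r.family_id, r)
    for p in pres:
        if labels[p.mirna_id]:
            r = by_fam[p.family_name]
            elem = seqs[r.interval.contig_id][r.interval.start:r.interval.end]
            # derived precursor differs from its source by ~5% of sites
            assert any(sum(a != b for a, b in
                           zip(p.sequence, elem[o:o + len(p.sequence)]))
                       <= 0.12 * len(p.sequence)
                       for o in range(len(elem) - len(p.sequence) + 1))
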