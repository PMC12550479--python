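import numpy as np
import pytest

from mitekit.detect import (DetectionParams, detect_genome,
                            find_tir_candidates, resolve_overlaps,
                            validate_candidate)
from mitekit.model import Contig, revcomp
from tests.conftest import make_element, plant, random_background


def test_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(mite_min_len=900)
    with pytest.raises(ValueError):
        DetectionParams(tsd_min_len=11)
    with pytest.raises(ValueError):
        DetectionParams(tir_min_len=4)
    with pytest.raises(ValueError):
        DetectionParams(tir_min_len=30, mite_min_len=50)
    with pytest.raises(ValueError):
        DetectionParams(tir_max_mismatch_frac=1.5)


def test_constructed_element_detected_exactly(rng):
    """TSD "TA" + 14 bp TIR + internal + TIR' + "TA" -> one candidate."""
    bg = random_background(rng, 1000)
    elem = make_element(rng, length=200, tir_len=14)
    seq, s = plant(bg, 400, elem, "TA")
    cands = find_tir_candidates(Contig(id="c1", sequence=seq))
    assert len(cands) == 1
    c = cands[0]
    assert (c.interval.start, c.interval.end) == (s, s + 200)
    assert c.tsd_seq == "TA"
    assert c.tir_length >= 14
    assert c.sequence == elem


def test_validate_candidate_requires_tsd(rng):
    bg = random_background(rng, 500)
    elem = make_element(rng, length=120, tir_len=14)
    # element inserted with no TSD at all
    seq = bg[:200] + elem + bg[200:]
    assert validate_candidate(seq, 200, 200 + 120, DetectionParams()) is None


def test_validate_candidate_rejects_n_in_tir(rng):
    bg = random_background(rng, 500)
    elem = make_element(rng, length=120, tir_len=14)
    broken = "N" + elem[1:]
    seq, s = plant(bg, 200, broken, "TAGC")
    assert validate_candidate(seq, s, s + 120, DetectionParams()) is None


def test_tir_mismatch_tolerance(rng):
    bg = random_background(rng, 600)
    tir = "GAAGGAGGTAGAAGGAGTAG"       # 20 bp, A/G-only: no self-RC inside
    internal = random_background(np.random.default_rng(2), 160)
    elem = tir + internal + revcomp(tir)
    # corrupt one base of the RIGHT TIR beyond the exact 12-mer core
    pos = len(elem) - 15             # inside TIR, outside outer 12-mer
    orig = elem[pos]
    sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[orig]
    elem2 = elem[:pos] + sub + elem[pos + 1:]
    seq, s = plant(bg, 300, elem2, "TCA")
    (c,) = find_tir_candidates(Contig(id="c", sequence=seq))
    assert (c.interval.start, c.interval.end) == (s, s + len(elem2))
    assert c.tir_mismatches >= 1
    assert c.tir_length >= 20


def test_length_bounds_respected(rng):
    bg = random_background(rng, 400)
    short = make_element(rng, length=40, tir_len=14)   # below 50
    seq, _ = plant(bg, 150, short, "TA")
    assert find_tir_candidates(Contig(id="c", sequence=seq)) == []


def test_no_spurious_candidates_in_background():
    """False-positive property: < 1 spurious candidate per 100 kb."""
    rng = np.random.default_rng(2024)
    total = 0
    for chunk in range(3):
        bg = random_background(rng, 100_000)
        total += len(find_tir_candidates(Contig(id="c", sequence=bg)))
    assert total / 3 < 1.0


def test_recall_on_pristine_planted_elements():
    """>= 99% of planted K=0 elements recovered with exact boundaries."""
    from mitekit.simulate import ConstantAge, SimulationSpec, generate_genome
    spec = SimulationSpec(genome_length=300_000, n_families=5,
                          copies_per_family=10, age_model=ConstantAge(0.0),
                          seed=99)
    genome, truth = generate_genome(spec)
    cands = detect_genome(genome)
    found = {(c.interval.start, c.interval.end) for c in cands}
    n_exact = sum((r.interval.start, r.interval.end) in found
                  for r in truth.records)
    assert n_exact / len(truth.records) >= 0.99


def test_recall_monotone_in_divergence():
    """Recall never increases as planted divergence grows."""
    from mitekit.simulate import ConstantAge, SimulationSpec, generate_genome
    recalls = []
    for k in (0.0, 0.05, 0.15):
        spec = SimulationSpec(genome_length=200_000, n_families=4,
                              copies_per_family=10, age_model=ConstantAge(k),
                              seed=77)
        genome, truth = generate_genome(spec)
        cands = detect_genome(genome)
        hit = 0
        for r in truth.records:
            if any(c.interval.overlap(r.interval)
                   > 0.8 * r.interval.length for c in cands):
                hit += 1
        recalls.append(hit / len(truth.records))
    assert recalls[0] >= recalls[1] >= recalls[2]


def test_resolve_overlaps_keeps_best(rng):
    from tests.conftest import candidate
    a = candidate(100, 300, tir=20, tsd="TATG")   # score 24
    b = candidate(110, 310, tir=14, tsd="GC")     # score 16, >50% overlap
    kept = resolve_overlaps([b, a])
    assert kept == [a]


def test_resolve_overlaps_prefers_signature_tsd(rng):
    """A TA TSD beats a higher-scoring arbitrary TSD on the same locus."""
    from tests.conftest import candidate
    true = candidate(100, 300, tir=20, tsd="TA")      # score 22, signature
    shifted = candidate(99, 301, tir=21, tsd="ATG")   # score 24, arbitrary
    assert resolve_overlaps([shifted, true]) == [true]


def test_resolve_overlaps_keeps_distinct(rng):
    from tests.conftest import candidate
    a = candidate(100, 300)
    b = candidate(600, 800)
    assert resolve_overlaps([b, a]) == [a, b]


def test_detection_order_invariance(rng):
    bg = random_background(rng, 2000)
    e1 = make_element(rng, 150, 14)
    e2 = make_element(rng, 200, 16)
    seq, _ = plant(bg, 300, e1, "TA")
    seq, _ = plant(seq, 1200, e2, "TAACCGGT")
    cands = find_tir_candidates(Contig(id="c", sequence=seq))
    assert len(cands) == 2
    assert cands == sorted(cands, key=lambda c: c.interval.start)
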