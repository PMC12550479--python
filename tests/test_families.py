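import itertools

import numpy as np
import pytest

from mitekit.families import (ClusterParams, build_families, cluster,
                              flank_distinctness_filter, merge_annotation_sets,
                              select_seed)
from mitekit.model import Contig, MITEFamily
from mitekit.simulate import mutate_k80
from tests.conftest import candidate, make_element, random_background


def test_params_validation():
    with pytest.raises(ValueError):
        ClusterParams(identity_threshold=0.0)
    with pytest.raises(ValueError):
        ClusterParams(flank_identity_collapse=1.5)


def _copies(rng, master, n, k, start=0, spacing=1000, cid="c1"):
    out = []
    for i in range(n):
        s = start + i * spacing
        seq = mutate_k80(master, k, 2.0, rng)
        out.append(candidate(s, s + len(master), seq=seq, cid=cid))
    return out


def test_cluster_groups_by_identity(rng):
    a = make_element(rng, 200, 14)
    b = make_element(rng, 200, 14)
    cands = _copies(rng, a, 4, 0.03) + _copies(rng, b, 3, 0.03, start=8000)
    fams, singles = cluster(cands)
    assert len(fams) == 2 and not singles
    sizes = sorted(len(f.members) for f in fams)
    assert sizes == [3, 4]


def test_cluster_min_copies_dissolves(rng):
    a = make_element(rng, 200, 14)
    cands = _copies(rng, a, 2, 0.0)
    fams, singles = cluster(cands)
    assert fams == [] and len(singles) == 2


def test_cluster_partition_order_invariant(rng):
    a = make_element(rng, 180, 14)
    b = make_element(rng, 220, 14)
    cands = _copies(rng, a, 3, 0.05) + _copies(rng, b, 3, 0.05, start=9000)

    def partition(order):
        fams, singles = cluster(list(order))
        return sorted(frozenset(m.interval.start for m in f.members)
                      for f in fams), sorted(s.interval.start
                                             for s in singles)

    base = partition(cands)
    for perm in itertools.islice(itertools.permutations(cands), 0, 24, 5):
        assert partition(perm) == base


def test_flank_collapse_merges_duplicated_locus(rng):
    bg = random_background(rng, 2000)
    elem = make_element(rng, 150, 14)
    # same element at two distinct loci plus a duplicate record of locus 1
    seq = bg[:300] + elem + bg[300:1200] + elem + bg[1200:]
    genome = [Contig(id="c1", sequence=seq)]
    m1 = candidate(300, 450, seq=elem, tir=16)
    m1_dup = candidate(300, 450, seq=elem, tir=14)
    m2 = candidate(150 + 1200, 150 + 1350, seq=elem)
    fam = MITEFamily(family_id="F", members=[m1, m1_dup, m2])
    out = flank_distinctness_filter(fam, genome)
    starts = sorted(m.interval.start for m in out.members)
    assert starts == [300, 1350]
    assert any(m.interval.start == 300 and m.tir_length == 16
               for m in out.members)   # higher score wins the collapse


def test_merge_annotation_sets_prefers_better_boundaries():
    a = [candidate(100, 300, tir=20, tsd="TAAT")]
    b = [candidate(105, 305, tir=14, tsd="TA"), candidate(900, 1100)]
    out = merge_annotation_sets(a, b)
    assert len(out) == 2
    assert out[0].tir_length == 20
    assert out[1].interval.start == 900


def test_merge_annotation_sets_tolerance():
    a = [candidate(100, 300)]
    b = [candidate(250, 450)]   # starts differ by 150 >= tolerance
    out = merge_annotation_sets(a, b, tolerance=100)
    assert [c.interval.start for c in out] == [100, 250]


def test_select_seed_completeness_key(rng):
    elem = make_element(rng, 150, 14)
    worse = candidate(0, 150, seq=elem, tsd="TA", tir=14)
    better = candidate(1000, 1150, seq=elem, tsd="TAGCTAGC", tir=14)
    fam = MITEFamily(family_id="F", members=[worse, better])
    assert select_seed(fam) is better
    with pytest.raises(ValueError):
        select_seed(MITEFamily(family_id="E", members=[]))


def test_select_seed_tie_breaks_by_centrality(rng):
    master = make_element(rng, 200, 14)
    outlier = mutate_k80(master, 0.15, 2.0, np.random.default_rng(1))
    central = [candidate(i * 1000, i * 1000 + 200, seq=master)
               for i in range(2)]
    far = candidate(5000, 5200, seq=outlier)
    fam = MITEFamily(family_id="F", members=[far] + central)
    seed = select_seed(fam)
    assert seed.sequence == master


def test_build_families_end_to_end(rng):
    master = make_element(rng, 200, 14)
    bg = random_background(rng, 12_000)
    cands, pieces, prev = [], [], 0
    rng2 = np.random.default_rng(7)
    points = [1000, 3000, 5000, 7000, 9000]
    offset = 0
    for p in points:
        copy = mutate_k80(master, 0.03, 2.0, rng2)
        pieces.append(bg[prev:p])
        s = p + offset + 2
        cands.append(candidate(s, s + 200, seq=copy))
        pieces.append("TA" + copy + "TA")
        offset += 204
        prev = p
    pieces.append(bg[prev:])
    genome = [Contig(id="c1", sequence="".join(pieces))]
    fams, singles = build_families(cands, genome)
    assert len(fams) == 1 and not singles
    assert len(fams[0].members) == 5
    assert fams[0].seed in fams[0].members
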