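import numpy as np
import pytest

from mitekit.model import Contig, GenomicInterval, MITECandidate, revcomp


def make_element(rng, length=200, tir_len=14):
    """A clean MITE element: perfect TIRs around a random internal region."""
    bases = "ACGT"
    tir = "".join(bases[i] for i in rng.integers(0, 4, tir_len))
    internal = "".join(bases[i] for i in rng.integers(0, 4,
                                                      length - 2 * tir_len))
    return tir + internal + revcomp(tir)


def plant(background: str, pos: int, element: str, tsd: str) -> tuple[str, int]:
    """Insert tsd+element+tsd at pos; returns (sequence, element_start)."""
    seq = background[:pos] + tsd + element + tsd + background[pos:]
    return seq, pos + len(tsd)


def random_background(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_contig(rng):
    """3 kb contig with two planted elements of the same family."""
    bg = random_background(rng, 3000)
    elem = make_element(rng, length=180, tir_len=14)
    seq, s1 = plant(bg, 500, elem, "TA")
    seq, s2 = plant(seq, 2000 + len(elem) + 4, elem, "TA")
    return Contig(id="c1", sequence=seq), [(s1, s1 + len(elem)),
                                           (s2, s2 + len(elem))]


def interval(s, e, cid="c1", strand="."):
    return GenomicInterval(cid, s, e, strand)


def candidate(s, e, seq="", tsd="TA", tir=14, mm=0, cid="c1"):
    return MITECandidate(interval=GenomicInterval(cid, s, e, "."),
                         tir_length=tir, tir_mismatches=mm, tsd_seq=tsd,
                         sequence=seq)
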