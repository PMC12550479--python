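"""MITE-derived miRNA identification and hairpin-stability comparison.

A miRNA precursor is called MITE-derived when a local alignment against a
MITE sequence passes E-value < 1e-5, identity > 0.8, and covers at least
half of the precursor's length (U is normalised to T before aligning).

Hairpin stability is scored with a deterministic maximum-weight nested
pairing (Nussinov-style dynamic program) with pair energies GC = -3,
AU = -2, GU = -1 and a minimum hairpin loop of three unpaired bases; the
optimum total is the ``mfe`` and ``nmfe = mfe / length``. This is a proxy
for thermodynamic folding — internally consistent but not comparable to
nearest-neighbour energies — and ``fold_energy`` accepts an external folder
callable for users who have one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .align import karlin_altschul_evalue, make_aligner

_LINK_ALIGNER = make_aligner("local", 2.0, -3.0, -5.0, -2.0)

PAIR_ENERGY = {("G", "C"): -3.0, ("C", "G"): -3.0,
               ("A", "T"): -2.0, ("T", "A"): -2.0,
               ("G", "T"): -1.0, ("T", "G"): -1.0}
MIN_LOOP = 3

EVALUE_MAX = 1e-5
IDENTITY_MIN = 0.8
COVERAGE_MIN = 0.5


@dataclass
class MiRNAPrecursor:
    mirna_id: str
    family_name: str
    sequence: str       # RNA or DNA; U is treated as T

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"empty precursor {self.mirna_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MiteMirnaLink:
    mirna_id: str
    element_id: str
    identity: float
    coverage: float     # aligned precursor residues / precursor length
    e_value: float
    score: float
    superfamily: str = ""


def link_mirnas(precursors: list[MiRNAPrecursor], mites,
                evalue_max: float = EVALUE_MAX,
                min_identity: float = IDENTITY_MIN,
                min_coverage: float = COVERAGE_MIN) -> list[MiteMirnaLink]:
    """Links between precursors and MITEs passing all three thresholds.

    ``mites`` is a list of (element_id, superfamily, sequence). Identity
    must exceed ``min_identity`` strictly; coverage of at least
    ``min_coverage`` (inclusive) of the precursor length counts. A precursor
    may link several MITEs; any MITE with a link is a MITE-miRNA.
    """
    from .align import alignment_stats

    n_total = sum(len(s) for _, _, s in mites)
    links: list[MiteMirnaLink] = []
    for pre in precursors:
        m = pre.length
        for element_id, superfamily, seq in mites:
            seq = seq.upper().replace("U", "T")
            alns = _LINK_ALIGNER.align(seq, pre.sequence)
            if len(alns) == 0 or alns.score <= 0:
                continue
            aln = alns[0]
            st = alignment_stats(aln, pre.sequence, seq)
            coverage = (st.query_end - st.query_start) / m
            ev = karlin_altschul_evalue(aln.score, m, n_total)
            if (ev < evalue_max and st.aligned_identity > min_identity
                    and coverage >= min_coverage):
                links.append(MiteMirnaLink(
                    mirna_id=pre.mirna_id, element_id=element_id,
                    identity=st.aligned_identity, coverage=coverage,
                    e_value=ev, score=aln.score, superfamily=superfamily))
    return links


def mite_mirna_ids(links: list[MiteMirnaLink]) -> set[str]:
    """Precursor ids with at least one link (the MITE-miRNAs)."""
    return {l.mirna_id for l in links}


@dataclass
class FoldEnergy:
    mfe: float
    nmfe: float         # mfe / length
    length: int


def fold_energy(sequence: str, folder=None) -> FoldEnergy:
    """Minimum pairing energy of the sequence and its length-normalised form.

    ``folder``, when given, is a callable sequence -> mfe replacing the
    built-in nested-pairing dynamic program (e.g. a thermodynamic folder).
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    if folder is not None:
        mfe = float(folder(seq))
        return FoldEnergy(mfe=mfe, nmfe=mfe / len(seq), length=len(seq))
    n = len(seq)
    # E[i][j] = minimum energy of seq[i..j] under nested pairing
    E = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                e = PAIR_ENERGY.get((seq[i], seq[k]))
                if e is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                rest = E[k + 1][j] if k + 1 <= j else 0.0
                cand = e + inner + rest
                if cand < best:
                    best = cand
            E[i][j] = best
    mfe = float(E[0][n - 1]) if n > 1 else 0.0
    return FoldEnergy(mfe=mfe, nmfe=mfe / n, length=n)


@dataclass
class NMFEComparison:
    median_mite: float
    median_other: float
    n_mite: int
    n_other: int
    u_statistic: float
    p_value: float      # nan when either group has fewer than 3 members


def compare_nmfe(mite_nmfe, other_nmfe) -> NMFEComparison:
    """Mann-Whitney U comparison of NMFE between MITE- and non-MITE-miRNAs.

    Uses the normal approximation with tie correction (two-sided). The
    p-value is reported as nan when either group has fewer than three
    values, where the approximation is meaningless.
    """
    a = np.asarray(list(mite_nmfe), dtype=float)
    b = np.asarray(list(other_nmfe), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a = float(np.median(a))
    med_b = float(np.median(b))
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="asymptotic")
    p = float(res.pvalue) if min(a.size, b.size) >= 3 else float("nan")
    return NMFEComparison(median_mite=med_a, median_other=med_b,
                          n_mite=int(a.size), n_other=int(b.size),
                          u_statistic=float(res.statistic), p_value=p)
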