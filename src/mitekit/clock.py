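"""Insertion dating: consensus construction and K80 distances.

Each copy of a family is compared with the family consensus; the Kimura
two-parameter distance K (transitions P and transversions Q estimated
separately) converts to an insertion age through T = K / (2r), where r is
the host's substitution rate per site per year. The consensus stands in for
the element's state at insertion, so K measures the substitutions
accumulated since then.

The multiple alignment is a deterministic center-star around the family
seed: every member is globally aligned to the seed and the pairwise
alignments are merged on seed coordinates. For substitution-dominated MITE
families this is adequate and dependency-free; an externally computed
alignment can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import numpy as np

from .align import PURINES, make_aligner

# Gap open -5 / extend -2: a k-column deletion+insertion pair then costs
# 4k + 6, always worse than the k mismatches (cost k) it could replace, so
# the aligner never hides substitution runs behind spurious indels — which
# would bias K (and therefore T = K/2r) low for old, diverged families.
_MSA_ALIGNER = make_aligner("global", 1.0, -1.0, -5.0, -2.0)
_ACGT = set("ACGT")


@dataclass
class K2PDistance:
    """Kimura 1980 two-parameter distance between two aligned sequences."""

    P: float          # transition proportion
    Q: float          # transversion proportion
    K: float          # substitutions per site (nan when saturated)
    valid: bool
    sites: int = 0


def k2p_from_counts(transitions: int, transversions: int,
                    sites: int) -> K2PDistance:
    if sites <= 0:
        return K2PDistance(0.0, 0.0, float("nan"), False, 0)
    P = transitions / sites
    Q = transversions / sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0 or b <= 0:
        return K2PDistance(P, Q, float("nan"), False, sites)
    K = -0.5 * log(a * sqrt(b))
    return K2PDistance(P, Q, K, True, sites)


def k2p(seq_a: str, seq_b: str) -> K2PDistance:
    """K80 distance over columns where both symbols are A/C/G/T."""
    if len(seq_a) != len(seq_b):
        raise ValueError("k2p requires equal-length aligned strings")
    ts = tv = sites = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _ACGT or b not in _ACGT:
            continue
        sites += 1
        if a != b:
            if (a in PURINES) == (b in PURINES):
                ts += 1
            else:
                tv += 1
    return k2p_from_counts(ts, tv, sites)


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class FamilyAlignment:
    """Gap-padded rows (one per input sequence) plus the aligned seed row."""

    rows: list[str]
    seed_row: str

    @property
    def n_columns(self) -> int:
        return len(self.seed_row)


def _pairwise_profile(seed: str, member: str):
    """(aligned_char per seed position, insertions before each position)."""
    aln = _MSA_ALIGNER.align(seed, member)[0]
    tblocks, qblocks = aln.aligned  # target=seed, query=member
    chars = ["-"] * len(seed)
    inserts = [""] * (len(seed) + 1)
    prev_q = 0
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if q0 > prev_q:  # member residues not aligned to seed: insertion
            inserts[t0] += member[prev_q:q0]
        for t, q in zip(range(t0, t1), range(q0, q1)):
            chars[t] = member[q]
        prev_q = q1
    if prev_q < len(member):
        inserts[len(seed)] += member[prev_q:]
    return chars, inserts


def family_alignment(members: list[str], seed: str) -> FamilyAlignment:
    """Center-star alignment of ``members`` around ``seed``.

    Rows come back in input order; the seed itself need not be a member.
    A single member aligns trivially against the seed.
    """
    if not members:
        raise ValueError("no sequences to align")
    profiles = [_pairwise_profile(seed, m) for m in members]
    slot_len = [0] * (len(seed) + 1)
    for _, inserts in profiles:
        for i, ins in enumerate(inserts):
            slot_len[i] = max(slot_len[i], len(ins))

    def build_row(chars, inserts):
        parts = []
        for i in range(len(seed) + 1):
            parts.append(inserts[i].ljust(slot_len[i], "-"))
            if i < len(seed):
                parts.append(chars[i])
        return "".join(parts)

    rows = [build_row(chars, inserts) for chars, inserts in profiles]
    seed_row = build_row(list(seed), [""] * (len(seed) + 1))
    return FamilyAlignment(rows=rows, seed_row=seed_row)


def consensus(alignment: FamilyAlignment) -> str:
    """Majority-rule consensus of the alignment.

    A column contributes iff at least half of the rows have a residue there;
    residue ties go to the seed's symbol when it is among the tied residues,
    then to the lexicographically smallest.
    """
    rows = alignment.rows
    if not rows:
        raise ValueError("empty alignment")
    out = []
    n = len(rows)
    for col in range(alignment.n_columns):
        residues = [r[col] for r in rows if r[col] != "-"]
        if len(residues) * 2 < n:
            continue
        counts: dict[str, int] = {}
        for ch in residues:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        tied = sorted(ch for ch, c in counts.items() if c == best)
        seed_ch = alignment.seed_row[col]
        out.append(seed_ch if seed_ch in tied else tied[0])
    return "".join(out)


def consensus_columns(alignment: FamilyAlignment) -> list[int]:
    """Indices of the alignment columns retained by ``consensus``."""
    rows = alignment.rows
    n = len(rows)
    return [col for col in range(alignment.n_columns)
            if sum(r[col] != "-" for r in rows) * 2 >= n]


def copy_divergences(alignment: FamilyAlignment,
                     cons: str | None = None) -> list[K2PDistance]:
    """K80 distance of every row to the consensus, on retained columns."""
    cols = consensus_columns(alignment)
    if cons is None:
        cons = consensus(alignment)
    assert len(cons) == len(cols)
    out = []
    for row in alignment.rows:
        sub = "".join(row[c] for c in cols)
        out.append(k2p(sub, cons))
    return out


# ---------------------------------------------------------------------------
# insertion times
# ---------------------------------------------------------------------------

@dataclass
class InsertionEstimate:
    element_id: str
    family_id: str
    K: float
    r: float
    T: float          # years


def insertion_times(distances, r: float, element_ids=None,
                    family_id: str = ""):
    """T = K/(2r) for each valid distance.

    Saturated (invalid) distances are excluded, not clamped — clamping would
    fabricate ancient insertions. Returns (estimates, n_invalid).
    """
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if element_ids is None:
        element_ids = [f"copy{i + 1}" for i in range(len(distances))]
    estimates = []
    invalid = 0
    for eid, d in zip(element_ids, distances):
        k = d.K if isinstance(d, K2PDistance) else float(d)
        ok = d.valid if isinstance(d, K2PDistance) else np.isfinite(k)
        if not ok:
            invalid += 1
            continue
        estimates.append(InsertionEstimate(element_id=eid, family_id=family_id,
                                           K=k, r=r, T=k / (2.0 * r)))
    return estimates, invalid


def amplification_histogram(estimates, bin_width: float):
    """Counts and fractions of insertion ages in [i*w, (i+1)*w) bins.

    Returns (bin_edges, counts, fractions); empty input gives empty arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = np.array([e.T for e in estimates], dtype=float)
    if ages.size == 0:
        return np.array([0.0]), np.array([], dtype=int), np.array([])
    n_bins = int(ages.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ages, bins=edges)
    return edges, counts, counts / counts.sum()


def date_family(members: list[str], seed: str, r: float,
                element_ids=None, family_id: str = "",
                max_consensus_members: int = 500, seed_rng: int = 0):
    """Full dating of one family: MSA, consensus, per-copy K and T.

    Families larger than ``max_consensus_members`` are subsampled (seeded)
    for the consensus step only; every member is still dated.

    Returns (consensus_string, estimates, n_invalid).
    """
    aln = family_alignment(members, seed)
    if len(members) > max_consensus_members:
        rng = np.random.default_rng([seed_rng, 41])
        idx = sorted(rng.choice(len(members), max_consensus_members,
                                replace=False).tolist())
        sub = FamilyAlignment(rows=[aln.rows[i] for i in idx],
                              seed_row=aln.seed_row)
        cols = consensus_columns(sub)
        cons = consensus(sub)
        dists = []
        for row in aln.rows:
            s = "".join(row[c] for c in cols)
            dists.append(k2p(s, cons))
    else:
        cons = consensus(aln)
        dists = copy_divergences(aln, cons)
    estimates, invalid = insertion_times(dists, r, element_ids, family_id)
    return cons, estimates, invalid
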