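"""Pairwise alignment utilities shared by clustering, scanning and linkage.

Global alignments (family clustering, consensus building) and local
alignments (genome scan, ortholog search, miRNA linkage) are delegated to
``Bio.Align.PairwiseAligner``; this module adds the identity definition used
for clustering (matching columns over all alignment columns, terminal gaps
included), transition/transversion bookkeeping for Kimura distances, k-mer
seeding of local searches, and Karlin-Altschul E-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log

import numpy as np
from Bio import Align

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

# Classical ungapped nucleotide Karlin-Altschul parameters for +2/-3 scoring.
KA_LAMBDA = 0.625
KA_K = 0.41


def make_aligner(mode: str, match: float, mismatch: float,
                 open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


# Path-choice scoring for the clustering identity (flat gap -2).
_CLUSTER_ALIGNER = make_aligner("global", 1.0, -1.0, -2.0, -2.0)


@dataclass
class AlignmentStats:
    """Column bookkeeping of one pairwise alignment."""

    matches: int
    mismatches: int
    transitions: int
    transversions: int
    gap_columns: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_identity(self) -> float:
        """Identity over residue-residue columns only (BLAST-style)."""
        n = self.matches + self.mismatches
        return self.matches / n if n else 0.0


def alignment_stats(aln, query: str, target: str) -> AlignmentStats:
    """Count matched/mismatched/gapped columns of a biopython Alignment.

    For local alignments the gap count covers internal gaps of the aligned
    region only; for global alignments it includes terminal gaps, which is
    exactly the iddef-1 identity denominator.
    """
    tblocks, qblocks = aln.aligned
    matches = mismatches = transitions = transversions = 0
    gap_cols = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t is not None:
            gap_cols += (t0 - prev_t) + (q0 - prev_q)
        for a, b in zip(target[t0:t1], query[q0:q1]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
                if (a in PURINES) == (b in PURINES):
                    transitions += 1
                else:
                    transversions += 1
        prev_t, prev_q = t1, q1
    t_start = int(tblocks[0][0]) if len(tblocks) else 0
    t_end = int(tblocks[-1][1]) if len(tblocks) else 0
    q_start = int(qblocks[0][0]) if len(qblocks) else 0
    q_end = int(qblocks[-1][1]) if len(qblocks) else 0
    return AlignmentStats(matches, mismatches, transitions, transversions,
                          gap_cols, q_start, q_end, t_start, t_end,
                          float(aln.score))


def global_identity(a: str, b: str) -> float:
    """iddef-1 identity: matching columns / all columns incl. terminal gaps."""
    if not a or not b:
        return 0.0
    aln = _CLUSTER_ALIGNER.align(a, b)[0]
    stats = alignment_stats(aln, b, a)
    # add terminal gaps to the denominator
    head = stats.target_start + stats.query_start
    tail = (len(a) - stats.target_end) + (len(b) - stats.query_end)
    cols = stats.columns + head + tail
    return stats.matches / cols if cols else 0.0


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = KA_LAMBDA, kk: float = KA_K) -> float:
    """E = K * m * n * exp(-lambda * S), guarded against overflow."""
    x = log(kk) + log(max(m, 1)) + log(max(n, 1)) - lam * score
    if x > 700:
        return float("inf")
    return exp(x)


def evalue_score_threshold(evalue: float, m: int, n: int,
                           lam: float = KA_LAMBDA, kk: float = KA_K) -> float:
    """Smallest score S with E(S) <= evalue."""
    return (log(kk) + log(max(m, 1)) + log(max(n, 1)) - log(evalue)) / lam


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains N."""
    b = encode(seq)
    if len(b) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    codes[win.min(axis=1) < 0] = -1
    return codes


class KmerIndex:
    """Sorted-array index of the k-mers of one sequence."""

    def __init__(self, seq: str, k: int):
        self.k = k
        codes = kmer_codes(seq, k)
        valid = np.flatnonzero(codes >= 0)
        order = np.argsort(codes[valid], kind="stable")
        self.codes = codes[valid][order]
        self.positions = valid[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.positions[lo:hi]

    def lookup_many(self, query_codes: np.ndarray):
        """Yield (query_pos, target_positions) for query k-mers present."""
        for qpos, code in enumerate(query_codes):
            if code < 0:
                continue
            hits = self.lookup(int(code))
            if hits.size:
                yield qpos, hits


def seed_windows(index: KmerIndex, query: str, pad: int = 100,
                 anchor_merge: int = 100,
                 min_anchors: int = 1) -> list[tuple[int, int]]:
    """Candidate target windows for a local search of ``query``.

    Anchors (target_pos - query_pos, the implied alignment start) are
    clustered; each cluster becomes a window padded on both sides. Overlapping
    windows are merged. Clusters with fewer than ``min_anchors`` anchors are
    dropped — chance k-mer collisions give isolated anchors, real homology
    gives runs of them.
    """
    qcodes = kmer_codes(query, index.k)
    anchors: list[int] = []
    for qpos, tpos in index.lookup_many(qcodes):
        anchors.extend((tpos - qpos).tolist())
    if not anchors:
        return []
    anchors.sort()
    qlen = len(query)
    windows: list[list[int]] = []
    group_start = prev = anchors[0]
    group_n = 1
    for a in anchors[1:]:
        if a - prev > anchor_merge:
            if group_n >= min_anchors:
                windows.append([group_start - pad, prev + qlen + pad])
            group_start = a
            group_n = 0
        prev = a
        group_n += 1
    if group_n >= min_anchors:
        windows.append([group_start - pad, prev + qlen + pad])
    if not windows:
        return []
    merged: list[list[int]] = []
    for s, e in windows:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(max(0, s), e) for s, e in merged]


@dataclass
class LocalHit:
    """One local alignment of a query against a target sequence."""

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    score: float
    stats: AlignmentStats
    strand: str = "+"
    query_blocks: list = None
    target_blocks: list = None


def local_search(query: str, target: str, index: KmerIndex,
                 aligner: Align.PairwiseAligner, min_score: float,
                 pad: int = 100, seed_query: str | None = None,
                 min_anchors: int = 1) -> list[LocalHit]:
    """k-mer seeded local alignment of query against target (one strand).

    Each seeded window contributes its best local alignment; sub-optimal
    repeats inside one window are found by re-searching the window with the
    best hit's target span masked, until the score drops below ``min_score``.
    ``seed_query``, when given, replaces the query for window seeding only
    (e.g. with repetitive stretches masked to N); it must have the same
    length as ``query``.
    """
    if seed_query is not None and len(seed_query) != len(query):
        raise ValueError("seed_query must have the same length as query")
    hits: list[LocalHit] = []
    for ws, we in seed_windows(index, seed_query or query, pad=pad,
                               min_anchors=min_anchors):
        we = min(we, len(target))
        sub = target[ws:we]
        _window_hits(query, sub, ws, aligner, min_score, hits)
    return hits


MAX_MASK_ROUNDS = 64


def _window_hits(query: str, sub: str, offset: int, aligner, min_score,
                 out: list[LocalHit], depth: int = 0):
    # depth caps the mask-and-research rounds, i.e. hits per window
    if len(sub) < 10 or depth >= MAX_MASK_ROUNDS:
        return
    alns = aligner.align(sub, query)
    try:
        aln = alns[0]
    except (IndexError, ValueError):
        return
    if aln.score < min_score:
        return
    stats = alignment_stats(aln, query, sub)
    tblocks, qblocks = aln.aligned
    out.append(LocalHit(
        target_start=offset + stats.target_start,
        target_end=offset + stats.target_end,
        query_start=stats.query_start,
        query_end=stats.query_end,
        score=float(aln.score),
        stats=stats,
        query_blocks=[(int(a), int(b)) for a, b in qblocks],
        target_blocks=[(offset + int(a), offset + int(b)) for a, b in tblocks],
    ))
    # mask the found span and look for additional local optima in the window
    masked = sub[:stats.target_start] + "N" * (stats.target_end - stats.target_start) \
        + sub[stats.target_end:]
    if masked != sub:
        _window_hits(query, masked, offset, aligner, min_score, out, depth + 1)
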