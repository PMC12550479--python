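"""De novo MITE candidate discovery.

A candidate is an interval [s, e) of 50-800 bp whose outermost
``tir_min_len`` bases form an exact reverse-complement pair (the terminal
inverted repeat core), whose TIR extends inward to the longest length with
mismatch fraction <= ``tir_max_mismatch_frac``, and which is flanked
immediately on both sides by an exact direct repeat of 2-10 bp (the target
site duplication). Candidates containing N in TIR or TSD are rejected.

Requiring exact TIR termini is this detector's stated sensitivity limit:
elements whose outermost core has decayed are expected to be recovered later
by the homology scan (genome_scan) once their family seed is known, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import kmer_codes, encode
from .model import Contig, GenomicInterval, MITECandidate

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DetectionParams:
    mite_min_len: int = 50
    mite_max_len: int = 800
    tsd_min_len: int = 2
    tsd_max_len: int = 10
    tir_min_len: int = 12
    tir_max_mismatch_frac: float = 0.1

    def __post_init__(self):
        if self.mite_min_len > self.mite_max_len:
            raise ValueError("mite_min_len > mite_max_len")
        if self.tsd_min_len > self.tsd_max_len:
            raise ValueError("tsd_min_len > tsd_max_len")
        if self.tir_min_len < 8:
            raise ValueError("tir_min_len must be >= 8")
        if 2 * self.tir_min_len > self.mite_min_len:
            raise ValueError("TIR cores would overlap in the shortest element")
        if not (0 <= self.tir_max_mismatch_frac < 1):
            raise ValueError("tir_max_mismatch_frac out of range")


def _rc_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Code of the reverse complement of every k-mer; -1 where N."""
    b = encode(seq)
    if len(b) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(b, k)
    powers = 4 ** np.arange(k, dtype=np.int64)  # reversed order
    codes = (3 - win) @ powers
    codes[win.min(axis=1) < 0] = -1
    return codes


def validate_candidate(seq: str, s: int, e: int,
                       params: DetectionParams) -> MITECandidate | None:
    """Apply the candidate invariants at fixed boundaries (s, e)."""
    w = params.tir_min_len
    length = e - s
    if not (params.mite_min_len <= length <= params.mite_max_len):
        return None
    core_left = seq[s:s + w]
    core_right = seq[e - w:e]
    if "N" in core_left or "N" in core_right:
        return None
    if any(_COMP.get(a) != b for a, b in zip(core_left, core_right[::-1])):
        return None
    # longest exact TSD immediately outside both TIRs
    tsd = ""
    for t in range(params.tsd_max_len, params.tsd_min_len - 1, -1):
        if s - t < 0 or e + t > len(seq):
            continue
        left = seq[s - t:s]
        if "N" not in left and left == seq[e:e + t]:
            tsd = left
            break
    if not tsd:
        return None
    # extend the TIR inward, tolerating mismatches up to the fraction bound
    max_tir = length // 2
    mismatches = 0
    best_len, best_mm = w, 0
    for L in range(w + 1, max_tir + 1):
        a = seq[s + L - 1]
        b = seq[e - L]
        if a == "N" or b == "N":
            break
        if _COMP[a] != b:
            mismatches += 1
        if mismatches / L <= params.tir_max_mismatch_frac:
            best_len, best_mm = L, mismatches
    return MITECandidate(
        interval=GenomicInterval(contig_id="", start=s, end=e, strand="."),
        tir_length=best_len, tir_mismatches=best_mm, tsd_seq=tsd,
        sequence=seq[s:e])


def find_tir_candidates(contig: Contig, params: DetectionParams | None = None,
                        resolve: bool = True) -> list[MITECandidate]:
    """All MITE candidates on one contig (overlaps resolved by default)."""
    params = params or DetectionParams()
    seq = contig.sequence
    w = params.tir_min_len
    if len(seq) < params.mite_min_len:
        return []
    codes = kmer_codes(seq, w)
    rcc = _rc_kmer_codes(seq, w)
    valid = np.flatnonzero(codes >= 0)
    order = np.argsort(codes[valid], kind="stable")
    sorted_codes = codes[valid][order]
    sorted_pos = valid[order]

    lo_off = params.mite_min_len - w
    hi_off = params.mite_max_len - w
    candidates: list[MITECandidate] = []
    present = np.isin(rcc, sorted_codes)
    for s in np.flatnonzero(present):
        code = rcc[s]
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        for p in sorted_pos[lo:hi]:
            if s + lo_off <= p <= s + hi_off:
                cand = validate_candidate(seq, int(s), int(p) + w, params)
                if cand is not None:
                    cand.interval = GenomicInterval(contig.id,
                                                    cand.interval.start,
                                                    cand.interval.end, ".")
                    candidates.append(cand)
    if resolve:
        candidates = resolve_overlaps(candidates)
    else:
        candidates.sort(key=lambda c: (c.interval.start, c.interval.end))
    return candidates


def _reciprocal_overlap(a: MITECandidate, b: MITECandidate) -> bool:
    ov = a.interval.overlap(b.interval)
    return ov > 0.5 * a.interval.length and ov > 0.5 * b.interval.length


def has_signature_tsd(cand: MITECandidate) -> bool:
    """Does the candidate's TSD match a known superfamily signature?

    TA (Tc1/Mariner, Micron), TAA/TTA (PIF/Harbinger), >= 8 bp (hAT,
    Mutator), or a 2-3 bp TSD together with a CACT[AG] TIR start (CACTA).
    Used as a boundary-correction tie-breaker: when a TSD is palindromic
    (e.g. TA) the TIR of the true element extends into it, so a boundary
    shifted outward by the shift length gains exactly that much TIR score
    and wins whenever a chance direct repeat in the flanks validates it.
    Such impostor TSDs are arbitrary short strings; the true TSD carries a
    superfamily signature, so preferring signature TSDs restores the exact
    boundary without consulting alignment evidence.
    """
    tsd = cand.tsd_seq
    if tsd == "TA" or tsd in ("TAA", "TTA") or len(tsd) >= 8:
        return True
    return len(tsd) <= 3 and cand.sequence[:5] in ("CACTA", "CACTG")


def resolve_overlaps(candidates: list[MITECandidate]) -> list[MITECandidate]:
    """Among candidates with >50% reciprocal overlap keep the best.

    Priority: superfamily-signature TSD first (see has_signature_tsd),
    then higher score, then longer TSD, then leftmost start (then shortest
    interval for full determinism). A candidate is dropped iff it
    reciprocally overlaps a kept, higher-priority candidate.
    """
    ranked = sorted(candidates,
                    key=lambda c: (not has_signature_tsd(c), -c.score,
                                   -c.tsd_len, c.interval.start,
                                   c.interval.end))
    kept: list[MITECandidate] = []
    for cand in ranked:
        if not any(_reciprocal_overlap(cand, k) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: (c.interval.contig_id, c.interval.start,
                             c.interval.end))
    return kept


def detect_genome(contigs: list[Contig],
                  params: DetectionParams | None = None) -> list[MITECandidate]:
    """Run candidate detection over every contig of a genome."""
    params = params or DetectionParams()
    out: list[MITECandidate] = []
    for contig in contigs:
        out.extend(find_tir_candidates(contig, params))
    return out
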