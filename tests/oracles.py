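"""Brute-force reference implementations used only by the test suite.

Each oracle restates a definition from first principles, without reusing
the production code paths it checks: candidate detection by O(L^2)
boundary enumeration, genome scanning by exhaustive local alignment of
whole contigs, folding by explicit enumeration of all nested pairings, and
confusion counting by per-base bitmaps.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# O(L^2) candidate enumeration
# ---------------------------------------------------------------------------

def brute_force_candidates(seq: str, params):
    """Every (start, end, tsd, tir_len, tir_mm) satisfying the definition.

    A candidate interval [s, e): length within bounds; the outermost
    ``tir_min_len`` bases an exact reverse-complement pair without N; an
    exact direct repeat of tsd_min..tsd_max bp immediately outside both
    ends (longest wins); TIR length = the largest inward extension whose
    mismatch fraction stays within the bound.
    """
    w = params.tir_min_len
    out = []
    L = len(seq)
    for s in range(L):
        for length in range(params.mite_min_len, params.mite_max_len + 1):
            e = s + length
            if e > L:
                break
            left = seq[s:s + w]
            right = seq[e - w:e]
            if "N" in left or "N" in right:
                continue
            if any(_COMP.get(left[i]) != right[w - 1 - i] for i in range(w)):
                continue
            tsd = ""
            for t in range(params.tsd_max_len, params.tsd_min_len - 1, -1):
                if s - t < 0 or e + t > L:
                    continue
                cand_tsd = seq[s - t:s]
                if "N" not in cand_tsd and cand_tsd == seq[e:e + t]:
                    tsd = cand_tsd
                    break
            if not tsd:
                continue
            # mismatch count as a function of TIR length
            best_len, best_mm = w, 0
            mm = 0
            for tl in range(w + 1, length // 2 + 1):
                a, b = seq[s + tl - 1], seq[e - tl]
                if a == "N" or b == "N":
                    break
                if _COMP[a] != b:
                    mm += 1
                if mm / tl <= params.tir_max_mismatch_frac:
                    best_len, best_mm = tl, mm
            out.append((s, e, tsd, best_len, best_mm))
    return sorted(out)


# ---------------------------------------------------------------------------
# exhaustive local-alignment scan (no k-mer seeding, no windows)
# ---------------------------------------------------------------------------

def exhaustive_scan(genome, seed_library, max_divergence=0.15,
                    min_score=50.0, full_length_coverage=0.9,
                    low_complexity_frac=0.8):
    """The genome scan with seeding replaced by whole-contig alignment.

    Mirrors scan()'s filtering, merging and conflict-resolution stages but
    finds raw local hits by aligning each query against the entire contig
    (iteratively masking found spans), so no hit can be lost to seeding.
    """
    from mitekit.align import _window_hits
    from mitekit.clock import k2p_from_counts
    from mitekit.model import Contig, GenomicInterval, MITEHit, revcomp
    from mitekit.scan import (_SCAN_ALIGNER, _dinucleotide_fraction,
                              _merge_per_family, _resolve_cross_family)

    raw = []
    counter = 0
    for contig in genome:
        for family_id, superfamily, seed in seed_library:
            for strand, query in (("+", seed), ("-", revcomp(seed))):
                found = []
                _window_hits(query, contig.sequence, 0, _SCAN_ALIGNER,
                             min_score, found)
                for hit in found:
                    st = hit.stats
                    dist = k2p_from_counts(st.transitions, st.transversions,
                                           st.matches + st.mismatches)
                    if not dist.valid or dist.K > max_divergence:
                        continue
                    if hit.target_end - hit.target_start < 50:
                        continue
                    hseq = contig.sequence[hit.target_start:hit.target_end]
                    if (superfamily != "Micron"
                            and _dinucleotide_fraction(hseq) > low_complexity_frac):
                        continue
                    qlen = len(query)
                    span = st.query_end - st.query_start
                    full = (span >= full_length_coverage * qlen
                            and st.query_start <= 5
                            and st.query_end >= qlen - 5)
                    counter += 1
                    raw.append(MITEHit(
                        hit_id=f"hit{counter}", family_id=family_id,
                        superfamily=superfamily,
                        interval=GenomicInterval(
                            contig.id, hit.target_start, hit.target_end,
                            "." if strand == "+" else "-"),
                        identity_to_seed=st.identity,
                        kimura_divergence=dist.K, full_length=full,
                        score=hit.score))
    resolved = _resolve_cross_family(_merge_per_family(raw))
    resolved.sort(key=lambda h: (h.interval.contig_id, h.interval.start,
                                 h.interval.end))
    for i, h in enumerate(resolved, start=1):
        h.hit_id = f"hit{i}"
    return resolved


# ---------------------------------------------------------------------------
# exhaustive nested-pairing enumeration
# ---------------------------------------------------------------------------

_PAIR = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "T"): -2.0,
         ("T", "A"): -2.0, ("G", "T"): -1.0, ("T", "G"): -1.0}


def enumerate_fold_min(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over ALL nested pairings of ``seq`` (<= 20 nt).

    Straight recursive enumeration: position i is either unpaired or
    paired with some admissible k; every branch is explored.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    assert n <= 20, "oracle is exponential; keep sequences short"

    def best(i: int, j: int) -> float:
        if i >= j:
            return 0.0
        # i unpaired
        energies = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            e = _PAIR.get((seq[i], seq[k]))
            if e is None:
                continue
            energies.append(e + best(i + 1, k - 1) + best(k + 1, j))
        return min(energies)

    return best(0, n - 1)


# ---------------------------------------------------------------------------
# per-base bitmap confusion counts
# ---------------------------------------------------------------------------

def bitmap_confusion(contig_lengths, predicted, reference):
    """(tp, fp, tn, fn) via explicit per-base boolean masks."""
    from mitekit.model import GenomicInterval

    def paint(intervals, masks):
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                cid, s, e = iv.contig_id, iv.start, iv.end
            else:
                cid, s, e = iv
            masks[cid][s:e] = True

    pred = {cid: np.zeros(n, dtype=bool) for cid, n in contig_lengths.items()}
    ref = {cid: np.zeros(n, dtype=bool) for cid, n in contig_lengths.items()}
    paint(predicted, pred)
    paint(reference, ref)
    tp = fp = tn = fn = 0
    for cid in contig_lengths:
        p, r = pred[cid], ref[cid]
        tp += int(np.sum(p & r))
        fp += int(np.sum(p & ~r))
        fn += int(np.sum(~p & r))
        tn += int(np.sum(~p & ~r))
    return tp, fp, tn, fn
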