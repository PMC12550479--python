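"""Nucleotide-level benchmarking of a MITE annotation against a reference.

Every base of the genome is scored TP (covered by both annotations), FP
(predicted only), FN (reference only) or TN (neither); the six standard
metrics follow. Undefined ratios (0/0) are reported as NaN, never 0.
A secondary element-level mode counts predicted/reference elements matched
by at least 80% reciprocal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

from .model import GenomicInterval, merge_intervals


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BenchmarkMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    false_positive_rate: float
    f1: float


def _by_contig(intervals) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list] = {}
    for iv in intervals:
        if isinstance(iv, GenomicInterval):
            out.setdefault(iv.contig_id, []).append((iv.start, iv.end))
        else:
            cid, s, e = iv
            out.setdefault(cid, []).append((s, e))
    return {cid: merge_intervals(ivs) for cid, ivs in out.items()}


def _overlap_bases(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap between two merged, sorted interval lists."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def confusion(contig_lengths: dict[str, int], predicted,
              reference) -> ConfusionCounts:
    """Base-level confusion counts summed over contigs.

    ``predicted`` and ``reference`` are GenomicIntervals or
    (contig_id, start, end) triples; overlaps within each set are merged
    before counting. Intervals beyond a contig end are an error.
    """
    pred = _by_contig(predicted)
    ref = _by_contig(reference)
    for name, ivs in (("predicted", pred), ("reference", ref)):
        for cid, merged in ivs.items():
            if cid not in contig_lengths:
                raise ValueError(f"{name} interval on unknown contig {cid!r}")
            if merged and merged[-1][1] > contig_lengths[cid]:
                raise ValueError(
                    f"{name} interval beyond end of contig {cid!r}")
    tp = fp = fn = 0
    for cid in contig_lengths:
        p = pred.get(cid, [])
        r = ref.get(cid, [])
        p_bases = sum(e - s for s, e in p)
        r_bases = sum(e - s for s, e in r)
        both = _overlap_bases(p, r)
        tp += both
        fp += p_bases - both
        fn += r_bases - both
    tn = sum(contig_lengths.values()) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else nan


def metrics(counts: ConfusionCounts) -> BenchmarkMetrics:
    """The six standard metrics; 0/0 ratios come out NaN."""
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    if min(counts.tp, counts.fp, counts.tn, counts.fn) < 0:
        raise ValueError("negative confusion counts")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    acc = (counts.tp + counts.tn) / counts.total
    fpr = _ratio(counts.fp, counts.fp + counts.tn)
    if prec == prec and sens == sens and prec + sens > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = nan
    return BenchmarkMetrics(sensitivity=sens, specificity=spec, accuracy=acc,
                            precision=prec, false_positive_rate=fpr, f1=f1)


def benchmark(contig_lengths: dict[str, int], predicted,
              reference) -> tuple[ConfusionCounts, BenchmarkMetrics]:
    counts = confusion(contig_lengths, predicted, reference)
    return counts, metrics(counts)


@dataclass
class ElementMatch:
    """Element-level matching at >=80% reciprocal overlap."""

    matched_predicted: int
    matched_reference: int
    n_predicted: int
    n_reference: int

    @property
    def element_precision(self) -> float:
        return _ratio(self.matched_predicted, self.n_predicted)

    @property
    def element_recall(self) -> float:
        return _ratio(self.matched_reference, self.n_reference)


def element_match(predicted, reference,
                  min_reciprocal: float = 0.8) -> ElementMatch:
    """Count elements matched by >= min_reciprocal overlap of both lengths."""
    def norm(ivs):
        out = []
        for iv in ivs:
            if isinstance(iv, GenomicInterval):
                out.append((iv.contig_id, iv.start, iv.end))
            else:
                out.append(tuple(iv))
        return out

    pred = norm(predicted)
    ref = norm(reference)

    def reciprocal(a, b) -> bool:
        if a[0] != b[0]:
            return False
        ov = min(a[2], b[2]) - max(a[1], b[1])
        if ov <= 0:
            return False
        return (ov >= min_reciprocal * (a[2] - a[1])
                and ov >= min_reciprocal * (b[2] - b[1]))

    mp = sum(any(reciprocal(p, r) for r in ref) for p in pred)
    mr = sum(any(reciprocal(r, p) for p in pred) for r in ref)
    return ElementMatch(matched_predicted=mp, matched_reference=mr,
                        n_predicted=len(pred), n_reference=len(ref))
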