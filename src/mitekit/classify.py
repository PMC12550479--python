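"""Superfamily assignment from TSD and TIR signatures.

The rule table encodes the community-standard diagnostics: a TA duplication
marks Tc1/Mariner (Stowaway-like), TAA/TTA marks PIF/Harbinger
(Tourist-like), an 8-10 bp duplication marks Mutator, 8 bp with a short TIR
marks hAT, a CACT[AG] TIR start marks CACTA, and insertion into a
(TA)n/(CA)n/(GT)n microsatellite context marks the Micron group. Micron is
context-defined rather than TSD-defined and therefore has the highest
priority. The table ships as editable YAML so curators can override it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .model import Contig, GenomicInterval, MITECandidate

MICRON_DINUCS = ("TA", "CA", "GT")


@dataclass
class SuperfamilyRule:
    name: str
    priority: int
    tsd_exact: tuple = ()
    tsd_len: tuple | None = None      # inclusive (lo, hi)
    tir_prefix: str | None = None     # regex anchored at the TIR start
    tir_len: tuple | None = None      # inclusive (lo, hi)
    micron_context: bool = False

    def matches(self, cand: MITECandidate, has_context: bool) -> bool:
        if self.micron_context and not has_context:
            return False
        if self.tsd_exact and cand.tsd_seq not in self.tsd_exact:
            return False
        if self.tsd_len is not None:
            lo, hi = self.tsd_len
            if not (lo <= cand.tsd_len <= hi):
                return False
        if self.tir_len is not None:
            lo, hi = self.tir_len
            if not (lo <= cand.tir_length <= hi):
                return False
        if self.tir_prefix is not None:
            tir = cand.sequence[:cand.tir_length]
            if not re.match(self.tir_prefix, tir):
                return False
        return True


def default_rules() -> tuple[list[SuperfamilyRule], dict]:
    text = resources.files("mitekit").joinpath("data/superfamily_rules.yaml") \
        .read_text()
    return load_rules_text(text)


def load_rules(path) -> tuple[list[SuperfamilyRule], dict]:
    with open(path) as fh:
        return load_rules_text(fh.read())


def load_rules_text(text: str):
    raw = yaml.safe_load(text)
    rules = [SuperfamilyRule(
        name=r["name"], priority=int(r["priority"]),
        tsd_exact=tuple(r.get("tsd_exact", ())),
        tsd_len=tuple(r["tsd_len"]) if "tsd_len" in r else None,
        tir_prefix=r.get("tir_prefix"),
        tir_len=tuple(r["tir_len"]) if "tir_len" in r else None,
        micron_context=bool(r.get("micron_context", False)))
        for r in raw["rules"]]
    rules.sort(key=lambda r: r.priority)
    micron_cfg = raw.get("micron", {"min_units": 5, "window": 20})
    return rules, micron_cfg


def detect_micron_context(interval: GenomicInterval, contig: Contig,
                          min_units: int = 5, window: int = 20) -> bool:
    """Is a (TA)n, (CA)n or (GT)n run adjacent to the element?

    True iff a run of at least ``min_units`` dinucleotide units lies outside
    the element and starts within ``window`` bp of either boundary.
    """
    seq = contig.sequence
    s, e = interval.start, interval.end
    span = 2 * min_units
    for d in MICRON_DINUCS:
        pattern = d * min_units
        for p in range(max(0, s - window), s - span + 1):
            if seq[p:p + span] == pattern:
                return True
        for p in range(e, min(len(seq) - span, e + window) + 1):
            if seq[p:p + span] == pattern:
                return True
    return False


def classify_superfamily(seed: MITECandidate, contig: Contig | None = None,
                         rules=None, return_reason: bool = False):
    """Label a family from its seed's TSD/TIR (and microsatellite context).

    Rules fire in priority order; the first match wins. A seed without a TSD
    is 'unknown'. ``contig`` is only needed for the Micron context rule; when
    omitted that rule is skipped.
    """
    if rules is None:
        rules, micron_cfg = default_rules()
    elif isinstance(rules, tuple):
        rules, micron_cfg = rules
    else:
        micron_cfg = {"min_units": 5, "window": 20}
    if not seed.tsd_seq:
        return ("unknown", "no_tsd") if return_reason else "unknown"
    has_context = False
    if contig is not None:
        has_context = detect_micron_context(
            seed.interval, contig, int(micron_cfg["min_units"]),
            int(micron_cfg["window"]))
    for rule in rules:
        if rule.micron_context and contig is None:
            continue
        if rule.matches(seed, has_context):
            return (rule.name, "rule") if return_reason else rule.name
    return ("unknown", "no_rule") if return_reason else "unknown"


def classify_families(families, genome, rules=None) -> None:
    """Assign ``superfamily`` in place by majority vote over the members.

    A single member's signature is fragile: detected boundaries can be
    shifted by chance flank repeats (especially around palindromic TSDs),
    which corrupts the TSD that the rules read. All members of a family
    inserted by the same machinery, so the modal label is the robust one.
    Ties go to the seed's own label when it is among the tied labels,
    otherwise to the lexicographically smallest for determinism. A family
    with no classifiable member is 'unknown'.
    """
    seqs = {c.id: c for c in genome}
    for fam in families:
        votes: dict[str, int] = {}
        for member in fam.members:
            mlabel = classify_superfamily(
                member, seqs.get(member.interval.contig_id), rules)
            if mlabel != "unknown":
                votes[mlabel] = votes.get(mlabel, 0) + 1
        if not votes:
            fam.superfamily = "unknown"
            continue
        best = max(votes.values())
        tied = sorted(n for n, c in votes.items() if c == best)
        seed_label = "unknown"
        if fam.seed is not None:
            seed_label = classify_superfamily(
                fam.seed, seqs.get(fam.seed.interval.contig_id), rules)
        fam.superfamily = seed_label if seed_label in tied else tied[0]
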