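"""Readers and writers for the formats the toolkit touches.

FASTA parsing is delegated to ``Bio.SeqIO`` and GFF3 gene models to
``gffutils``; the annotation dialects written here (GFF3 / BED / TSV) are the
toolkit's own output contracts and round-trip losslessly through their
paired readers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import Contig, GeneModel, GenomicInterval, MITECandidate, MITEHit

# Any IUPAC ambiguity code other than N is collapsed to N on input.
_AMBIG = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNT")

ANNOTATION_DIALECTS = ("gff3", "bed", "tsv")

_HIT_COLUMNS = ["hit_id", "family_id", "superfamily", "contig_id", "start",
                "end", "strand", "identity_to_seed", "kimura_divergence",
                "full_length", "score"]


class FormatError(ValueError):
    pass


def read_fasta(path) -> list[Contig]:
    """Read a multi-FASTA file into Contigs (uppercase, ambiguity -> N)."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: expected FASTA header")
            break
        else:
            raise FormatError(f"{path}: empty FASTA file (line 1)")
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().translate(_AMBIG)
        contigs.append(Contig(id=rec.id, sequence=seq))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records (line 1)")
    return contigs


def write_fasta(records, path) -> None:
    """Write Contigs or (id, sequence) pairs as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, Contig) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_gff(path, contig_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Exons are attached through their Parent chain (exon -> mRNA -> gene or
    exon -> gene); exons with no resolvable gene parent are skipped with a
    warning. Genes without exon children get a single exon spanning the gene.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    for feat in db.all_features():
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature {feat.id}: end < start")
        if contig_lengths is not None:
            clen = contig_lengths.get(feat.seqid)
            if clen is not None and feat.end > clen:
                raise FormatError(
                    f"{path}: feature {feat.id} beyond contig {feat.seqid} end")

    genes: list[GeneModel] = []
    claimed_exons: set[str] = set()
    for g in db.features_of_type("gene", order_by="start"):
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            claimed_exons.add(str(ex))
            exons.append(GenomicInterval(g.seqid, ex.start - 1, ex.end, g.strand))
        interval = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        if not exons:
            exons = [interval]
        genes.append(GeneModel(gene_id=g.id, interval=interval, exons=exons,
                               strand=g.strand))
    for ex in db.features_of_type("exon"):
        if str(ex) not in claimed_exons:
            warnings.warn(f"exon at {ex.seqid}:{ex.start}-{ex.end} has no "
                          f"resolvable gene parent; skipped")
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (used by the synthetic generator)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.contig_id}\tmitekit\tgene\t{iv.start + 1}\t{iv.end}"
                     f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, ex in enumerate(g.exons, start=1):
                fh.write(f"{iv.contig_id}\tmitekit\texon\t{ex.start + 1}\t{ex.end}"
                         f"\t.\t{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# MITE hit annotation dialects
# ---------------------------------------------------------------------------

def write_annotation(records: list[MITEHit], path, dialect: str = "gff3") -> None:
    if dialect not in ANNOTATION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of "
                         f"{ANNOTATION_DIALECTS}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for h in records:
                iv = h.interval
                attrs = (f"ID={h.hit_id};family_id={h.family_id};"
                         f"superfamily={h.superfamily};"
                         f"identity_to_seed={h.identity_to_seed!r};"
                         f"kimura_divergence={h.kimura_divergence!r};"
                         f"full_length={int(h.full_length)}")
                fh.write(f"{iv.contig_id}\tmitekit\tdispersed_repeat\t"
                         f"{iv.start + 1}\t{iv.end}\t{h.score!r}\t{iv.strand}"
                         f"\t.\t{attrs}\n")
        elif dialect == "bed":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tfamily_id\t"
                     "superfamily\tidentity_to_seed\tkimura_divergence\t"
                     "full_length\n")
            for h in records:
                iv = h.interval
                fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{h.hit_id}\t"
                         f"{h.score!r}\t{iv.strand}\t{h.family_id}\t"
                         f"{h.superfamily}\t{h.identity_to_seed!r}\t"
                         f"{h.kimura_divergence!r}\t{int(h.full_length)}\n")
        else:  # tsv
            fh.write("\t".join(_HIT_COLUMNS) + "\n")
            for h in records:
                iv = h.interval
                fh.write("\t".join([h.hit_id, h.family_id, h.superfamily,
                                    iv.contig_id, str(iv.start), str(iv.end),
                                    iv.strand, repr(h.identity_to_seed),
                                    repr(h.kimura_divergence),
                                    str(int(h.full_length)), repr(h.score)])
                         + "\n")


def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_annotation(path, dialect: str = "gff3") -> list[MITEHit]:
    if dialect not in ANNOTATION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[MITEHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "gff3":
                attrs = _parse_gff_attrs(f[8])
                hits.append(MITEHit(
                    hit_id=attrs["ID"], family_id=attrs["family_id"],
                    superfamily=attrs["superfamily"],
                    interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                    identity_to_seed=float(attrs["identity_to_seed"]),
                    kimura_divergence=float(attrs["kimura_divergence"]),
                    full_length=bool(int(attrs["full_length"])),
                    score=float(f[5])))
            elif dialect == "bed":
                hits.append(MITEHit(
                    hit_id=f[3], family_id=f[6], superfamily=f[7],
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    identity_to_seed=float(f[8]),
                    kimura_divergence=float(f[9]),
                    full_length=bool(int(f[10])), score=float(f[4])))
            else:
                if f[0] == "hit_id":  # header row
                    continue
                rec = dict(zip(_HIT_COLUMNS, f))
                hits.append(MITEHit(
                    hit_id=rec["hit_id"], family_id=rec["family_id"],
                    superfamily=rec["superfamily"],
                    interval=GenomicInterval(rec["contig_id"],
                                             int(rec["start"]),
                                             int(rec["end"]), rec["strand"]),
                    identity_to_seed=float(rec["identity_to_seed"]),
                    kimura_divergence=float(rec["kimura_divergence"]),
                    full_length=bool(int(rec["full_length"])),
                    score=float(rec["score"])))
    return hits


# ---------------------------------------------------------------------------
# Candidate and truth tables
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: list[MITECandidate], path) -> None:
    rows = [{"contig_id": c.interval.contig_id, "start": c.interval.start,
             "end": c.interval.end, "strand": c.interval.strand,
             "tir_length": c.tir_length, "tir_mismatches": c.tir_mismatches,
             "tsd_seq": c.tsd_seq, "sequence": c.sequence}
            for c in candidates]
    pd.DataFrame(rows, columns=["contig_id", "start", "end", "strand",
                                "tir_length", "tir_mismatches", "tsd_seq",
                                "sequence"]).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path) -> list[MITECandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str, "sequence": str})
    return [MITECandidate(
        interval=GenomicInterval(str(r.contig_id), int(r.start), int(r.end),
                                 str(r.strand)),
        tir_length=int(r.tir_length), tir_mismatches=int(r.tir_mismatches),
        tsd_seq=str(r.tsd_seq), sequence=str(r.sequence))
        for r in df.itertuples()]


def write_truth_tsv(truth, path) -> None:
    rows = [{"element_id": r.element_id, "family_id": r.family_id,
             "superfamily": r.superfamily, "contig_id": r.interval.contig_id,
             "start": r.interval.start, "end": r.interval.end,
             "strand": r.interval.strand, "tsd_seq": r.tsd_seq,
             "tir_length": r.tir_length, "planted_k": repr(r.planted_k),
             "species_id": r.species_id, "locus_id": r.locus_id,
             "locus_class": r.locus_class}
            for r in truth.records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path):
    from .model import TruthRecord, TruthSet
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"tsd_seq": str, "species_id": str,
                            "locus_id": str, "locus_class": str})
    records = [TruthRecord(
        element_id=str(r.element_id), family_id=str(r.family_id),
        superfamily=str(r.superfamily),
        interval=GenomicInterval(str(r.contig_id), int(r.start), int(r.end),
                                 str(r.strand)),
        tsd_seq=str(r.tsd_seq), tir_length=int(r.tir_length),
        planted_k=float(r.planted_k), species_id=str(r.species_id),
        locus_id=str(r.locus_id), locus_class=str(r.locus_class))
        for r in df.itertuples()]
    return TruthSet(records=records)


def read_rates_tsv(path) -> dict[str, float]:
    """Per-species substitution rates (substitutions/site/year).

    Two tab-separated columns: species_id, rate. Header optional.
    """
    rates: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sp, val = line.split("\t")[:2]
            try:
                rates[sp] = float(val)
            except ValueError:
                continue  # header row
    return rates


def write_families_tsv(families, path) -> None:
    """Family membership table: one row per member, seed flagged."""
    rows = []
    for fam in families:
        for cand in fam.members:
            rows.append({
                "family_id": fam.family_id, "superfamily": fam.superfamily,
                "role": "seed" if cand is fam.seed else "member",
                "contig_id": cand.interval.contig_id,
                "start": cand.interval.start, "end": cand.interval.end,
                "strand": cand.interval.strand, "tir_length": cand.tir_length,
                "tir_mismatches": cand.tir_mismatches,
                "tsd_seq": cand.tsd_seq, "sequence": cand.sequence})
    pd.DataFrame(rows, columns=["family_id", "superfamily", "role",
                                "contig_id", "start", "end", "strand",
                                "tir_length", "tir_mismatches", "tsd_seq",
                                "sequence"]).to_csv(path, sep="\t",
                                                    index=False)


def read_families_tsv(path):
    from .model import MITEFamily
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str, "sequence": str})
    families: dict[str, MITEFamily] = {}
    for r in df.itertuples():
        cand = MITECandidate(
            interval=GenomicInterval(str(r.contig_id), int(r.start),
                                     int(r.end), str(r.strand)),
            tir_length=int(r.tir_length),
            tir_mismatches=int(r.tir_mismatches),
            tsd_seq=str(r.tsd_seq), sequence=str(r.sequence))
        fam = families.setdefault(str(r.family_id), MITEFamily(
            family_id=str(r.family_id), members=[],
            superfamily=str(r.superfamily)))
        fam.members.append(cand)
        if str(r.role) == "seed":
            fam.seed = cand
    return [families[k] for k in families]
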