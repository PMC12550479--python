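"""Synthetic genomes with planted MITEs and a machine-readable truth set.

The generator plants family masters with perfect TIRs and
superfamily-consistent TSDs into i.i.d. background sequence, mutates each
copy under the K80 substitution model at a per-copy expected divergence drawn
from an age model, and records exact final coordinates. It also builds
multi-species ortholog scenarios (shared vs species-specific insertion
sites) and miRNA precursor sets with known MITE ancestry.

Substitutions are the only mutation type, matching the K80 assumptions of
the insertion-dating stage. One 64-bit seed drives everything; sub-generators
use derived streams so adding a feature does not shuffle earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Contig, GeneModel, GenomicInterval, TruthRecord, TruthSet, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# age models: per-copy expected divergence K* from the family master
# ---------------------------------------------------------------------------

@dataclass
class UniformAge:
    low: float
    high: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, n)


@dataclass
class ConstantAge:
    k: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.k)


@dataclass
class MixtureAge:
    """Weighted mixture of age components (e.g. recent burst + ancient tail)."""

    components: list

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        weights = np.array([w for w, _ in self.components])
        idx = rng.choice(len(self.components), size=n, p=weights / weights.sum())
        out = np.empty(n)
        for i, (_, comp) in enumerate(self.components):
            mask = idx == i
            out[mask] = comp.draw(rng, int(mask.sum()))
        return out


def default_age_model() -> MixtureAge:
    """A dominant recent expansion plus a smaller ancient component."""
    return MixtureAge([(0.75, UniformAge(0.0, 0.05)),
                       (0.20, UniformAge(0.08, 0.13)),
                       (0.05, UniformAge(0.13, 0.20))])


DEFAULT_SUPERFAMILY_MIX = {
    "Mutator": 0.30, "Tc1/Mariner": 0.25, "PIF/Harbinger": 0.20,
    "hAT": 0.15, "CACTA": 0.05, "Micron": 0.05,
}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic genome."""

    genome_length: int = 1_000_000      # background bp (before insertions)
    gc_content: float = 0.40
    n_contigs: int = 1
    n_families: int = 10
    copies_per_family: int = 20
    superfamily_mix: dict = field(default_factory=lambda: dict(DEFAULT_SUPERFAMILY_MIX))
    age_model: object = field(default_factory=default_age_model)
    substitution_rate: float = 1.3e-8   # substitutions/site/year
    kappa: float = 2.0                  # transition:transversion rate ratio
    seed: int = 0
    element_len_range: tuple = (120, 450)
    tir_len_range: tuple = (14, 25)
    min_gap: int = 150                  # bp of background between insertions

    def __post_init__(self):
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0,1)")
        if abs(sum(self.superfamily_mix.values()) - 1.0) > 1e-6:
            raise ValueError("superfamily_mix fractions must sum to 1")
        for name, val in [("genome_length", self.genome_length),
                          ("n_contigs", self.n_contigs)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_families < 0 or self.copies_per_family < 0:
            raise ValueError("counts must be non-negative")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]
    arr = rng.choice(_BASES, size=n, p=probs)
    return arr.tobytes().decode("ascii")


def mutate_k80(seq: str, k: float, kappa: float,
               rng: np.random.Generator) -> str:
    """Apply K80 substitutions at expected divergence ``k`` subs/site.

    Exact per-site substitution probabilities of the K80 process are used,
    so the K80 distance estimator recovers ``k`` in expectation (including
    multiple hits at the same site).
    """
    if k <= 0 or not seq:
        return seq
    alpha_t = k * kappa / (kappa + 2.0)
    beta_t = k / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * np.exp(-4 * beta_t) - 0.5 * np.exp(-2 * (alpha_t + beta_t))
    q_total = 0.5 - 0.5 * np.exp(-4 * beta_t)
    q_each = q_total / 2
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    # map A,C,G,T -> 0..3; other symbols (N) untouched
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    c = lut[codes]
    valid = c >= 0
    u = rng.random(len(codes))
    ts = valid & (u < p_ts)
    tv1 = valid & (u >= p_ts) & (u < p_ts + q_each)
    tv2 = valid & (u >= p_ts + q_each) & (u < p_ts + 2 * q_each)
    new = c.copy()
    new[ts] = c[ts] ^ 2          # A<->G, C<->T
    new[tv1] = (c[tv1] + 1) % 4  # one transversion partner
    new[tv2] = (c[tv2] + 3) % 4  # the other transversion partner
    out = codes.copy()
    out[valid] = _BASES[new[valid]]
    return out.tobytes().decode("ascii")


def draw_tsd(superfamily: str, rng: np.random.Generator) -> str:
    if superfamily in ("Tc1/Mariner", "Micron"):
        return "TA"
    if superfamily == "PIF/Harbinger":
        return str(rng.choice(["TAA", "TTA"]))
    if superfamily == "hAT":
        return random_dna(rng, 8)
    if superfamily == "Mutator":
        return random_dna(rng, int(rng.integers(9, 11)))
    if superfamily == "CACTA":
        return random_dna(rng, int(rng.integers(2, 4)))
    raise ValueError(f"unknown superfamily {superfamily!r}")


@dataclass
class _FamilyMaster:
    family_id: str
    superfamily: str
    element: str       # full master: TIR + internal + revcomp(TIR)
    tir_length: int


def _make_master(family_id: str, superfamily: str, spec: SimulationSpec,
                 rng: np.random.Generator) -> _FamilyMaster:
    lo, hi = spec.element_len_range
    length = int(rng.integers(lo, hi + 1))
    tlo, thi = spec.tir_len_range
    if superfamily == "hAT":
        thi = min(thi, 25)  # hAT TIRs stay short
    tir_len = int(rng.integers(tlo, thi + 1))
    if superfamily == "CACTA":
        tir = "CACT" + str(rng.choice(["A", "G"])) + random_dna(rng, tir_len - 5)
    else:
        tir = random_dna(rng, tir_len)
        while tir.startswith(("CACTA", "CACTG")):
            tir = random_dna(rng, tir_len)
    internal = random_dna(rng, length - 2 * tir_len, spec.gc_content)
    return _FamilyMaster(family_id, superfamily, tir + internal + revcomp(tir),
                         tir_len)


def _place_points(rng: np.random.Generator, usable_lo: int, usable_hi: int,
                  n: int, gap: int) -> list[int]:
    """n sorted insertion points in [lo, hi) separated by >= gap bp."""
    span = usable_hi - usable_lo - (n - 1) * gap if n > 1 else usable_hi - usable_lo
    if n > 0 and span < n:
        raise ValueError("genome too small to host requested copies without overlap")
    if n == 0:
        return []
    xs = np.sort(rng.choice(span, size=n, replace=False))
    return [int(usable_lo + x + i * gap) for i, x in enumerate(xs)]


def generate_genome(spec: SimulationSpec):
    """Build the genome and truth set described by ``spec``.

    Returns (contigs, truth). Planted intervals cover the element only; the
    TSD copies (and, for Micron, a (TA)n microsatellite run) sit immediately
    outside the recorded interval. Element copies and both TSD copies are
    mutated at the copy's drawn divergence.
    """
    rng_bg = _rng(spec.seed, 1)
    rng_fam = _rng(spec.seed, 2)
    rng_place = _rng(spec.seed, 3)
    rng_mut = _rng(spec.seed, 4)

    per_contig = spec.genome_length // spec.n_contigs
    backgrounds = [random_dna(rng_bg, per_contig, spec.gc_content)
                   for _ in range(spec.n_contigs)]
    contig_ids = [f"chr{i + 1}" for i in range(spec.n_contigs)]

    names = sorted(spec.superfamily_mix)
    probs = np.array([spec.superfamily_mix[n] for n in names])
    masters = []
    for f in range(spec.n_families):
        sf = str(rng_fam.choice(names, p=probs / probs.sum()))
        masters.append(_make_master(f"FAM{f + 1}", sf, spec, rng_fam))

    # assign copies to contigs, then place points per contig
    copies = []  # (family_index, copy_index, contig_index)
    for fi, master in enumerate(masters):
        ages = spec.age_model.draw(rng_mut, spec.copies_per_family)
        for ci in range(spec.copies_per_family):
            contig_idx = int(rng_place.integers(spec.n_contigs))
            copies.append((fi, ci, contig_idx, float(ages[ci])))

    margin = 200
    records: list[TruthRecord] = []
    contigs: list[Contig] = []
    for idx, (cid, bg) in enumerate(zip(contig_ids, backgrounds)):
        mine = [c for c in copies if c[2] == idx]
        points = _place_points(rng_place, margin, len(bg) - margin,
                               len(mine), spec.min_gap)
        pieces = []
        prev = 0
        offset = 0
        for (fi, ci, _, age), point in zip(mine, points):
            master = masters[fi]
            tsd = draw_tsd(master.superfamily, rng_mut)
            element = mutate_k80(master.element, age, spec.kappa, rng_mut)
            left_tsd = mutate_k80(tsd, age, spec.kappa, rng_mut)
            right_tsd = mutate_k80(tsd, age, spec.kappa, rng_mut)
            prefix = "TA" * 6 if master.superfamily == "Micron" else ""
            construct = prefix + left_tsd + element + right_tsd
            pieces.append(bg[prev:point])
            elem_start = point + offset + len(prefix) + len(left_tsd)
            records.append(TruthRecord(
                element_id=f"{master.family_id}.{ci + 1}",
                family_id=master.family_id,
                superfamily=master.superfamily,
                interval=GenomicInterval(cid, elem_start,
                                         elem_start + len(element), "."),
                tsd_seq=tsd, tir_length=master.tir_length, planted_k=age))
            pieces.append(construct)
            offset += len(construct)
            prev = point
        pieces.append(bg[prev:])
        contigs.append(Contig(id=cid, sequence="".join(pieces)))
    records.sort(key=lambda r: (r.interval.contig_id, r.interval.start))
    return contigs, TruthSet(records=records, spec=spec)


def family_masters(spec: SimulationSpec) -> list[_FamilyMaster]:
    """The master sequences generate_genome(spec) plants (same draws)."""
    rng_fam = _rng(spec.seed, 2)
    names = sorted(spec.superfamily_mix)
    probs = np.array([spec.superfamily_mix[n] for n in names])
    return [_make_master(f"FAM{f + 1}",
                         str(rng_fam.choice(names, p=probs / probs.sum())),
                         spec, rng_fam)
            for f in range(spec.n_families)]


# ---------------------------------------------------------------------------
# multi-species ortholog scenarios
# ---------------------------------------------------------------------------

def generate_ortholog_scenario(base_spec: SimulationSpec, n_species: int = 3,
                               shared_fraction: float = 0.3,
                               flank_conservation: float = 0.95,
                               n_loci: int = 20):
    """Shared vs species-specific insertion sites across related genomes.

    An ancestral background is generated once; each species' genome is that
    background mutated at divergence (1 - flank_conservation). Shared loci
    carry the element in every species; specific loci carry it in exactly one
    species and leave a contiguous empty site in the others. The number of
    shared loci is exactly round(shared_fraction * n_loci).

    Returns ({species_id: [Contig]}, TruthSet).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not (0 <= shared_fraction <= 1):
        raise ValueError("shared_fraction must be in [0, 1]")
    spec = base_spec
    rng_bg = _rng(spec.seed, 11)
    rng_loc = _rng(spec.seed, 12)
    rng_mut = _rng(spec.seed, 13)

    bg = random_dna(rng_bg, spec.genome_length, spec.gc_content)
    masters = family_masters(spec)
    flank_div = 1.0 - flank_conservation

    n_shared = round(shared_fraction * n_loci)
    shared_ids = set(rng_loc.permutation(n_loci)[:n_shared].tolist())
    points = _place_points(rng_loc, 1500, len(bg) - 1500, n_loci, 2600)
    loci = []
    for li in range(n_loci):
        master = masters[int(rng_loc.integers(len(masters)))]
        tsd = draw_tsd(master.superfamily, rng_loc)
        owner = int(rng_loc.integers(n_species))
        loci.append({"locus_id": f"L{li + 1}", "point": points[li],
                     "master": master, "tsd": tsd,
                     "cls": "shared" if li in shared_ids else "specific",
                     "owner": owner})

    species_ids = [f"sp{i + 1}" for i in range(n_species)]
    genomes: dict[str, list[Contig]] = {}
    records: list[TruthRecord] = []
    for si, sp in enumerate(species_ids):
        sp_bg = mutate_k80(bg, flank_div, spec.kappa, rng_mut)
        pieces = []
        prev = 0
        offset = 0
        for locus in loci:
            present = locus["cls"] == "shared" or locus["owner"] == si
            pieces.append(sp_bg[prev:locus["point"]])
            prev = locus["point"]
            if not present:
                continue
            element = mutate_k80(locus["master"].element, 0.01, spec.kappa,
                                 rng_mut)
            construct = locus["tsd"] + element + locus["tsd"]
            elem_start = locus["point"] + offset + len(locus["tsd"])
            records.append(TruthRecord(
                element_id=f"{locus['locus_id']}.{sp}",
                family_id=locus["master"].family_id,
                superfamily=locus["master"].superfamily,
                interval=GenomicInterval("chr1", elem_start,
                                         elem_start + len(element), "."),
                tsd_seq=locus["tsd"], tir_length=locus["master"].tir_length,
                planted_k=0.01, species_id=sp, locus_id=locus["locus_id"],
                locus_class=locus["cls"]))
            pieces.append(construct)
            offset += len(construct)
        pieces.append(sp_bg[prev:])
        genomes[sp] = [Contig(id="chr1", sequence="".join(pieces))]
    return genomes, TruthSet(records=records, spec=spec)


# ---------------------------------------------------------------------------
# gene models and miRNA precursors
# ---------------------------------------------------------------------------

def generate_gene_models(contigs: list[Contig], n_genes: int,
                         seed: int = 0) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models on the given contigs."""
    rng = _rng(seed, 21)
    genes: list[GeneModel] = []
    per_contig = max(1, n_genes // len(contigs))
    gi = 0
    for contig in contigs:
        length = contig.length
        n = per_contig if contig is not contigs[-1] else n_genes - gi
        if n <= 0:
            continue
        points = _place_points(rng, 200, length - 4200, n, 12_000)
        for p in points:
            gi += 1
            glen = int(rng.integers(1200, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            bounds = sorted(rng.choice(np.arange(100, glen - 100), size=2 * (n_exons - 1),
                                       replace=False).tolist()) if n_exons > 1 else []
            edges = [0] + bounds + [glen]
            exons = [GenomicInterval(contig.id, p + edges[2 * k], p + edges[2 * k + 1],
                                     strand)
                     for k in range(n_exons)]
            genes.append(GeneModel(gene_id=f"gene{gi}",
                                   interval=GenomicInterval(contig.id, p, p + glen,
                                                            strand),
                                   exons=exons, strand=strand))
    return genes


def generate_mirna_set(contigs: list[Contig], truth: TruthSet,
                       n_from_mite: int = 10, n_background: int = 10,
                       seed: int = 0):
    """Precursor set with known MITE ancestry.

    MITE-derived precursors are subsequences of planted elements (lightly
    mutated, 5% of sites); background precursors are random stem-loops with
    no planted homology. Returns (precursors, {mirna_id: is_mite_derived}).
    """
    from .mirna import MiRNAPrecursor

    rng = _rng(seed, 31)
    if n_from_mite > 0 and not truth.records:
        raise ValueError("truth set has no planted MITEs")
    seqs = {c.id: c.sequence for c in contigs}
    precursors: list[MiRNAPrecursor] = []
    labels: dict[str, bool] = {}
    eligible = [r for r in truth.records if r.interval.length >= 120]
    for i in range(n_from_mite):
        rec = eligible[int(rng.integers(len(eligible)))]
        elem = seqs[rec.interval.contig_id][rec.interval.start:rec.interval.end]
        plen = min(150, len(elem))
        off = int(rng.integers(0, len(elem) - plen + 1))
        seq = mutate_k80(elem[off:off + plen], 0.05, 2.0, rng)
        mid = f"mir-mite-{i + 1}"
        precursors.append(MiRNAPrecursor(mirna_id=mid, family_name=rec.family_id,
                                         sequence=seq))
        labels[mid] = True
    for i in range(n_background):
        stem = random_dna(rng, 35)
        loop = random_dna(rng, 8)
        seq = stem + loop + revcomp(stem) + random_dna(rng, 12)
        mid = f"mir-bg-{i + 1}"
        precursors.append(MiRNAPrecursor(mirna_id=mid, family_name="background",
                                         sequence=seq))
        labels[mid] = False
    return precursors, labels
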