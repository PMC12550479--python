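# mitekit

Annotation, classification, dating and comparative analysis of miniature
inverted-repeat transposable elements (MITEs) in plant genomes.

MITEs are short (50–800 bp), non-autonomous DNA transposons bounded by
terminal inverted repeats (TIRs) and flanked by a target site duplication
(TSD) created on insertion. `mitekit` implements a complete workflow around
these structural hallmarks:

- **De novo detection** — exact-TSD, near-exact-TIR structural search of raw
  genome sequence (`mitekit.detect`).
- **Family building** — greedy identity clustering of candidates into
  families with representative seeds (`mitekit.families`).
- **Superfamily classification** — a declarative, user-overridable rule
  table mapping TSD/TIR signatures to Tc1/Mariner, PIF/Harbinger, CACTA,
  hAT, Mutator and Micron (`mitekit.classify`).
- **Genome-wide scan** — k-mer-seeded local alignment of family seeds
  against both strands, with a Kimura divergence ceiling, plus landscape
  summaries (coverage, density, length) (`mitekit.scan`).
- **Insertion dating** — per-copy Kimura two-parameter distance to the
  family consensus, converted to ages with T = K/(2r)
  (`mitekit.clock`).
- **Ortholog comparison** — flank-anchored classification of each insertion
  locus as shared or species-specific across related genomes, with a
  presence/absence matrix and phylogenetic node assignment
  (`mitekit.ortho`).
- **Gene context** — assignment of insertions to exon/intron/flank/
  intergenic compartments and binned flank densities (`mitekit.genes`).
- **miRNA linkage** — identification of MITE-derived miRNA precursors by
  homology plus hairpin-energy comparison (`mitekit.mirna`).
- **Benchmarking** — nucleotide- and element-level accuracy metrics against
  a reference annotation (`mitekit.bench`).
- **Simulation** — seeded synthetic genomes with planted elements, exact
  ground truth, gene models, ortholog scenarios and labelled miRNA
  precursor sets for end-to-end validation (`mitekit.simulate`).

See [`docs/methods.md`](docs/methods.md) for the underlying models, all
default parameters and known limitations.

## Quick start (command line)

All commands are deterministic: identical inputs and seeds produce
byte-identical outputs.

```sh
# 1. A synthetic 100 kb genome with 3 planted families, 12 copies each,
#    4 gene models and 3 MITE-derived miRNA precursors
mitekit simulate --seed 17 --length 100000 --families 3 --copies 12 \
    --genes 4 --mirnas 3 --out-dir run/

# 2. Structural candidate detection
mitekit detect --genome run/genome.fa --out run/candidates.tsv

# 3. Cluster into families, pick seeds, classify superfamilies
mitekit families --candidates run/candidates.tsv --genome run/genome.fa \
    --out run/families.tsv --seeds run/seeds.fa

# 4. Genome-wide homology scan + landscape summary
mitekit scan --genome run/genome.fa --seeds run/seeds.fa \
    --out run/hits.gff3 --summary run/landscape.tsv

# 5. Accuracy against the planted truth
mitekit bench --genome run/genome.fa --pred run/hits.gff3 \
    --truth run/truth.tsv --out-prefix run/bench

# 6. Insertion ages (r = substitutions/site/year) + amplification histogram
mitekit date --families run/families.tsv --rate 1.3e-8 \
    --out-prefix run/dates

# 7. Gene-relative context of the hits
mitekit context --hits run/hits.gff3 --gff run/genes.gff3 \
    --out-prefix run/context

# 8. MITE-derived miRNA precursors
mitekit mirna --precursors run/precursors.fa --mites run/seeds.fa \
    --out run/mirna_links.tsv --energies run/mirna_nmfe.tsv
```

For cross-species locus classification:

```sh
mitekit ortho --ref speciesA.fa --hits speciesA.hits.gff3 \
    --targets speciesB.fa --targets speciesC.fa \
    --tree species.nwk --out-prefix run/ortho
```

which writes per-locus classifications (`shared`, `species_specific`,
`ambiguous`), the binary presence/absence matrix, and — when a Newick tree
with branch lengths in My is given — insertion counts and rates per tree
node.

## Quick start (Python)

```python
from mitekit.pipeline import annotate_genome
from mitekit.simulate import SimulationSpec, generate_genome

genome, truth = generate_genome(SimulationSpec(seed=17))
result = annotate_genome(genome)
for fam in result.families:
    print(fam.family_id, fam.superfamily, len(fam.members))
print(result.landscape.proportion_of_genome, "% of genome is MITE")
```

## Validation and reproduction

The repository validates itself against generated data with known ground
truth:

```sh
pytest -o addopts= -q tests/          # full suite incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Representative numbers from the acceptance run at seed 1 (1 Mb genome,
10 families × 20 copies, ages uniform in 0–0.05 substitutions/site):

| quantity | value |
| --- | --- |
| nucleotide sensitivity | 0.9987 |
| false positive rate | 0.0 |
| precision / F1 | 1.0 / 0.9994 |
| element-level recall | 1.0 |
| families recovered | 10 / 10 |
| superfamily accuracy | 0.90 |
| mean-age relative error at 1 / 5 / 20 My | 2.3% / 0.2% / 0.4% |
| ortholog locus agreement (20 loci, 3 species) | 1.0 |
| miRNA link precision / recall | 1.0 / 1.0 |

The closed-form check `K(P=0.10, Q=0.05) = 0.17018` is also asserted to
within 5·10⁻⁶.

## Repository layout

```
src/mitekit/        package modules (one per workflow stage)
src/mitekit/data/   built-in superfamily rule table (YAML)
tests/              unit tests + tests/test_acceptance.py
tests/oracles.py    brute-force reference implementations used by tests
scripts/acceptance.py   headline-metric JSON report
docs/methods.md     models, parameters, limitations
```
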