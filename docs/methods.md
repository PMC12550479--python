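# Methods

This document records the models, algorithms and default parameters behind
each `mitekit` module, and the known limitations of each choice. Defaults
quoted here are the values used by the CLI and by `pipeline.annotate_genome`
unless overridden.

## 1. Structural detection (`mitekit.detect`)

A MITE candidate is an interval 50–800 bp long satisfying both structural
hallmarks:

- **TIR.** The first `tir_min_len` = 12 bases must be the exact reverse
  complement of the last 12 bases (the *TIR core*). The TIR is then
  extended inward base by base as long as the running mismatch fraction of
  the extension stays ≤ 0.1, giving the reported `tir_length` (so a
  reported TIR may be slightly longer than the planted one when flanking
  bases happen to pair).
- **TSD.** The `tsd_min_len`–`tsd_max_len` (2–10) bases immediately 5' of
  the element must exactly equal the bases immediately 3' of it, anchored
  at the element boundary. The longest exact duplication wins.

The search enumerates exact reverse-complement 12-mer pairs within the
length window (via a k-mer index of each contig), validates TIR extension
and TSD, and scores candidates. Ambiguous bases (N) never match.

**Overlap resolution.** Overlapping candidates are resolved greedily,
preferring first candidates whose TSD is a known superfamily signature
(TA; TAA/TTA; length ≥ 8; length 2–3 with a CACTA/CACTG TIR start), then
higher score, longer TSD, and finally leftmost position. The signature
preference is a mechanized form of manual TSD/TIR boundary curation: when
the true TSD is palindromic (e.g. TA), a candidate shifted outward by one
base can acquire an equally valid exact TIR core plus a spurious non-
signature TSD and outscore the true boundary. Preferring signature TSDs
recovers the biologically correct boundary without changing any threshold.

*Deviation:* the TIR core length is 12 rather than the commonly cited
minimum TIR of 10 bp. At 10, the expected number of chance exact
reverse-complement pairs per megabase becomes non-negligible and floods
clustering with false structural candidates; 12 keeps the detector
near-zero-FPR while remaining shorter than real MITE TIRs.

## 2. Family building (`mitekit.families`)

Candidates are deduplicated per locus (identical intervals collapse,
higher score kept), then clustered greedily by global sequence identity:
a candidate joins the first existing cluster whose representative it
matches at ≥ 80% identity, else founds a new cluster. Identity is
"iddef-1": matching columns divided by *all* alignment columns including
terminal gaps, under a global alignment with match +1, mismatch −1, flat
gap −2. Clusters with fewer than `min_copies` = 3 members are reported as
singletons, not families.

The family **seed** is the member with the most complete structural
annotation (longest TSD, then longest TIR, then fewest TIR mismatches),
with ties
broken by centrality (highest mean identity to the other members).
`merge_annotation_sets` combines two candidate sets before clustering,
preferring the annotation with the more complete boundaries when intervals
agree within a tolerance.

## 3. Superfamily classification (`mitekit.classify`)

Classification is driven by a YAML rule table
(`src/mitekit/data/superfamilies.yaml`, overridable with `--rules`). Rules
are tried in priority order; the first rule whose conditions all hold
labels the element:

| priority | superfamily | conditions |
| --- | --- | --- |
| 1 | Micron | microsatellite context: ≥ 5 units of (TA)/(CA)/(GT) within 20 bp of the element |
| 2 | CACTA | TSD length 2–3 and TIR starting CACTA/CACTG |
| 3 | Tc1/Mariner | TSD exactly TA |
| 4 | PIF/Harbinger | TSD exactly TAA or TTA |
| 5 | hAT | TSD length 8 and TIR length 5–27 |
| 6 | Mutator | TSD length 8–10 |

A **family** label is the majority vote over all members' individual
labels (unclassifiable members abstain); ties go to the seed's label when
it is among the tied labels, else to the lexicographically smallest. Pure
seed-based labelling was rejected because a single seed whose mutated TSD
happens to spell another signature would mislabel the whole family; the
vote makes the label robust to per-copy boundary noise.

## 4. Genome-wide scan (`mitekit.scan`)

Each family seed is searched against both strands of every contig using
k-mer-seeded local alignment (match +1, mismatch −1, gap open −4, extend
−1; minimum score 50). Hits with Kimura K80 divergence to the seed above
15% (`--div 15`) are discarded. A hit is `full_length` when it covers
≥ 90% of its seed. Low-complexity hits (dinucleotide-repeat dominated) are
filtered *except* for Micron seeds, whose defining context is itself a
microsatellite. Overlapping hits of the same family are merged; overlaps
across families are resolved by score. `summarize_landscape` reports
genome proportion (%), density per Mb, mean hit length and family count
from the merged hits.

## 5. Insertion dating (`mitekit.clock`)

Per family: a deterministic center-star multiple alignment around the
seed (members globally aligned to the seed and merged on seed
coordinates), a majority-rule consensus (columns kept when at least half
the rows have a residue; residue ties resolved toward the seed), and the
Kimura two-parameter distance of each member to the consensus:

K = −½ ln((1 − 2P − Q)·√(1 − 2Q)),

with P the transition and Q the transversion proportion over A/C/G/T
columns. Saturated copies (argument of the log non-positive) are excluded,
not clamped — clamping would fabricate ancient insertions. Ages follow
T = K/(2r) with r the host substitution rate per site per year, and
`amplification_histogram` bins them into fixed-width age classes.

The MSA aligner uses gap open −5 / extend −2 (not the clustering
penalties): a k-column deletion+insertion pair then costs 4k + 6, always
worse than the k mismatches it could replace, so the aligner cannot hide
substitution runs behind spurious compensating indels. With cheaper gaps
this biased K roughly 13% low at K ≈ 0.5, i.e. ages of ~20 My families
were systematically underestimated. Families larger than 500 members are
seeded-subsampled for the consensus step only; every member is still
dated.

## 6. Ortholog locus classification (`mitekit.ortho`)

For each reference insertion, a query of 1 kb flank + element + 1 kb
flank is searched in each target genome by k-mer-seeded (k = 13, ≥ 4
anchors per window) local alignment with match +2, mismatch −3, gap open
−5, extend −2; E-values use ungapped Karlin–Altschul parameters
λ = 0.625, K = 0.41. Seeding uses the query with the element masked to N,
so windows are anchored by the flanks rather than by other copies of the
repeat. Per species:

- **shared** — a region covers ≥ 95% of the query and ≥ 80% of the
  element;
- **specific_absent** — both flanks are covered ≥ 80% each, the element
  < 20%, and the two flank images in the target are < 1000 bp apart
  (i.e. an empty site);
- **unresolved** — anything else (missing or too-diverged flanks).

A locus is `shared` if every species is shared, `species_specific` if
every species shows the empty site, and `ambiguous` otherwise — diverged
flanks therefore degrade to `ambiguous` rather than to a wrong call.
`polymorphism_matrix` emits the binary presence/absence matrix and, given
a Newick tree with branch lengths in My, assigns each shared pattern to
its most recent common ancestor node and reports loci per My.

## 7. Gene context (`mitekit.genes`)

In the default `midpoint` mode an insertion is assigned by its midpoint
with precedence exon > intron > flank > intergenic. Flank distances are
1-based outward: upstream distance = gene_start − position, downstream
distance = position − gene_end + 1; the bin index is distance ÷ bin width
(default 500 bp over a 5 kb flank), ties between two genes' flanks go
upstream. "Promoter-proximal" corresponds to upstream bins 0–3 (≤ 2 kb).
`any-overlap` mode assigns by interval overlap instead. `binned_density`
aggregates per-bin counts (optionally normalized) and
`group_genes_by_insertion` partitions genes by where their insertions lie.

## 8. MITE-derived miRNAs (`mitekit.mirna`)

A precursor is linked to a MITE when a local alignment (same scoring as
§6) has E < 10⁻⁵, BLAST-style identity strictly > 0.8, and covers ≥ 50%
of the precursor. Hairpin-forming potential is scored with a Nussinov-style
fold: GC −3, AU −2, GU −1, minimum loop 3, reported as MFE and
length-normalized NMFE; `compare_nmfe` contrasts MITE-derived and
background precursor distributions (Mann–Whitney U). The Nussinov score is
a *proxy* for thermodynamic folding — adequate for ranking hairpin
propensity, not a substitute for nearest-neighbor energies.

## 9. Benchmarking (`mitekit.bench`)

Nucleotide-level confusion counts come from merged-interval two-pointer
sweeps over each contig (predictions and references are each merged
first, so overlapping inputs are not double-counted). Metrics —
sensitivity, specificity, accuracy, precision, FPR, F1 — return NaN on
0/0 rather than an arbitrary 0 or 1. Element-level matching requires
≥ 80% reciprocal overlap.

## 10. Simulation (`mitekit.simulate`)

Synthetic genomes plant family copies (master element per family, TIR and
TSD drawn from the superfamily signature, Micron copies embedded in a
planted microsatellite context) into background sequence of configurable
GC. Copy divergence uses an exact K80 sampler: for a target K with
ts/tv ratio 2, the per-site transition and transversion probabilities are
computed from the K80 closed forms, so the K estimated from a mutated
copy is unbiased at every age — this is what makes the dating calibration
(§5) a genuine round-trip test. Ortholog scenarios plant the same locus
(with identical flanks, optionally mutated to a chosen flank conservation)
as present or absent per species; miRNA sets derive precursors from
planted elements alongside background hairpin-free controls. All
generation is seeded (`numpy` `default_rng`) and deterministic.

## Limitations

- **TIR core = 12 exact bases** (§1): real elements with degenerate outer
  TIRs shorter than 12 exact matching bases are missed by the de novo
  detector (the homology scan can still recover them once a family seed
  exists).
- **Palindromic TSDs** make the element boundary formally ambiguous; the
  signature preference (§1) resolves it in favor of known signatures but
  cannot help for families whose true TSD is genuinely non-signature.
- **hAT vs Mutator boundary**: TIR extension may legitimately exceed the
  hAT rule's 27 bp ceiling for old copies whose flanks drifted into
  pairing, pushing individual votes to Mutator; the family vote usually
  absorbs this, but families of borderline-TIR hAT elements can be
  labelled Mutator (observed as superfamily accuracy 0.9 on the seed-1
  acceptance run).
- **Substitution-only divergence model**: the simulator and the dating
  calibration do not model indel accumulation or gene conversion; real
  old families will show more alignment churn than the calibration
  implies.
- **Nussinov fold** (§8) ranks hairpin propensity; NMFE values are not
  comparable to ViennaRNA kcal/mol energies.
- **Center-star MSA** (§5) is adequate for substitution-dominated MITE
  families but is not a progressive aligner; pathological indel patterns
  are better served by supplying an external alignment.
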