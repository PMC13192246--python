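# Methods

This note records the model behind each module, the default parameters and
why they hold, the numerical conventions, and the limits of the synthetic
generators.

## Model and assumptions

The package assumes the marker-gene model of dot-microchromosome recovery:
dot chromosomes are gene-dense and carry genes conserved across birds, so a
protein set built from conserved dot-located orthogroups will map almost
exclusively onto dot-chromosome fragments of any reasonably complete draft
assembly, while repeat-only unplaced scaffolds collect no hits. Sorting
scaffolds by marker-hit count therefore surfaces dot fragments in a Hi-C
curation view. The model further assumes a reference species with trusted
dot-chromosome annotations (e.g. chicken chromosomes 16 and 29–37), and that
cytology (diploid counts) is the ground truth against which assembly
chromosome counts are judged.

## Marker-set construction (`markerset`)

- **Fuzzy conservation criteria** (`FuzzyCriteria`): present in ≥ 50 % of
  species, ≤ 3 copies per species. Both comparisons are inclusive. The
  defaults mirror the common "fuzzy single-copy" orthology setting (KinFin
  `--max 3 -x 0.5`): strict single-copy filtering discards most dot genes
  because tandem duplicates and annotation noise are common on gene-dense
  chromosomes.
- **Dot filter**: an orthogroup is retained when at least one member gene of
  a designated reference species lies on an annotated dot chromosome. Genes
  of non-reference species never influence the filter; a reference gene
  without a known location counts as non-dot (with a warning). A pooled gene
  that cannot be resolved to a proteome sequence is a hard error, not a
  silent drop.
- **Clustering**: CD-HIT's conventions — sequences sorted by length
  descending, each joins the first representative reached at ≥ 0.90
  identity, where identity is the maximum number of matching residues over
  all global alignments divided by the shorter length. The maximum-match
  count is computed exactly with `Bio.Align.PairwiseAligner` (match 1,
  mismatch 0, gaps 0: the optimal score *is* the maximum match count). A
  k-mer count screen skips pairs only when a proved bound shows the
  threshold is unreachable; at the default (0.90, word 5) the bound is
  vacuous, so the default behaviour is exactly the quadratic algorithm.

## Built-in translated search (`aligner`)

The built-in searcher exists so the pipeline is self-contained; it is
deliberately ungapped and intron-unaware and is validated on intron-free
fixtures. Real genomes should be mapped with a spliced aligner (miniprot,
etc.) and imported via `import_external_hits` (PAF or GFF3); everything
downstream is aligner-agnostic.

- Six-frame translation via a base-5 codon lookup (A0 C1 G2 T3 N4);
  N-containing codons translate to the unique resolved residue when all
  resolutions agree, else to `X`, matching standard ambiguous translation.
- Seeds are exact 5-mer amino-acid matches, found with a rolling base-23
  hash into a bitmask plus CSR lookup over the concatenated frames (frames
  separated by sentinels so extensions cannot cross frame boundaries).
- Seeds sharing (protein, frame, diagonal) are extended once from the
  earliest seed (numba-compiled ungapped x-drop extension, match +2,
  mismatch −1, x-drop 20); later seeds beyond the covered span extend
  separately.
- Hits scoring below `min_score` = 30 (a ~15-residue exact match) are seed
  noise and never reported. This keeps chance 5-mer hits in multi-megabase
  random sequence out of the counts.
- Per-protein top hit: ranked by score, then identity, then alignment
  length; residual ties break to the smallest (target id, target start), so
  the result is a deterministic function of the hit multiset, invariant
  under input permutation.
- **Identity filter**: hits with identity *strictly below* 0.70 are removed;
  exactly 0.70 is retained. Identity is matches / alignment columns.

## Ordering (`ordering`)

Scaffolds with ≥ 1 retained hit (and, when a cutoff is set, length ≤ cutoff)
are prioritized, sorted by hit count descending, ties by length descending,
then input order; all other scaffolds follow in input order. The recommended
cutoff is 5 Mb: dot chromosomes sit far below it, while macrochromosome
scaffolds — which occasionally catch a spurious hit from a divergent paralog
— are excluded from prioritization without losing their counts.

## Coverage and homology (`homology`)

Breadth of coverage is the covered-base count of the merged interval union
(the bedtools convention); merging joins overlapping *and* adjacent
intervals. Deltas are signed, per chromosome — curation can remove wrongly
placed content, so decreases are meaningful. Homology assignment gives each
query chromosome the reference dot chromosome with the most *merged* aligned
bases (raw sums would double-count overlapping alignments); exact ties are
left unassigned with a warning rather than broken arbitrarily.

## Karyotype statistics (`karyostats`)

Each species' diploid cytology reports are halved and summarized by their
mode; mode ties resolve to the smallest value and are flagged, and odd
counts produce half-integers that are kept exact rather than rounded. The
assembly count minus the summary is classified with a ±1 margin: difference
0 is a match, 0 < |d| ≤ 1 is within the margin (homogametic-sex assemblies
usually carry one fewer assembled chromosome), |d| ≥ 2 is discordant.
Flagged outlier reports (database errors) are dropped before summarizing.

## Synthetic generators (`synthetic`)

The draft-assembly generator emulates: reverse-translated marker genes
point-mutated to an exact amino-acid identity (default 0.85, comfortably
above the 0.70 filter while still exercising it), embedded in GC-rich spacer
(GC 0.60, dot chromosomes are GC-rich); a pericentromeric-style
tandem-repeat tail; fragmentation with cuts that avoid gene interiors;
repeat-only filler scaffolds with zero markers; macro scaffolds above the
5 Mb cutoff; and size-descending output order, as in a size-sorted draft
map. Markers per dot chromosome default to 15–67, the observed
marker-locus range on real dot chromosomes.

It does **not** emulate introns (the built-in search is intron-unaware),
real repeat families, sequencing error, assembly chimerism, or paralogy
between planted genes. Scaffold sizes are scaled down (dots 200–400 kb,
macros 5.2–6 Mb, fillers 20–60 kb) — a deliberate choice so whole-pipeline
sweeps run in seconds per replicate; the recovery property depends on the
structure (marker presence vs. absence, cutoff relations), not on absolute
scaffold size.

The orthology generator labels each orthogroup with
(`should_pass_fuzzy`, `is_dot`) from its own construction arithmetic, so
selection code is checked against construction, not against itself. The
karyotype-table generator plants the survey marginals (105 species, 62
discordant, 57 of those with fewer chromosomes) and randomizes everything
else: haploid numbers, report multiplicity, minority ±1 reports, and flagged
outliers; it is a structured stand-in for a curated literature survey, not a
real dataset.

## Numerical conventions

- Coordinates are 0-based half-open everywhere internally; GFF3 output
  converts to 1-based closed at the boundary only.
- Identity values are exact rational arithmetic on integers
  (matches / length) held as floats; classification comparisons
  (≥ 0.70, ±1 margin) happen on these exact values, and tests pin the
  boundary cases (0.70 vs 0.699).
- All generators are pure functions of their configuration and seed.

## Limitations

- The built-in aligner cannot model introns or frameshifts; on real genomes
  use an external spliced aligner.
- Greedy clustering is order-dependent by design (CD-HIT semantics), so the
  representative set depends on the length-descending order, not on a global
  optimum.
- The karyotype survey numbers describe the synthetic stand-in table; on a
  real curated survey the same code reports that table's marginals instead.
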