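# dotfinder

Find and prioritise dot-microchromosome scaffolds in draft bird genome
assemblies.

## The problem

Bird genomes typically carry around 40 chromosome pairs, but roughly a third
of them are *microchromosomes* — tiny, gene-dense, GC-rich chromosomes that
cytogenetics has known about for a century and that genome assemblies
routinely lose. The smallest of them, the "dot" chromosomes, are so small and
repeat-flanked that in a draft assembly their fragments hide among thousands
of unplaced repeat-only scaffolds, and manual Hi-C curation rarely surfaces
them. A survey across cytology-backed species shows the scale of the problem:
most chromosome-scale bird assemblies contain *fewer* chromosomes than the
karyotype predicts.

`dotfinder` attacks this with a marker-gene strategy:

1. **Marker set construction** (`dotfinder.markerset`): from multi-species
   orthology tables, select orthogroups under relaxed ("fuzzy") conservation
   criteria — present in at least half the species, at most three copies in
   any species — keep those with a member on a reference species' annotated
   dot chromosomes, pool the member proteins, and collapse redundancy with
   CD-HIT-style greedy clustering at 0.90 identity.
2. **Mapping** (`dotfinder.aligner`): map the marker proteins onto a draft
   assembly. A built-in six-frame seed-and-extend translated search makes the
   package self-contained; output from an external spliced aligner (PAF or
   GFF3) can be ingested instead. Each protein keeps its single best hit, and
   hits below 0.70 alignment identity are discarded.
3. **Reordering** (`dotfinder.ordering`): count retained hits per scaffold
   and emit the assembly with marker-bearing scaffolds first, sorted by hit
   count (recommended: restricted to scaffolds ≤ 5 Mb, since
   macrochromosomes occasionally catch a spurious hit). Loaded into a Hi-C
   curation viewer, the candidate dot fragments now lead the contact map.
4. **Validation** (`dotfinder.homology`): bedtools-style per-base breadth of
   coverage of reference dot chromosomes from whole-genome alignments,
   before/after-curation deltas, and homology assignment of assembled
   chromosomes to reference dots by merged aligned bases.
5. **Meta-analysis** (`dotfinder.karyostats`): karyotype-versus-assembly
   correspondence. Diploid cytology counts are halved, summarized by mode,
   and compared to assembly chromosome counts with a ±1 margin; differences
   of two or more are discordant.

`dotfinder.synthetic` generates deterministic synthetic inputs with the
structure the method assumes (planted marker genes at controlled identity,
repeat fillers, oversized macro scaffolds, orthology tables with known
labels), which power the examples and the test suite.

## Worked example

`examples/01_sort_draft_assembly.py` simulates a fragmented draft — three dot
chromosomes split into fragments that carry marker genes diverged to 85%
amino-acid identity, six repeat-only fillers, one 5.3 Mb macro scaffold —
then maps the markers and sorts:

```
draft assembly: 13 scaffolds (5,623,263 bp), 27 planted marker genes

rank  scaffold        length hits  class
   0  dot0_frag0      24,957   10  dot  <- prioritized
   1  dot1_frag0      39,814    8  dot  <- prioritized
   2  dot2_frag1      34,357    5  dot  <- prioritized
   3  dot2_frag0       6,997    4  dot  <- prioritized
   4  macro0       5,278,796    0  macro
   5  filler4         59,648    0  filler
   ...
all marker-bearing dot fragments precede fillers/macros: True
```

Every marker-bearing dot fragment outranks every filler and macrochromosome
scaffold; without markers, the 7 kb `dot2_frag0` would sit at the very bottom
of a size-sorted map. The other examples cover marker-set construction,
coverage validation and the karyotype survey.

The same pipeline from the shell:

```
dotfinder simulate --seed 7 -o work/sim
dotfinder run --assembly work/sim.assembly.fa --proteins work/sim.markers.fa \
    --recommended -o work/curated
# -> work/curated.sorted.fa, work/curated.counts.tsv, work/curated.hits.gff3
```

`dotfinder run --hits alignments.paf ...` substitutes external alignments for
the built-in search. See `dotfinder --help` for the full command list
(`markerset`, `map`, `sort`, `coverage`, `homologs`, `karyostats`, …).

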