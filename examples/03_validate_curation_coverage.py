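"""Validate a curation round with alignment-coverage deltas and homology.

Emulates whole-genome alignments of an assembly against a reference with two
dot chromosomes, before and after curation placed a previously unassembled
fragment. Coverage is bedtools-style breadth (covered bases of the merged
interval union); homology assignment picks the reference dot chromosome with
the most merged aligned bases.
"""

from dotfinder import (AlignmentHit, assign_dot_homologs, coverage_delta,
                       per_base_coverage)

REF_LENGTHS = {"ref_dot29": 3_000_000, "ref_dot30": 2_500_000}


def aln(query, target, start, end):
    span = end - start
    return AlignmentHit(query_id=query, query_len=span, query_start=0,
                        query_end=span, target_id=target,
                        target_len=REF_LENGTHS[target], target_start=start,
                        target_end=end, strand="+", matches=span, aln_len=span,
                        score=span, identity=1.0)


before_alns = [aln("chr29", "ref_dot29", 0, 900_000),
               aln("chr29", "ref_dot29", 850_000, 1_400_000)]   # overlap merges
after_alns = before_alns + [aln("chr29", "ref_dot29", 1_400_000, 2_600_000),
                            aln("chr30", "ref_dot30", 100_000, 2_000_000)]

before = per_base_coverage(before_alns, REF_LENGTHS)
after = per_base_coverage(after_alns, REF_LENGTHS)
print("reference dot coverage (merged union, bp):")
for chrom in REF_LENGTHS:
    print(f"  {chrom}: before={before.per_chrom[chrom]:>9,} "
          f"after={after.per_chrom[chrom]:>9,}")

print("\nper-chromosome delta (after - before):")
for chrom, d in coverage_delta(before, after).items():
    print(f"  {chrom}: {d:+,}")

print("\nhomology assignment (most merged aligned bases):")
for a in assign_dot_homologs(after_alns, REF_LENGTHS):
    print(f"  {a.query_chrom} -> {a.ref_chrom} "
          f"({a.aligned_bases:,} bp, runner-up {a.runner_up_bases:,} bp)")
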