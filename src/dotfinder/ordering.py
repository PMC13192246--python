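"""Per-scaffold marker counting and assembly reordering for Hi-C curation.

Scaffolds carrying retained marker hits (and, optionally, shorter than a
maximum scaffold length) are moved to the front of the assembly sorted by
hit count, so putative dot-microchromosome fragments lead the Hi-C
contact map; everything else keeps its original relative order. A 5 Mb
cutoff is recommended because macrochromosome scaffolds occasionally pick
up a handful of spurious hits from divergent paralogs or mis-mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .aligner import (SearchParams, filter_min_identity, search_proteins,
                      top_hit_per_protein)
from .io_formats import (AlignmentHit, Assembly, SequenceRecord,
                         atomic_write_text, write_fasta, write_hits_gff3)

logger = logging.getLogger(__name__)

RECOMMENDED_MAX_SCAFFOLD_LENGTH = 5_000_000


@dataclass
class ScaffoldCountTable:
    """Per-scaffold marker hit counts, the pipeline's sort key."""

    rows: list[tuple[str, int, int]]          # (scaffold_id, length, marker_hits)
    max_scaffold_length: int | None = None

    def counts(self) -> dict[str, int]:
        return {sid: n for sid, _, n in self.rows}

    def total_hits(self) -> int:
        return sum(n for _, _, n in self.rows)

    def to_frame(self, prioritized: set[str] | None = None) -> pd.DataFrame:
        rows = []
        for sid, length, n in self.rows:
            row = {"scaffold": sid, "length": length, "marker_hits": n}
            if prioritized is not None:
                row["prioritized"] = "yes" if sid in prioritized else "no"
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class OrderingResult:
    permutation: list[str]
    prioritized: set[str]


def count_hits_per_scaffold(filtered_hits: Sequence[AlignmentHit] | Mapping[str, AlignmentHit],
                            assembly: Assembly,
                            max_scaffold_length: int | None = None) -> ScaffoldCountTable:
    """Count retained hits per scaffold (zero for scaffolds without hits).

    Counts reflect protein hits from the marker set, not distinct loci: two
    markers hitting the same locus both count. A hit whose target is not in
    the assembly is a hard error.
    """
    hits = list(filtered_hits.values()) if isinstance(filtered_hits, Mapping) \
        else list(filtered_hits)
    lengths = assembly.lengths()
    counts = {sid: 0 for sid in assembly.ids()}
    for h in hits:
        if h.target_id not in counts:
            raise ValueError(f"hit targets unknown scaffold {h.target_id!r}")
        counts[h.target_id] += 1
    rows = [(sid, lengths[sid], counts[sid]) for sid in assembly.ids()]
    return ScaffoldCountTable(rows=rows, max_scaffold_length=max_scaffold_length)


def order_assembly(assembly: Assembly, count_table: ScaffoldCountTable,
                   max_scaffold_length: int | None = None) -> OrderingResult:
    """Compute the curation ordering.

    Prioritized scaffolds are those with >=1 marker hit and (if a cutoff is
    set) length <= cutoff, sorted by hit count descending (ties: length
    descending, then input order). The remainder follows in original input
    order; over-cutoff scaffolds keep their hits in the counts table but are
    only excluded from prioritization.
    """
    if max_scaffold_length is None:
        max_scaffold_length = count_table.max_scaffold_length
    counts = count_table.counts()
    lengths = assembly.lengths()
    input_order = {sid: i for i, sid in enumerate(assembly.ids())}
    missing = [sid for sid in assembly.ids() if sid not in counts]
    if missing:
        raise ValueError(f"count table does not cover scaffolds: {missing[:5]}")
    prioritized = [
        sid for sid in assembly.ids()
        if counts[sid] >= 1 and (max_scaffold_length is None
                                 or lengths[sid] <= max_scaffold_length)
    ]
    prioritized.sort(key=lambda sid: (-counts[sid], -lengths[sid], input_order[sid]))
    pset = set(prioritized)
    remainder = [sid for sid in assembly.ids() if sid not in pset]
    return OrderingResult(permutation=prioritized + remainder, prioritized=pset)


@dataclass
class PipelineResult:
    sorted_assembly: Assembly
    count_table: ScaffoldCountTable
    ordering: OrderingResult
    hits: list[AlignmentHit]                 # retained (top, identity-filtered)
    n_raw_hits: int = 0
    n_top_hits: int = 0


def run_pipeline(assembly: Assembly,
                 markers: Sequence[SequenceRecord] | None = None,
                 hits: Sequence[AlignmentHit] | None = None,
                 params: SearchParams = SearchParams(),
                 max_scaffold_length: int | None = None,
                 out_prefix: str | Path | None = None,
                 line_width: int = 60) -> PipelineResult:
    """Search (or ingest) -> top hit -> identity filter -> count -> reorder.

    Exactly one of ``markers`` (raw proteins for the built-in search) or
    ``hits`` (pre-computed external alignments) must be given. When
    ``out_prefix`` is set, writes ``<prefix>.sorted.fa``,
    ``<prefix>.counts.tsv`` and ``<prefix>.hits.gff3`` atomically.
    """
    if (markers is None) == (hits is None):
        raise ValueError("provide exactly one of markers or hits")
    raw = search_proteins(markers, assembly, params) if markers is not None else list(hits)
    top = top_hit_per_protein(raw)
    retained = filter_min_identity(top, params.min_identity)
    kept = sorted(retained.values(),
                  key=lambda h: (h.target_id, h.target_start, h.query_id))
    count_table = count_hits_per_scaffold(kept, assembly, max_scaffold_length)
    ordering = order_assembly(assembly, count_table, max_scaffold_length)
    logger.info("hits: %d raw, %d top, %d >= identity %.2f; %d scaffolds prioritized",
                len(raw), len(top), len(kept), params.min_identity,
                len(ordering.prioritized))
    if not ordering.prioritized:
        logger.warning("no scaffolds prioritized; output order equals input order")
    by_id = {r.id: r for r in assembly.records}
    sorted_assembly = Assembly(records=[by_id[sid] for sid in ordering.permutation],
                               name=assembly.name)
    result = PipelineResult(sorted_assembly=sorted_assembly, count_table=count_table,
                            ordering=ordering, hits=kept,
                            n_raw_hits=len(raw), n_top_hits=len(top))
    if out_prefix is not None:
        write_pipeline_outputs(result, out_prefix, line_width)
    return result


def write_pipeline_outputs(result: PipelineResult, out_prefix: str | Path,
                           line_width: int = 60) -> None:
    prefix = str(out_prefix)
    atomic_write_text(prefix + ".sorted.fa",
                      lambda fh: write_fasta(result.sorted_assembly, fh, line_width))
    df = result.count_table.to_frame(result.ordering.prioritized)
    atomic_write_text(prefix + ".counts.tsv",
                      lambda fh: df.to_csv(fh, sep="\t", index=False))
    atomic_write_text(prefix + ".hits.gff3",
                      lambda fh: write_hits_gff3(result.hits, fh))
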