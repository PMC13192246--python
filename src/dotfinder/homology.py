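"""Coverage arithmetic for curation validation.

Implements the validation side of the workflow: per-base breadth of
coverage of reference dot chromosomes from whole-genome alignments
(bedtools-coverage equivalent, i.e. covered bases of the merged interval
union), before/after curation deltas, homology assignment of assembly
chromosomes to reference dot chromosomes by maximum merged aligned bases,
and fixed-window feature density (10 kb windows by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit, Interval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomologyAssignment:
    """An assembly chromosome assigned to the reference dot chromosome with
    the most merged aligned bases; the runner-up quantifies ambiguity."""

    query_chrom: str
    ref_chrom: str
    aligned_bases: int
    runner_up_bases: int

    def __post_init__(self) -> None:
        if not (self.aligned_bases >= self.runner_up_bases >= 0):
            raise ValueError("aligned_bases must be >= runner_up_bases >= 0")


@dataclass
class CoverageSummary:
    per_chrom: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_chrom.values())


def merge_intervals(intervals: Iterable[tuple[int, int] | Interval]) -> list[tuple[int, int]]:
    """Merge to the minimal disjoint sorted set with the same union.

    Adjacent intervals ([0,5),[5,9)) merge. Input may be (start, end)
    tuples or :class:`Interval` objects on a single chromosome.
    """
    spans = sorted((iv.start, iv.end) if isinstance(iv, Interval) else (iv[0], iv[1])
                   for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if s >= e:
            raise ValueError(f"invalid interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def covered_bases(intervals: Iterable[tuple[int, int] | Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def _ref_intervals(alignments: Iterable[AlignmentHit | Interval]) -> Iterable[tuple[str, int, int]]:
    for a in alignments:
        if isinstance(a, Interval):
            yield a.chrom, a.start, a.end
        else:
            yield a.target_id, a.target_start, a.target_end


def per_base_coverage(alignments: Iterable[AlignmentHit | Interval],
                      ref_chrom_lengths: Mapping[str, int],
                      restrict_to: Iterable[str] | None = None) -> CoverageSummary:
    """Covered bases of the merged alignment union per reference chromosome.

    ``restrict_to`` limits the summary to a chromosome subset (e.g. the
    reference dot chromosomes); chromosomes without alignments report 0.
    Intervals running past the chromosome end are clipped with a warning.
    """
    chroms = set(restrict_to) if restrict_to is not None else set(ref_chrom_lengths)
    unknown = chroms - set(ref_chrom_lengths)
    if unknown:
        raise ValueError(f"restrict_to chromosomes without lengths: {sorted(unknown)}")
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    clipped = 0
    for chrom, s, e in _ref_intervals(alignments):
        if chrom not in by_chrom:
            continue
        limit = ref_chrom_lengths[chrom]
        if e > limit:
            clipped += 1
            e = min(e, limit)
            if s >= e:
                continue
        by_chrom[chrom].append((s, e))
    if clipped:
        warnings.warn(f"{clipped} alignments clipped to chromosome ends", stacklevel=2)
    return CoverageSummary(per_chrom={c: covered_bases(ivs) if ivs else 0
                                      for c, ivs in sorted(by_chrom.items())})


def filter_placed(alignments: Sequence[AlignmentHit],
                  placed_query_ids: Iterable[str]) -> list[AlignmentHit]:
    """Drop alignments whose query sequence is unplaced assembly content
    (content not in chromosome models)."""
    placed = set(placed_query_ids)
    return [a for a in alignments if a.query_id in placed]


def coverage_delta(before: CoverageSummary, after: CoverageSummary) -> dict[str, int]:
    """Signed per-chromosome coverage change (after - before).

    Decreases are meaningful: corrections during curation can remove
    wrongly placed content.
    """
    if set(before.per_chrom) != set(after.per_chrom):
        raise ValueError("coverage summaries cover different chromosome sets")
    return {c: after.per_chrom[c] - before.per_chrom[c] for c in sorted(before.per_chrom)}


def assign_dot_homologs(alignments: Sequence[AlignmentHit],
                        ref_dot_set: Iterable[str]) -> list[HomologyAssignment]:
    """Assign each query chromosome to the reference dot chromosome with the
    most merged aligned bases.

    Merged (not raw summed) bases are used so overlapping alignments do not
    double count. Queries aligning only outside the dot set get no
    assignment; exact ties are left unassigned with a warning.
    """
    dots = set(ref_dot_set)
    pair_ivs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a in alignments:
        if a.target_id in dots:
            pair_ivs.setdefault((a.query_id, a.target_id), []).append(
                (a.target_start, a.target_end))
    by_query: dict[str, list[tuple[int, str]]] = {}
    for (q, r), ivs in pair_ivs.items():
        by_query.setdefault(q, []).append((covered_bases(ivs), r))
    out: list[HomologyAssignment] = []
    for q in sorted(by_query):
        ranked = sorted(by_query[q], key=lambda t: (-t[0], t[1]))
        best_bases, best_ref = ranked[0]
        runner = ranked[1][0] if len(ranked) > 1 else 0
        if len(ranked) > 1 and ranked[1][0] == best_bases:
            warnings.warn(f"query {q!r}: tie between {best_ref!r} and "
                          f"{ranked[1][1]!r}; left unassigned", stacklevel=2)
            continue
        out.append(HomologyAssignment(query_chrom=q, ref_chrom=best_ref,
                                      aligned_bases=best_bases,
                                      runner_up_bases=runner))
    return out


def window_density(features: Sequence[int | tuple[int, int] | Interval],
                   chrom_length: int, window: int = 10_000,
                   mode: str = "auto") -> list[int]:
    """Feature counts (point mode) or overlap bp (interval mode) per fixed
    window; the last window may be short.

    ``mode`` is 'point', 'interval' or 'auto' (inferred from the first
    feature). Features outside the chromosome are clipped with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    n_windows = -(-chrom_length // window)
    counts = [0] * n_windows
    if not features:
        return counts
    if mode == "auto":
        mode = "point" if isinstance(features[0], int) else "interval"
    clipped = 0
    for f in features:
        if mode == "point":
            pos = int(f)
            if pos < 0 or pos >= chrom_length:
                clipped += 1
                continue
            counts[pos // window] += 1
        else:
            s, e = (f.start, f.end) if isinstance(f, Interval) else (f[0], f[1])
            if s < 0 or e > chrom_length:
                clipped += 1
                s, e = max(s, 0), min(e, chrom_length)
            if s >= e:
                continue
            for w in range(s // window, (e - 1) // window + 1):
                ws, we = w * window, min((w + 1) * window, chrom_length)
                counts[w] += min(e, we) - max(s, ws)
    if clipped:
        warnings.warn(f"{clipped} features clipped to the chromosome", stacklevel=2)
    return counts
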