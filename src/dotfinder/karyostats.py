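"""Karyotype-versus-assembly correspondence meta-analysis.

Cytology reports diploid (2n) chromosome counts; chromosome-scale
assemblies report a haploid set. Each species' cytology reports are
halved and summarized by their mode, the assembly count is compared to
that summary, and the difference is classified with a ±1 margin (male
assemblies of the homogametic sex usually carry one fewer assembled
chromosome). Species differing by two or more are discordant, and the
analysis tracks whether discordant assemblies have fewer chromosomes than
expected — the signature of unassembled microchromosomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import read_table


@dataclass(frozen=True)
class HaploidSummary:
    value: float
    tied: bool = False
    half_integer: bool = False


@dataclass
class KaryotypeRecord:
    """One species' cytology counts and assembly chromosome count."""

    species: str
    diploid_counts: list[int]
    assembly_count: int
    excluded_counts: list[int] = field(default_factory=list)
    haploid_summary: HaploidSummary | None = None
    diff: float | None = None
    diff_class: str | None = None
    fewer: bool | None = None

    def summarize(self) -> "KaryotypeRecord":
        self.haploid_summary = summarize_haploid(self.diploid_counts)
        self.diff = self.assembly_count - self.haploid_summary.value
        self.diff_class = classify_diff(self.diff)
        self.fewer = self.assembly_count < self.haploid_summary.value
        return self


def summarize_haploid(diploid_counts: Sequence[int]) -> HaploidSummary:
    """Halve each diploid count and take the mode.

    Odd diploid counts yield half-integers, which are kept exact and
    flagged. Mode ties resolve to the smallest value, flagged.
    """
    if not diploid_counts:
        raise ValueError("at least one diploid count is required")
    halved = [c / 2 for c in diploid_counts]
    counts = Counter(halved)
    top = max(counts.values())
    modes = sorted(v for v, n in counts.items() if n == top)
    value = modes[0]
    return HaploidSummary(value=value, tied=len(modes) > 1,
                          half_integer=value != int(value))


def classify_diff(diff: float) -> str:
    """'match' (diff 0), 'within_1' (0 < |diff| <= 1) or 'discordant'.

    On integer differences this is exactly the 0 / ±1 / >=2 partition;
    half-integer differences fall into the nearest enclosing band by exact
    arithmetic, so every record lands in exactly one class.
    """
    a = abs(diff)
    if a == 0:
        return "match"
    if a <= 1:
        return "within_1"
    return "discordant"


def classify(record: KaryotypeRecord) -> str:
    """Classify a record (summarizing it first if needed)."""
    if record.haploid_summary is None:
        record.summarize()
    return record.diff_class


@dataclass
class CorrespondenceSummary:
    matrix: pd.DataFrame            # unit-binned haploid (rows) x assembly (cols)
    n_total: int
    n_discordant: int
    n_discordant_fewer: int

    @property
    def discordant_fraction(self) -> float:
        return self.n_discordant / self.n_total if self.n_total else 0.0


def correspondence_summary(records: Iterable[KaryotypeRecord]) -> CorrespondenceSummary:
    """Headline counts plus a unit-binned 2-D histogram of (haploid
    summary, assembly count) over all species."""
    records = [r.summarize() for r in records]
    n_total = len(records)
    discordant = [r for r in records if r.diff_class == "discordant"]
    n_fewer = sum(1 for r in discordant if r.fewer)
    if records:
        h = [r.haploid_summary.value for r in records]
        a = [r.assembly_count for r in records]
        h_bins = np.arange(np.floor(min(h)), np.floor(max(h)) + 2)
        a_bins = np.arange(min(a), max(a) + 2)
        hist, _, _ = np.histogram2d(h, a, bins=[h_bins, a_bins])
        matrix = pd.DataFrame(hist.astype(int),
                              index=h_bins[:-1].astype(int),
                              columns=a_bins[:-1].astype(int))
        matrix.index.name = "haploid_summary"
        matrix.columns.name = "assembly_count"
    else:
        matrix = pd.DataFrame()
    return CorrespondenceSummary(matrix=matrix, n_total=n_total,
                                 n_discordant=len(discordant),
                                 n_discordant_fewer=n_fewer)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def read_karyotype_table(path_or_stream) -> list[KaryotypeRecord]:
    """Read the karyotype TSV.

    Columns: ``species``, ``diploid_counts`` (semicolon-separated),
    ``assembly_count``, optional ``exclude`` (semicolon-separated diploid
    values flagged as database errors; they are dropped before
    summarizing, mirroring manual outlier checking).
    """
    df = read_table(path_or_stream,
                    schema={"species": str, "diploid_counts": str, "assembly_count": int})
    records = []
    for _, row in df.iterrows():
        counts = [int(x) for x in str(row["diploid_counts"]).split(";") if x.strip()]
        excluded: list[int] = []
        if "exclude" in df.columns and pd.notna(row.get("exclude")):
            excluded = [int(x) for x in str(row["exclude"]).split(";") if x.strip()]
            for v in excluded:
                if v in counts:
                    counts.remove(v)
        if not counts:
            continue
        records.append(KaryotypeRecord(species=row["species"], diploid_counts=counts,
                                       assembly_count=int(row["assembly_count"]),
                                       excluded_counts=excluded))
    return records


def summary_frame(records: Iterable[KaryotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        r.summarize()
        rows.append({
            "species": r.species,
            "haploid_summary": r.haploid_summary.value,
            "assembly_count": r.assembly_count,
            "diff": r.diff,
            "diff_class": r.diff_class,
            "fewer": "yes" if r.fewer else "no",
            "mode_tied": "yes" if r.haploid_summary.tied else "no",
            "half_integer": "yes" if r.haploid_summary.half_integer else "no",
        })
    return pd.DataFrame(rows)
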