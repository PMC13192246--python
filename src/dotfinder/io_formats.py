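"""Readers and writers for the formats the pipeline speaks.

All in-memory coordinates are 0-based half-open (PAF/BED convention);
GFF3 emission converts to 1-based closed at the boundary and parsing
converts back, so round trips are the identity.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised on malformed input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A single named sequence (nucleotide or amino acid)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of scaffolds; order defines the Hi-C map order."""

    records: list[SequenceRecord]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in assembly")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.records}

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


@dataclass(frozen=True)
class AlignmentHit:
    """One protein-vs-scaffold alignment.

    Query coordinates are in residues (aa for protein queries), target
    coordinates in bp, both 0-based half-open. ``identity`` is
    matches/aln_len, which is what a PAF line's columns 10/11 provide.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    aln_len: int
    score: int
    identity: float

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"bad query span {self.query_start}..{self.query_end} "
                f"(len {self.query_len}) for {self.query_id}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"bad target span {self.target_start}..{self.target_end} "
                f"(len {self.target_len}) for {self.target_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.matches > self.aln_len:
            raise ValueError(f"matches {self.matches} > aln_len {self.aln_len}")
        if abs(self.identity - self.matches / self.aln_len) > 1e-9:
            raise ValueError("identity inconsistent with matches/aln_len")


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _as_handle(path_or_stream, mode: str):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode), True
    return path_or_stream, False


def read_fasta(path_or_stream, name: str = "") -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Record id is the first whitespace-delimited token of the header; the
    remainder is kept as the description. Sequences are uppercased.
    """
    handle, close = _as_handle(path_or_stream, "r")
    try:
        first = handle.read(1)
        if first == "":
            return Assembly(records=[], name=name)
        if first != ">":
            raise FormatError("not a FASTA file: first byte is not '>'")
        handle.seek(0) if hasattr(handle, "seek") else None
        stream = handle
        if not hasattr(handle, "seek"):
            stream = io.StringIO(first + handle.read())
        records = []
        for rec in SeqIO.parse(stream, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for record {rec.id!r}")
            records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
        return Assembly(records=records, name=name)
    finally:
        if close:
            handle.close()


def write_fasta(assembly: Assembly | Iterable[SequenceRecord], path_or_stream,
                line_width: int = 60) -> None:
    """Write records in order, wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    records = assembly.records if isinstance(assembly, Assembly) else list(assembly)
    handle, close = _as_handle(path_or_stream, "w")
    try:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        for rec in records:
            header_desc = rec.description or ""
            bio = SeqRecord(Seq(rec.sequence), id=rec.id, description=header_desc)
            writer.write_record(bio)
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def parse_paf(path_or_stream) -> list[AlignmentHit]:
    """Parse minimap2/miniprot PAF into :class:`AlignmentHit` objects.

    ``matches`` is column 10, ``aln_len`` column 11, identity their ratio.
    The alignment score is read from an ``AS:i:`` tag when present, else it
    defaults to the match count.
    """
    handle, close = _as_handle(path_or_stream, "r")
    hits: list[AlignmentHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
            try:
                qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
                tlen, ts, te = int(cols[6]), int(cols[7]), int(cols[8])
                matches, aln_len = int(cols[9]), int(cols[10])
            except ValueError as exc:
                raise FormatError(f"PAF line {lineno}: non-integer coordinate field") from exc
            if qe <= qs or te <= ts:
                raise FormatError(f"PAF line {lineno}: end <= start")
            score = matches
            for tag in cols[12:]:
                if tag.startswith("AS:i:"):
                    score = int(tag[5:])
                    break
            hits.append(AlignmentHit(
                query_id=cols[0], query_len=qlen, query_start=qs, query_end=qe,
                target_id=cols[5], target_len=tlen, target_start=ts, target_end=te,
                strand=cols[4], matches=matches, aln_len=aln_len, score=score,
                identity=matches / aln_len,
            ))
    finally:
        if close:
            handle.close()
    return hits


def write_paf(hits: Sequence[AlignmentHit], path_or_stream) -> None:
    """Write hits as 12-column PAF plus an AS:i: score tag."""
    handle, close = _as_handle(path_or_stream, "w")
    try:
        for h in hits:
            handle.write("\t".join(map(str, [
                h.query_id, h.query_len, h.query_start, h.query_end, h.strand,
                h.target_id, h.target_len, h.target_start, h.target_end,
                h.matches, h.aln_len, 255, f"AS:i:{h.score}",
            ])) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GFF3 (protein_match features, miniprot-like)
# ---------------------------------------------------------------------------

_GFF_SOURCE = "dotfinder"


def write_hits_gff3(hits: Sequence[AlignmentHit], path_or_stream) -> None:
    """Write hits as GFF3 ``protein_match`` features (1-based closed coords)."""
    handle, close = _as_handle(path_or_stream, "w")
    try:
        handle.write("##gff-version 3\n")
        for h in hits:
            attrs = (
                f"ID={h.query_id};Target={h.query_id} {h.query_start + 1} {h.query_end};"
                f"Identity={h.identity:.4f};Matches={h.matches};AlnLen={h.aln_len};"
                f"QueryLen={h.query_len};TargetLen={h.target_len}"
            )
            handle.write("\t".join(map(str, [
                h.target_id, _GFF_SOURCE, "protein_match",
                h.target_start + 1, h.target_end, h.score, h.strand, ".", attrs,
            ])) + "\n")
    finally:
        if close:
            handle.close()


def _parse_gff_attrs(attr_col: str) -> dict[str, str]:
    out = {}
    for part in attr_col.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_hits_gff3(path_or_stream) -> list[AlignmentHit]:
    """Parse protein_match GFF3 (miniprot dialect or our own output).

    Identity comes from the ``Identity`` attribute when present; match and
    alignment-length attributes are used when available, otherwise they are
    reconstructed from the identity and target span. Features without a
    resolvable identity are skipped.
    """
    handle, close = _as_handle(path_or_stream, "r")
    hits: list[AlignmentHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"GFF3 line {lineno}: expected 9 columns")
            ftype = cols[2]
            if ftype not in ("protein_match", "mRNA"):
                continue
            attrs = _parse_gff_attrs(cols[8])
            target = attrs.get("Target", "")
            tparts = target.split()
            start1, end1 = int(cols[3]), int(cols[4])
            ts, te = start1 - 1, end1
            if "Identity" in attrs:
                identity = float(attrs["Identity"])
            elif "Matches" in attrs and "AlnLen" in attrs:
                identity = int(attrs["Matches"]) / int(attrs["AlnLen"])
            else:
                continue
            if "AlnLen" in attrs:
                aln_len = int(attrs["AlnLen"])
            else:
                aln_len = (te - ts) // 3 if ftype in ("protein_match", "mRNA") else te - ts
            if "Matches" in attrs:
                matches = int(attrs["Matches"])
            else:
                matches = round(identity * aln_len)
            identity = matches / aln_len
            if tparts and len(tparts) >= 3:
                qid, qs, qe = tparts[0], int(tparts[1]) - 1, int(tparts[2])
            else:
                qid = attrs.get("ID", f"feature{lineno}")
                qs, qe = 0, aln_len
            qlen = int(attrs.get("QueryLen", qe))
            tlen = int(attrs.get("TargetLen", te))
            try:
                score = int(float(cols[5]))
            except ValueError:
                score = matches
            hits.append(AlignmentHit(
                query_id=qid, query_len=qlen, query_start=qs, query_end=qe,
                target_id=cols[0], target_len=tlen, target_start=ts, target_end=te,
                strand=cols[6], matches=matches, aln_len=aln_len,
                score=score, identity=identity,
            ))
    finally:
        if close:
            handle.close()
    return hits


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_table(path_or_stream, schema: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a tab-separated table with a header row.

    ``schema`` maps required column names to types; a missing column raises
    a :class:`FormatError` naming it. Empty cells become pandas NA.
    """
    df = pd.read_csv(path_or_stream, sep="\t", dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    if schema:
        for col, typ in schema.items():
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r}")
            if typ is not str:
                df[col] = df[col].astype(typ)
    return df


def write_table(df: pd.DataFrame, path_or_stream) -> None:
    df.to_csv(path_or_stream, sep="\t", index=False)


def atomic_write_text(path: str | Path, writer) -> None:
    """Write via a temp file + rename so partial runs never truncate outputs."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        writer(fh)
    os.replace(tmp, path)
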