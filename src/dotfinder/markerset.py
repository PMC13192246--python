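"""Construction of the conserved dot-microchromosome marker protein set.

The marker set is built from orthogroup tables (OrthoFinder
``Orthogroups.tsv`` dialect) in four steps: fuzzy conservation filtering
(present in at least a fraction of species, at most a copy cap per
species), restriction to orthogroups with a member on a reference
species' dot microchromosomes, pooling of the member proteins, and
CD-HIT-style greedy redundancy reduction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import Align

from .io_formats import FormatError, SequenceRecord, read_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup id -> species -> gene ids."""

    orthogroups: dict[str, dict[str, list[str]]]
    species: list[str]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must be non-empty")
        seen: dict[str, str] = {}
        for og, by_sp in self.orthogroups.items():
            for sp, genes in by_sp.items():
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} appears in both {seen[g]!r} and {og!r}"
                        )
                    seen[g] = og


@dataclass(frozen=True)
class FuzzyCriteria:
    """Relaxed conservation criteria for orthogroup selection.

    Defaults match KinFin's ``--max 3 -x 0.5``: present in at least half
    of the species with at most three gene copies in any species.
    """

    min_species_fraction: float = 0.5
    max_copies: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_species_fraction <= 1):
            raise ValueError("min_species_fraction must be in (0, 1]")
        if self.max_copies < 1:
            raise ValueError("max_copies must be a positive integer")


class GeneLocation(NamedTuple):
    species: str
    chrom: str
    start: int = 0
    end: int = 0


@dataclass
class MarkerSet:
    """Deduplicated marker proteins with provenance.

    ``proteins`` are the cluster representatives; ``cluster_map`` sends every
    input protein id to its representative's id; ``provenance`` records which
    orthogroup and species each protein came from.
    """

    proteins: list[SequenceRecord]
    provenance: dict[str, tuple[str, str]]
    cluster_map: dict[str, str]


# ---------------------------------------------------------------------------
# Orthogroup table I/O
# ---------------------------------------------------------------------------


def read_orthogroups_tsv(path_or_stream) -> OrthogroupTable:
    """Read an ``Orthogroups.tsv``-dialect table.

    First column is the orthogroup id; remaining columns are species, each
    cell a comma-separated gene list (empty cell = absent).
    """
    df = pd.read_csv(path_or_stream, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("orthogroup table needs an id column plus >=1 species")
    species = list(df.columns[1:])
    ogs: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og_id = row.iloc[0]
        by_sp: dict[str, list[str]] = {}
        for sp in species:
            cell = row[sp].strip()
            if cell:
                by_sp[sp] = [g.strip() for g in cell.split(",") if g.strip()]
        ogs[og_id] = by_sp
    return OrthogroupTable(orthogroups=ogs, species=species)


def write_orthogroups_tsv(table: OrthogroupTable, path_or_stream) -> None:
    rows = []
    for og_id, by_sp in table.orthogroups.items():
        row = {"Orthogroup": og_id}
        for sp in table.species:
            row[sp] = ", ".join(by_sp.get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path_or_stream, sep="\t", index=False)


def read_gene_locations(path_or_stream) -> dict[str, GeneLocation]:
    """Read a gene-location TSV (gene, species, chrom, start, end)."""
    df = read_table(path_or_stream, schema={"gene": str, "species": str, "chrom": str})
    out: dict[str, GeneLocation] = {}
    for _, row in df.iterrows():
        start = int(row["start"]) if "start" in df.columns and pd.notna(row.get("start")) else 0
        end = int(row["end"]) if "end" in df.columns and pd.notna(row.get("end")) else 0
        out[row["gene"]] = GeneLocation(row["species"], row["chrom"], start, end)
    return out


# ---------------------------------------------------------------------------
# Fuzzy selection
# ---------------------------------------------------------------------------


def copy_number_table(table: OrthogroupTable) -> dict[str, dict[str, int]]:
    """Per-orthogroup, per-species gene copy counts (absent species -> 0)."""
    return {
        og: {sp: len(by_sp.get(sp, [])) for sp in table.species}
        for og, by_sp in table.orthogroups.items()
    }


def select_fuzzy(copy_table: Mapping[str, Mapping[str, int]],
                 criteria: FuzzyCriteria = FuzzyCriteria()) -> set[str]:
    """Select orthogroups passing the relaxed conservation criteria.

    An orthogroup passes iff the fraction of species with at least one copy
    is >= ``min_species_fraction`` and no species exceeds ``max_copies``.
    """
    selected: set[str] = set()
    for og, counts in copy_table.items():
        n_species = len(counts)
        if n_species == 0:
            continue
        present = sum(1 for c in counts.values() if c >= 1)
        if present / n_species >= criteria.min_species_fraction and \
                max(counts.values()) <= criteria.max_copies:
            selected.add(og)
    return selected


def filter_dot_orthogroups(
    selected_ids: Iterable[str],
    table: OrthogroupTable,
    gene_locations: Mapping[str, GeneLocation],
    dot_chroms_by_species: Mapping[str, set[str]],
) -> set[str]:
    """Keep orthogroups with >=1 member on a reference species' dot chromosome.

    Only genes of the reference species listed in ``dot_chroms_by_species``
    count; genes of other species never influence the filter. A reference
    species gene without a known location is treated as non-dot (warning).
    """
    retained: set[str] = set()
    missing = 0
    for og in selected_ids:
        by_sp = table.orthogroups.get(og, {})
        hit = False
        for sp, dot_chroms in dot_chroms_by_species.items():
            for gene in by_sp.get(sp, []):
                loc = gene_locations.get(gene)
                if loc is None:
                    missing += 1
                    continue
                if loc.chrom in dot_chroms:
                    hit = True
                    break
            if hit:
                break
        if hit:
            retained.add(og)
    if missing:
        warnings.warn(
            f"{missing} reference-species genes had no location and were "
            "treated as non-dot", stacklevel=2)
    return retained


# ---------------------------------------------------------------------------
# Greedy identity clustering (CD-HIT style)
# ---------------------------------------------------------------------------


def _max_matches_aligner() -> Align.PairwiseAligner:
    # match=1, mismatch=0, gaps=0: the optimal global score is the maximum
    # number of exactly matching residues over all global alignments.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """CD-HIT-convention identity: max matching residues of the optimal
    global alignment divided by the shorter sequence's length."""
    if aligner is None:
        aligner = _max_matches_aligner()
    matches = aligner.score(a, b)
    return matches / min(len(a), len(b))


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def _screen_can_skip(query_counts: Mapping[str, int], q_len: int,
                     rep_counts: Mapping[str, int], rep_len: int,
                     threshold: float, k: int) -> bool:
    """Word-count screen: True only when the pair provably cannot reach
    the identity threshold.

    If identity >= t then the global alignment has M >= ceil(t*L) matches
    (L the shorter length). Non-match columns touching the shorter
    sequence's residues number at most L - M, and gap columns in the
    shorter sequence number at most len_long - M; each such column spoils
    at most k of the shorter sequence's k-mers. Hence the sequences must
    share at least (L - k + 1) - k*((L - M) + (len_long - M)) k-mer
    occurrences. At the default threshold (0.90, k=5) this bound is
    vacuous, so the screen only activates at high thresholds.
    """
    short_len = min(q_len, rep_len)
    long_len = max(q_len, rep_len)
    m0 = ceil(threshold * short_len)
    bound = (short_len - k + 1) - k * ((short_len - m0) + (long_len - m0))
    if bound <= 0:
        return False
    shared = 0
    small, big = (query_counts, rep_counts) if len(query_counts) <= len(rep_counts) \
        else (rep_counts, query_counts)
    for w, c in small.items():
        if w in big:
            shared += min(c, big[w])
            if shared >= bound:
                return False
    return shared < bound


def greedy_cluster(proteins: Sequence[SequenceRecord],
                   identity_threshold: float = 0.90,
                   word_size: int = 5) -> MarkerSet:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by length descending (ties by id); each sequence
    joins the first existing representative to which its identity reaches
    the threshold, else founds a new cluster. Identity is the maximum
    matching-residue count of a global alignment divided by the shorter
    length (CD-HIT's convention, and its default threshold 0.90 / word 5).
    """
    if not proteins:
        return MarkerSet(proteins=[], provenance={}, cluster_map={})
    ordered = sorted(proteins, key=lambda r: (-len(r), r.id))
    aligner = _max_matches_aligner()
    reps: list[SequenceRecord] = []
    rep_counts: list[dict[str, int]] = []
    cluster_map: dict[str, str] = {}
    for rec in ordered:
        counts = _kmer_counts(rec.sequence, word_size)
        assigned = None
        for rep, rcounts in zip(reps, rep_counts):
            if _screen_can_skip(counts, len(rec), rcounts, len(rep),
                                identity_threshold, word_size):
                continue
            if pairwise_identity(rec.sequence, rep.sequence, aligner) >= identity_threshold:
                assigned = rep
                break
        if assigned is None:
            reps.append(rec)
            rep_counts.append(counts)
            cluster_map[rec.id] = rec.id
        else:
            cluster_map[rec.id] = assigned.id
    return MarkerSet(proteins=reps, provenance={}, cluster_map=cluster_map)


# ---------------------------------------------------------------------------
# Full marker-set pipeline
# ---------------------------------------------------------------------------


def build_markerset(
    table: OrthogroupTable,
    proteomes: Mapping[str, Mapping[str, SequenceRecord]],
    gene_locations: Mapping[str, GeneLocation],
    dot_chroms_by_species: Mapping[str, set[str]],
    criteria: FuzzyCriteria = FuzzyCriteria(),
    identity_threshold: float = 0.90,
    word_size: int = 5,
) -> MarkerSet:
    """Fuzzy-select, dot-filter, pool and cluster into a marker set.

    ``proteomes`` maps species -> gene id -> protein record. Every gene of
    a retained orthogroup must resolve to a proteome sequence.
    """
    copy_table = copy_number_table(table)
    fuzzy = select_fuzzy(copy_table, criteria)
    dot_ogs = filter_dot_orthogroups(fuzzy, table, gene_locations, dot_chroms_by_species)
    logger.info("orthogroups: %d total, %d fuzzy, %d dot-associated",
                len(table.orthogroups), len(fuzzy), len(dot_ogs))

    pooled: list[SequenceRecord] = []
    provenance: dict[str, tuple[str, str]] = {}
    unresolved: list[str] = []
    for og in sorted(dot_ogs):
        for sp in table.species:
            for gene in table.orthogroups[og].get(sp, []):
                rec = proteomes.get(sp, {}).get(gene)
                if rec is None:
                    unresolved.append(gene)
                    continue
                pooled.append(rec)
                provenance[rec.id] = (og, sp)
    if unresolved:
        raise ValueError(
            f"{len(unresolved)} orthogroup genes not found in proteomes: "
            f"{', '.join(unresolved[:10])}{'...' if len(unresolved) > 10 else ''}")

    clustered = greedy_cluster(pooled, identity_threshold, word_size)
    clustered.provenance = {p.id: provenance[p.id] for p in clustered.proteins}
    logger.info("marker set: %d pooled proteins -> %d representatives",
                len(pooled), len(clustered.proteins))
    return clustered


def write_markerset(marker_set: MarkerSet, fasta_path, provenance_path) -> None:
    """Serialize as FASTA (representatives) + provenance/cluster TSV."""
    from .io_formats import write_fasta
    write_fasta(marker_set.proteins, fasta_path)
    rows = []
    for pid, rep in marker_set.cluster_map.items():
        og, sp = marker_set.provenance.get(rep, ("", ""))
        rows.append({"protein": pid, "representative": rep,
                     "orthogroup": og, "species": sp})
    pd.DataFrame(rows, columns=["protein", "representative", "orthogroup", "species"]) \
        .to_csv(provenance_path, sep="\t", index=False)
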