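"""Deterministic synthetic fixtures with the structure the method assumes.

The draft-assembly generator emulates the curation scenario the pipeline
targets: gene-dense dot-microchromosome fragments carrying
reverse-translated marker genes at controlled amino-acid divergence,
GC-biased spacer between genes, pericentromeric-style tandem-repeat
blocks, repeat-only filler scaffolds with zero markers, and
macrochromosome scaffolds above the sorting cutoff. Scaffold sizes are
scaled down from real bird chromosomes so whole-pipeline sweeps run in
seconds per replicate; the structure, not the absolute size, is what the
recovery tests exercise. Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .aligner import AA_ORDER
from .io_formats import Assembly, SequenceRecord
from .markerset import GeneLocation, OrthogroupTable

_NT = "ACGT"
_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codon_backtable() -> tuple[np.ndarray, np.ndarray]:
    """(codons[aa_code, choice, 3] nt codes, n_choices[aa_code])."""
    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    max_c = max(len(v) for v in by_aa.values())
    codons = np.zeros((len(AA_ORDER), max_c, 3), dtype=np.uint8)
    counts = np.zeros(len(AA_ORDER), dtype=np.int64)
    for i, aa in enumerate(AA_ORDER):
        opts = sorted(by_aa[aa])
        counts[i] = len(opts)
        for j, codon in enumerate(opts):
            codons[i, j] = [_NT.index(b) for b in codon]
    return codons, counts


_CODONS, _CODON_COUNTS = _codon_backtable()
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Sequence-level generators
# ---------------------------------------------------------------------------


def reverse_translate(protein: str, codon_choice_seed) -> str:
    """A DNA sequence of length 3*len translating exactly back to ``protein``.

    Codons are drawn uniformly from each residue's synonymous codons using
    the given seed (or Generator), so a fixed seed gives byte-identical DNA.
    """
    rng = _rng(codon_choice_seed)
    try:
        aa_codes = np.array([_AA_INDEX[a] for a in protein.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid amino acid {exc.args[0]!r}") from None
    choice = rng.integers(0, _CODON_COUNTS[aa_codes])
    nt_codes = _CODONS[aa_codes, choice].reshape(-1)
    return _NT_BYTES[nt_codes].tobytes().decode("ascii")


def mutate_to_identity(protein: str, target_identity: float, seed) -> str:
    """Point-substitute so exactly ceil(target_identity*len) positions match."""
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    rng = _rng(seed)
    L = len(protein)
    n_keep = ceil(target_identity * L)
    n_mut = L - n_keep
    if n_mut == 0:
        return protein
    positions = rng.choice(L, size=n_mut, replace=False)
    out = list(protein)
    for p in positions:
        alternatives = [a for a in AA_ORDER if a != out[p]]
        out[p] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def random_protein(length: int, rng) -> str:
    rng = _rng(rng)
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


def make_marker_proteins(n: int, seed, length_range: tuple[int, int] = (80, 200),
                         prefix: str = "marker") -> list[SequenceRecord]:
    """Random amino-acid marker proteins with deterministic ids."""
    rng = _rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(SequenceRecord(id=f"{prefix}{i:04d}", sequence=random_protein(L, rng)))
    return out


def _random_dna(n: int, rng, gc: float = 0.42) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.searchsorted(np.cumsum(p), rng.random(n), side="right").astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _NT_BYTES[codes].tobytes().decode("ascii")


def _revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _tandem_repeat(target_len: int, rng, unit_len_range=(300, 800),
                   sub_rate: float = 0.02) -> np.ndarray:
    """Tandem copies of one unit with per-copy substitutions: the character
    of repetitive unplaced content without modelling real repeat families."""
    unit_len = int(rng.integers(*unit_len_range))
    unit = _random_dna(unit_len, rng, gc=0.45)
    n_copies = -(-target_len // unit_len)
    block = np.tile(unit, n_copies)[:target_len]
    n_sub = int(sub_rate * len(block))
    if n_sub:
        pos = rng.integers(0, len(block), size=n_sub)
        block[pos] = (block[pos] + rng.integers(1, 4, size=n_sub)) % 4
    return block


# ---------------------------------------------------------------------------
# Draft-assembly simulation
# ---------------------------------------------------------------------------


class PlantedMarker(NamedTuple):
    protein_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    target_identity: float


@dataclass
class SyntheticTruth:
    scaffold_class: dict[str, str]           # scaffold_id -> dot | macro | filler
    planted: list[PlantedMarker]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the draft-assembly generator.

    ``markers_per_dot`` defaults to the observed per-chromosome marker-locus
    range on real dot chromosomes (15-67); ``marker_identity`` 0.85 plants
    genes comfortably above the 0.70 identity filter while exercising it;
    macro scaffolds exceed the recommended 5 Mb sorting cutoff and dot
    fragments stay below it. ``gc_bias`` is the GC fraction of the
    gene-dense euchromatic spacer (dot chromosomes are GC-rich).
    """

    seed: int = 0
    n_dot_chroms: int = 10
    n_macro_scaffolds: int = 5
    n_filler_scaffolds: int = 40
    markers_per_dot: tuple[int, int] = (15, 67)
    marker_identity: float = 0.85
    dot_chrom_len: tuple[int, int] = (200_000, 400_000)
    macro_len: tuple[int, int] = (5_200_000, 6_000_000)
    filler_len: tuple[int, int] = (20_000, 60_000)
    fragmentation: int = 2
    gc_bias: float = 0.60
    spacer_len: tuple[int, int] = (300, 1_500)
    allow_gene_splitting: bool = False

    def __post_init__(self) -> None:
        if self.dot_chrom_len[1] > 5_000_000:
            raise ValueError("dot chromosomes must stay below the 5 Mb cutoff")
        if self.macro_len[0] <= 5_000_000:
            raise ValueError("macro scaffolds must exceed the 5 Mb cutoff")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")


def simulate_draft_assembly(config: SimulationConfig,
                            marker_proteins: Sequence[SequenceRecord]
                            ) -> tuple[Assembly, SyntheticTruth]:
    """Build a draft assembly with planted markers and recorded ground truth.

    Dot chromosomes are a gene-dense euchromatic arm (planted
    reverse-translated mutated markers separated by GC-biased spacer)
    followed by a tandem-repeat block, fragmented into
    ``config.fragmentation`` scaffolds with cuts outside gene bodies by
    default. Filler scaffolds are pure repeat with zero markers; macro
    scaffolds are above the cutoff. The emitted scaffold order is size
    descending, as in a size-sorted draft Hi-C map.
    """
    rng = np.random.default_rng(config.seed)
    marker_counts = [int(rng.integers(config.markers_per_dot[0],
                                      config.markers_per_dot[1] + 1))
                     for _ in range(config.n_dot_chroms)]
    if sum(marker_counts) > len(marker_proteins):
        raise ValueError(
            f"need {sum(marker_counts)} marker proteins, got {len(marker_proteins)}")

    scaffolds: list[SequenceRecord] = []
    truth = SyntheticTruth(scaffold_class={}, planted=[])
    next_protein = 0

    for d in range(config.n_dot_chroms):
        n_markers = marker_counts[d]
        proteins = marker_proteins[next_protein:next_protein + n_markers]
        next_protein += n_markers
        target_len = int(rng.integers(*config.dot_chrom_len))

        parts: list[str] = []
        gene_intervals: list[tuple[int, int]] = []   # on the chromosome
        planted_local: list[tuple[str, int, int, str]] = []
        pos = 0
        for prot in proteins:
            spacer = _codes_to_str(_random_dna(int(rng.integers(*config.spacer_len)),
                                               rng, gc=config.gc_bias))
            parts.append(spacer)
            pos += len(spacer)
            mutated = mutate_to_identity(prot.sequence, config.marker_identity, rng)
            dna = reverse_translate(mutated, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                dna = _revcomp_str(dna)
            parts.append(dna)
            gene_intervals.append((pos, pos + len(dna)))
            planted_local.append((prot.id, pos, pos + len(dna), strand))
            pos += len(dna)
        if pos >= target_len:
            raise ValueError(
                f"dot chromosome {d}: genes+spacers ({pos} bp) exceed the "
                f"target length {target_len}; increase dot_chrom_len")
        parts.append(_codes_to_str(_tandem_repeat(target_len - pos, rng)))
        chrom = "".join(parts)

        # fragmentation: cuts at uniform random positions, excluding
        # gene interiors unless splitting is explicitly allowed
        n_cuts = config.fragmentation - 1
        cuts: list[int] = []
        if n_cuts:
            if config.allow_gene_splitting:
                cuts = sorted(int(c) for c in rng.integers(1, len(chrom), size=n_cuts))
            else:
                allowed = np.ones(len(chrom), dtype=bool)
                allowed[0] = False
                for s, e in gene_intervals:
                    allowed[max(s - 1, 0):e + 1] = False
                candidates = np.flatnonzero(allowed)
                n_cuts = min(n_cuts, len(candidates))
                cuts = sorted(int(c) for c in
                              rng.choice(candidates, size=n_cuts, replace=False))
        bounds = [0, *dict.fromkeys(cuts), len(chrom)]
        for j in range(len(bounds) - 1):
            fs, fe = bounds[j], bounds[j + 1]
            sid = f"dot{d}_frag{j}"
            scaffolds.append(SequenceRecord(id=sid, sequence=chrom[fs:fe]))
            truth.scaffold_class[sid] = "dot"
            for pid, gs, ge, strand in planted_local:
                os_, oe = max(gs, fs), min(ge, fe)
                if os_ < oe:
                    truth.planted.append(PlantedMarker(
                        protein_id=pid, scaffold_id=sid, start=os_ - fs,
                        end=oe - fs, strand=strand,
                        target_identity=config.marker_identity))

    for i in range(config.n_filler_scaffolds):
        sid = f"filler{i}"
        length = int(rng.integers(*config.filler_len))
        scaffolds.append(SequenceRecord(id=sid,
                                        sequence=_codes_to_str(_tandem_repeat(length, rng))))
        truth.scaffold_class[sid] = "filler"

    for i in range(config.n_macro_scaffolds):
        sid = f"macro{i}"
        length = int(rng.integers(*config.macro_len))
        scaffolds.append(SequenceRecord(id=sid,
                                        sequence=_codes_to_str(_random_dna(length, rng))))
        truth.scaffold_class[sid] = "macro"

    scaffolds.sort(key=lambda r: (-len(r), r.id))
    return Assembly(records=scaffolds, name=f"synthetic_seed{config.seed}"), truth


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = [{"protein": p.protein_id, "scaffold": p.scaffold_id, "start": p.start,
             "end": p.end, "strand": p.strand, "target_identity": p.target_identity}
            for p in truth.planted]
    return pd.DataFrame(rows, columns=["protein", "scaffold", "start", "end",
                                       "strand", "target_identity"])


def classes_frame(truth: SyntheticTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [{"scaffold": sid, "class": cls} for sid, cls in truth.scaffold_class.items()])


# ---------------------------------------------------------------------------
# Orthogroup-table simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedOrthology:
    table: OrthogroupTable
    gene_locations: dict[str, GeneLocation]
    labels: dict[str, tuple[bool, bool]]      # og -> (should_pass_fuzzy, is_dot)
    proteomes: dict[str, dict[str, SequenceRecord]]
    dot_chroms_by_species: dict[str, set[str]]


def simulate_orthogroup_table(n_species: int = 6, n_ogs: int = 50,
                              presence_range: tuple[float, float] = (0.25, 1.0),
                              copy_probs: Sequence[float] = (0.65, 0.20, 0.10, 0.05),
                              dot_fraction: float = 0.3,
                              seed: int = 0,
                              min_species_fraction: float = 0.5,
                              max_copies: int = 3) -> SimulatedOrthology:
    """Orthogroup tables with controlled presence/copy-number and dot labels.

    The first species acts as the dot-annotated reference: dot orthogroups
    get one of its genes placed on a reference dot chromosome. Each
    orthogroup is labelled (should_pass_fuzzy, is_dot) from the generator's
    own arithmetic, so selection code can be checked against construction.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i}" for i in range(1, n_species + 1)]
    ref = species[0]
    dot_chroms = {"chr29", "chr30"}
    ogs: dict[str, dict[str, list[str]]] = {}
    labels: dict[str, tuple[bool, bool]] = {}
    gene_locations: dict[str, GeneLocation] = {}
    proteomes: dict[str, dict[str, SequenceRecord]] = {sp: {} for sp in species}
    copy_probs = np.asarray(copy_probs) / np.sum(copy_probs)
    gene_no = 0
    for g in range(n_ogs):
        og_id = f"OG{g:05d}"
        is_dot = rng.random() < dot_fraction
        presence_p = rng.uniform(*presence_range)
        present = [sp for sp in species if rng.random() < presence_p]
        if is_dot and ref not in present:
            present.insert(0, ref)
        if not present:
            present = [species[int(rng.integers(0, n_species))]]
        ancestor = random_protein(int(rng.integers(50, 150)), rng)
        by_sp: dict[str, list[str]] = {}
        max_copy_seen = 0
        for sp in present:
            n_copies = 1 + int(np.searchsorted(np.cumsum(copy_probs), rng.random()))
            max_copy_seen = max(max_copy_seen, n_copies)
            genes = []
            for c in range(n_copies):
                gid = f"{sp}_g{gene_no:06d}"
                gene_no += 1
                genes.append(gid)
                seq = mutate_to_identity(ancestor, float(rng.uniform(0.85, 1.0)), rng)
                proteomes[sp][gid] = SequenceRecord(id=gid, sequence=seq)
                if sp == ref:
                    if is_dot and c == 0:
                        chrom = sorted(dot_chroms)[int(rng.integers(0, len(dot_chroms)))]
                    else:
                        chrom = "chr1"
                    start = int(rng.integers(0, 1_000_000))
                    gene_locations[gid] = GeneLocation(sp, chrom, start, start + 1000)
            by_sp[sp] = genes
        ogs[og_id] = by_sp
        passes = (len(present) / n_species >= min_species_fraction
                  and max_copy_seen <= max_copies)
        labels[og_id] = (passes, is_dot)
    table = OrthogroupTable(orthogroups=ogs, species=species)
    return SimulatedOrthology(table=table, gene_locations=gene_locations,
                              labels=labels, proteomes=proteomes,
                              dot_chroms_by_species={ref: dot_chroms})


# ---------------------------------------------------------------------------
# Karyotype-table stand-in (synthetic)
# ---------------------------------------------------------------------------


def simulate_karyotype_table(seed: int = 0, n_species: int = 105,
                             n_discordant: int = 62,
                             n_discordant_fewer: int = 57,
                             n_excluded_outliers: int = 7) -> pd.DataFrame:
    """A synthetic karyotype/assembly table with realistic structure.

    Stands in for a curated survey of bird species with both cytology and
    chromosome-scale assemblies: the marginal composition (total species,
    species discordant by two or more chromosomes, and the subset of those
    with fewer assembled chromosomes than the karyotype predicts) is fixed
    by the arguments; per-species haploid numbers, report multiplicity,
    minority ±1 reports and flagged database outliers are randomized.
    """
    rng = np.random.default_rng(seed)
    diffs: list[int] = []
    n_more = n_discordant - n_discordant_fewer
    n_conc = n_species - n_discordant
    diffs += [int(-rng.integers(2, 16)) for _ in range(n_discordant_fewer)]
    diffs += [int(rng.integers(2, 6)) for _ in range(n_more)]
    diffs += [int(rng.choice([0, -1, 1], p=[0.5, 0.4, 0.1])) for _ in range(n_conc)]
    rng.shuffle(diffs)
    outlier_species = set(rng.choice(n_species, size=n_excluded_outliers, replace=False))
    rows = []
    for i, diff in enumerate(diffs):
        h = int(rng.integers(33, 46))
        assembly = max(h + diff, 2)
        n_rep = int(rng.integers(1, 4))
        counts = [2 * h] * n_rep
        # minority higher report never displaces the mode (ties resolve low)
        if n_rep >= 2 and rng.random() < 0.3:
            counts[-1] = 2 * h + 2
        exclude: list[int] = []
        if i in outlier_species:
            bad = 2 * h + int(rng.integers(18, 30))
            counts.append(bad)
            exclude.append(bad)
        rows.append({
            "species": f"species_{i:03d}",
            "diploid_counts": ";".join(map(str, counts)),
            "assembly_count": assembly,
            "exclude": ";".join(map(str, exclude)),
        })
    return pd.DataFrame(rows, columns=["species", "diploid_counts",
                                       "assembly_count", "exclude"])


# ---------------------------------------------------------------------------
# Fixture helper
# ---------------------------------------------------------------------------


def longest_transcript_per_gene(
        transcripts_by_gene: Mapping[str, Sequence[SequenceRecord]]
) -> dict[str, SequenceRecord]:
    """Pick each gene's longest transcript (ties by id) — fixture helper for
    emulating representative-transcript selection upstream of orthology."""
    return {gene: max(recs, key=lambda r: (len(r), r.id))
            for gene, recs in transcripts_by_gene.items() if recs}
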