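"""Built-in translated search: translation, seeding/extension, top hits."""

import io
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from dotfinder import (AlignmentHit, Assembly, SearchParams, SequenceRecord,
                       filter_min_identity, import_external_hits,
                       search_protein, search_proteins, six_frame_translate,
                       top_hit_per_protein, write_hits_gff3, write_paf)
from dotfinder.synthetic import (make_marker_proteins, mutate_to_identity,
                                 random_protein, reverse_translate)

from conftest import nw_global_identity, random_hits


# --- six-frame translation ---------------------------------------------------


def _random_dna(rng, n, with_n=False):
    alpha = "ACGTN" if with_n else "ACGT"
    return "".join(alpha[i] for i in rng.integers(0, len(alpha), size=n))


def test_six_frame_matches_biopython_oracle(rng):
    for trial in range(20):
        seq = _random_dna(rng, int(rng.integers(3, 120)), with_n=(trial % 2 == 0))
        frames = six_frame_translate(SequenceRecord(id="s", sequence=seq))
        assert len(frames) == 6
        rc = str(Seq(seq).reverse_complement())
        for fr in frames:
            src = seq if fr.strand == "+" else rc
            n_codons = (len(src) - fr.offset) // 3
            expected = str(Seq(src[fr.offset:fr.offset + 3 * n_codons]).translate())
            assert fr.aa == expected, (fr.strand, fr.offset, seq)


def test_codon_interval_maps_back_to_source():
    seq = "ATGGCCTAACGTAGGTTTCA"
    rec = SequenceRecord(id="s", sequence=seq)
    for fr in six_frame_translate(rec):
        for p, aa in enumerate(fr.aa):
            s, e = fr.codon_interval(p)
            assert 0 <= s < e <= len(seq) and e - s == 3
            codon = seq[s:e]
            if fr.strand == "-":
                codon = str(Seq(codon).reverse_complement())
            assert str(Seq(codon).translate()) == aa
        with pytest.raises(IndexError):
            fr.codon_interval(len(fr.aa))


# --- exact planted genes -----------------------------------------------------


def _plant(protein_dna: str, strand: str, flank_codons: int = 10) -> tuple[str, int]:
    """Embed a coding sequence between in-frame stop codons; returns
    (scaffold sequence, genomic start of the gene)."""
    if strand == "-":
        protein_dna = str(Seq(protein_dna).reverse_complement())
        stop = "TTA"          # reads TAA on the reverse strand
    else:
        stop = "TAA"
    return stop * flank_codons + protein_dna + stop * flank_codons, 3 * flank_codons


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exact_gene_identity_one_and_exact_span(rng, strand):
    prot = SequenceRecord(id="p", sequence=random_protein(120, rng))
    dna = reverse_translate(prot.sequence, rng)
    scaffold, start = _plant(dna, strand)
    asm = Assembly([SequenceRecord(id="s1", sequence=scaffold)])
    hits = search_protein(prot, asm)
    assert hits, "planted gene not found"
    top = hits[0]
    assert top.identity == pytest.approx(1.0)
    assert top.matches == top.aln_len == len(prot.sequence)
    assert (top.query_start, top.query_end) == (0, len(prot.sequence))
    assert top.strand == strand
    assert (top.target_start, top.target_end) == (start, start + len(dna))


def test_hits_sorted_by_score_then_deterministic(rng):
    prots = make_marker_proteins(5, 42)
    parts, pos = [], 0
    for p in prots:
        dna = reverse_translate(p.sequence, rng)
        seg, _ = _plant(dna, "+", flank_codons=4)
        parts.append(seg)
    asm = Assembly([SequenceRecord(id="s1", sequence="".join(parts))])
    hits = search_proteins(prots, asm)
    keys = [(-h.score, -h.identity, -h.aln_len, h.target_id, h.target_start, h.query_id)
            for h in hits]
    assert keys == sorted(keys)
    assert {h.query_id for h in hits} >= {p.id for p in prots}


def test_mutated_gene_identity_tracks_nw_oracle(rng):
    """Identity of hits against diverged genes stays within 0.03 of a full
    Needleman-Wunsch identity on the protein pair."""
    errors = []
    for trial in range(12):
        prot = SequenceRecord(id=f"p{trial}", sequence=random_protein(150, rng))
        target_ident = float(rng.uniform(0.75, 0.95))
        mutated = mutate_to_identity(prot.sequence, target_ident, rng)
        scaffold, _ = _plant(reverse_translate(mutated, rng),
                             "+" if trial % 2 else "-")
        asm = Assembly([SequenceRecord(id="s1", sequence=scaffold)])
        hits = search_protein(prot, asm)
        assert hits, f"diverged gene at identity {target_ident:.2f} not found"
        oracle = nw_global_identity(prot.sequence, mutated)
        errors.append(abs(hits[0].identity - oracle))
    assert max(errors) <= 0.03


def test_no_hits_on_unrelated_sequence(rng):
    prot = SequenceRecord(id="p", sequence=random_protein(100, rng))
    asm = Assembly([SequenceRecord(id="s1",
                                   sequence=_random_dna(rng, 20_000))])
    hits = search_protein(prot, asm)
    # random DNA may contain short chance seeds, but nothing near full length
    assert all(h.aln_len < 50 for h in hits)


def test_search_empty_inputs(rng):
    asm = Assembly([SequenceRecord(id="s1", sequence="ACGTACGTACGT")])
    assert search_proteins([], asm) == []
    prot = SequenceRecord(id="p", sequence=random_protein(60, rng))
    tiny = Assembly([SequenceRecord(id="s1", sequence="ACGT")])
    assert search_proteins([prot], tiny) == []


def test_search_params_validation():
    with pytest.raises(ValueError):
        SearchParams(seed_word=2)
    with pytest.raises(ValueError):
        SearchParams(min_identity=1.5)


def test_min_score_suppresses_short_chance_hits(rng):
    prot = SequenceRecord(id="p", sequence=random_protein(100, rng))
    asm = Assembly([SequenceRecord(id="s1", sequence=_random_dna(rng, 50_000))])
    for h in search_protein(prot, asm, SearchParams(min_score=40)):
        assert h.score >= 40


# --- top-hit selection --------------------------------------------------------


def _ranking_oracle(hits):
    """Independent per-query argmax over the documented ranking key."""
    best = {}
    for h in hits:
        key = (-h.score, -h.identity, -h.aln_len, h.target_id, h.target_start)
        if h.query_id not in best or key < best[h.query_id][0]:
            best[h.query_id] = (key, h)
    return {q: h for q, (k, h) in best.items()}


def test_top_hit_matches_argmax_oracle(rng):
    hits = random_hits(rng, 400)
    assert top_hit_per_protein(hits) == _ranking_oracle(hits)


def test_top_hit_permutation_invariant(rng):
    hits = random_hits(rng, 300)
    base = top_hit_per_protein(hits)
    pyrng = random.Random(7)
    for _ in range(10):
        shuffled = hits[:]
        pyrng.shuffle(shuffled)
        assert top_hit_per_protein(shuffled) == base


def test_top_hit_empty():
    assert top_hit_per_protein([]) == {}


# --- identity filter ----------------------------------------------------------


def _hit_with_identity(matches, aln_len, qid="p"):
    return AlignmentHit(query_id=qid, query_len=aln_len, query_start=0,
                        query_end=aln_len, target_id="s", target_len=10 * aln_len,
                        target_start=0, target_end=3 * aln_len, strand="+",
                        matches=matches, aln_len=aln_len, score=matches,
                        identity=matches / aln_len)


def test_identity_filter_boundary():
    at = _hit_with_identity(70, 100, "at")          # exactly 0.70
    below = _hit_with_identity(699, 1000, "below")  # 0.699
    kept = filter_min_identity([at, below], 0.70)
    assert kept == [at]
    mapping = filter_min_identity({"at": at, "below": below}, 0.70)
    assert mapping == {"at": at}


def test_identity_filter_monotone_in_threshold(rng):
    hits = random_hits(rng, 300)
    prev = set(id(h) for h in filter_min_identity(hits, 0.0))
    assert len(prev) == len(hits)
    for t in (0.2, 0.5, 0.7, 0.9, 1.0):
        cur = set(id(h) for h in filter_min_identity(hits, t))
        assert cur <= prev
        prev = cur


# --- external ingestion -------------------------------------------------------


def test_import_external_hits_round_trips(rng):
    hits = random_hits(rng, 50)
    paf = io.StringIO()
    write_paf(hits, paf)
    paf.seek(0)
    back = import_external_hits(paf, dialect="paf")
    assert [(h.query_id, h.target_id, h.target_start) for h in back] == \
        [(h.query_id, h.target_id, h.target_start) for h in hits]
    gff = io.StringIO()
    write_hits_gff3(hits, gff)
    gff.seek(0)
    back = import_external_hits(gff, dialect="miniprot-gff3")
    assert [(h.query_id, h.target_id, h.target_start) for h in back] == \
        [(h.query_id, h.target_id, h.target_start) for h in hits]
    with pytest.raises(ValueError, match="dialect"):
        import_external_hits(io.StringIO(""), dialect="sam")
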