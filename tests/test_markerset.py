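"""Fuzzy orthogroup selection, dot filtering and greedy clustering."""

import io

import numpy as np
import pytest

from dotfinder import (FuzzyCriteria, GeneLocation, OrthogroupTable,
                       SequenceRecord, build_markerset, copy_number_table,
                       filter_dot_orthogroups, greedy_cluster,
                       select_fuzzy, simulate_orthogroup_table)
from dotfinder.markerset import read_orthogroups_tsv, write_orthogroups_tsv
from dotfinder.synthetic import mutate_to_identity, random_protein

from conftest import shorter_identity

DOT_SET = {"16"} | {str(c) for c in range(29, 38)}   # chicken dot chromosomes


def _random_table(rng, n_species=6, n_ogs=30):
    species = [f"sp{i}" for i in range(n_species)]
    ogs = {}
    gene_no = 0
    for g in range(n_ogs):
        by_sp = {}
        for sp in species:
            n = int(rng.integers(0, 5))
            if n:
                by_sp[sp] = [f"{sp}_g{gene_no + i}" for i in range(n)]
                gene_no += n
        ogs[f"OG{g}"] = by_sp
    return OrthogroupTable(orthogroups=ogs, species=species)


# --- copy_number_table -------------------------------------------------------


def test_copy_number_table_counts_and_absent_species():
    table = OrthogroupTable(
        orthogroups={"OG1": {"A": ["g1", "g2"], "B": ["g3"]}},
        species=["A", "B", "C"])
    assert copy_number_table(table) == {"OG1": {"A": 2, "B": 1, "C": 0}}


def test_copy_number_table_empty():
    table = OrthogroupTable(orthogroups={}, species=["A"])
    assert copy_number_table(table) == {}


def test_copy_number_conservation(rng):
    for _ in range(50):
        table = _random_table(rng)
        counts = copy_number_table(table)
        total_genes = sum(len(g) for by_sp in table.orthogroups.values()
                          for g in by_sp.values())
        assert sum(sum(r.values()) for r in counts.values()) == total_genes


# --- select_fuzzy ------------------------------------------------------------


def test_select_fuzzy_boundary_inclusive():
    # present in exactly half the species meets "at least 50%"
    counts = {"OG1": {f"s{i}": (1 if i < 6 else 0) for i in range(12)}}
    assert select_fuzzy(counts) == {"OG1"}


def test_select_fuzzy_copy_cap():
    counts = {"OG1": {"A": 4, "B": 1, "C": 1, "D": 1}}
    assert select_fuzzy(counts) == set()
    counts["OG1"]["A"] = 3
    assert select_fuzzy(counts) == {"OG1"}


def test_select_fuzzy_matches_exhaustive_oracle(rng):
    crit = FuzzyCriteria()
    for _ in range(1000):
        n_sp = int(rng.integers(2, 9))
        counts = {f"OG{g}": {f"s{i}": int(rng.integers(0, 6)) for i in range(n_sp)}
                  for g in range(int(rng.integers(1, 6)))}
        expected = set()
        for og, row in counts.items():       # independent re-evaluation
            present = [c for c in row.values() if c > 0]
            if len(present) / n_sp >= 0.5 and all(c <= 3 for c in row.values()):
                expected.add(og)
        assert select_fuzzy(counts, crit) == expected


def test_select_fuzzy_monotone_in_criteria(rng):
    counts = {f"OG{g}": {f"s{i}": int(rng.integers(0, 6)) for i in range(8)}
              for g in range(200)}
    strict = select_fuzzy(counts, FuzzyCriteria(min_species_fraction=0.75, max_copies=2))
    relaxed = select_fuzzy(counts, FuzzyCriteria(min_species_fraction=0.5, max_copies=3))
    very_relaxed = select_fuzzy(counts, FuzzyCriteria(min_species_fraction=0.25, max_copies=5))
    assert strict <= relaxed <= very_relaxed


# --- filter_dot_orthogroups --------------------------------------------------


def _loc_table():
    return {
        "GG_g1": GeneLocation("GGswu", "29"),
        "GG_g2": GeneLocation("GGswu", "1"),
        "TG_g1": GeneLocation("bTaeGut1", "30"),
    }


def test_filter_dot_retains_dot_member():
    table = OrthogroupTable(
        orthogroups={"OG1": {"GGswu": ["GG_g1"], "other": ["o1"]},
                     "OG2": {"GGswu": ["GG_g2"], "other": ["o2"]}},
        species=["GGswu", "other"])
    kept = filter_dot_orthogroups({"OG1", "OG2"}, table, _loc_table(),
                                  {"GGswu": DOT_SET})
    assert kept == {"OG1"}


def test_filter_dot_union_over_reference_species(rng):
    for trial in range(200):
        n_og = int(rng.integers(1, 10))
        table_rows = {}
        locations = {}
        for g in range(n_og):
            by_sp = {}
            for sp in ("refA", "refB"):
                if rng.random() < 0.7:
                    gid = f"{sp}_g{trial}_{g}"
                    by_sp[sp] = [gid]
                    chrom = "dot" if rng.random() < 0.4 else "macro"
                    locations[gid] = GeneLocation(sp, chrom)
            table_rows[f"OG{g}"] = by_sp
        table = OrthogroupTable(orthogroups=table_rows, species=["refA", "refB"])
        ids = set(table_rows)
        both = filter_dot_orthogroups(ids, table, locations,
                                      {"refA": {"dot"}, "refB": {"dot"}})
        only_a = filter_dot_orthogroups(ids, table, locations, {"refA": {"dot"}})
        only_b = filter_dot_orthogroups(ids, table, locations, {"refB": {"dot"}})
        assert both == only_a | only_b


def test_filter_dot_unknown_location_warns_as_non_dot():
    table = OrthogroupTable(orthogroups={"OG1": {"GGswu": ["GG_missing"]}},
                            species=["GGswu"])
    with pytest.warns(UserWarning, match="no location"):
        kept = filter_dot_orthogroups({"OG1"}, table, {}, {"GGswu": DOT_SET})
    assert kept == set()


# --- greedy_cluster ----------------------------------------------------------


def test_greedy_cluster_identical_pair():
    seq = random_protein(80, np.random.default_rng(1))
    recs = [SequenceRecord(id="a", sequence=seq), SequenceRecord(id="b", sequence=seq)]
    ms = greedy_cluster(recs)
    assert len(ms.proteins) == 1
    rep = ms.proteins[0].id
    assert ms.cluster_map == {"a": rep, "b": rep}


def test_greedy_cluster_dissimilar_pair():
    rng = np.random.default_rng(2)
    a, b = random_protein(100, rng), random_protein(100, rng)
    assert shorter_identity(a, b) < 0.9
    ms = greedy_cluster([SequenceRecord(id="a", sequence=a),
                         SequenceRecord(id="b", sequence=b)])
    assert len(ms.proteins) == 2


def test_greedy_cluster_empty():
    ms = greedy_cluster([])
    assert ms.proteins == [] and ms.cluster_map == {}


def _quadratic_oracle(records, threshold):
    """No-screen greedy clustering with the independent DP identity."""
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps, cmap = [], {}
    for rec in ordered:
        for rep in reps:
            if shorter_identity(rec.sequence, rep.sequence) >= threshold:
                cmap[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            cmap[rec.id] = rec.id
    return [r.id for r in reps], cmap


@pytest.mark.parametrize("threshold", [0.90, 0.95])
def test_greedy_cluster_matches_quadratic_oracle(rng, threshold):
    # families of mutated variants plus unrelated singletons
    records = []
    for f in range(8):
        ancestor = random_protein(int(rng.integers(50, 200)), rng)
        for v in range(int(rng.integers(1, 6))):
            ident = float(rng.uniform(0.80, 1.0))
            records.append(SequenceRecord(
                id=f"f{f}v{v}",
                sequence=mutate_to_identity(ancestor, ident, rng)))
    while len(records) < 50:
        records.append(SequenceRecord(id=f"solo{len(records)}",
                                      sequence=random_protein(int(rng.integers(50, 200)), rng)))
    ms = greedy_cluster(records, identity_threshold=threshold)
    rep_ids, cmap = _quadratic_oracle(records, threshold)
    assert sorted(r.id for r in ms.proteins) == sorted(rep_ids)
    assert ms.cluster_map == cmap


def test_greedy_cluster_member_identity_invariant(rng):
    records = [SequenceRecord(id=f"r{i}", sequence=random_protein(int(rng.integers(40, 120)), rng))
               for i in range(20)]
    ancestor = records[0].sequence
    records += [SequenceRecord(id=f"m{i}", sequence=mutate_to_identity(ancestor, 0.95, rng))
                for i in range(5)]
    ms = greedy_cluster(records)
    assert 1 <= len(ms.proteins) <= len(records)
    by_id = {r.id: r.sequence for r in records}
    for member, rep in ms.cluster_map.items():
        if member != rep:
            assert shorter_identity(by_id[member], by_id[rep]) >= 0.90


# --- build_markerset ---------------------------------------------------------


def test_build_markerset_only_dot_orthogroups():
    sim = simulate_orthogroup_table(n_species=4, n_ogs=12, dot_fraction=0.4,
                                    presence_range=(0.9, 1.0), seed=7)
    ms = build_markerset(sim.table, sim.proteomes, sim.gene_locations,
                         sim.dot_chroms_by_species)
    dot_ogs = {og for og, (passes, is_dot) in sim.labels.items() if passes and is_dot}
    assert len(ms.proteins) > 0
    for pid, (og, sp) in ms.provenance.items():
        assert og in dot_ogs


def test_build_markerset_strict_criteria_is_subset():
    sim = simulate_orthogroup_table(n_species=4, n_ogs=30, dot_fraction=0.5, seed=11)
    relaxed = build_markerset(sim.table, sim.proteomes, sim.gene_locations,
                              sim.dot_chroms_by_species, FuzzyCriteria())
    strict = build_markerset(sim.table, sim.proteomes, sim.gene_locations,
                             sim.dot_chroms_by_species,
                             FuzzyCriteria(min_species_fraction=1.0, max_copies=1))
    strict_ogs = {og for og, _ in strict.provenance.values()}
    relaxed_ogs = {og for og, _ in relaxed.provenance.values()}
    assert strict_ogs <= relaxed_ogs


def test_build_markerset_invariant_under_row_permutation():
    sim = simulate_orthogroup_table(n_species=4, n_ogs=20, dot_fraction=0.5, seed=3)
    ms1 = build_markerset(sim.table, sim.proteomes, sim.gene_locations,
                          sim.dot_chroms_by_species)
    reversed_ogs = dict(reversed(list(sim.table.orthogroups.items())))
    table2 = OrthogroupTable(orthogroups=reversed_ogs, species=sim.table.species)
    ms2 = build_markerset(table2, sim.proteomes, sim.gene_locations,
                          sim.dot_chroms_by_species)
    assert sorted(r.id for r in ms1.proteins) == sorted(r.id for r in ms2.proteins)
    assert ms1.cluster_map == ms2.cluster_map


def test_build_markerset_unresolvable_gene_is_hard_error():
    sim = simulate_orthogroup_table(n_species=4, n_ogs=10, dot_fraction=1.0,
                                    presence_range=(0.9, 1.0), seed=5)
    retained_og = next(og for og, (passes, is_dot) in sim.labels.items()
                       if passes and is_dot)
    victim_sp, genes = next(iter(sim.table.orthogroups[retained_og].items()))
    victim = genes[0]
    broken = {sp: dict(g) for sp, g in sim.proteomes.items()}
    del broken[victim_sp][victim]
    with pytest.raises(ValueError, match=victim):
        build_markerset(sim.table, broken, sim.gene_locations,
                        sim.dot_chroms_by_species)


# --- orthogroup TSV dialect --------------------------------------------------


def test_orthogroups_tsv_round_trip():
    table = OrthogroupTable(
        orthogroups={"OG0": {"A": ["a1", "a2"], "B": ["b1"]},
                     "OG1": {"B": ["b2"]}},
        species=["A", "B"])
    buf = io.StringIO()
    write_orthogroups_tsv(table, buf)
    buf.seek(0)
    back = read_orthogroups_tsv(buf)
    assert back.species == table.species
    assert back.orthogroups == table.orthogroups
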