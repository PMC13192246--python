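"""Build a conserved dot-chromosome marker protein set from orthogroup tables.

Simulates an orthology run over six species (the first carries dot-chromosome
annotations), applies the fuzzy conservation criteria (present in >=50% of
species, <=3 copies each), keeps orthogroups with a member on a reference dot
chromosome, and collapses redundancy with CD-HIT-style greedy clustering.
"""

from dotfinder import (FuzzyCriteria, build_markerset, copy_number_table,
                       select_fuzzy, simulate_orthogroup_table)
from dotfinder.markerset import filter_dot_orthogroups

sim = simulate_orthogroup_table(n_species=6, n_ogs=80, dot_fraction=0.3, seed=3)
table = sim.table
print(f"orthogroup table: {len(table.orthogroups)} orthogroups, "
      f"{len(table.species)} species")

counts = copy_number_table(table)
fuzzy = select_fuzzy(counts, FuzzyCriteria())
print(f"fuzzy criteria (>=50% presence, <=3 copies): {len(fuzzy)} pass")

dot_ogs = filter_dot_orthogroups(fuzzy, table, sim.gene_locations,
                                 sim.dot_chroms_by_species)
print(f"with a member on a reference dot chromosome: {len(dot_ogs)}")

ms = build_markerset(table, sim.proteomes, sim.gene_locations,
                     sim.dot_chroms_by_species)
pooled = len(ms.cluster_map)
print(f"pooled member proteins: {pooled}")
print(f"after clustering at 0.90 identity: {len(ms.proteins)} representatives")
print("\nfirst five representatives (id, orthogroup, species, length):")
for rec in ms.proteins[:5]:
    og, sp = ms.provenance[rec.id]
    print(f"  {rec.id:<14} {og:<9} {sp:<5} {len(rec)} aa")
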