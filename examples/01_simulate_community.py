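"""Simulate a clonal strain community with known ground truth.

Builds 3 strain types (GSTs) x 4 strains on a 120 kb genome, prints the
true tree and the within/between-GST SNV distance structure that the rest
of the toolkit relies on.
"""

import gstprofiler as gp

cfg = gp.SimulationConfig(
    seed=7, genome_length=120_000, n_genes=100, gene_length_range=(400, 900),
    n_gsts=3, strains_per_gst=4, within_gst_snv=50, between_gst_snv=1200,
)
coll = gp.simulate_strain_genomes(cfg)

print(f"{len(coll.records)} genomes; type strain: {coll.type_strain_id}")
print(coll.tree.ascii_art())

ref = gp.build_core_reference(coll.ancestral_core_genes)
snvs = {g: gp.call_snvs(g, coll.core_genes_of(g), ref) for g in coll.genome_ids}
dm = gp.distance_matrix(list(snvs.values()), ref)

within, between = [], []
ids = coll.genome_ids
for i, a in enumerate(ids):
    for b in ids[i + 1 :]:
        (within if coll.genome_gst[a] == coll.genome_gst[b] else between).append(dm.get(a, b))
print(f"max within-GST SNV distance:  {max(within)}  (cap {cfg.within_gst_snv})")
print(f"min between-GST SNV distance: {min(between)} (floor {cfg.between_gst_snv})")
# Strains of one GST are nearly clonal; different GSTs are far apart —
# the separation a clade-merging threshold between the two will recover.
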