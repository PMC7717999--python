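"""Cluster a phylogeny into genome-based strain types (GSTs).

Prioritizes genomes (assembly level, then N50), merges sister clades under
a pairwise SNV cap starting from the type strain, picks representatives,
and collapses the tree into the custom taxonomy used for classification.
"""

import gstprofiler as gp

cfg = gp.SimulationConfig(
    seed=7, genome_length=120_000, n_genes=100, gene_length_range=(400, 900),
    n_gsts=3, strains_per_gst=4, within_gst_snv=50, between_gst_snv=1200,
)
coll = gp.simulate_strain_genomes(cfg)
ref = gp.build_core_reference(coll.ancestral_core_genes)
snvs = {g: gp.call_snvs(g, coll.core_genes_of(g), ref) for g in coll.genome_ids}
dm = gp.distance_matrix(list(snvs.values()), ref)

priority = gp.prioritize_genomes(coll.records)
print("priority head:", priority[:4])

# cap of 200 SNVs sits between the within-GST max (~50) and between-GST
# floor (~2400), the analog of 20,000 SNVs on a ~1.1 Mb species core
assignment = gp.cluster_gsts(coll.tree, dm, priority, threshold=200,
                             first_seed=coll.type_strain_id)
for label, members in assignment.gsts.items():
    rep = assignment.representative[label]
    print(f"GST {label}: {len(members)} genomes, representative {rep}")

taxonomy = gp.build_taxonomy(coll.tree, assignment)
print(taxonomy.to_frame().to_string(index=False))
# Each GST clade is now one taxonomy leaf; k-mers shared by several GSTs
# will map to the internal (LCA) nodes of this tree.
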