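"""Shared synthetic fixtures.

Two strain communities are generated once per session:

* ``coll3`` — 3 GSTs x 4 strains on a 120 kb genome, used by the typing,
  reference and pan-genome tests.
* ``coll5`` — 5 GSTs x 2 strains on a 200 kb genome, used by the
  classification / cohort tests (the desk-scale analog of a low-complexity
  sample containing five strain types).

Between-GST substitution budgets are kept near 2-4% of the core length so
that cross-GST copies of a gene family stay above the 90% identity floor,
mirroring the real-data regime (a 20,000 SNV cap on a ~1.1 Mb core).
"""

import numpy as np
import pytest

import gstprofiler as gp


@pytest.fixture(scope="session")
def coll3():
    cfg = gp.SimulationConfig(
        seed=7,
        genome_length=120_000,
        n_genes=100,
        gene_length_range=(400, 900),
        n_gsts=3,
        strains_per_gst=4,
        within_gst_snv=50,
        between_gst_snv=1200,
    )
    return gp.simulate_strain_genomes(cfg)


@pytest.fixture(scope="session")
def typed3(coll3):
    ref = gp.build_core_reference(coll3.ancestral_core_genes)
    snvs = {g: gp.call_snvs(g, coll3.core_genes_of(g), ref) for g in coll3.genome_ids}
    dm = gp.distance_matrix(list(snvs.values()), ref)
    priority = gp.prioritize_genomes(coll3.records)
    assignment = gp.cluster_gsts(
        coll3.tree, dm, priority, threshold=200, first_seed=coll3.type_strain_id
    )
    taxonomy = gp.build_taxonomy(coll3.tree, assignment)
    return {
        "reference": ref,
        "snvs": snvs,
        "dm": dm,
        "priority": priority,
        "assignment": assignment,
        "taxonomy": taxonomy,
    }


@pytest.fixture(scope="session")
def pan3(coll3):
    cds = [
        (f"{gid}|{fam}", gid, coll3.sequences[gid][a:b])
        for gid in coll3.genome_ids
        for fam, a, b in coll3.gene_intervals[gid]
    ]
    pan = gp.cluster_genes(cds)
    return gp.label_core_singleton(pan)


@pytest.fixture(scope="session")
def coll5():
    cfg = gp.SimulationConfig(
        seed=19,
        genome_length=200_000,
        n_genes=160,
        gene_length_range=(400, 900),
        n_gsts=5,
        strains_per_gst=2,
        within_gst_snv=60,
        between_gst_snv=1500,
    )
    return gp.simulate_strain_genomes(cfg)


@pytest.fixture(scope="session")
def typed5(coll5):
    ref = gp.build_core_reference(coll5.ancestral_core_genes)
    snvs = {g: gp.call_snvs(g, coll5.core_genes_of(g), ref) for g in coll5.genome_ids}
    dm = gp.distance_matrix(list(snvs.values()), ref)
    priority = gp.prioritize_genomes(coll5.records)
    assignment = gp.cluster_gsts(
        coll5.tree, dm, priority, threshold=250, first_seed=coll5.type_strain_id
    )
    taxonomy = gp.build_taxonomy(coll5.tree, assignment)
    return {
        "reference": ref,
        "snvs": snvs,
        "dm": dm,
        "priority": priority,
        "assignment": assignment,
        "taxonomy": taxonomy,
    }


@pytest.fixture(scope="session")
def db5(coll5, typed5):
    assignment = typed5["assignment"]
    rep_genes = {
        label: list(coll5.core_genes_of(rep).values())
        for label, rep in assignment.representative.items()
    }
    return gp.build_kmer_db(rep_genes, typed5["taxonomy"], k=31)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
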