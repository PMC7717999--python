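"""Reference pan-genome: greedy gene-family clustering and gene profiling.

Coding sequences are clustered greedily at 90% nucleotide identity with 90%
bidirectional alignment coverage: sequences are visited longest-first and
join the first existing cluster whose representative they match, otherwise
found a new cluster. Per-sample gene composition is the set of clusters hit
by the sample's predicted CDSs under the same thresholds.

An exact-k-mer candidate filter narrows which representatives are aligned;
at the 90% identity floor, matching pairs always share seed k-mers, so the
filter trades nothing for speed at these scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import align_stats, passes_thresholds
from .kmers import kmer_set

MIN_ID = 0.90
MIN_COV = 0.90
CORE_FRACTION = 0.95
_FILTER_K = 15


@dataclass
class GeneCluster:
    cluster_id: str
    representative_id: str
    representative_seq: str
    members: list[tuple[str, str]]  # (gene_id, genome_id)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def genomes(self) -> set[str]:
        return {g for _, g in self.members}


@dataclass
class PanGenome:
    clusters: dict[str, GeneCluster]
    n_genomes: int = 0
    core_flags: dict[str, bool] = field(default_factory=dict)
    singleton_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        self._rep_index: dict[int, list[str]] | None = None

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.clusters)

    def rep_index(self) -> dict[int, list[str]]:
        """Exact-k-mer index over representatives (built lazily)."""
        if self._rep_index is None:
            idx: dict[int, list[str]] = {}
            for cid, cl in self.clusters.items():
                for km in kmer_set(cl.representative_seq, _FILTER_K).tolist():
                    idx.setdefault(km, []).append(cid)
            self._rep_index = idx
        return self._rep_index

    def candidates(self, seq: str) -> list[str]:
        """Cluster ids sharing at least one seed k-mer, in creation order."""
        idx = self.rep_index()
        hits: set[str] = set()
        for km in kmer_set(seq, _FILTER_K).tolist():
            hits.update(idx.get(km, ()))
        return sorted(hits, key=lambda c: int(c.split("_")[-1]))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            (
                cid,
                cl.n_members,
                len(cl.genomes),
                self.core_flags.get(cid, False),
                self.singleton_flags.get(cid, False),
            )
            for cid, cl in self.clusters.items()
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "n_members", "n_genomes", "core", "singleton"]
        )

    def members_frame(self) -> pd.DataFrame:
        rows = [
            (cid, gid, genome, gid == cl.representative_id)
            for cid, cl in self.clusters.items()
            for gid, genome in cl.members
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "member_id", "genome_id", "is_representative"]
        )


@dataclass
class GeneProfile:
    """Presence set of pan-genome clusters in one sample."""

    sample_id: str
    present: frozenset[str]
    n_hits: int


def cluster_genes(
    cds: list[tuple[str, str, str]],
    min_id: float = MIN_ID,
    min_cov: float = MIN_COV,
    prefix: str = "clu",
) -> PanGenome:
    """Greedy incremental clustering of (gene_id, genome_id, sequence) CDSs.

    Visiting order is descending length with gene-id tie-break, so the
    longest member of each family founds and represents it. A sequence
    joins the first (oldest) cluster whose representative it matches at
    >= min_id identity over >= min_cov of both sequences.
    """
    if not cds:
        raise ValueError("empty CDS input")
    ordered = sorted(cds, key=lambda t: (-len(t[2]), t[0]))
    pan = PanGenome(clusters={})
    n = 0
    for gene_id, genome_id, seq in ordered:
        placed = None
        for cid in pan.candidates(seq):
            rep = pan.clusters[cid].representative_seq
            if passes_thresholds(seq, rep, min_id, min_cov):
                placed = cid
                break
        if placed is None:
            n += 1
            cid = f"{prefix}_{n}"
            pan.clusters[cid] = GeneCluster(cid, gene_id, seq, [(gene_id, genome_id)])
            if pan._rep_index is not None:
                for km in kmer_set(seq, _FILTER_K).tolist():
                    pan._rep_index.setdefault(km, []).append(cid)
        else:
            pan.clusters[placed].members.append((gene_id, genome_id))
    pan.n_genomes = len({g for _, g, _ in cds})
    return pan


def label_core_singleton(
    pan: PanGenome, n_genomes: int | None = None, core_fraction: float = CORE_FRACTION
) -> PanGenome:
    """Flag clusters as core (present in over ``core_fraction`` of genomes,
    strict) or singleton (exactly one member)."""
    n = pan.n_genomes if n_genomes is None else n_genomes
    for cid, cl in pan.clusters.items():
        pan.core_flags[cid] = len(cl.genomes) > core_fraction * n
        pan.singleton_flags[cid] = cl.n_members == 1
    return pan


def drop_decoy_clusters(pan: PanGenome, decoy_genomes: set[str]) -> PanGenome:
    """Remove clusters containing any member from a decoy genome.

    Stands in for restricting the pan-genome to species-specific clusters:
    families shared with decoy (other-species) genomes are discarded.
    """
    keep = {
        cid: cl for cid, cl in pan.clusters.items() if not (cl.genomes & decoy_genomes)
    }
    out = PanGenome(clusters=keep, n_genomes=pan.n_genomes)
    out.core_flags = {c: v for c, v in pan.core_flags.items() if c in keep}
    out.singleton_flags = {c: v for c, v in pan.singleton_flags.items() if c in keep}
    return out


def profile_genes(
    predicted_cds: list[tuple[str, str]],
    pan: PanGenome,
    min_id: float = MIN_ID,
    min_cov: float = MIN_COV,
    sample_id: str = "sample",
) -> GeneProfile:
    """Match predicted CDSs against cluster representatives.

    Each CDS's best hit (highest identity among representatives passing
    both thresholds) marks that cluster present; ``n_hits`` counts matched
    CDSs. A fragment covering less than ``min_cov`` of the representative
    cannot hit it, whatever its identity.
    """
    present: set[str] = set()
    n_hits = 0
    for _, seq in predicted_cds:
        best_cid, best_ident = None, -1.0
        for cid in pan.candidates(seq):
            rep = pan.clusters[cid].representative_seq
            st = align_stats(seq, rep, max_dist_frac=2.0 * (1.0 - min_id) + 0.05)
            if st.identity >= min_id and st.cov_a >= min_cov and st.cov_b >= min_cov:
                if st.identity > best_ident:
                    best_cid, best_ident = cid, st.identity
        if best_cid is not None:
            present.add(best_cid)
            n_hits += 1
    return GeneProfile(sample_id, frozenset(present), n_hits)


def true_cluster_content(pan: PanGenome, genome_id: str) -> frozenset[str]:
    """Cluster ids that have a member from the given genome (truth helper)."""
    return frozenset(
        cid for cid, cl in pan.clusters.items() if genome_id in cl.genomes
    )
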