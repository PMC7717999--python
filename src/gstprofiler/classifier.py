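"""k-mer LCA database and read classification over the GST taxonomy.

The database maps each canonical k-mer of the representative core genes to
the lowest common ancestor of the GSTs carrying it. Reads are classified by
the classic root-to-leaf path score: each node's hit count contributes to
every path through it, the read is assigned to the deepest node of the
maximum-scoring path, and equal-scoring paths resolve to the LCA of their
deepest nodes. Internal-node counts are then redistributed to GST leaves
proportionally to the leaves' direct counts to produce abundance profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .kmers import canonical_kmers, kmer_set
from .taxonomy import TaxonomyTree

DEFAULT_K = 31


@dataclass
class KmerDb:
    k: int
    kmer_to_node: dict[int, int]
    taxonomy: TaxonomyTree

    def save(self, path) -> None:
        kmers = np.fromiter(self.kmer_to_node.keys(), dtype=np.uint64, count=len(self.kmer_to_node))
        nodes = np.fromiter(self.kmer_to_node.values(), dtype=np.int32, count=len(self.kmer_to_node))
        np.savez_compressed(path, k=self.k, kmers=kmers, nodes=nodes)

    @classmethod
    def load(cls, path, taxonomy: TaxonomyTree) -> "KmerDb":
        data = np.load(path)
        mapping = dict(zip(data["kmers"].tolist(), data["nodes"].tolist()))
        return cls(int(data["k"]), mapping, taxonomy)


@dataclass
class AbundanceProfile:
    """Per-sample GST abundance after internal-count redistribution."""

    sample_id: str
    counts: dict[str, float]      # GST label -> re-estimated read count
    relative: dict[str, float]    # GST label -> fraction (sums to 1)
    n_classified: int
    empty: bool = False


def build_kmer_db(
    rep_core_genes: dict[str, list[str]],
    taxonomy: TaxonomyTree,
    k: int = DEFAULT_K,
) -> KmerDb:
    """Map every canonical k-mer of the GST representatives to its LCA.

    ``rep_core_genes`` maps GST label -> that representative's core gene
    sequences. Sequences shorter than k contribute nothing.
    """
    leaf_of = taxonomy.gst_leaves
    mapping: dict[int, int] = {}
    for gst, seqs in rep_core_genes.items():
        node = leaf_of[f"GST {gst}"] if f"GST {gst}" in leaf_of else leaf_of[gst]
        gst_kmers = np.unique(np.concatenate(
            [kmer_set(s, k) for s in seqs] or [np.empty(0, dtype=np.uint64)]
        ))
        for km in gst_kmers.tolist():
            prev = mapping.get(km)
            mapping[km] = node if prev is None else taxonomy.lca([prev, node])
    return KmerDb(k, mapping, taxonomy)


def classify_read(read: str, db: KmerDb) -> int | None:
    """Classify one read; returns a taxonomy node id or None (unclassified)."""
    hits: Counter[int] = Counter()
    for km in canonical_kmers(read, db.k).tolist():
        node = db.kmer_to_node.get(km)
        if node is not None:
            hits[node] += 1
    if not hits:
        return None
    tax = db.taxonomy
    # score each root-to-leaf path by the sum of hit counts on its nodes
    leaf_scores: Counter[int] = Counter()
    for node, count in hits.items():
        for leaf in tax.leaves_under(node):
            leaf_scores[leaf] += count
    best = max(leaf_scores.values())
    winners = [leaf for leaf, s in leaf_scores.items() if s == best]
    if len(winners) == 1:
        return winners[0]
    return tax.lca(winners)


def classify_reads(reads: list[tuple[str, str]], db: KmerDb) -> dict[str, int | None]:
    """Per-read assignments (read id -> node id or None)."""
    return {rid: classify_read(seq, db) for rid, seq in reads}


def estimate_abundance(
    assignments: dict[str, int | None],
    taxonomy: TaxonomyTree,
    sample_id: str = "sample",
) -> AbundanceProfile:
    """Redistribute internal-node counts to GST leaves and normalize.

    A node's count is shared among its descendant GST leaves proportionally
    to their direct-assignment counts (uniformly when all are zero). The
    total redistributed count equals the number of classified reads.
    """
    if not assignments:
        raise ValueError("no read assignments")
    direct: Counter[int] = Counter()
    for node in assignments.values():
        if node is not None:
            direct[node] += 1
    n_classified = sum(direct.values())
    if n_classified == 0:
        return AbundanceProfile(sample_id, {}, {}, 0, empty=True)

    gst_leaves = taxonomy.gst_leaves          # name -> node id
    leaf_name = {v: k for k, v in gst_leaves.items()}
    leaf_counts: dict[int, float] = {leaf: float(direct.get(leaf, 0)) for leaf in leaf_name}
    out: dict[int, float] = dict(leaf_counts)
    for node, count in direct.items():
        if node in leaf_name:
            continue
        leaves = taxonomy.leaves_under(node)
        total = sum(leaf_counts[l] for l in leaves)
        if total > 0:
            for l in leaves:
                out[l] += count * leaf_counts[l] / total
        else:
            for l in leaves:
                out[l] += count / len(leaves)

    label = lambda leaf: leaf_name[leaf].removeprefix("GST ")
    counts = {label(l): c for l, c in out.items() if c > 0}
    total = sum(counts.values())
    relative = {g: c / total for g, c in counts.items()}
    return AbundanceProfile(sample_id, counts, relative, n_classified)


def kraken_style_report(
    assignments: dict[str, int | None], taxonomy: TaxonomyTree
):
    """Summary rows (percentage, clade_count, direct_count, rank, node, name)."""
    import pandas as pd

    direct: Counter[int] = Counter()
    unclassified = 0
    for node in assignments.values():
        if node is None:
            unclassified += 1
        else:
            direct[node] += 1
    total = len(assignments)
    rows = []
    clade: dict[int, int] = {}
    order = []
    for node in taxonomy.nodes:
        order.append(node)
    for node in reversed(sorted(order, key=taxonomy.depth)):
        clade[node] = direct.get(node, 0) + sum(
            clade.get(c, 0) for c in taxonomy.children.get(node, [])
        )
    for node in sorted(order, key=lambda n: (taxonomy.depth(n), n)):
        rows.append(
            (
                100.0 * clade[node] / total if total else 0.0,
                clade[node],
                direct.get(node, 0),
                taxonomy.rank[node],
                node,
                taxonomy.name[node],
            )
        )
    df = pd.DataFrame(
        rows, columns=["percentage", "clade_count", "direct_count", "rank", "node_id", "name"]
    )
    df.attrs["unclassified"] = unclassified
    return df
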