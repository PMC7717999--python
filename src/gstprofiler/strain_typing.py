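"""Genome-based strain types (GSTs) by greedy sister-clade merging.

A GST is a largest clade of the (rooted) phylogeny whose all-against-all
pairwise SNV distance stays below a fixed cap (20,000 in the default,
matching a ~1.1 Mb core alignment). Clustering is greedy: seed at the
type strain, absorb the sister subtree while every pair in the enlarged
clade remains below the cap and no leaf is already clustered, freeze,
then reseed at the highest-priority unclustered genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .reference import DistanceMatrix
from .taxonomy import RANK_GST, RANK_INTERNAL, RANK_ROOT, TaxonomyTree

DEFAULT_SNV_THRESHOLD = 20_000


@dataclass
class GstAssignment:
    """Partition of tree leaves into GSTs, with representatives."""

    gsts: dict[str, tuple[str, ...]]             # GST label ("1"..) -> member genome ids
    representative: dict[str, str]

    def gst_of(self) -> dict[str, str]:
        return {g: label for label, members in self.gsts.items() for g in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, label, g == self.representative.get(label))
            for label, members in sorted(self.gsts.items(), key=lambda kv: int(kv[0]))
            for g in members
        ]
        return pd.DataFrame(rows, columns=["genome_id", "gst_id", "is_representative"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _leafsets(tree: TreeNode) -> dict[int, frozenset[str]]:
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            sets[id(node)] = frozenset([node.name])
        else:
            acc: set[str] = set()
            for c in node.children:
                acc |= sets[id(c)]
            sets[id(node)] = frozenset(acc)
    return sets


def cluster_gsts(
    tree: TreeNode,
    d: DistanceMatrix,
    priority: list[str],
    threshold: int = DEFAULT_SNV_THRESHOLD,
    first_seed: str | None = None,
) -> GstAssignment:
    """Greedy merging of sister clades under a pairwise SNV cap.

    ``priority`` orders reseeding (and representative choice); the first
    seed is the type strain when given, else the highest-priority leaf.
    A merge is allowed only while the enlarged clade's maximum pairwise
    distance is strictly below ``threshold`` and absorbs no leaf that is
    already clustered. GST labels follow creation order ("1", "2", ...).
    """
    leaves = {n.name: n for n in tree.tips()}
    if len(leaves) != len(list(tree.tips())):
        raise ValueError("duplicate leaf labels")
    missing = set(leaves) - set(priority)
    if missing:
        raise ValueError(f"priority list misses leaves: {sorted(missing)}")
    missing_d = set(leaves) - set(d.ids)
    if missing_d:
        raise ValueError(f"distance matrix misses leaves: {sorted(missing_d)}")

    sets = _leafsets(tree)
    unclustered = set(leaves)
    order = [g for g in priority if g in leaves]
    if first_seed is not None:
        order = [first_seed] + [g for g in order if g != first_seed]

    gsts: dict[str, tuple[str, ...]] = {}
    label = 0
    for seed in order:
        if seed not in unclustered:
            continue
        node = leaves[seed]
        while node.parent is not None:
            parent = node.parent
            cand = sets[id(parent)]
            if not cand <= unclustered:
                break
            if d.submax(cand) >= threshold:
                break
            node = parent
        members = sets[id(node)]
        label += 1
        gsts[str(label)] = tuple(sorted(members))
        unclustered -= members

    assignment = GstAssignment(gsts, {})
    assignment.representative = select_representatives(assignment, priority)
    return assignment


def select_representatives(assignment: GstAssignment, priority: list[str]) -> dict[str, str]:
    """Per GST, the member earliest in the priority order."""
    rank = {g: i for i, g in enumerate(priority)}
    return {
        label: min(members, key=lambda g: rank[g])
        for label, members in assignment.gsts.items()
    }


def build_taxonomy(tree: TreeNode, assignment: GstAssignment) -> TaxonomyTree:
    """Collapse each GST clade to a leaf and build the custom taxonomy.

    The result mirrors the input topology above the GST clades, with unary
    internal nodes suppressed and a species-rank root on top. Fails hard
    if any GST's members do not form a clade.
    """
    sets = _leafsets(tree)
    gst_by_leafset = {frozenset(m): label for label, m in assignment.gsts.items()}
    covered = set().union(*gst_by_leafset) if gst_by_leafset else set()
    if covered != {n.name for n in tree.tips()}:
        raise ValueError("assignment does not cover the tree's leaves")

    def collapse(node: TreeNode):
        ls = sets[id(node)]
        if ls in gst_by_leafset:
            return ("gst", gst_by_leafset[ls])
        if node.is_tip():
            raise ValueError(f"leaf {node.name} not in any GST clade")
        kids = []
        for c in node.children:
            kids.append(collapse(c))
        # any child subtree fully inside a GST must itself be that GST clade
        if len(kids) == 1:
            return kids[0]  # unary suppression
        return ("node", kids)

    collapsed = collapse(tree)
    tax = TaxonomyTree()
    tax.root_id = 1
    tax.add_node(1, 0, "species", RANK_ROOT)
    counter = [1]

    def emit(item, parent_id: int) -> None:
        counter[0] += 1
        nid = counter[0]
        if item[0] == "gst":
            tax.add_node(nid, parent_id, f"GST {item[1]}", RANK_GST)
        else:
            tax.add_node(nid, parent_id, f"node_{nid}", RANK_INTERNAL)
            for child in item[1]:
                emit(child, nid)

    if collapsed[0] == "gst":
        emit(collapsed, 1)
    else:
        for child in collapsed[1]:
            emit(child, 1)
    return tax


def _validate_clades(tree: TreeNode, assignment: GstAssignment) -> None:
    sets = set(_leafsets(tree).values())
    for label, members in assignment.gsts.items():
        if frozenset(members) not in sets:
            raise ValueError(f"GST {label} is not a clade of the tree")


# ---------------------------------------------------------------------------
# tree construction for synthetic pipelines


def neighbor_joining_tree(d: DistanceMatrix) -> TreeNode:
    """Midpoint-rooted neighbor-joining tree from an SNV distance matrix.

    Provided for synthetic data only; real analyses supply their own
    (maximum-likelihood) tree.
    """
    dm = _SkbioDM(d.d.astype(float), ids=d.ids)
    tree = _skbio_nj(dm)
    rooted = tree.root_at_midpoint()
    # negative NJ branch lengths are an artifact; clamp for downstream use
    for node in rooted.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return rooted


def read_newick(path_or_str) -> TreeNode:
    if isinstance(path_or_str, str) and path_or_str.strip().endswith(";"):
        return TreeNode.read(StringIO(path_or_str))
    return TreeNode.read(str(path_or_str))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))
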