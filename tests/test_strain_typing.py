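"""GST clustering by greedy sister-clade merging, representatives, taxonomy.

The central oracle is an independent re-implementation of the stated
merging rule that works on the set of clades (leaf subsets) rather than on
parent pointers: starting from the seed leaf, repeatedly move to the
smallest clade strictly containing the current one while all of its leaves
are unclustered and its maximum pairwise distance stays under the cap.
"""

from io import StringIO
from itertools import combinations

import numpy as np
import pytest
from skbio import TreeNode

import gstprofiler as gp


def _clades(tree: TreeNode) -> list[frozenset]:
    out = []
    for node in tree.postorder():
        out.append(frozenset(t.name for t in node.tips()) or frozenset([node.name]))
    return out


def _replay_greedy(tree, dmat, ids, priority, threshold, first_seed=None):
    """Second implementation of the merging rule, on clade sets."""
    clades = sorted(set(_clades(tree)), key=len)
    idx = {g: i for i, g in enumerate(ids)}

    def maxpair(clade):
        if len(clade) < 2:
            return 0
        return max(dmat[idx[a], idx[b]] for a, b in combinations(sorted(clade), 2))

    unclustered = set(ids)
    order = list(priority)
    if first_seed:
        order = [first_seed] + [g for g in order if g != first_seed]
    result = []
    for seed in order:
        if seed not in unclustered:
            continue
        current = frozenset([seed])
        while True:
            supersets = [c for c in clades if current < c]
            if not supersets:
                break
            nxt = min(supersets, key=len)
            if not nxt <= unclustered or maxpair(nxt) >= threshold:
                break
            current = nxt
        result.append(frozenset(current))
        unclustered -= current
    return result


def _random_instance(rng, n):
    def build(ls):
        if len(ls) == 1:
            return ls[0]
        k = int(rng.integers(1, len(ls)))
        return f"({build(ls[:k])},{build(ls[k:])})"

    ids = [f"L{i}" for i in range(n)]
    tree = TreeNode.read(StringIO(build(ids) + ";"))
    m = rng.integers(0, 100, (n, n))
    m = np.triu(m, 1)
    m = m + m.T
    prio = list(ids)
    rng.shuffle(prio)
    return tree, m, ids, prio


def test_all_distant_leaves_become_singletons(typed3, coll3):
    assign = gp.cluster_gsts(coll3.tree, typed3["dm"], typed3["priority"], threshold=1)
    assert len(assign.gsts) == len(coll3.genome_ids)
    assert all(len(m) == 1 for m in assign.gsts.values())


def test_all_close_leaves_become_one_gst(typed3, coll3):
    big = int(typed3["dm"].d.max()) + 1
    assign = gp.cluster_gsts(coll3.tree, typed3["dm"], typed3["priority"], threshold=big)
    assert len(assign.gsts) == 1
    assert set(assign.gsts["1"]) == set(coll3.genome_ids)


def test_caterpillar_hand_instance_matches_replay():
    tree = TreeNode.read(StringIO("((((((A,B),C),D),E),F));"))
    ids = list("ABCDEF")
    m = np.array(
        [
            [0, 5, 30, 90, 90, 90],
            [5, 0, 30, 90, 90, 90],
            [30, 30, 0, 90, 90, 90],
            [90, 90, 90, 0, 10, 90],
            [90, 90, 90, 10, 0, 90],
            [90, 90, 90, 90, 90, 0],
        ]
    )
    dm = gp.DistanceMatrix(ids, m)
    prio = list("ABCDEF")
    assign = gp.cluster_gsts(tree, dm, prio, threshold=50)
    expected = _replay_greedy(tree, m, ids, prio, 50)
    assert [frozenset(v) for v in assign.gsts.values()] == expected
    assert set(assign.gsts["1"]) == {"A", "B", "C"}


def test_greedy_rule_matches_independent_replay_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(120):
        n = int(rng.integers(3, 13))
        tree, m, ids, prio = _random_instance(rng, n)
        threshold = int(rng.integers(1, 120))
        assign = gp.cluster_gsts(tree, gp.DistanceMatrix(ids, m), prio, threshold=threshold)
        expected = _replay_greedy(tree, m, ids, prio, threshold)
        assert [frozenset(v) for v in assign.gsts.values()] == expected


def test_partition_threshold_determinism_monotonicity_invariants():
    rng = np.random.default_rng(99)
    clade_sets = {}
    for _ in range(80):
        n = int(rng.integers(3, 13))
        tree, m, ids, prio = _random_instance(rng, n)
        dm = gp.DistanceMatrix(ids, m)
        t1, t2 = sorted(rng.integers(1, 120, 2).tolist())
        a1 = gp.cluster_gsts(tree, dm, prio, threshold=int(t1))
        # partition: disjoint cover by connected clades
        all_members = [g for mem in a1.gsts.values() for g in mem]
        assert sorted(all_members) == sorted(ids)
        clades = set(_clades(tree))
        for mem in a1.gsts.values():
            assert frozenset(mem) in clades
            assert dm.submax(mem) < t1
        # determinism
        again = gp.cluster_gsts(tree, dm, prio, threshold=int(t1))
        assert again.gsts == a1.gsts
        # monotonicity: larger cap, no more GSTs
        a2 = gp.cluster_gsts(tree, dm, prio, threshold=int(t2))
        assert len(a2.gsts) <= len(a1.gsts)


def test_cluster_input_validation(typed3, coll3):
    with pytest.raises(ValueError, match="priority"):
        gp.cluster_gsts(coll3.tree, typed3["dm"], typed3["priority"][:-1])
    bad_dm = gp.DistanceMatrix(["x"], np.zeros((1, 1), dtype=int))
    with pytest.raises(ValueError, match="distance matrix"):
        gp.cluster_gsts(coll3.tree, bad_dm, typed3["priority"])


def test_recovers_true_gst_partition(coll3, typed3):
    truth = {
        frozenset(m) for m in coll3.gst_members().values()
    }
    got = {frozenset(m) for m in typed3["assignment"].gsts.values()}
    assert got == truth


def test_representative_is_highest_priority_member(typed3):
    prio = typed3["priority"]
    rank = {g: i for i, g in enumerate(prio)}
    assign = typed3["assignment"]
    for label, members in assign.gsts.items():
        assert assign.representative[label] == min(members, key=rank.__getitem__)


def test_representatives_bruteforce_random_partitions(rng):
    ids = [f"g{i}" for i in range(12)]
    prio = list(ids)
    rng.shuffle(prio)
    rank = {g: i for i, g in enumerate(prio)}
    blocks = np.array_split(np.array(ids), 4)
    assign = gp.GstAssignment(
        {str(i + 1): tuple(b.tolist()) for i, b in enumerate(blocks)}, {}
    )
    reps = gp.select_representatives(assign, prio)
    for label, members in assign.gsts.items():
        assert reps[label] == min(members, key=rank.__getitem__)


def test_taxonomy_single_gst_is_root_plus_leaf():
    tree = TreeNode.read(StringIO("((A,B),(C,D));"))
    assign = gp.GstAssignment({"1": ("A", "B", "C", "D")}, {"1": "A"})
    tax = gp.build_taxonomy(tree, assign)
    assert len(tax.nodes) == 2
    (leaf,) = [n for n in tax.nodes if tax.rank[n] == "strain-type"]
    assert tax.parent[leaf] == tax.root_id


def test_taxonomy_unary_suppression_balanced_tree():
    tree = TreeNode.read(StringIO("((A,B),(C,D));"))
    assign = gp.GstAssignment({"1": ("A", "B"), "2": ("C", "D")}, {})
    tax = gp.build_taxonomy(tree, assign)
    leaves = tax.gst_leaves
    assert set(leaves) == {"GST 1", "GST 2"}
    assert all(tax.parent[n] == tax.root_id for n in leaves.values())


def test_taxonomy_internal_nodes_not_unary(coll5, typed5):
    tax = typed5["taxonomy"]
    for n in tax.nodes:
        if tax.rank[n] != "strain-type":
            assert len(tax.children[n]) >= 1
            if n != tax.root_id:
                assert len(tax.children[n]) >= 2


def test_taxonomy_rejects_non_clade():
    tree = TreeNode.read(StringIO("((A,B),(C,D));"))
    assign = gp.GstAssignment({"1": ("A", "C"), "2": ("B", "D")}, {})
    with pytest.raises(ValueError):
        gp.build_taxonomy(tree, assign)


def test_taxonomy_tsv_and_dmp_roundtrip(tmp_path, typed3):
    tax = typed3["taxonomy"]
    tax.to_tsv(tmp_path / "tax.tsv")
    back = gp.TaxonomyTree.from_tsv(tmp_path / "tax.tsv")
    assert back.parent == tax.parent and back.rank == tax.rank
    tax.to_dmp(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
    assert (tmp_path / "nodes.dmp").read_text().count("|") > 0


def test_neighbor_joining_tree_supports_typing(coll3, typed3):
    njt = gp.neighbor_joining_tree(typed3["dm"])
    assign = gp.cluster_gsts(njt, typed3["dm"], typed3["priority"], threshold=200,
                             first_seed=coll3.type_strain_id)
    got = {frozenset(m) for m in assign.gsts.values()}
    truth = {frozenset(m) for m in coll3.gst_members().values()}
    assert got == truth
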