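"""Tree-shaped custom taxonomy for LCA-based read classification.

The taxonomy mirrors the strain phylogeny with each strain-type (GST) clade
collapsed to a single leaf, unary nodes suppressed, and a species-rank root
on top. Node ids are stable integers assigned in preorder (root = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RANK_ROOT = "species"
RANK_INTERNAL = "no rank"
RANK_GST = "strain-type"


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent pointers and GST leaves."""

    parent: dict[int, int] = field(default_factory=dict)   # node -> parent (root maps to 0)
    children: dict[int, list[int]] = field(default_factory=dict)
    name: dict[int, str] = field(default_factory=dict)
    rank: dict[int, str] = field(default_factory=dict)
    root_id: int = 1

    def __post_init__(self) -> None:
        self._depth: dict[int, int] = {}
        self._leaves_under: dict[int, tuple[int, ...]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: int, parent_id: int, name: str, rank: str) -> None:
        if node_id in self.parent:
            raise ValueError(f"duplicate node id {node_id}")
        self.parent[node_id] = parent_id
        self.children.setdefault(node_id, [])
        if parent_id:
            self.children.setdefault(parent_id, []).append(node_id)
        self.name[node_id] = name
        self.rank[node_id] = rank
        self._depth.clear()
        self._leaves_under.clear()

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    @property
    def gst_leaves(self) -> dict[str, int]:
        """GST label -> leaf node id."""
        return {self.name[n]: n for n in self.parent if self.rank[n] == RANK_GST}

    def depth(self, node: int) -> int:
        if node not in self._depth:
            d, cur = 0, node
            while cur != self.root_id:
                cur = self.parent[cur]
                d += 1
            self._depth[node] = d
        return self._depth[node]

    def path_to_root(self, node: int) -> list[int]:
        out = [node]
        while out[-1] != self.root_id:
            out.append(self.parent[out[-1]])
        return out

    def is_ancestor_or_self(self, anc: int, node: int) -> bool:
        cur = node
        while True:
            if cur == anc:
                return True
            if cur == self.root_id:
                return False
            cur = self.parent[cur]

    def lca(self, nodes: list[int]) -> int:
        if not nodes:
            raise ValueError("lca of empty node set")
        it = iter(nodes)
        cur = next(it)
        for other in it:
            cur = self._lca2(cur, other)
        return cur

    def _lca2(self, a: int, b: int) -> int:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a, da = self.parent[a], da - 1
        while db > da:
            b, db = self.parent[b], db - 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    def leaves_under(self, node: int) -> tuple[int, ...]:
        """GST leaf node ids in the subtree rooted at ``node``."""
        if node not in self._leaves_under:
            if self.rank[node] == RANK_GST:
                self._leaves_under[node] = (node,)
            else:
                acc: list[int] = []
                for c in self.children.get(node, []):
                    acc.extend(self.leaves_under(c))
                self._leaves_under[node] = tuple(acc)
        return self._leaves_under[node]

    # -- IO ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (n, self.parent[n], self.rank[n], self.name[n])
            for n in sorted(self.parent)
        ]
        return pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t")
        tax = cls()
        roots = df[df.parent_id == 0]
        if len(roots) != 1:
            raise ValueError("taxonomy must have exactly one root")
        tax.root_id = int(roots.iloc[0].node_id)
        for row in df.itertuples(index=False):
            tax.add_node(int(row.node_id), int(row.parent_id), str(row.name), str(row.rank))
        return tax

    def to_dmp(self, nodes_path, names_path) -> None:
        """Kraken-style nodes.dmp / names.dmp dialect."""
        with open(nodes_path, "w") as fh:
            for n in sorted(self.parent):
                parent = self.parent[n] or n  # root points to itself
                fh.write(f"{n}\t|\t{parent}\t|\t{self.rank[n]}\t|\n")
        with open(names_path, "w") as fh:
            for n in sorted(self.parent):
                fh.write(f"{n}\t|\t{self.name[n]}\t|\t\t|\tscientific name\t|\n")
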