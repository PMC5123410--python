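"""Rooted binary phylogeny with genome labels.

A thin recursive node structure; Newick reading and writing is delegated
to dendropy.  Internal nodes without labels are named deterministically by
post-order index (``N1``, ``N2``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import dendropy

from .genomes import Genome


@dataclass
class TreeNode:
    name: str
    length: float | None = None  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def clone(self) -> "TreeNode":
        node = TreeNode(self.name, self.length)
        for child in self.children:
            c = child.clone()
            c.parent = node
            node.children.append(c)
        return node


class TreeError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Rooted binary tree plus leaf genomes and reconstructed internal labels."""

    root: TreeNode
    genomes: dict[str, Genome] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._name_internals()
        for node in self.root.postorder():
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"node {node.name!r} has {len(node.children)} children; "
                    "the tree must be binary"
                )

    def _name_internals(self) -> None:
        used = {n.name for n in self.root.postorder() if n.name}
        counter = 0
        for node in self.root.postorder():
            if not node.name:
                counter += 1
                while f"N{counter}" in used:
                    counter += 1
                node.name = f"N{counter}"
                used.add(node.name)

    # -- queries ------------------------------------------------------------

    def nodes(self) -> list[TreeNode]:
        return list(self.root.postorder())

    def node(self, name: str) -> TreeNode:
        for n in self.root.postorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        return [
            (n.parent, n) for n in self.root.postorder() if n.parent is not None
        ]

    def attach_leaf_genomes(self, genomes: dict[str, Genome]) -> None:
        missing = [n for n in self.leaf_names() if n not in genomes]
        if missing:
            raise TreeError(f"no genome for leaves {missing}")
        for name in self.leaf_names():
            self.genomes[name] = genomes[name]

    def set_lengths(self, lengths: dict[tuple[str, str], float]) -> None:
        for parent, child in self.edges():
            child.length = lengths[(parent.name, child.name)]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.clone(), dict(self.genomes))

    # -- unrooted view -------------------------------------------------------

    def unrooted_adjacency(self) -> dict[str, list[tuple[str, float]]]:
        """Neighbor map with the root suppressed (its edges joined)."""
        adj: dict[str, list[tuple[str, float]]] = {}

        def add(u: str, v: str, w: float) -> None:
            adj.setdefault(u, []).append((v, w))
            adj.setdefault(v, []).append((u, w))

        for parent, child in self.edges():
            if parent is self.root:
                continue
            add(parent.name, child.name, child.length or 0.0)
        kids = self.root.children
        if len(kids) == 2:
            add(kids[0].name, kids[1].name, (kids[0].length or 0.0) + (kids[1].length or 0.0))
        elif len(kids) == 1:  # degenerate
            pass
        return adj

    # -- Newick I/O ----------------------------------------------------------

    @staticmethod
    def from_newick(text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )

        def convert(dnode) -> TreeNode:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label or ""
            node = TreeNode(label or "", dnode.edge.length)
            for dchild in dnode.child_nodes():
                child = convert(dchild)
                child.parent = node
                node.children.append(child)
            return node

        return PhyloTree(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                base = node.name
            else:
                base = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if node.length is not None and node.parent is not None:
                base += f":{node.length:.8g}"
            return base

        return fmt(self.root) + ";"


def map_tree(node: TreeNode, fn: Callable[[TreeNode], None]) -> None:
    for n in node.postorder():
        fn(n)
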