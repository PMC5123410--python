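"""Adjacency-weight generation for ancestral nodes.

Leaf genomes give 0/1 indicator weights (an adjacency weighs 1 where it is
present).  At an internal node with children L, R at distances D_L, D_R,
the weight of adjacency ij is the distance-weighted convex combination

    w(ij) = (D_L * w_R(ij) + D_R * w_L(ij)) / (D_L + D_R),

so the closer child counts more.  For the node being *reconstructed*, the
information of its own subtree is already in the breakpoint graph of its
children; its guiding weights are therefore computed on the rest of the
tree: prune the node's subtree, drop the original root (suppressing the
degree-2 join), reroot at the node's former parent and run the recursion
there.  The root of the input tree, having no "rest of the tree", is
weighted by running the recursion on the full tree directly.

A reader for externally produced weight tables (TSV: node, ext1, ext2,
weight) is also provided.
"""

from __future__ import annotations

from .genomes import Genome, parse_extremity, fmt_extremity
from .mwig import WeightTable
from .trees import PhyloTree, TreeError, TreeNode

#: floor for zero/missing branch lengths, to keep the recursion defined
MIN_BRANCH_LENGTH = 1e-6

NodeWeights = dict[str, WeightTable]


def _blen(length: float | None) -> float:
    if length is None or length < MIN_BRANCH_LENGTH:
        return MIN_BRANCH_LENGTH
    return length


def _combine(
    wl: WeightTable, wr: WeightTable, dl: float, dr: float
) -> WeightTable:
    out = WeightTable()
    keys = {k for k, _ in wl.items()} | {k for k, _ in wr.items()}
    denom = dl + dr
    for key in keys:
        w = (dl * wr.get_adj(key) + dr * wl.get_adj(key)) / denom
        if w > 0:
            out.set(key[0], key[1], w)
    return out


def recursive_weights(tree: PhyloTree, root: TreeNode | None = None) -> WeightTable:
    """Bottom-up distance-weighted averaging from the leaf indicators."""
    root = root if root is not None else tree.root

    def rec(node: TreeNode) -> WeightTable:
        if node.is_leaf:
            return WeightTable.from_genome(tree.genomes[node.name])
        left, right = node.children
        return _combine(rec(left), rec(right), _blen(left.length), _blen(right.length))

    return rec(root)


def _weights_outside(tree: PhyloTree, alpha: str) -> WeightTable:
    """Eq.-style weights for node ``alpha`` from the pruned, rerooted tree.

    Works on the unrooted (root-suppressed) neighbor map: after removing
    alpha's subtree, the recursion runs from alpha's former parent gamma
    away from the removed subtree.
    """
    node = tree.node(alpha)
    if node.parent is None:
        return recursive_weights(tree)
    gamma = node.parent
    adj = tree.unrooted_adjacency()
    subtree = {n.name for n in node.postorder()}

    def rec(name: str, came_from: str | None) -> tuple[WeightTable, float]:
        """Weights of the subtree hanging at ``name``; second value unused
        for leaves (their distance is the edge that led here)."""
        nbrs = [
            (v, w) for v, w in adj.get(name, [])
            if v != came_from and v not in subtree
        ]
        if not nbrs:
            return WeightTable.from_genome(tree.genomes[name]), 0.0
        if len(nbrs) == 1:  # pass-through (suppressed degree-2 situation)
            v, w = nbrs[0]
            sub, extra = rec(v, name)
            return sub, w + extra
        if len(nbrs) != 2:
            raise TreeError(f"node {name!r} is not binary in the rerooted view")
        (v1, w1), (v2, w2) = nbrs
        sub1, e1 = rec(v1, name)
        sub2, e2 = rec(v2, name)
        return _combine(sub1, sub2, _blen(w1 + e1), _blen(w2 + e2)), 0.0

    if gamma.parent is None:
        # alpha hangs off the root: the pruned, root-suppressed tree is just
        # the sibling subtree, so the recursion starts at the sibling
        sibling = next(c for c in gamma.children if c.name != alpha)
        table, _ = rec(sibling.name, None)
        return table

    # gamma, rerooted: its neighbors minus the removed subtree
    table, _ = rec(gamma.name, None)
    return table


def node_weights_by_rerooting(tree: PhyloTree) -> NodeWeights:
    """Adjacency weights for every internal node via prune-and-reroot."""
    out: NodeWeights = {}
    for node in tree.internal_nodes():
        out[node.name] = _weights_outside(tree, node.name)
    return out


# ---------------------------------------------------------------------------
# external weight tables
# ---------------------------------------------------------------------------

def write_weight_tables(weights: NodeWeights) -> str:
    lines = ["node\text1\text2\tweight"]
    for node in sorted(weights):
        for (x, y), w in sorted(weights[node].items()):
            lines.append(
                f"{node}\t{fmt_extremity(x)}\t{fmt_extremity(y)}\t{w:.10g}"
            )
    return "\n".join(lines) + "\n"


def load_weight_table(text: str, node_names: set[str] | None = None) -> NodeWeights:
    """Parse a node/ext1/ext2/weight TSV into per-node weight tables."""
    out: NodeWeights = {}
    lines = text.splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith("node\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"line {lineno}: expected 4 tab-separated fields")
        node, e1, e2, w = fields
        if node_names is not None and node not in node_names:
            raise ValueError(f"line {lineno}: unknown node {node!r}")
        try:
            x, y = parse_extremity(e1), parse_extremity(e2)
            weight = float(w)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        out.setdefault(node, WeightTable()).set(x, y, weight)
    return out
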