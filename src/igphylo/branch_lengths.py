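"""Branch-length estimation from pairwise leaf distances.

The unrooted input topology with k leaves has n = 2k - 3 edges.  For each
of the m = k(k-1)/2 leaf pairs, the 0/1 design matrix M marks which edges
lie on the connecting path, and d holds the pairwise DCJ-indel distances.
Two classic estimators are provided:

* Fitch-Margoliash least squares: w* = argmin ||Mw - d||^2 (negative
  entries clamped to zero afterwards);
* Minimum Evolution: minimize sum(w) subject to Mw >= d, w >= 0, solved as
  a linear program.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import linprog

from .bpgraph import dcj_indel_distance
from .genomes import Genome
from .trees import PhyloTree, TreeError


@dataclass
class PathDesign:
    pairs: list[tuple[str, str]]
    edges: list[tuple[str, str]]  # unrooted edges as sorted name pairs
    matrix: np.ndarray  # m x n over {0, 1}
    distances: np.ndarray  # length m


def _unrooted_edges(tree: PhyloTree) -> tuple[list[tuple[str, str]], dict[str, list[tuple[str, int]]]]:
    adj = tree.unrooted_adjacency()
    edges: list[tuple[str, str]] = []
    index: dict[tuple[str, str], int] = {}
    nbrs: dict[str, list[tuple[str, int]]] = {}
    for u in sorted(adj):
        for v, _w in adj[u]:
            key = (u, v) if u < v else (v, u)
            if key not in index:
                index[key] = len(edges)
                edges.append(key)
    for u in sorted(adj):
        nbrs[u] = [
            (v, index[(u, v) if u < v else (v, u)]) for v, _w in adj[u]
        ]
    return edges, nbrs


def build_design(tree: PhyloTree, genomes: dict[str, Genome]) -> PathDesign:
    """Leaf-pair path design and DCJ-indel distance vector."""
    leaves = sorted(tree.leaf_names())
    if len(leaves) < 3:
        raise TreeError("branch-length estimation needs at least 3 leaves")
    edges, nbrs = _unrooted_edges(tree)
    pairs = list(combinations(leaves, 2))
    m, n = len(pairs), len(edges)
    matrix = np.zeros((m, n), dtype=float)
    dist = np.zeros(m, dtype=float)

    def path_edges(src: str, dst: str) -> list[int]:
        stack = [(src, None, [])]
        while stack:
            node, came, used = stack.pop()
            if node == dst:
                return used
            for v, ei in nbrs[node]:
                if v != came:
                    stack.append((v, node, used + [ei]))
        raise TreeError(f"no path between leaves {src} and {dst}")

    for r, (u, v) in enumerate(pairs):
        for ei in path_edges(u, v):
            matrix[r, ei] = 1.0
        dist[r] = dcj_indel_distance(genomes[u], genomes[v])
    return PathDesign(pairs, edges, matrix, dist)


def estimate_least_squares(pd: PathDesign) -> tuple[np.ndarray, float]:
    """Unweighted least squares; returns (clamped lengths, residual norm)."""
    m, n = pd.matrix.shape
    if m < n:
        raise ValueError(f"under-determined design: {m} pairs for {n} edges")
    if np.linalg.matrix_rank(pd.matrix) < n:
        raise ValueError("rank-deficient path design; topology degenerate")
    w, _res, _rank, _sv = np.linalg.lstsq(pd.matrix, pd.distances, rcond=None)
    residual = float(np.linalg.norm(pd.matrix @ w - pd.distances))
    return np.maximum(w, 0.0), residual


def estimate_minimum_evolution(pd: PathDesign) -> np.ndarray:
    """Minimize total length subject to path sums covering the distances."""
    m, n = pd.matrix.shape
    res = linprog(
        c=np.ones(n),
        A_ub=-pd.matrix,
        b_ub=-pd.distances,
        bounds=[(0, None)] * n,
        method="highs",
    )
    if not res.success:  # pragma: no cover - LP is always feasible
        raise RuntimeError(f"minimum-evolution LP failed: {res.message}")
    return res.x


def assign_lengths(tree: PhyloTree, pd: PathDesign, w: np.ndarray) -> None:
    """Write unrooted edge lengths back onto the rooted tree.

    The suppressed root edge's length is split evenly between the root's
    two children.
    """
    lengths = {edge: float(val) for edge, val in zip(pd.edges, w)}
    kids = tree.root.children
    root_key = tuple(sorted((kids[0].name, kids[1].name)))
    for parent, child in tree.edges():
        if parent is tree.root:
            child.length = lengths[root_key] / 2.0
        else:
            key = (parent.name, child.name) if parent.name < child.name else (
                child.name, parent.name
            )
            child.length = lengths[key]
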