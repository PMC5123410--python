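"""The space of optimal completions of a breakpoint graph.

A completion pairs up the A-open vertices (adding prosthetic adjacencies to
genome A) and the B-open vertices, making the gene contents equal.  Optimal
completions — those minimizing the resulting DCJ distance — link open
components of the breakpoint graph in restricted ways, captured by a
hypergraph whose vertices are the open components and whose (hyper)edges
come from eleven classes:

T1 odd-A x even-A      T5 even-A x even-A     T8  odd-A x AB x odd-B
T2 odd-B x even-B      T6 odd-B x odd-B       T9  odd-A x AB x even-B
T3 AB x AB             T7 even-B x even-B     T10 even-A x AB x odd-B
T4 odd-A x odd-A                              T11 even-A x AB x even-B

Which classes are active depends on the component inventory through six
exhaustive case rules; AA- and BB-paths are always self-closed and are not
hypergraph vertices.  This module also provides a brute-force enumerator of
*all* completions (optimal or not) for small instances, used as the
correctness oracle throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import prod
from typing import Iterator, Sequence

from .bpgraph import (
    BreakpointGraph,
    Component,
    ComponentInventory,
    ComponentKind,
    build_bp_graph,
    dcj_distance,
    _optimal_delta_twice,
)
from .genomes import Adjacency, Extremity, Genome, adjacency

PAIR_CLASSES = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")
TRIPLE_CLASSES = ("T8", "T9", "T10", "T11")

#: endpoint signature of each triple class: (A-path parity, B-path parity)
TRIPLE_PARITY = {
    "T8": (True, True),
    "T9": (True, False),
    "T10": (False, True),
    "T11": (False, False),
}


@dataclass(frozen=True)
class CaseRule:
    case_id: int
    pair_classes: tuple[str, ...]
    triple_class: str | None
    triple_count: str  # "none" | "one" | "many"


_CASES = (
    CaseRule(1, ("T1", "T2", "T3", "T5", "T6"), None, "none"),
    CaseRule(2, ("T1", "T2", "T3", "T4", "T7"), None, "none"),
    CaseRule(3, ("T1", "T2", "T3", "T5", "T6"), "T10", "one"),
    CaseRule(4, ("T1", "T2", "T3", "T4", "T7"), "T9", "one"),
    CaseRule(5, ("T1", "T2", "T3", "T5", "T7"), "T11", "many"),
    CaseRule(6, ("T1", "T2", "T3", "T4", "T6"), "T8", "many"),
)


def select_case(inv: ComponentInventory) -> CaseRule:
    """The lowest-numbered applicable case rule (the six are exhaustive)."""
    even = inv.p_AB % 2 == 0
    a_le = inv.p_A_odd <= inv.p_A_even
    a_ge = inv.p_A_odd >= inv.p_A_even
    b_le = inv.p_B_odd <= inv.p_B_even
    b_ge = inv.p_B_odd >= inv.p_B_even
    conds = (
        even and a_le and b_ge,
        even and a_ge and b_le,
        (not even) and a_le and b_ge,
        (not even) and a_ge and b_le,
        (not a_ge) and (not b_ge),  # strictly fewer odd than even on both sides
        (not a_le) and (not b_le),
    )
    for rule, ok in zip(_CASES, conds):
        if ok:
            return rule
    raise AssertionError("case rules are not exhaustive")  # pragma: no cover


@dataclass(frozen=True)
class HyperEdge:
    klass: str
    components: tuple[int, ...]  # component indices, in (A, [AB,] B) order
    weight: float = 0.0


@dataclass
class CompletionHypergraph:
    """Open components as vertices; optimal linkings as weighted edges."""

    case: CaseRule
    vertices: dict[str, list[int]]  # class name -> component indices
    pair_edges: list[HyperEdge] = field(default_factory=list)
    triple_edges: list[HyperEdge] = field(default_factory=list)

    def to_dot(self) -> str:
        lines = ["graph H {"]
        for cls, comps in self.vertices.items():
            for c in comps:
                lines.append(f'  c{c} [label="{cls}:{c}"];')
        for e in self.pair_edges:
            u, v = e.components
            lines.append(f'  c{u} -- c{v} [label="{e.klass}:{e.weight:.3g}"];')
        for e in self.triple_edges:
            lines.append(
                "  "
                + " -- ".join(f"c{c}" for c in e.components)
                + f' [style=dashed, label="{e.klass}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def _class_vertices(graph: BreakpointGraph) -> dict[str, list[int]]:
    lam_o, lam_e, ups, gam_o, gam_e = [], [], [], [], []
    for comp in graph.components:
        if comp.kind is ComponentKind.A:
            (lam_o if comp.odd else lam_e).append(comp.index)
        elif comp.kind is ComponentKind.B:
            (gam_o if comp.odd else gam_e).append(comp.index)
        elif comp.kind is ComponentKind.AB:
            ups.append(comp.index)
    return {
        "lambda_odd": lam_o,
        "lambda_even": lam_e,
        "upsilon": ups,
        "gamma_odd": gam_o,
        "gamma_even": gam_e,
    }


_PAIR_SETS = {
    "T1": ("lambda_odd", "lambda_even"),
    "T2": ("gamma_odd", "gamma_even"),
    "T3": ("upsilon", "upsilon"),
    "T4": ("lambda_odd", "lambda_odd"),
    "T5": ("lambda_even", "lambda_even"),
    "T6": ("gamma_odd", "gamma_odd"),
    "T7": ("gamma_even", "gamma_even"),
}

_TRIPLE_SETS = {
    "T8": ("lambda_odd", "gamma_odd"),
    "T9": ("lambda_odd", "gamma_even"),
    "T10": ("lambda_even", "gamma_odd"),
    "T11": ("lambda_even", "gamma_even"),
}


def build_hypergraph(
    graph: BreakpointGraph,
    inv: ComponentInventory | None = None,
    weight_fn=None,
) -> CompletionHypergraph:
    """Instantiate the active hyperedge classes for the selected case.

    ``weight_fn(components) -> float`` scores a candidate merged component
    (see :func:`igphylo.mwig.score_hyperedge`); without it edges carry 0.
    """
    inv = inv if inv is not None else graph.inventory
    case = select_case(inv)
    verts = _class_vertices(graph)
    hg = CompletionHypergraph(case, verts)

    def score(comps: tuple[int, ...]) -> float:
        return 0.0 if weight_fn is None else weight_fn(comps)

    for klass in case.pair_classes:
        set1, set2 = _PAIR_SETS[klass]
        if set1 == set2:
            pairs = combinations(verts[set1], 2)
        else:
            pairs = (
                (u, v) for u in verts[set1] for v in verts[set2] if u != v
            )
        for u, v in pairs:
            hg.pair_edges.append(HyperEdge(klass, (u, v), score((u, v))))
    if case.triple_class is not None:
        aset, bset = _TRIPLE_SETS[case.triple_class]
        for u in verts[aset]:
            for m in verts["upsilon"]:
                for v in verts[bset]:
                    hg.triple_edges.append(
                        HyperEdge(case.triple_class, (u, m, v))
                    )
    return hg


# ---------------------------------------------------------------------------
# completions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Completion:
    """A perfect pairing of A-open vertices and of B-open vertices."""

    a_pairs: frozenset[Adjacency]
    b_pairs: frozenset[Adjacency]


def apply_completion(a: Genome, b: Genome, comp: Completion) -> tuple[Genome, Genome]:
    """Extend both genomes with the completion's prosthetic adjacencies."""
    graph = build_bp_graph(a, b)
    return apply_completion_reduced(graph, comp)


def apply_completion_reduced(
    graph: BreakpointGraph, comp: Completion
) -> tuple[Genome, Genome]:
    a_open = set(graph.a_open)
    b_open = set(graph.b_open)
    for pair in comp.a_pairs:
        for ext in pair:
            if ext not in a_open:
                raise ValueError(f"{ext} is not an uncovered A-open vertex")
            a_open.discard(ext)
    for pair in comp.b_pairs:
        for ext in pair:
            if ext not in b_open:
                raise ValueError(f"{ext} is not an uncovered B-open vertex")
            b_open.discard(ext)
    if a_open or b_open:
        raise ValueError(f"completion leaves open vertices uncovered: {a_open | b_open}")

    genes = graph.genes

    def completed(genome: Genome, extra: frozenset[Adjacency]) -> Genome:
        adjs = set(
            adj
            for adj in genome.adjacencies
            if all(ext[0] == 0 or ext[0] in genes for ext in adj)
        )
        adjs |= extra
        return Genome(genome.name + "'", frozenset(adjs), genes)

    return completed(graph.a_genome, comp.a_pairs), completed(
        graph.b_genome, comp.b_pairs
    )


def _double_factorial(k: int) -> int:
    return prod(range(k, 0, -2)) if k > 0 else 1


def _perfect_pairings(vertices: Sequence[Extremity]) -> Iterator[frozenset[Adjacency]]:
    """All perfect pairings of an even-sized vertex list, deterministically."""
    verts = sorted(vertices)

    def rec(rest: tuple[Extremity, ...]) -> Iterator[tuple[Adjacency, ...]]:
        if not rest:
            yield ()
            return
        first, tail_ = rest[0], rest[1:]
        for i, partner in enumerate(tail_):
            pair = adjacency(first, partner)
            remaining = tail_[:i] + tail_[i + 1:]
            for more in rec(remaining):
                yield (pair,) + more

    for pairing in rec(tuple(verts)):
        yield frozenset(pairing)


def completion_count(graph: BreakpointGraph) -> int:
    """(2n_A - 1)!! * (2n_B - 1)!! on the singleton-reduced graph."""
    return _double_factorial(len(graph.a_open) - 1) * _double_factorial(
        len(graph.b_open) - 1
    )


def enumerate_completions(
    graph: BreakpointGraph, cap: int = 10**6
) -> Iterator[Completion]:
    """Yield every completion of the (singleton-reduced) breakpoint graph."""
    total = completion_count(graph)
    if total > cap:
        raise ValueError(
            f"completion space has {total} elements, above the cap of {cap}"
        )
    for a_pairs in _perfect_pairings(sorted(graph.a_open)):
        for b_pairs in _perfect_pairings(sorted(graph.b_open)):
            yield Completion(a_pairs, b_pairs)


def optimal_completion_distance(
    graph: BreakpointGraph, inv: ComponentInventory | None = None
) -> int:
    """min over completions of d_DCJ(A', B'), from the case rules.

    This is the DCJ-indel distance *without* the singleton term.
    """
    inv = inv if inv is not None else graph.inventory
    twice = (
        2 * inv.n - 2 * inv.cycles - inv.p_even_not_open - _optimal_delta_twice(inv)
    )
    assert twice % 2 == 0 and twice >= 0
    return twice // 2


def enumerated_min_distance(graph: BreakpointGraph, cap: int = 10**6) -> int:
    """Brute-force min over all completions (oracle for the closed form)."""
    best: int | None = None
    for comp in enumerate_completions(graph, cap=cap):
        a2, b2 = apply_completion_reduced(graph, comp)
        d = dcj_distance(a2, b2)
        if best is None or d < best:
            best = d
    if best is None:  # no open vertices: the empty completion
        a2, b2 = apply_completion_reduced(graph, Completion(frozenset(), frozenset()))
        best = dcj_distance(a2, b2)
    return best
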