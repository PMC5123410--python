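"""Breakpoint graph, component classification, DCJ and DCJ-indel distances.

The breakpoint graph BP(A, B) has one vertex per extremity of the union gene
set and one edge per non-telomeric adjacency, colored by genome.  Every
vertex has degree at most one in each color, so the graph is a disjoint
union of color-alternating cycles and paths.

For unequal gene content, a vertex is *A-open* if its gene is absent from A
(symmetrically *B-open*); open vertices are always path endpoints.  Paths
are classified by their endpoint openness (AA, BB, AB, A, B, not-open) and
by the parity of their edge count.  Circular chromosomes made entirely of
genes unique to one genome (*singletons*) are excised before construction
and counted separately; they each cost one indel.

The equal-content DCJ distance is ``n - c - p_even/2`` where ``c`` counts
cycles and ``p_even`` even paths.  The DCJ-indel distance minimizes that
quantity over all *completions* (pairings of open vertices into prosthetic
chromosomes) and adds the singleton count; the minimum is computed in
closed form from the component inventory, without enumerating completions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .genomes import (
    TELOMERE,
    Adjacency,
    Extremity,
    Genome,
    GenomeError,
    head,
    is_telomeric,
    tail,
)


class ComponentKind(Enum):
    CYCLE = "cycle"
    AA = "AA-path"
    BB = "BB-path"
    AB = "AB-path"
    A = "A-path"
    B = "B-path"
    NOT_OPEN = "not-open path"


@dataclass
class Component:
    """One alternating cycle or path of the breakpoint graph.

    ``walk`` lists the vertices in order; for paths the first and last
    entries are the endpoints (a single-vertex path has a one-element walk
    and both endpoints coincide).  For the open-path kinds the walk is
    oriented so that the *A-open* end comes first when present (A-, AA- and
    AB-paths), and the B-open end first for B-paths.
    """

    walk: list[Extremity]
    kind: ComponentKind
    index: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.walk) if self.kind is ComponentKind.CYCLE else len(self.walk) - 1

    @property
    def odd(self) -> bool:
        return self.n_edges % 2 == 1

    @property
    def open_ends(self) -> tuple[Extremity, ...]:
        if self.kind is ComponentKind.AA or self.kind is ComponentKind.BB:
            return (self.walk[0], self.walk[-1])
        if self.kind is ComponentKind.AB:
            return (self.walk[0], self.walk[-1])  # (A-open, B-open)
        if self.kind is ComponentKind.A or self.kind is ComponentKind.B:
            return (self.walk[0],)
        return ()


@dataclass
class ComponentInventory:
    """Counts of breakpoint-graph features entering the distance formulas."""

    n: int = 0  # genes in the singleton-reduced union set
    cycles: int = 0
    p_even_not_open: int = 0
    p_odd_not_open: int = 0
    p_AB: int = 0
    p_AA: int = 0
    p_BB: int = 0
    p_A_odd: int = 0
    p_A_even: int = 0
    p_B_odd: int = 0
    p_B_even: int = 0
    sing: int = 0
    n_A: int = 0  # |V_B - V_A|, unique genes of B
    n_B: int = 0  # |V_A - V_B|, unique genes of A

    @property
    def paths(self) -> int:
        return (
            self.p_even_not_open
            + self.p_odd_not_open
            + self.p_AB
            + self.p_AA
            + self.p_BB
            + self.p_A_odd
            + self.p_A_even
            + self.p_B_odd
            + self.p_B_even
        )


@dataclass
class BreakpointGraph:
    a_genome: Genome
    b_genome: Genome
    genes: frozenset[int] = field(default_factory=frozenset)
    a_edges: dict[Extremity, Extremity] = field(default_factory=dict)
    b_edges: dict[Extremity, Extremity] = field(default_factory=dict)
    a_open: frozenset[Extremity] = field(default_factory=frozenset)
    b_open: frozenset[Extremity] = field(default_factory=frozenset)
    components: list[Component] = field(default_factory=list)
    inventory: ComponentInventory = field(default_factory=ComponentInventory)

    def components_of(self, *kinds: ComponentKind) -> list[Component]:
        return [c for c in self.components if c.kind in kinds]


def _singleton_genes(genome: Genome, unique: frozenset[int]) -> tuple[int, frozenset[int]]:
    """Count circular chromosomes made only of ``unique`` genes; return genes."""
    count = 0
    genes: set[int] = set()
    for chrom in genome.chromosomes():
        if chrom.circular and chrom.gene_set <= unique:
            count += 1
            genes |= chrom.gene_set
    return count, frozenset(genes)


def build_bp_graph(a: Genome, b: Genome) -> BreakpointGraph:
    """Construct BP(A, B), classify components and fill the inventory."""
    unique_a = a.genes - b.genes
    unique_b = b.genes - a.genes
    sing_a, sing_genes_a = _singleton_genes(a, unique_a)
    sing_b, sing_genes_b = _singleton_genes(b, unique_b)
    removed = sing_genes_a | sing_genes_b
    genes = (a.genes | b.genes) - removed

    def edge_map(genome: Genome) -> dict[Extremity, Extremity]:
        edges: dict[Extremity, Extremity] = {}
        for adj in genome.adjacencies:
            if is_telomeric(adj):
                continue
            x, y = adj
            if x[0] in removed:  # whole singleton chromosomes are excised
                continue
            edges[x] = y
            edges[y] = x
        return edges

    graph = BreakpointGraph(
        a_genome=a,
        b_genome=b,
        genes=frozenset(genes),
        a_edges=edge_map(a),
        b_edges=edge_map(b),
        a_open=frozenset(
            ext for g in unique_b - removed for ext in (tail(g), head(g))
        ),
        b_open=frozenset(
            ext for g in unique_a - removed for ext in (tail(g), head(g))
        ),
    )
    inv = graph.inventory
    inv.n = len(genes)
    inv.sing = sing_a + sing_b
    inv.n_A = len(unique_b)
    inv.n_B = len(unique_a)

    _classify_components(graph)
    return graph


def _classify_components(graph: BreakpointGraph) -> None:
    inv = graph.inventory
    seen: set[Extremity] = set()
    vertices = sorted(
        ext for g in sorted(graph.genes) for ext in (tail(g), head(g))
    )

    def degree1(v: Extremity) -> bool:
        in_a = v in graph.a_edges
        in_b = v in graph.b_edges
        return not (in_a and in_b)

    def trace_path(start: Extremity) -> list[Extremity]:
        """Trace an alternating path starting at a degree<=1 vertex."""
        walk = [start]
        prev_color: str | None = None
        while True:
            cur = walk[-1]
            candidates = []
            if prev_color != "a" and cur in graph.a_edges:
                candidates.append(("a", graph.a_edges[cur]))
            if prev_color != "b" and cur in graph.b_edges:
                candidates.append(("b", graph.b_edges[cur]))
            if not candidates:
                return walk
            color, nxt = candidates[0]
            walk.append(nxt)
            prev_color = color

    # paths: start from endpoints (degree <= 1)
    for v in vertices:
        if v in seen or not degree1(v):
            continue
        walk = trace_path(v)
        if walk[-1] < walk[0]:
            walk.reverse()
        seen.update(walk)
        comp = Component(walk, _path_kind(graph, walk))
        _orient_open_first(graph, comp)
        comp.index = len(graph.components)
        graph.components.append(comp)
        _tally_path(inv, comp)

    # remaining vertices lie on cycles
    for v in vertices:
        if v in seen:
            continue
        walk = [v]
        prev_color = "b"  # start by following an A-edge
        cur = v
        while True:
            edges = graph.a_edges if prev_color == "b" else graph.b_edges
            nxt = edges[cur]
            prev_color = "a" if prev_color == "b" else "b"
            if nxt == v:
                break
            walk.append(nxt)
            cur = nxt
        seen.update(walk)
        comp = Component(walk, ComponentKind.CYCLE, index=len(graph.components))
        graph.components.append(comp)
        inv.cycles += 1


def _path_kind(graph: BreakpointGraph, walk: list[Extremity]) -> ComponentKind:
    ends = [walk[0], walk[-1]]
    a_open = sum(1 for e in ends if e in graph.a_open)
    b_open = sum(1 for e in ends if e in graph.b_open)
    if len(walk) == 1:
        # a single vertex: one open (or closed) end, the other end closed
        if walk[0] in graph.a_open:
            return ComponentKind.A
        if walk[0] in graph.b_open:
            return ComponentKind.B
        return ComponentKind.NOT_OPEN
    if a_open == 2:
        return ComponentKind.AA
    if b_open == 2:
        return ComponentKind.BB
    if a_open == 1 and b_open == 1:
        return ComponentKind.AB
    if a_open == 1:
        return ComponentKind.A
    if b_open == 1:
        return ComponentKind.B
    return ComponentKind.NOT_OPEN


def _orient_open_first(graph: BreakpointGraph, comp: Component) -> None:
    if comp.kind is ComponentKind.AB:
        if comp.walk[0] not in graph.a_open:
            comp.walk.reverse()
    elif comp.kind is ComponentKind.A:
        if comp.walk[0] not in graph.a_open:
            comp.walk.reverse()
    elif comp.kind is ComponentKind.B:
        if comp.walk[0] not in graph.b_open:
            comp.walk.reverse()


def _tally_path(inv: ComponentInventory, comp: Component) -> None:
    odd = comp.odd
    kind = comp.kind
    if kind is ComponentKind.NOT_OPEN:
        if odd:
            inv.p_odd_not_open += 1
        else:
            inv.p_even_not_open += 1
    elif kind is ComponentKind.AB:
        inv.p_AB += 1
    elif kind is ComponentKind.AA:
        inv.p_AA += 1
    elif kind is ComponentKind.BB:
        inv.p_BB += 1
    elif kind is ComponentKind.A:
        if odd:
            inv.p_A_odd += 1
        else:
            inv.p_A_even += 1
    elif kind is ComponentKind.B:
        if odd:
            inv.p_B_odd += 1
        else:
            inv.p_B_even += 1


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def dcj_distance(a: Genome, b: Genome) -> int:
    """Equal-content DCJ distance ``n - c - p_even/2``."""
    if a.genes != b.genes:
        raise GenomeError(
            "genomes have unequal gene content; use dcj_indel_distance"
        )
    graph = build_bp_graph(a, b)
    inv = graph.inventory
    twice = 2 * inv.n - 2 * inv.cycles - inv.p_even_not_open
    assert twice % 2 == 0 and twice >= 0
    return twice // 2


def _optimal_delta_twice(inv: ComponentInventory) -> int:
    """Twice the cycles-plus-half-even-paths gained by an optimal completion.

    Pairs of AB-paths close into cycles, AA- and BB-paths self-close, odd
    A-paths pair with even A-paths into even paths (same for B), and when
    the number of AB-paths is odd one A-/AB-/B-path triple absorbs the
    leftover; in the strict-inequality regimes the triple itself forms an
    even path, gaining an extra half unit.
    """
    q = inv.p_AB
    delta2 = 2 * (inv.p_AA + inv.p_BB) + 2 * (q // 2)
    delta2 += min(inv.p_A_odd, inv.p_A_even) + min(inv.p_B_odd, inv.p_B_even)
    if q % 2 == 1:
        strict5 = inv.p_A_odd < inv.p_A_even and inv.p_B_odd < inv.p_B_even
        strict6 = inv.p_A_odd > inv.p_A_even and inv.p_B_odd > inv.p_B_even
        if strict5 or strict6:
            delta2 += 1
    return delta2


def dcj_indel_distance(a: Genome, b: Genome) -> int:
    """DCJ-indel distance via the closed-form optimal-completion formula."""
    graph = build_bp_graph(a, b)
    return dcj_indel_distance_from_graph(graph)


def dcj_indel_distance_from_graph(graph: BreakpointGraph) -> int:
    inv = graph.inventory
    twice = (
        2 * inv.n
        - 2 * inv.cycles
        - inv.p_even_not_open
        - _optimal_delta_twice(inv)
    )
    assert twice % 2 == 0 and twice >= 0, "non-integral DCJ-indel distance"
    return twice // 2 + inv.sing


# ---------------------------------------------------------------------------
# circularization
# ---------------------------------------------------------------------------

ARTIFICIAL = "art"


def artificial_vertex(idx: int) -> Extremity:
    """Artificial circularization vertex; distinct from the telomere marker."""
    return (-idx - 1, ARTIFICIAL)


def is_artificial(ext: Extremity) -> bool:
    return ext[1] == ARTIFICIAL


def circularize_walk(
    walk: list[Extremity], is_cycle: bool, next_idx: int = 0
) -> tuple[list[Extremity], int]:
    """Close a path into a cycle with 1 (even path) or 2 (odd) new vertices.

    Returns the cyclic vertex order and the updated artificial-vertex
    counter.  Cycles pass through unchanged.
    """
    if is_cycle:
        return list(walk), next_idx
    n_edges = len(walk) - 1
    if n_edges % 2 == 0:
        return list(walk) + [artificial_vertex(next_idx)], next_idx + 1
    return (
        list(walk)
        + [artificial_vertex(next_idx), artificial_vertex(next_idx + 1)],
        next_idx + 2,
    )


def circularize(graph: BreakpointGraph) -> tuple[list[list[Extremity]], int]:
    """Circularized component list plus the artificial-vertex count.

    On the resulting all-cycle graph, the DCJ distance equals
    ``n' - c'`` with ``n' = n + k/2`` for ``k`` artificial vertices.
    """
    cycles: list[list[Extremity]] = []
    idx = 0
    for comp in graph.components:
        cyc, idx = circularize_walk(comp.walk, comp.kind is ComponentKind.CYCLE, idx)
        cycles.append(cyc)
    return cycles, idx
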