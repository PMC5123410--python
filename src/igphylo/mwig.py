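"""Maximum Weight Intermediate Genome (MWIG) machinery.

An *intermediate genome* of A and B is any genome lying on an optimal
DCJ-indel scenario between them; equivalently (for independent-component
scenarios) a set of non-crossing chords covering all vertices of the
circularized optimal completion of BP(A, B), with artificial singletons
stripped.  Given per-adjacency confidence weights, the MWIG problem asks
for the intermediate genome of maximum total weight.

The heuristic here scores each candidate component linking by a maximum
weight non-crossing perfect chord matching (interval dynamic programming),
then picks the linking itself by a maximum-weight perfect matching over the
completion hypergraph, handling an odd number of AB-paths through three
dummy vertices that select a single component triple.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .bpgraph import (
    BreakpointGraph,
    Component,
    ComponentKind,
    artificial_vertex,
    build_bp_graph,
    circularize_walk,
    dcj_indel_distance,
    is_artificial,
)
from .completions import (
    _TRIPLE_SETS,
    Completion,
    select_case,
)
from .genomes import (
    TELOMERE,
    Adjacency,
    Chromosome,
    Extremity,
    Genome,
    adjacency,
)

PairKey = tuple[Extremity, Extremity]


class WeightTable:
    """Symmetric map from extremity pairs to nonnegative weights.

    Absent pairs weigh 0.  Telomeric adjacencies are keyed by
    ``(TELOMERE, x)``; chords to artificial circularization vertices look
    their weight up through that key.
    """

    def __init__(self, weights: Mapping[PairKey, float] | Iterable[tuple[PairKey, float]] = ()):
        self._w: dict[PairKey, float] = {}
        self._index: dict[Extremity, list[tuple[Extremity, float]]] | None = None
        items = weights.items() if isinstance(weights, Mapping) else weights
        for (x, y), w in items:
            self.set(x, y, w)

    def set(self, x: Extremity, y: Extremity, w: float) -> None:
        if w < 0 or w != w:
            raise ValueError(f"weight for ({x}, {y}) must be finite and >= 0")
        self._w[adjacency(x, y)] = float(w)
        self._index = None

    def get(self, x: Extremity, y: Extremity) -> float:
        return self._w.get(adjacency(x, y), 0.0)

    def get_adj(self, adj: Adjacency) -> float:
        return self._w.get(adj, 0.0)

    def items(self):
        return self._w.items()

    def __len__(self) -> int:
        return len(self._w)

    def __eq__(self, other) -> bool:
        return isinstance(other, WeightTable) and self._w == other._w

    def positive_partners(self, x: Extremity) -> list[tuple[Extremity, float]]:
        if self._index is None:
            index: dict[Extremity, list[tuple[Extremity, float]]] = {}
            for (u, v), w in self._w.items():
                if w <= 0:
                    continue
                index.setdefault(u, []).append((v, w))
                index.setdefault(v, []).append((u, w))
            self._index = index
        return self._index.get(x, [])

    @staticmethod
    def from_genome(genome: Genome) -> "WeightTable":
        """Leaf indicator table: weight 1 for every present adjacency."""
        return WeightTable({adj: 1.0 for adj in genome.adjacencies})


def chord_weight(table: WeightTable, x: Extremity, y: Extremity) -> float:
    """Weight of a chord of the circularized completion.

    Chords to an artificial vertex encode telomeric adjacencies and use the
    telomeric weight of the real endpoint; a chord joining two artificial
    vertices carries no adjacency and weighs 0.
    """
    ax, ay = is_artificial(x), is_artificial(y)
    if ax and ay:
        return 0.0
    if ax:
        return table.get(TELOMERE, y)
    if ay:
        return table.get(TELOMERE, x)
    return table.get(x, y)


def chords_to_adjacencies(chords: Iterable[PairKey]) -> set[Adjacency]:
    adjs: set[Adjacency] = set()
    for x, y in chords:
        ax, ay = is_artificial(x), is_artificial(y)
        if ax and ay:
            continue
        if ax:
            adjs.add(adjacency(TELOMERE, y))
        elif ay:
            adjs.add(adjacency(TELOMERE, x))
        else:
            adjs.add(adjacency(x, y))
    return adjs


# ---------------------------------------------------------------------------
# maximum weight non-crossing perfect chord matching
# ---------------------------------------------------------------------------

def max_noncrossing_matching(
    cycle: list[Extremity], table: WeightTable
) -> tuple[list[PairKey], float]:
    """Best non-crossing perfect matching of a cyclic vertex order.

    Interval dynamic programming; when no chord has positive weight the
    adjacent pairing is returned directly.  Split points are restricted to
    the neighborhoods of positive-chord endpoints, which leaves the optimum
    unchanged (sliding a zero chord's endpoint across positions that touch
    no positive chord moves free vertices between faces of the chord
    partition without changing any face's parity).
    """
    L = len(cycle)
    if L == 0:
        return [], 0.0
    if L % 2 == 1:
        raise ValueError("odd vertex count; circularize first")

    pos: dict[Extremity, int] = {v: i for i, v in enumerate(cycle)}
    art_positions = [i for i, v in enumerate(cycle) if is_artificial(v)]

    positive: dict[tuple[int, int], float] = {}
    for i, v in enumerate(cycle):
        if is_artificial(v):
            continue
        for partner, w in table.positive_partners(v):
            if partner == TELOMERE:
                for j in art_positions:
                    positive[(min(i, j), max(i, j))] = w
            else:
                j = pos.get(partner)
                if j is not None and j != i:
                    positive[(min(i, j), max(i, j))] = w

    if not positive:
        chords = [(cycle[i], cycle[i + 1]) for i in range(0, L, 2)]
        return chords, 0.0

    endpoints = sorted({e for pair in positive for e in pair})

    def w_at(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key in positive:
            return positive[key]
        return chord_weight(table, cycle[i], cycle[j])

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * L + 100))
    memo: dict[tuple[int, int], tuple[float, int]] = {}

    def candidates(i: int, j: int) -> list[int]:
        ks = {i + 1, j}
        for e in endpoints:
            if i < e <= j:
                for k in (e - 1, e, e + 1):
                    if i < k <= j and (k - i) % 2 == 1:
                        ks.add(k)
        return sorted(k for k in ks if (k - i) % 2 == 1)

    def best(i: int, j: int) -> float:
        if i > j:
            return 0.0
        key = (i, j)
        if key in memo:
            return memo[key][0]
        best_w, best_k = -1.0, -1
        for k in candidates(i, j):
            w = w_at(i, k) + best(i + 1, k - 1) + best(k + 1, j)
            if w > best_w:
                best_w, best_k = w, k
        memo[key] = (best_w, best_k)
        return best_w

    total = best(0, L - 1)

    chords: list[PairKey] = []

    def collect(i: int, j: int) -> None:
        if i > j:
            return
        _, k = memo[(i, j)]
        chords.append((cycle[i], cycle[k]))
        collect(i + 1, k - 1)
        collect(k + 1, j)

    collect(0, L - 1)
    return chords, total


# ---------------------------------------------------------------------------
# hyperedge scoring: merge components, circularize, run the chord DP
# ---------------------------------------------------------------------------

@dataclass
class ScoredComponent:
    """A (merged) component with its best chord matching."""

    cycle: list[Extremity]
    chords: list[PairKey]
    weight: float
    a_links: list[PairKey] = field(default_factory=list)
    b_links: list[PairKey] = field(default_factory=list)


def merge_components(
    comps: list[Component], next_artificial: int = 0
) -> tuple[ScoredComponent, int]:
    """Apply the forced linking of a hyperedge and circularize the result.

    Single components pass through (AA/BB self-close); pairs of same-side
    paths join their open ends; an AB pair closes into a cycle; a triple
    chains A-path -> AB-path -> B-path through its open endpoints.
    """
    kinds = [c.kind for c in comps]
    a_links: list[PairKey] = []
    b_links: list[PairKey] = []
    if len(comps) == 1:
        c = comps[0]
        if c.kind is ComponentKind.AA:
            a_links.append((c.walk[0], c.walk[-1]))
            cycle, nxt = list(c.walk), next_artificial
        elif c.kind is ComponentKind.BB:
            b_links.append((c.walk[0], c.walk[-1]))
            cycle, nxt = list(c.walk), next_artificial
        else:  # a cycle or a not-open path
            cycle, nxt = circularize_walk(
                c.walk, c.kind is ComponentKind.CYCLE, next_artificial
            )
    elif len(comps) == 2:
        c1, c2 = comps
        if set(kinds) == {ComponentKind.AB}:
            a_links.append((c1.walk[0], c2.walk[0]))
            b_links.append((c1.walk[-1], c2.walk[-1]))
            cycle, nxt = list(c1.walk) + list(reversed(c2.walk)), next_artificial
        elif set(kinds) == {ComponentKind.A}:
            a_links.append((c1.walk[0], c2.walk[0]))
            merged = list(reversed(c1.walk)) + list(c2.walk)
            cycle, nxt = circularize_walk(merged, False, next_artificial)
        elif set(kinds) == {ComponentKind.B}:
            b_links.append((c1.walk[0], c2.walk[0]))
            merged = list(reversed(c1.walk)) + list(c2.walk)
            cycle, nxt = circularize_walk(merged, False, next_artificial)
        else:
            raise ValueError(f"cannot link components of kinds {kinds}")
    elif len(comps) == 3:
        ca, cab, cb = comps
        if (ca.kind, cab.kind, cb.kind) != (
            ComponentKind.A,
            ComponentKind.AB,
            ComponentKind.B,
        ):
            raise ValueError(f"triple must be (A, AB, B), got {kinds}")
        a_links.append((ca.walk[0], cab.walk[0]))
        b_links.append((cab.walk[-1], cb.walk[0]))
        merged = list(reversed(ca.walk)) + list(cab.walk) + list(cb.walk)
        cycle, nxt = circularize_walk(merged, False, next_artificial)
    else:
        raise ValueError("hyperedges have at most three components")
    return ScoredComponent(cycle, [], 0.0, a_links, b_links), nxt


def score_component(
    comps: list[Component], table: WeightTable, next_artificial: int = 0
) -> tuple[ScoredComponent, int]:
    scored, nxt = merge_components(comps, next_artificial)
    scored.chords, scored.weight = max_noncrossing_matching(scored.cycle, table)
    return scored, nxt


def score_hyperedge(
    components: tuple[int, ...], graph: BreakpointGraph, table: WeightTable,
    _cache: dict | None = None,
) -> float:
    """Weight of a hyperedge: the chord-DP optimum of its merged component."""
    key = tuple(sorted(components))
    if _cache is not None and key in _cache:
        return _cache[key]
    comps = _ordered_edge_components(graph, components)
    scored, _ = score_component(comps, table)
    if _cache is not None:
        _cache[key] = scored.weight
    return scored.weight


def _ordered_edge_components(
    graph: BreakpointGraph, components: tuple[int, ...]
) -> list[Component]:
    comps = [graph.components[i] for i in components]
    if len(comps) == 3:
        comps.sort(key=lambda c: {ComponentKind.A: 0, ComponentKind.AB: 1,
                                  ComponentKind.B: 2}[c.kind])
    return comps


# ---------------------------------------------------------------------------
# the MWIG heuristic
# ---------------------------------------------------------------------------

@dataclass
class IGCandidate:
    """Heuristic MWIG output: chords M', stripped singletons S, M = M' - S."""

    genome: Genome
    m_prime: frozenset[Adjacency]
    singletons: list[Chromosome]
    weight: float
    completion: Completion


_DUMMY_EPS = 1e-9

#: triple types that keep a completion optimal, per case (the case's own
#: printed type first; the alternatives consume a surplus parity instead and
#: yield the same distance)
_OPTIMAL_TRIPLE_TYPES = {
    3: ("T10", "T8", "T11"),
    4: ("T9", "T8", "T11"),
    5: ("T11",),
    6: ("T8",),
}


def _class_members(graph: BreakpointGraph) -> dict[str, list[Component]]:
    open_comps = graph.components_of(
        ComponentKind.A, ComponentKind.B, ComponentKind.AB
    )
    return {
        "lambda_odd": [c for c in open_comps if c.kind is ComponentKind.A and c.odd],
        "lambda_even": [c for c in open_comps if c.kind is ComponentKind.A and not c.odd],
        "gamma_odd": [c for c in open_comps if c.kind is ComponentKind.B and c.odd],
        "gamma_even": [c for c in open_comps if c.kind is ComponentKind.B and not c.odd],
        "upsilon": [c for c in open_comps if c.kind is ComponentKind.AB],
    }


def _pair_matching(
    graph: BreakpointGraph,
    case,
    by_class: dict[str, list[Component]],
    table: WeightTable,
    cache: dict,
    excluded: set[int] = frozenset(),
    dummy_sets: tuple[str, str] | None = None,
) -> tuple[float, list[tuple[int, ...]], tuple[int, int, int] | None] | None:
    """Maximum-weight perfect matching over open components.

    ``excluded`` components are left out (a triple chosen by the sweep);
    with ``dummy_sets`` three zero-weight dummy vertices pick the triple
    instead.  Returns (pair weight, pair groups, dummy triple) or None when
    no perfect matching exists.
    """
    from .completions import _PAIR_SETS

    G = nx.Graph()
    active = [
        c for cs in by_class.values() for c in cs if c.index not in excluded
    ]
    for c in sorted(active, key=lambda c: c.index):
        G.add_node(c.index)

    def members(cls: str) -> list[Component]:
        return [c for c in by_class[cls] if c.index not in excluded]

    for klass in case.pair_classes:
        s1, s2 = _PAIR_SETS[klass]
        if s1 == s2:
            ms = members(s1)
            pairs = [
                (u.index, v.index)
                for i, u in enumerate(ms)
                for v in ms[i + 1:]
            ]
        else:
            pairs = [(u.index, v.index) for u in members(s1) for v in members(s2)]
        for u, v in pairs:
            G.add_edge(u, v, weight=score_hyperedge((u, v), graph, table, cache))

    dummies = ("dummy_a", "dummy_ab", "dummy_b")
    if dummy_sets is not None:
        aset, bset = dummy_sets
        for dummy, ms in (
            ("dummy_a", members(aset)),
            ("dummy_ab", members("upsilon")),
            ("dummy_b", members(bset)),
        ):
            G.add_node(dummy)
            for c in ms:
                # zero weight; tiny penalty prefers small components
                G.add_edge(dummy, c.index, weight=-_DUMMY_EPS * len(c.walk))

    matching = nx.max_weight_matching(G, maxcardinality=True)
    matched: dict = {}
    for u, v in matching:
        matched[u] = v
        matched[v] = u
    if any(n not in matched for n in G.nodes):
        return None

    triple: tuple[int, int, int] | None = None
    if dummy_sets is not None:
        triple = tuple(matched[d] for d in dummies)  # type: ignore[assignment]
    done: set[int] = set(triple or ())
    weight = 0.0
    groups: list[tuple[int, ...]] = []
    for u, v in sorted(
        (min(u, v), max(u, v))
        for u, v in matching
        if not isinstance(u, str) and not isinstance(v, str)
    ):
        if u in done or v in done:
            continue
        groups.append((u, v))
        weight += G.edges[u, v]["weight"]
        done |= {u, v}
    return weight, groups, triple


def mwig_heuristic(
    a: Genome,
    b: Genome,
    table: WeightTable,
    name: str = "M",
    triple_mode: str = "auto",
    sweep_cap: int = 500,
) -> IGCandidate:
    """Reconstruct a high-weight intermediate genome of ``a`` and ``b``.

    Builds the completion hypergraph without triple hyperedges, scores each
    pair edge with the chord DP, and extracts a maximum-weight perfect
    matching.  An odd number of AB-paths needs one component triple; since
    the pairwise matching cannot see a triple's own chord score, the
    single-triple regime is solved exactly by sweeping all candidate
    triples (``triple_mode="sweep"``), falling back to the fast reduction
    with three zero-weight dummy vertices (``"dummy"``) when the candidate
    count exceeds ``sweep_cap`` (``"auto"``).  Dummy edges are restricted
    to the parity classes of the applicable case's triple type so every
    matching remains an optimal completion.
    """
    graph = build_bp_graph(a, b)
    inv = graph.inventory
    case = select_case(inv)
    by_class = _class_members(graph)
    cache: dict = {}

    chosen: tuple[float, list[tuple[int, ...]], tuple[int, ...] | None] | None = None
    if inv.p_AB % 2 == 0:
        res = _pair_matching(graph, case, by_class, table, cache)
        if res is None:
            raise RuntimeError("no perfect matching over open components")
        chosen = (res[0], res[1], None)
    else:
        assert case.triple_class is not None
        types = _OPTIMAL_TRIPLE_TYPES[case.case_id]
        candidates: list[tuple[int, int, int]] = []
        if triple_mode in ("auto", "sweep"):
            for t in types:
                aset, bset = _TRIPLE_SETS[t]
                for ca in by_class[aset]:
                    for cab in by_class["upsilon"]:
                        for cb in by_class[bset]:
                            candidates.append((ca.index, cab.index, cb.index))
            candidates = sorted(set(candidates))
        use_sweep = triple_mode == "sweep" or (
            triple_mode == "auto" and 0 < len(candidates) <= sweep_cap
        )
        if use_sweep:
            best = None
            for trip in candidates:
                res = _pair_matching(
                    graph, case, by_class, table, cache, excluded=set(trip)
                )
                if res is None:
                    continue
                t_w = score_hyperedge(trip, graph, table, cache)
                total_w = res[0] + t_w
                if best is None or total_w > best[0] + 1e-12:
                    best = (total_w, res[1], trip)
            if best is None:
                raise RuntimeError("no feasible triple linking found")
            chosen = best
        else:
            aset, bset = _TRIPLE_SETS[case.triple_class]
            res = _pair_matching(
                graph, case, by_class, table, cache, dummy_sets=(aset, bset)
            )
            if res is None:
                raise RuntimeError("no perfect matching over open components")
            chosen = (res[0], res[1], res[2])

    _, pair_groups, triple = chosen
    groups: list[tuple[int, ...]] = []
    if triple is not None:
        groups.append(tuple(triple))
    groups.extend(pair_groups)
    done: set[int] = {i for g in groups for i in g}
    for comp in graph.components:
        if comp.index not in done and comp.kind not in (
            ComponentKind.A, ComponentKind.B, ComponentKind.AB
        ):
            groups.append((comp.index,))

    # score every group and collect chords and completion edges
    total = 0.0
    all_chords: list[PairKey] = []
    a_pairs: set[Adjacency] = set()
    b_pairs: set[Adjacency] = set()
    next_art = 0
    for group in groups:
        comps = _ordered_edge_components(graph, group)
        scored, next_art = score_component(comps, table, next_art)
        total += scored.weight
        all_chords.extend(scored.chords)
        a_pairs |= {adjacency(x, y) for x, y in scored.a_links}
        b_pairs |= {adjacency(x, y) for x, y in scored.b_links}

    completion = Completion(frozenset(a_pairs), frozenset(b_pairs))
    m_prime = frozenset(chords_to_adjacencies(all_chords))

    covered = {
        ext for adj in m_prime for ext in adj if ext != TELOMERE
    }
    telomeric_fill = {
        adjacency(TELOMERE, ext)
        for g in graph.genes
        for ext in ((g, "t"), (g, "h"))
        if ext not in covered
    }
    full = Genome(name + "'", frozenset(m_prime | telomeric_fill), graph.genes)

    unique_a = a.genes - b.genes
    unique_b = b.genes - a.genes
    singles: list[Chromosome] = []
    keep_adjs: set[Adjacency] = set()
    keep_genes: set[int] = set()
    for chrom in full.chromosomes():
        if chrom.circular and (
            chrom.gene_set <= unique_a or chrom.gene_set <= unique_b
        ):
            singles.append(chrom)
        else:
            keep_adjs |= chrom.adjacencies()
            keep_genes |= chrom.gene_set
    m_genome = Genome(name, frozenset(keep_adjs), frozenset(keep_genes))

    candidate = IGCandidate(m_genome, m_prime, singles, total, completion)
    assert verify_intermediate(a, m_genome, b), (
        "heuristic output is not an intermediate genome"
    )
    return candidate


def verify_intermediate(a: Genome, m: Genome, b: Genome) -> bool:
    """Does ``m`` split the DCJ-indel distance between ``a`` and ``b`` exactly?

    ``d(A,M) + d(M,B) = d(A,B)`` holds for every intermediate genome; it is
    used as the post-condition on heuristic outputs.
    """
    return (
        dcj_indel_distance(a, m) + dcj_indel_distance(m, b)
        == dcj_indel_distance(a, b)
    )
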