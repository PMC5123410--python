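"""Deterministic generators of small instances for oracle-based testing.

These are first-class test instruments, not production paths: random
genome pairs with controlled unique-gene structure, random weight tables,
and a brute-force Maximum Weight Intermediate Genome search that
enumerates every completion and every non-crossing perfect chord matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .bpgraph import BreakpointGraph, build_bp_graph, dcj_distance
from .completions import (
    Completion,
    apply_completion_reduced,
    completion_count,
    enumerate_completions,
)
from .genomes import Chromosome, Extremity, Genome, TELOMERE, adjacency
from .mwig import PairKey, WeightTable, chord_weight, chords_to_adjacencies
from .bpgraph import ComponentKind, circularize_walk


@dataclass(frozen=True)
class FixtureSpec:
    shared: int = 4
    a_unique: int = 0
    b_unique: int = 0
    max_chromosomes: int = 2
    circular_prob: float = 0.3
    seed: int = 0


def random_genome_pair(spec: FixtureSpec) -> tuple[Genome, Genome]:
    """Random pair with exactly the requested unique-gene structure."""
    if spec.shared + spec.a_unique < 1 or spec.shared + spec.b_unique < 1:
        raise ValueError("each genome needs at least one gene")
    rng = np.random.default_rng(spec.seed)
    shared = list(range(1, spec.shared + 1))
    a_extra = list(range(spec.shared + 1, spec.shared + spec.a_unique + 1))
    b_extra = list(
        range(
            spec.shared + spec.a_unique + 1,
            spec.shared + spec.a_unique + spec.b_unique + 1,
        )
    )

    def build(name: str, genes: list[int]) -> Genome:
        genes = list(genes)
        rng.shuffle(genes)
        signed = [g if rng.random() < 0.5 else -g for g in genes]
        n_chrom = int(rng.integers(1, min(spec.max_chromosomes, len(signed)) + 1))
        cuts = sorted(
            rng.choice(range(1, len(signed)), size=n_chrom - 1, replace=False)
        ) if n_chrom > 1 else []
        bounds = [0] + [int(c) for c in cuts] + [len(signed)]
        chroms = []
        for lo, hi in zip(bounds, bounds[1:]):
            circ = bool(rng.random() < spec.circular_prob)
            chroms.append(Chromosome(tuple(signed[lo:hi]), circ))
        return Genome.from_chromosomes(name, chroms)

    return build("A", shared + a_extra), build("B", shared + b_extra)


def random_weight_table(
    genomes: tuple[Genome, ...], seed: int = 0, density: float = 0.5
) -> WeightTable:
    """Random weights on extremity pairs of the union gene set."""
    rng = np.random.default_rng(seed)
    exts: list[Extremity] = sorted(
        ext
        for g in sorted(set().union(*(gen.genes for gen in genomes)))
        for ext in ((g, "t"), (g, "h"))
    )
    table = WeightTable()
    for i, x in enumerate(exts):
        for y in exts[i + 1:]:
            if rng.random() < density:
                table.set(x, y, float(rng.uniform(0.0, 1.0)))
        if rng.random() < density / 2:
            table.set(TELOMERE, x, float(rng.uniform(0.0, 1.0)))
    return table


# ---------------------------------------------------------------------------
# brute-force MWIG oracle
# ---------------------------------------------------------------------------

def enumerate_noncrossing_matchings(k: int) -> Iterator[list[tuple[int, int]]]:
    """All non-crossing perfect matchings of positions 0..k-1 (Catalan many)."""
    if k == 0:
        yield []
        return
    for j in range(1, k, 2):
        for inner in enumerate_noncrossing_matchings(j - 1):
            for outer in enumerate_noncrossing_matchings(k - j - 1):
                inside = [(a + 1, b + 1) for a, b in inner]
                outside = [(a + j + 1, b + j + 1) for a, b in outer]
                yield [(0, j)] + inside + outside


def _completed_cycles(graph: BreakpointGraph, comp: Completion) -> list[list[Extremity]]:
    """Circularized components of the completed breakpoint graph."""
    a2, b2 = apply_completion_reduced(graph, comp)
    g2 = build_bp_graph(a2, b2)
    cycles = []
    idx = 0
    for c in g2.components:
        cyc, idx = circularize_walk(c.walk, c.kind is ComponentKind.CYCLE, idx)
        cycles.append(cyc)
    return cycles


@dataclass
class OracleResult:
    completion: Completion
    chords: list[PairKey]
    weight: float
    distance: int


def brute_force_mwig(
    a: Genome,
    b: Genome,
    table: WeightTable,
    completion_cap: int = 10**5,
    cycle_cap: int = 16,
) -> OracleResult:
    """Exhaustive MWIG over all optimal completions and chord matchings."""
    graph = build_bp_graph(a, b)
    if completion_count(graph) > completion_cap:
        raise ValueError("completion space above the oracle cap")

    completions = list(enumerate_completions(graph, cap=completion_cap))
    dists = []
    for comp in completions:
        a2, b2 = apply_completion_reduced(graph, comp)
        dists.append(dcj_distance(a2, b2))
    dmin = min(dists)

    best: OracleResult | None = None
    for comp, d in zip(completions, dists):
        if d != dmin:
            continue
        total = 0.0
        chords: list[PairKey] = []
        for cycle in _completed_cycles(graph, comp):
            if len(cycle) > cycle_cap:
                raise ValueError(
                    f"cycle of length {len(cycle)} above the oracle cap"
                )
            best_w, best_ch = -1.0, None
            for matching in enumerate_noncrossing_matchings(len(cycle)):
                w = sum(
                    chord_weight(table, cycle[i], cycle[j]) for i, j in matching
                )
                if w > best_w:
                    best_w = w
                    best_ch = [(cycle[i], cycle[j]) for i, j in matching]
            assert best_ch is not None
            total += best_w
            chords.extend(best_ch)
        if best is None or total > best.weight + 1e-12:
            best = OracleResult(comp, chords, total, dmin)
    assert best is not None
    return best


def oracle_genome(a: Genome, b: Genome, result: OracleResult, name: str = "M") -> Genome:
    """Assemble the oracle's chord set into a genome (singletons stripped)."""
    graph = build_bp_graph(a, b)
    adjs = chords_to_adjacencies(result.chords)
    covered = {ext for adj in adjs for ext in adj if ext != TELOMERE}
    fill = {
        adjacency(TELOMERE, (g, e))
        for g in graph.genes
        for e in ("t", "h")
        if (g, e) not in covered
    }
    full = Genome(name + "'", frozenset(adjs | fill), graph.genes)
    unique_a = a.genes - b.genes
    unique_b = b.genes - a.genes
    keep_adjs: set = set()
    keep_genes: set[int] = set()
    for chrom in full.chromosomes():
        if chrom.circular and (
            chrom.gene_set <= unique_a or chrom.gene_set <= unique_b
        ):
            continue
        keep_adjs |= chrom.adjacencies()
        keep_genes |= chrom.gene_set
    return Genome(name, frozenset(keep_adjs), frozenset(keep_genes))
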