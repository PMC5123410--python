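"""Breakpoint graph construction, component inventory, distances."""

import pytest

from igphylo.bpgraph import (
    ComponentKind,
    build_bp_graph,
    circularize,
    dcj_distance,
    dcj_indel_distance,
)
from igphylo.fixtures import FixtureSpec, random_genome_pair
from igphylo.genomes import GenomeError, parse_genomes


class TestInventory:
    def test_worked_unequal_pair(self, fig_pair):
        a, b = fig_pair
        inv = build_bp_graph(a, b).inventory
        assert inv.p_AA == 1
        assert inv.p_AB == 2
        assert inv.cycles == 0
        assert inv.sing == 0
        assert inv.n_A == 2 and inv.n_B == 1

    def test_identical_circular_genome_all_two_cycles(self):
        (g,) = parse_genomes(">G\n1 2 3 4 5 @\n")
        graph = build_bp_graph(g, g.renamed("H"))
        inv = graph.inventory
        assert inv.cycles == inv.n == 5
        assert inv.paths == 0

    def test_two_disjoint_circular_singletons(self):
        a, b = parse_genomes(">A\n1 @\n>B\n2 @\n")
        graph = build_bp_graph(a, b)
        assert graph.inventory.sing == 2
        assert graph.components == []
        assert graph.inventory.n == 0

    @pytest.mark.parametrize("seed", range(60))
    def test_open_endpoint_conservation(self, seed):
        """2 n_A A-open and 2 n_B B-open vertices appear as path endpoints."""
        a, b = random_genome_pair(
            FixtureSpec(
                shared=(seed % 5) + 1,
                a_unique=seed % 3,
                b_unique=(seed // 3) % 3,
                circular_prob=0.0,  # keep unique genes out of singletons
                seed=seed,
            )
        )
        graph = build_bp_graph(a, b)
        inv = graph.inventory
        a_open_ends = 2 * inv.p_AA + inv.p_AB + inv.p_A_odd + inv.p_A_even
        b_open_ends = 2 * inv.p_BB + inv.p_AB + inv.p_B_odd + inv.p_B_even
        assert a_open_ends == len(graph.a_open) == 2 * inv.n_A
        assert b_open_ends == len(graph.b_open) == 2 * inv.n_B


class TestDCJDistance:
    def test_fragmentation_costs_n_minus_1(self, toy_linear):
        x, y, _ = toy_linear
        assert dcj_distance(x, y) == 3

    def test_reordering_two_blocks(self, toy_linear):
        x, _, z = toy_linear
        assert dcj_distance(x, z) == 2

    def test_self_distance_zero(self, toy_linear):
        for g in toy_linear:
            assert dcj_distance(g, g.renamed("copy")) == 0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_full_fragmentation_general(self, n):
        text = ">A\n" + " ".join(map(str, range(1, n + 1))) + " $\n"
        text += ">B\n" + "".join(f"{i} $\n" for i in range(1, n + 1))
        a, b = parse_genomes(text)
        assert dcj_distance(a, b) == n - 1

    def test_rejects_unequal_content(self, fig_pair):
        with pytest.raises(GenomeError, match="dcj_indel"):
            dcj_distance(*fig_pair)


class TestDCJIndelDistance:
    def test_worked_pair_distance_three(self, fig_pair):
        assert dcj_indel_distance(*fig_pair) == 3

    def test_identical_genomes(self):
        (g,) = parse_genomes(">G\n1 -2 3 $\n4 @\n")
        assert dcj_indel_distance(g, g.renamed("H")) == 0

    def test_disjoint_singletons(self):
        a, b = parse_genomes(">A\n1 @\n>B\n2 @\n")
        assert dcj_indel_distance(a, b) == 2

    def test_single_insertion(self):
        a, b = parse_genomes(">A\n1 $\n>B\n1 2 $\n")
        assert dcj_indel_distance(a, b) == 1

    def test_equals_dcj_on_equal_content(self):
        for seed in range(30):
            a, b = random_genome_pair(
                FixtureSpec(shared=(seed % 6) + 2, seed=seed)
            )
            assert dcj_indel_distance(a, b) == dcj_distance(a, b)

    @pytest.mark.parametrize("seed", range(40))
    def test_metric_properties_on_random_triples(self, seed):
        specs = [
            FixtureSpec(shared=4, a_unique=1, b_unique=1, seed=seed + off)
            for off in (0, 1000, 2000)
        ]
        gs = [random_genome_pair(s)[0].renamed(f"G{i}") for i, s in enumerate(specs)]
        d01 = dcj_indel_distance(gs[0], gs[1])
        d10 = dcj_indel_distance(gs[1], gs[0])
        d12 = dcj_indel_distance(gs[1], gs[2])
        d02 = dcj_indel_distance(gs[0], gs[2])
        assert d01 == d10 >= 0
        assert d02 <= d01 + d12

    def test_zero_iff_equal_adjacency_sets(self):
        a, b = parse_genomes(">A\n1 2 $\n>B\n1 -2 $\n")
        assert dcj_indel_distance(a, b) > 0
        c, d = parse_genomes(">C\n1 2 $\n>D\n-2 -1 $\n")
        assert dcj_indel_distance(c, d) == 0


class TestCircularize:
    def test_even_and_odd_path_closure_sizes(self):
        # A=(1) linear vs B=(1 2) linear: one odd path, one even A-path,
        # one isolated not-open vertex
        a, b = parse_genomes(">A\n1 $\n>B\n1 2 $\n")
        graph = build_bp_graph(a, b)
        cycles, k = circularize(graph)
        assert all(len(c) % 2 == 0 for c in cycles)
        by_kind = {c.kind for c in graph.components}
        assert ComponentKind.A in by_kind

    @pytest.mark.parametrize("seed", range(200))
    def test_distance_preserved_on_equal_content_pairs(self, seed):
        a, b = random_genome_pair(
            FixtureSpec(shared=(seed % 7) + 2, max_chromosomes=2, seed=seed)
        )
        graph = build_bp_graph(a, b)
        cycles, k = circularize(graph)
        n_prime = graph.inventory.n + k / 2
        c_prime = len(cycles)
        assert n_prime - c_prime == dcj_distance(a, b)
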