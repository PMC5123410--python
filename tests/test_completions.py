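"""Optimal-completion space: case rules, hypergraph, enumeration oracle."""

import pytest

from igphylo.bpgraph import build_bp_graph, dcj_distance
from igphylo.completions import (
    Completion,
    apply_completion_reduced,
    build_hypergraph,
    completion_count,
    enumerate_completions,
    enumerated_min_distance,
    optimal_completion_distance,
    select_case,
)
from igphylo.fixtures import FixtureSpec, random_genome_pair
from igphylo.genomes import parse_genomes


class TestCaseSelection:
    def test_worked_pair_is_case_one(self, fig_pair):
        inv = build_bp_graph(*fig_pair).inventory
        case = select_case(inv)
        assert case.case_id == 1
        assert set(case.pair_classes) == {"T1", "T2", "T3", "T5", "T6"}
        assert case.triple_class is None

    def test_odd_ab_forces_one_triple(self):
        """p_AB=1 with an even A-path and an odd B-path selects T10."""
        from igphylo.bpgraph import ComponentInventory

        inv = ComponentInventory(
            p_AB=1, p_A_odd=0, p_A_even=1, p_B_odd=1, p_B_even=0
        )
        case = select_case(inv)
        assert case.case_id == 3
        assert case.triple_class == "T10"
        assert case.triple_count == "one"

    def test_equal_content_trivial_case(self):
        (g,) = parse_genomes(">G\n1 2 3 @\n")
        graph = build_bp_graph(g, g.renamed("H"))
        hg = build_hypergraph(graph)
        assert hg.pair_edges == [] and hg.triple_edges == []

    def test_cases_exhaustive_on_random_inventories(self):
        from igphylo.bpgraph import ComponentInventory

        for p_ab in range(4):
            for ao in range(3):
                for ae in range(3):
                    for bo in range(3):
                        for be in range(3):
                            inv = ComponentInventory(
                                p_AB=p_ab, p_A_odd=ao, p_A_even=ae,
                                p_B_odd=bo, p_B_even=be,
                            )
                            case = select_case(inv)  # must not raise
                            assert 1 <= case.case_id <= 6


class TestHypergraph:
    def test_worked_pair_single_t3_edge(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        hg = build_hypergraph(graph)
        assert len(hg.vertices["upsilon"]) == 2
        t3 = [e for e in hg.pair_edges if e.klass == "T3"]
        assert len(t3) == 1
        assert hg.triple_edges == []

    def test_one_odd_one_even_a_path_gives_t1(self):
        # A=(1) linear vs B=(1 2) linear: odd A-path + even A-path
        a, b = parse_genomes(">A\n1 $\n>B\n1 2 $\n")
        graph = build_bp_graph(a, b)
        hg = build_hypergraph(graph)
        assert [e.klass for e in hg.pair_edges] == ["T1"]

    def test_dot_dump_mentions_edges(self, fig_pair):
        hg = build_hypergraph(build_bp_graph(*fig_pair))
        assert "T3" in hg.to_dot()


class TestEnumeration:
    def test_worked_pair_has_three_completions(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        comps = list(enumerate_completions(graph))
        assert len(comps) == 3 == completion_count(graph)

    def test_no_open_vertices_single_empty_completion(self):
        (g,) = parse_genomes(">G\n1 2 @\n")
        graph = build_bp_graph(g, g.renamed("H"))
        comps = list(enumerate_completions(graph))
        assert comps == [Completion(frozenset(), frozenset())]

    def test_three_unique_genes_fifteen_completions(self):
        # B has 3 extra genes inside one chromosome: n_A=3, n_B=0
        a, b = parse_genomes(">A\n1 2 @\n>B\n1 3 4 5 2 @\n")
        graph = build_bp_graph(a, b)
        assert completion_count(graph) == 15
        assert sum(1 for _ in enumerate_completions(graph)) == 15

    def test_cap_rejected_with_count(self):
        a, b = parse_genomes(">A\n1 @\n>B\n1 2 3 4 5 6 7 8 9 @\n")
        graph = build_bp_graph(a, b)
        with pytest.raises(ValueError, match=str(completion_count(graph))):
            list(enumerate_completions(graph, cap=10))

    @pytest.mark.parametrize("seed", range(80))
    def test_count_law_on_random_pairs(self, seed):
        a, b = random_genome_pair(
            FixtureSpec(
                shared=(seed % 4) + 1,
                a_unique=seed % 3,
                b_unique=(seed // 2) % 3,
                seed=seed,
            )
        )
        graph = build_bp_graph(a, b)
        assert sum(1 for _ in enumerate_completions(graph)) == completion_count(graph)


class TestOptimality:
    def test_worked_pair_minimum_three(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        assert optimal_completion_distance(graph) == 3
        assert enumerated_min_distance(graph) == 3

    def test_every_completion_at_least_optimal(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        for comp in enumerate_completions(graph):
            a2, b2 = apply_completion_reduced(graph, comp)
            assert dcj_distance(a2, b2) >= 3

    def test_uncovered_vertex_rejected(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        with pytest.raises(ValueError, match="uncovered"):
            apply_completion_reduced(graph, Completion(frozenset(), frozenset()))

    @pytest.mark.parametrize("seed", range(150))
    def test_case_rule_optimum_equals_enumerated_minimum(self, seed):
        a, b = random_genome_pair(
            FixtureSpec(
                shared=(seed % 6) + 1,
                a_unique=seed % 4,
                b_unique=(seed // 2) % 4,
                max_chromosomes=2,
                seed=seed + 5000,
            )
        )
        graph = build_bp_graph(a, b)
        assert optimal_completion_distance(graph) == enumerated_min_distance(graph)
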