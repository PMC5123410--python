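"""MWIG machinery: chord DP, hyperedge scoring, heuristic vs oracle."""

import itertools

import pytest

from igphylo.bpgraph import build_bp_graph
from igphylo.completions import completion_count, select_case
from igphylo.fixtures import (
    FixtureSpec,
    brute_force_mwig,
    enumerate_noncrossing_matchings,
    oracle_genome,
    random_genome_pair,
    random_weight_table,
)
from igphylo.genomes import TELOMERE, head, parse_genomes, tail
from igphylo.mwig import (
    WeightTable,
    chord_weight,
    max_noncrossing_matching,
    mwig_heuristic,
    score_hyperedge,
    verify_intermediate,
)

V = [(i, "t") for i in range(1, 13)]  # abstract vertices for DP tests


class TestChordDP:
    def test_two_vertex_cycle_forced(self):
        t = WeightTable({((1, "t"), (1, "h")): 2.5})
        chords, w = max_noncrossing_matching([tail(1), head(1)], t)
        assert chords == [(tail(1), head(1))] and w == 2.5

    def test_crossing_pair_excluded(self):
        """On a 4-cycle the heavy crossing chords cannot both be taken."""
        u1, u2, u3, u4 = V[:4]
        t = WeightTable({
            (u1, u2): 1, (u3, u4): 1, (u1, u4): 5, (u2, u3): 5,
            (u1, u3): 9, (u2, u4): 9,
        })
        chords, w = max_noncrossing_matching([u1, u2, u3, u4], t)
        assert w == 10
        assert set(map(frozenset, chords)) == {frozenset((u1, u4)), frozenset((u2, u3))}

    def test_all_zero_weights_returns_perfect_matching(self):
        chords, w = max_noncrossing_matching(V[:6], WeightTable())
        assert w == 0.0
        assert sorted(x for ch in chords for x in ch) == sorted(V[:6])

    def test_odd_cycle_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            max_noncrossing_matching(V[:3], WeightTable())

    @pytest.mark.parametrize("seed", range(60))
    @pytest.mark.parametrize("size", [4, 6, 8, 10])
    def test_dp_matches_exhaustive_enumeration(self, seed, size):
        import numpy as np

        rng = np.random.default_rng(seed * 100 + size)
        cycle = V[:size]
        t = WeightTable()
        for x, y in itertools.combinations(cycle, 2):
            if rng.random() < 0.45:  # sparse tables exercise the split pruning
                t.set(x, y, float(rng.uniform(0, 1)))
        chords, w = max_noncrossing_matching(cycle, t)
        best = max(
            sum(chord_weight(t, cycle[i], cycle[j]) for i, j in m)
            for m in enumerate_noncrossing_matchings(size)
        )
        assert w == pytest.approx(best, abs=1e-12)
        # chords must be non-crossing and cover every vertex
        pos = {v: i for i, v in enumerate(cycle)}
        spans = sorted((min(pos[a], pos[b]), max(pos[a], pos[b])) for a, b in chords)
        for (a1, b1), (a2, b2) in itertools.combinations(spans, 2):
            assert not (a1 < a2 < b1 < b2)
        assert sorted(x for ch in chords for x in ch) == sorted(cycle)


class TestScoreHyperedge:
    def test_two_vertex_component(self):
        a, b = parse_genomes(">A\n1 2 @\n>B\n1 2 @\n")
        graph = build_bp_graph(a, b)
        t = WeightTable({(head(1), tail(2)): 3.0})
        comp = next(c for c in graph.components if head(1) in c.walk)
        assert score_hyperedge((comp.index,), graph, t) == 3.0

    def test_zero_table_scores_zero(self, fig_pair):
        graph = build_bp_graph(*fig_pair)
        ab = [c for c in graph.components if c.kind.name == "AB"]
        assert score_hyperedge(tuple(c.index for c in ab), graph, WeightTable()) == 0.0

    def test_merged_ab_pair_matches_exhaustive(self, fig_pair):
        """Weight of the merged 6-vertex cycle equals brute-force best."""
        graph = build_bp_graph(*fig_pair)
        t = random_weight_table(fig_pair, seed=3, density=0.6)
        ab = [c for c in graph.components if c.kind.name == "AB"]
        got = score_hyperedge(tuple(c.index for c in ab), graph, t)
        from igphylo.mwig import merge_components

        merged, _ = merge_components(ab)
        best = max(
            sum(
                chord_weight(t, merged.cycle[i], merged.cycle[j])
                for i, j in m
            )
            for m in enumerate_noncrossing_matchings(len(merged.cycle))
        )
        assert got == pytest.approx(best)


class TestHeuristic:
    def test_worked_example_recovery(self, fig_pair):
        """Weights favoring the printed chord set recover M=(1,2,-4,-3), S={5}."""
        a, b = fig_pair
        t = WeightTable()
        for x, y in [
            (head(1), tail(2)), (head(2), head(4)),
            (tail(4), head(3)), (tail(3), tail(1)),
        ]:
            t.set(x, y, 1.0)
        cand = mwig_heuristic(a, b, t)
        chroms = cand.genome.chromosomes()
        assert len(chroms) == 1 and chroms[0].circular
        assert chroms[0].genes == (1, 2, -4, -3)
        assert [c.genes for c in cand.singletons] == [(5,)]
        assert cand.weight == pytest.approx(4.0)

    def test_equal_content_splits_distance(self):
        a, b = parse_genomes(">A\n1 2 3 4 5 $\n>B\n1 -3 -2 4 5 $\n")
        t = random_weight_table((a, b), seed=1)
        cand = mwig_heuristic(a, b, t)
        assert verify_intermediate(a, cand.genome, b)

    def test_stripping_never_removes_shared_genes(self):
        for seed in range(30):
            a, b = random_genome_pair(
                FixtureSpec(shared=4, a_unique=2, b_unique=1, seed=seed)
            )
            t = random_weight_table((a, b), seed=seed)
            cand = mwig_heuristic(a, b, t)
            assert (a.genes & b.genes) <= cand.genome.genes

    def test_verify_intermediate_rejects_detour(self, fig_pair):
        a, b = fig_pair
        # a genome two extra operations away from b is no intermediate
        (far,) = parse_genomes(">F\n1 -2 4 -3 @\n")
        assert not verify_intermediate(a, far, b)

    def test_intermediate_endpoints(self, fig_pair):
        a, b = fig_pair
        assert verify_intermediate(a, a.renamed("M"), b)
        assert verify_intermediate(a, b.renamed("M"), b)


class TestHeuristicVsOracle:
    @staticmethod
    def single_triple_regime(inv) -> bool:
        case = select_case(inv)
        if case.case_id in (1, 2, 3, 4):
            return True
        return min(
            abs(inv.p_A_even - inv.p_A_odd),
            abs(inv.p_B_even - inv.p_B_odd),
            inv.p_AB,
        ) <= 1

    @pytest.mark.parametrize("seed", range(120))
    def test_heuristic_attains_oracle_weight(self, seed):
        spec = FixtureSpec(
            shared=(seed % 4) + 2,
            a_unique=seed % 3,
            b_unique=(seed // 2) % 3,
            seed=seed + 400,
        )
        a, b = random_genome_pair(spec)
        graph = build_bp_graph(a, b)
        if completion_count(graph) > 2000:
            pytest.skip("outside oracle range")
        t = random_weight_table((a, b), seed=seed, density=0.4)
        oracle = brute_force_mwig(a, b, t)
        cand = mwig_heuristic(a, b, t)
        if self.single_triple_regime(graph.inventory):
            assert cand.weight == pytest.approx(oracle.weight, abs=1e-9)
        else:
            assert cand.weight <= oracle.weight + 1e-9
        # oracle outputs are themselves valid intermediate genomes
        m = oracle_genome(a, b, oracle)
        assert verify_intermediate(a, m, b)

    def test_dummy_mode_is_valid_and_below_sweep(self):
        hits = 0
        for seed in range(60):
            a, b = random_genome_pair(
                FixtureSpec(shared=3, a_unique=2, b_unique=2, seed=seed + 900)
            )
            graph = build_bp_graph(a, b)
            if graph.inventory.p_AB % 2 == 0:
                continue
            hits += 1
            t = random_weight_table((a, b), seed=seed, density=0.4)
            dummy = mwig_heuristic(a, b, t, triple_mode="dummy")
            sweep = mwig_heuristic(a, b, t, triple_mode="sweep")
            assert dummy.weight <= sweep.weight + 1e-9
            assert verify_intermediate(a, dummy.genome, b)
        assert hits >= 3  # the regime actually occurred
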