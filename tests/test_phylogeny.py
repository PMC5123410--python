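"""Small-phylogeny driver and file pipeline."""

import pytest

from igphylo.bpgraph import dcj_indel_distance
from igphylo.evaluation import score_genome_maps
from igphylo.genomes import head, parse_genomes, tail, write_genomes
from igphylo.mwig import WeightTable, verify_intermediate
from igphylo.phylogeny import ig_small_phylogeny, reconstruct_pipeline
from igphylo.simulator import SimulationConfig, simulate_dataset, write_dataset
from igphylo.trees import PhyloTree, TreeError
from igphylo.weights import node_weights_by_rerooting


class TestSmallPhylogeny:
    def test_identical_leaves_reproduce_ancestor(self):
        t = PhyloTree.from_newick("(A:1,B:1)R;")
        t.attach_leaf_genomes(
            {g.name: g for g in parse_genomes(">A\n1 2 3 $\n>B\n1 2 3 $\n")}
        )
        res = ig_small_phylogeny(t, {"R": WeightTable()})
        assert t.genomes["R"].adjacencies == t.genomes["A"].adjacencies

    def test_cherry_with_favoring_weights(self, fig_pair):
        a, b = fig_pair
        t = PhyloTree.from_newick("(A:1,B:1)R;")
        t.attach_leaf_genomes({"A": a, "B": b})
        w = WeightTable()
        for x, y in [
            (head(1), tail(2)), (head(2), head(4)),
            (tail(4), head(3)), (tail(3), tail(1)),
        ]:
            w.set(x, y, 1.0)
        ig_small_phylogeny(t, {"R": w}, tie_break=False)
        assert t.genomes["R"].chromosomes()[0].genes == (1, 2, -4, -3)

    def test_missing_weight_table_rejected(self):
        t = PhyloTree.from_newick("(A:1,B:1)R;")
        t.attach_leaf_genomes(
            {g.name: g for g in parse_genomes(">A\n1 $\n>B\n1 $\n")}
        )
        with pytest.raises(TreeError, match="weight table"):
            ig_small_phylogeny(t, {})

    def test_every_internal_node_is_an_intermediate(self):
        cfg = SimulationConfig(
            leaves=8, genes=80, diameter_factor=0.8, indel_prob=0.4,
            indel_max=2, seed=21,
        )
        ds = simulate_dataset(cfg)
        rec = ds.tree.copy()
        rec.genomes = {n: ds.tree.genomes[n] for n in rec.leaf_names()}
        ig_small_phylogeny(rec, node_weights_by_rerooting(rec))
        for node in rec.internal_nodes():
            left, right = node.children
            assert verify_intermediate(
                rec.genomes[left.name], rec.genomes[node.name],
                rec.genomes[right.name],
            )

    def test_beats_naive_root_labeling(self):
        """Tree length no worse than labeling every internal with the truth root."""
        cfg = SimulationConfig(
            leaves=12, genes=120, diameter_factor=1.0, indel_prob=0.2,
            indel_max=1, seed=22,
        )
        ds = simulate_dataset(cfg)
        rec = ds.tree.copy()
        rec.genomes = {n: ds.tree.genomes[n] for n in rec.leaf_names()}
        res = ig_small_phylogeny(rec, node_weights_by_rerooting(rec))
        root_g = ds.tree.genomes[ds.tree.root.name]
        naive = 0
        for parent, child in ds.tree.edges():
            pg = root_g if not parent.is_leaf else ds.tree.genomes[parent.name]
            cg = root_g if not child.is_leaf else ds.tree.genomes[child.name]
            naive += dcj_indel_distance(pg.renamed("p"), cg.renamed("c"))
        assert res.tree_length <= naive


@pytest.fixture(scope="module")
def dataset_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(
        leaves=6, genes=60, diameter_factor=0.5, indel_prob=0.2,
        indel_max=1, seed=30,
    )
    write_dataset(simulate_dataset(cfg), outdir)
    return outdir


class TestPipeline:

    def test_smoke_all_internals_written(self, dataset_dir, tmp_path):
        res = reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk", tmp_path
        )
        anc = parse_genomes((tmp_path / "ancestral.grimm").read_text())
        assert len(anc) == 5  # 6 leaves -> 5 internal nodes
        assert (tmp_path / "report.tsv").read_text().count("\n") == 6

    def test_weight_file_bypasses_recursion(self, dataset_dir, tmp_path):
        first = tmp_path / "first"
        reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk", first
        )
        second = tmp_path / "second"
        reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk", second,
            weights_path=first / "weights_used.tsv",
        )
        assert "file" in (second / "report.tsv").read_text()

    @pytest.mark.parametrize("mode", ["me", "ls"])
    def test_estimated_branch_lengths_modes(self, dataset_dir, tmp_path, mode):
        res = reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk",
            tmp_path / mode, branch_lengths=mode,
        )
        assert res.tree_length >= 0

    def test_deterministic_outputs(self, dataset_dir, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk", out1
        )
        reconstruct_pipeline(
            dataset_dir / "leaves.grimm", dataset_dir / "tree.nwk", out2
        )
        for name in ("ancestral.grimm", "labeled_tree.nwk", "report.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_stage_errors_are_labeled(self, dataset_dir, tmp_path):
        bad_tree = tmp_path / "bad.nwk"
        bad_tree.write_text("(A:1,Missing:1)R;")
        with pytest.raises(RuntimeError, match="stage tree-parsing"):
            reconstruct_pipeline(dataset_dir / "leaves.grimm", bad_tree, tmp_path / "o")
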