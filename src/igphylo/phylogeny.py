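"""Bottom-up small-phylogeny reconstruction with intermediate genomes.

Given a rooted binary tree with genomes at the leaves, each internal node
is reconstructed — in post-order, so both children are always labeled
first — as the heuristic Maximum Weight Intermediate Genome of its two
children under that node's adjacency-weight table.  Every reconstructed
node therefore lies on an optimal DCJ-indel scenario between its children.

Adjacency choices in regions where the guiding weights are silent would
otherwise be resolved arbitrarily; a tiny branch-length prior over the
node's two children (the closer child is the likelier source of the
ancestral state) breaks those ties without ever overriding a supported
weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .branch_lengths import (
    assign_lengths,
    build_design,
    estimate_least_squares,
    estimate_minimum_evolution,
)
from .bpgraph import dcj_indel_distance
from .genomes import Genome, parse_genomes, write_genomes
from .mwig import IGCandidate, mwig_heuristic
from .trees import PhyloTree, TreeError
from .weights import (
    NodeWeights,
    load_weight_table,
    node_weights_by_rerooting,
    write_weight_tables,
)


@dataclass
class ReconstructionResult:
    tree: PhyloTree
    candidates: dict[str, IGCandidate] = field(default_factory=dict)

    @property
    def tree_length(self) -> int:
        total = 0
        for parent, child in self.tree.edges():
            total += dcj_indel_distance(
                self.tree.genomes[parent.name], self.tree.genomes[child.name]
            )
        return total


#: scale of the child-prior tie-break; far below any supported weight
TIE_BREAK_EPS = 1e-6


def _with_child_prior(
    table, left_g, right_g, d_left: float, d_right: float
):
    """Augment a weight table with an epsilon prior from the two children.

    An adjacency present in the left child gets an extra
    eps * D_R / (D_L + D_R) (and symmetrically), so unsupported regions
    follow the closer child instead of an arbitrary fill.
    """
    from .mwig import WeightTable
    from .weights import MIN_BRANCH_LENGTH

    aug = WeightTable(dict(table.items()))
    dl = max(d_left, MIN_BRANCH_LENGTH)
    dr = max(d_right, MIN_BRANCH_LENGTH)
    for adj in left_g.adjacencies:
        aug.set(adj[0], adj[1], aug.get_adj(adj) + TIE_BREAK_EPS * dr / (dl + dr))
    for adj in right_g.adjacencies:
        aug.set(adj[0], adj[1], aug.get_adj(adj) + TIE_BREAK_EPS * dl / (dl + dr))
    return aug


def ig_small_phylogeny(
    tree: PhyloTree, weights: NodeWeights, tie_break: bool = True
) -> ReconstructionResult:
    """Label every internal node with a heuristic MWIG of its children."""
    for leaf in tree.leaf_names():
        if leaf not in tree.genomes:
            raise TreeError(f"missing genome for leaf {leaf!r}")
    for node in tree.internal_nodes():
        if node.name not in weights:
            raise TreeError(f"missing weight table for internal node {node.name!r}")

    result = ReconstructionResult(tree)
    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        left, right = node.children
        table = weights[node.name]
        if tie_break:
            table = _with_child_prior(
                table,
                tree.genomes[left.name],
                tree.genomes[right.name],
                left.length or 0.0,
                right.length or 0.0,
            )
        cand = mwig_heuristic(
            tree.genomes[left.name],
            tree.genomes[right.name],
            table,
            name=node.name,
        )
        tree.genomes[node.name] = cand.genome
        result.candidates[node.name] = cand
    return result


def reconstruct_pipeline(
    genomes_path: str | Path,
    tree_path: str | Path,
    outdir: str | Path,
    weights_path: str | Path | None = None,
    branch_lengths: str = "given",
) -> ReconstructionResult:
    """File-level orchestration: lengths -> weights -> reconstruction -> output.

    ``branch_lengths`` is one of ``given`` (use the Newick lengths), ``me``
    (Minimum Evolution) or ``ls`` (least squares).  Outputs
    ``ancestral.grimm``, ``labeled_tree.nwk``, ``report.tsv``,
    ``weights_used.tsv`` and ``run.log`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    try:
        genomes = {
            g.name: g for g in parse_genomes(Path(genomes_path).read_text())
        }
    except Exception as exc:
        raise RuntimeError(f"stage genome-parsing: {exc}") from exc
    try:
        tree = PhyloTree.from_newick(Path(tree_path).read_text())
        tree.attach_leaf_genomes(genomes)
    except Exception as exc:
        raise RuntimeError(f"stage tree-parsing: {exc}") from exc
    log.append(f"leaves: {len(tree.leaf_names())}")

    if branch_lengths not in ("given", "me", "ls"):
        raise RuntimeError(f"stage branch-lengths: unknown mode {branch_lengths!r}")
    if branch_lengths != "given":
        try:
            design = build_design(tree, tree.genomes)
            if branch_lengths == "me":
                w = estimate_minimum_evolution(design)
            else:
                w, residual = estimate_least_squares(design)
                log.append(f"least-squares residual: {residual:.6g}")
            assign_lengths(tree, design, w)
            log.append(f"branch lengths estimated with {branch_lengths}")
        except Exception as exc:
            raise RuntimeError(f"stage branch-lengths: {exc}") from exc
    else:
        log.append("branch lengths taken from the input tree")

    try:
        if weights_path is not None:
            internal = {n.name for n in tree.internal_nodes()}
            weights = load_weight_table(Path(weights_path).read_text(), internal)
            missing = internal - set(weights)
            if missing:
                raise ValueError(f"weight file lacks nodes {sorted(missing)}")
            log.append(f"weights loaded from {weights_path}")
        else:
            weights = node_weights_by_rerooting(tree)
            log.append("weights computed by pruned-tree rerooting")
    except Exception as exc:
        raise RuntimeError(f"stage weights: {exc}") from exc

    try:
        result = ig_small_phylogeny(tree, weights)
    except Exception as exc:
        raise RuntimeError(f"stage reconstruction: {exc}") from exc

    internals = [
        tree.genomes[n.name] for n in tree.root.postorder() if not n.is_leaf
    ]
    (outdir / "ancestral.grimm").write_text(write_genomes(internals))
    (outdir / "labeled_tree.nwk").write_text(tree.to_newick() + "\n")
    (outdir / "weights_used.tsv").write_text(write_weight_tables(weights))

    rows = ["node\tweight_source\tcandidate_weight\tchild1\td1\tchild2\td2"]
    source = "file" if weights_path is not None else "rerooting"
    for node in tree.internal_nodes():
        cand = result.candidates[node.name]
        left, right = node.children
        d1 = dcj_indel_distance(tree.genomes[node.name], tree.genomes[left.name])
        d2 = dcj_indel_distance(tree.genomes[node.name], tree.genomes[right.name])
        rows.append(
            f"{node.name}\t{source}\t{cand.weight:.6g}"
            f"\t{left.name}\t{d1}\t{right.name}\t{d2}"
        )
    (outdir / "report.tsv").write_text("\n".join(rows) + "\n")

    log.append(f"tree length (sum of edge DCJ-indel distances): {result.tree_length}")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "run_config.json").write_text(
        json.dumps(
            {"branch_lengths": branch_lengths, "weights": str(weights_path or "rerooting")},
            indent=2,
        )
        + "\n"
    )
    return result
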