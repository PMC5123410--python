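"""Simulation of gene-order evolution on a birth-death tree.

The protocol: a constant-rate birth-death process (birth 0.001, death 0 —
a pure Yule process) grows an ultrametric tree to N leaves; every branch
length is perturbed by a factor e^d with d uniform on [-2, 2]; lengths are
then rescaled so the tree *diameter* (maximum leaf-to-leaf path length)
equals a target D, expressed as a multiple of the gene count.  The root
carries a single linear chromosome of genes 1..n, and each edge applies
round(length) random events to a copy of the parent genome: a reversal
with probability 1 - P, a deletion with P/2, an insertion with P/2, indel
lengths uniform on {1..I}.  Inserted genes receive fresh ids; every node's
genome is retained so reconstructions can be scored against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomes import Chromosome, Genome, write_genomes
from .trees import PhyloTree, TreeNode


@dataclass
class SimulationConfig:
    leaves: int = 12
    genes: int = 1000
    birth_rate: float = 0.001
    death_rate: float = 0.0
    diameter_factor: float = 1.0  # D as a multiple of the gene count
    indel_prob: float = 0.2  # P
    indel_max: int = 1  # I
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.indel_prob <= 1.0):
            raise ValueError("indel probability must lie in [0, 1]")
        if self.indel_max < 1 or self.leaves < 2 or self.genes < 1:
            raise ValueError("invalid simulation sizes")

    @property
    def diameter(self) -> float:
        return self.diameter_factor * self.genes

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class EventRecord:
    edge: tuple[str, str]
    kind: str  # reversal | deletion | insertion
    detail: str


def simulate_tree(cfg: SimulationConfig, rng: np.random.Generator) -> PhyloTree:
    """Birth-death tree to N leaves, perturbed and rescaled to diameter D."""
    root = TreeNode("", None)
    tips: list[tuple[TreeNode, float]] = [(root, 0.0)]  # (node, birth time)
    t = 0.0
    while len(tips) < cfg.leaves:
        k = len(tips)
        total_rate = k * (cfg.birth_rate + cfg.death_rate)
        t += rng.exponential(1.0 / total_rate)
        i = int(rng.integers(k))
        node, born = tips.pop(i)
        p_birth = cfg.birth_rate / (cfg.birth_rate + cfg.death_rate)
        if rng.random() < p_birth:
            node.length = t - born
            for _ in range(2):
                child = TreeNode("", None, parent=node)
                node.children.append(child)
                tips.append((child, t))
        else:  # death; restart if the whole tree dies
            node.length = t - born
            if not tips:
                return simulate_tree(cfg, rng)
    # extend all extant tips to the present (one more waiting time)
    t += rng.exponential(1.0 / (len(tips) * cfg.birth_rate))
    leaf_count = 0
    for node, born in tips:
        node.length = t - born
        leaf_count += 1
        node.name = f"L{leaf_count}"
    root.length = None

    # perturb every branch by e^d, d ~ U[-2, 2]
    for node in root.postorder():
        if node.parent is not None:
            node.length = (node.length or 0.0) * float(np.exp(rng.uniform(-2.0, 2.0)))

    tree = PhyloTree(root)
    diam = tree_diameter(tree)
    if diam > 0:
        scale = cfg.diameter / diam
        for node in root.postorder():
            if node.parent is not None:
                node.length = (node.length or 0.0) * scale
    return tree


def tree_diameter(tree: PhyloTree) -> float:
    """Maximum leaf-to-leaf path length."""
    adj = tree.unrooted_adjacency()
    leaves = tree.leaf_names()

    def far(src: str) -> dict[str, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    best = 0.0
    for leaf in leaves:
        dist = far(leaf)
        for other in leaves:
            best = max(best, dist.get(other, 0.0))
    return best


# ---------------------------------------------------------------------------
# evolution along edges
# ---------------------------------------------------------------------------

def _reversal(chroms: list[Chromosome], rng: np.random.Generator) -> tuple[list[Chromosome], str]:
    sizes = np.array([len(c.genes) for c in chroms], dtype=float)
    ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
    chrom = chroms[ci]
    k = len(chrom.genes)
    i = int(rng.integers(k))
    j = int(rng.integers(k))
    i, j = min(i, j), max(i, j)
    genes = (
        chrom.genes[:i]
        + tuple(-g for g in reversed(chrom.genes[i:j + 1]))
        + chrom.genes[j + 1:]
    )
    out = list(chroms)
    out[ci] = Chromosome(genes, chrom.circular)
    return out, f"reversal chrom={ci} span=[{i},{j}]"


def _deletion(
    chroms: list[Chromosome], rng: np.random.Generator, max_len: int
) -> tuple[list[Chromosome], str] | None:
    total = sum(len(c.genes) for c in chroms)
    sizes = np.array([len(c.genes) for c in chroms], dtype=float)
    ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
    chrom = chroms[ci]
    k = len(chrom.genes)
    length = int(rng.integers(1, max_len + 1))
    length = min(length, k)
    if length >= total:  # never delete the genome's last gene
        return None
    start = int(rng.integers(k - length + 1)) if not chrom.circular else int(rng.integers(k))
    out = list(chroms)
    if chrom.circular:
        idx = [(start + off) % k for off in range(length)]
        keep = tuple(g for p, g in enumerate(chrom.genes) if p not in set(idx))
    else:
        keep = chrom.genes[:start] + chrom.genes[start + length:]
    if keep:
        out[ci] = Chromosome(keep, chrom.circular)
    else:
        del out[ci]
    return out, f"deletion chrom={ci} start={start} len={length}"


def _insertion(
    chroms: list[Chromosome], rng: np.random.Generator, max_len: int, next_gene: int
) -> tuple[list[Chromosome], str, int]:
    sizes = np.array([len(c.genes) + 1 for c in chroms], dtype=float)
    ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
    chrom = chroms[ci]
    length = int(rng.integers(1, max_len + 1))
    fresh = tuple(range(next_gene, next_gene + length))
    pos = int(rng.integers(len(chrom.genes) + 1))
    genes = chrom.genes[:pos] + fresh + chrom.genes[pos:]
    out = list(chroms)
    out[ci] = Chromosome(genes, chrom.circular)
    return out, f"insertion chrom={ci} pos={pos} genes={fresh[0]}..{fresh[-1]}", next_gene + length


def evolve_genomes(
    tree: PhyloTree, cfg: SimulationConfig, rng: np.random.Generator
) -> list[EventRecord]:
    """Attach genomes to every node by simulating events along each edge."""
    root_chrom = Chromosome(tuple(range(1, cfg.genes + 1)), circular=False)
    tree.genomes[tree.root.name] = Genome.from_chromosomes(
        tree.root.name, [root_chrom]
    )
    next_gene = cfg.genes + 1
    events: list[EventRecord] = []

    order = [n for n in _preorder(tree.root)]
    for node in order:
        if node.parent is None:
            continue
        parent_g = tree.genomes[node.parent.name]
        chroms = [Chromosome(c.genes, c.circular) for c in parent_g.chromosomes()]
        n_events = max(0, round(node.length or 0.0))
        for _ in range(n_events):
            r = rng.random()
            if r < 1.0 - cfg.indel_prob or not chroms:
                if not chroms:
                    break
                chroms, detail = _reversal(chroms, rng)
                kind = "reversal"
            elif r < 1.0 - cfg.indel_prob / 2.0:
                res = _deletion(chroms, rng, cfg.indel_max)
                if res is None:  # would empty the genome: resample as insertion
                    chroms, detail, next_gene = _insertion(
                        chroms, rng, cfg.indel_max, next_gene
                    )
                    kind = "insertion"
                else:
                    chroms, detail = res
                    kind = "deletion"
            else:
                chroms, detail, next_gene = _insertion(
                    chroms, rng, cfg.indel_max, next_gene
                )
                kind = "insertion"
            events.append(EventRecord((node.parent.name, node.name), kind, detail))
        tree.genomes[node.name] = Genome.from_chromosomes(node.name, chroms)
    return events


def _preorder(node: TreeNode):
    yield node
    for child in node.children:
        yield from _preorder(child)


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    config: SimulationConfig
    tree: PhyloTree
    events: list[EventRecord] = field(default_factory=list)

    @property
    def leaf_genomes(self) -> list[Genome]:
        return [self.tree.genomes[n] for n in self.tree.leaf_names()]

    @property
    def ancestral_genomes(self) -> list[Genome]:
        return [
            self.tree.genomes[n.name]
            for n in self.tree.root.postorder()
            if not n.is_leaf
        ]


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Full deterministic dataset from a config (tree + genomes + log)."""
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg, rng)
    events = evolve_genomes(tree, cfg, rng)
    return Dataset(cfg, tree, events)


def write_dataset(ds: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "leaves.grimm").write_text(write_genomes(ds.leaf_genomes))
    (outdir / "ancestral_true.grimm").write_text(write_genomes(ds.ancestral_genomes))
    (outdir / "tree.nwk").write_text(ds.tree.to_newick() + "\n")
    (outdir / "sim_config.json").write_text(ds.config.to_json() + "\n")
    rows = ["parent\tchild\tkind\tdetail"]
    for ev in ds.events:
        rows.append(f"{ev.edge[0]}\t{ev.edge[1]}\t{ev.kind}\t{ev.detail}")
    (outdir / "event_log.tsv").write_text("\n".join(rows) + "\n")
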