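"""Scoring reconstructions against simulated truth.

Adjacency-level quality per internal node: the true-positive percentage is
the fraction of the true genome's adjacencies recovered, the false-positive
percentage the fraction of reconstructed adjacencies that are wrong
(telomeric adjacencies count in both).  Distance-level quality is the
DCJ-indel distance between the true and reconstructed genomes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .bpgraph import dcj_indel_distance
from .genomes import Genome
from .trees import PhyloTree, TreeError


def adjacency_tp_fp(true_g: Genome, rec_g: Genome) -> tuple[float, float]:
    """(TP%, FP%) of the reconstructed adjacency set against the truth."""
    true_adj = true_g.adjacencies
    rec_adj = rec_g.adjacencies
    tp = 100.0 * len(rec_adj & true_adj) / len(true_adj) if true_adj else 100.0
    fp = 100.0 * len(rec_adj - true_adj) / len(rec_adj) if rec_adj else 0.0
    return tp, fp


@dataclass
class NodeScore:
    node: str
    tp_pct: float
    fp_pct: float
    distance: int


@dataclass
class EvalReport:
    scores: list[NodeScore] = field(default_factory=list)

    @property
    def mean_tp(self) -> float:
        return sum(s.tp_pct for s in self.scores) / len(self.scores)

    @property
    def mean_fp(self) -> float:
        return sum(s.fp_pct for s in self.scores) / len(self.scores)

    @property
    def mean_distance(self) -> float:
        return sum(s.distance for s in self.scores) / len(self.scores)

    def extend(self, other: "EvalReport") -> None:
        self.scores.extend(other.scores)

    def to_tsv(self, replicate: int | str = 0) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(["replicate", "node", "tp_pct", "fp_pct", "dcj_indel"])
        for s in self.scores:
            writer.writerow(
                [replicate, s.node, f"{s.tp_pct:.4f}", f"{s.fp_pct:.4f}", s.distance]
            )
        return buf.getvalue()


def distance_report(truth: PhyloTree, rec: PhyloTree) -> EvalReport:
    """Per-internal-node TP/FP and distance; trees must share node names."""
    t_internal = {n.name for n in truth.internal_nodes()}
    r_internal = {n.name for n in rec.internal_nodes()}
    if t_internal != r_internal:
        raise TreeError(
            f"topology/name mismatch: {sorted(t_internal ^ r_internal)}"
        )
    report = EvalReport()
    for name in sorted(t_internal):
        true_g = truth.genomes[name]
        rec_g = rec.genomes[name]
        tp, fp = adjacency_tp_fp(true_g, rec_g)
        d = dcj_indel_distance(true_g, rec_g)
        report.scores.append(NodeScore(name, tp, fp, d))
    return report


def score_genome_maps(
    truth: dict[str, Genome], rec: dict[str, Genome]
) -> EvalReport:
    """Like :func:`distance_report` but on plain name->genome maps."""
    if set(truth) != set(rec):
        raise ValueError(f"node sets differ: {sorted(set(truth) ^ set(rec))}")
    report = EvalReport()
    for name in sorted(truth):
        tp, fp = adjacency_tp_fp(truth[name], rec[name])
        report.scores.append(
            NodeScore(name, tp, fp, dcj_indel_distance(truth[name], rec[name]))
        )
    return report
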