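# igphylo

Ancestral gene-order reconstruction for genomes with **unequal gene
content**, built on the double-cut-and-join (DCJ) rearrangement model with
insertions and deletions (the DCJ-indel model) and on the concept of
**intermediate genomes**.

## The problem

Given a rooted binary phylogeny with extant genomes at its leaves — each a
set of chromosomes over signed gene markers, where gene content may differ
between species — infer the gene orders of the ancestral genomes at the
internal nodes.  Event-based methods minimize the number of rearrangements
on the tree (NP-hard); homology-based methods assemble ancestral
adjacencies by weight.  This package combines the two: every reconstructed
ancestor is constrained to be an *intermediate genome* (IG) of its two
children — a genome lying on an optimal DCJ-indel scenario between them —
and among all IGs the one maximizing the total weight of its adjacencies
is sought (the *Maximum Weight Intermediate Genome*, MWIG).

## The model in brief

For genomes *A*, *B* over the gene union 𝒢, the breakpoint graph BP(A, B)
has one vertex per gene extremity and one edge per (non-telomeric)
adjacency, colored by genome; it decomposes into alternating cycles and
paths.  With equal content the DCJ distance is

    d_DCJ(A, B) = n − c − p_even / 2,

where *n* = |𝒢|, *c* counts cycles and *p_even* even paths.  With unequal
content, genes missing from one genome leave *open* path ends; a
*completion* pairs the open ends of each side into prosthetic chromosomes,
and

    d_ind(A, B) = min over completions of d_DCJ(A′, B′) + sing(A, B),

with sing counting circular chromosomes made purely of one side's unique
genes.  Optimal completions link open components in eleven restricted ways
(pair classes T1–T7, triples T8–T11) selected by six exhaustive case rules
on the component inventory; the package evaluates the minimum in closed
form and can also enumerate all (2n_A−1)!!·(2n_B−1)!! completions for
small instances.

An IG corresponds to a non-crossing perfect chord matching of the
circularized optimal completion (artificial singleton chromosomes
stripped).  Reconstruction therefore solves, per component, a maximum
weight non-crossing matching by interval dynamic programming, and picks
the component linking by a maximum-weight perfect matching over the
completion hypergraph.  Adjacency weights at each internal node come from
a distance-weighted recursion over the rest of the tree
(w_α = (D_L·w_R + D_R·w_L)/(D_L + D_R), leaves scored 0/1, computed on
the pruned tree rerooted at the node's parent), or from an external
per-node weight table.  Branch lengths may be given, or estimated from
pairwise DCJ-indel distances by Fitch–Margoliash least squares or by the
Minimum Evolution linear program.

## Worked example

Simulate a small dataset (birth-death tree, reversals + indels along the
edges), reconstruct the ancestors, and score against the simulated truth:

```sh
igphylo simulate -o demo --leaves 6 --genes 50 --diameter-factor 0.5 \
        --indel-prob 0.2 --seed 42
igphylo reconstruct -g demo/leaves.grimm -t demo/tree.nwk -o demo_rec
igphylo evaluate --truth demo/ancestral_true.grimm \
        --reconstruction demo_rec/ancestral.grimm
```

which prints

```
replicate	node	tp_pct	fp_pct	dcj_indel
0	N1	100.0000	0.0000	0
0	N2	100.0000	0.0000	0
0	N3	96.0000	4.0000	1
0	N4	100.0000	0.0000	0
0	N5	88.2353	10.0000	3
# mean TP 96.85%  mean FP 2.80%  mean distance 0.80
```

Per ancestral node: the percentage of true adjacencies recovered (tp_pct),
the percentage of reconstructed adjacencies that are wrong (fp_pct), and
the DCJ-indel distance between the true and reconstructed genome.  Here
four of five ancestors are recovered exactly; the deepest node (N5, the
root) misses a few adjacencies, the typical pattern since no outgroup
information exists above the root.

Pairwise distances work directly on a GRIMM file:

```sh
$ igphylo distance genomes.grimm --pair A B
3
```

Library use mirrors the CLI:

```python
from igphylo import parse_genomes, dcj_indel_distance
a, b = parse_genomes(">A\n1 -3 5 @\n>B\n1 2 3 4 @\n")
dcj_indel_distance(a, b)   # -> 3
```

## File formats

* **Genomes**: GRIMM-style text — `>name` headers, chromosome lines of
  signed integers ending in `$` (linear) or `@` (circular), `#` comments.
* **Trees**: Newick, optionally with branch lengths and internal labels.
* **Weight tables**: TSV with columns `node`, `ext1`, `ext2`, `weight`,
  extremities written `5h`/`5t` or `TEL` for telomeric adjacencies.

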