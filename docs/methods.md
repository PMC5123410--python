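# Methods

This note records the models, algorithms, numerical conventions and design
choices behind igphylo, at the level of detail a maintainer or reviewer
needs to interpret its output.

## Genomes and the breakpoint graph

A genome is a set of adjacencies over gene extremities (`g^t`, `g^h`),
with telomeric adjacencies (`TEL–x`) stored explicitly for linear
chromosome ends.  Gene ids are positive integers; id 0 is reserved for the
telomere marker and negative first components tag the artificial vertices
introduced by circularization.  Canonical forms (circular chromosomes
rotated to the smallest gene id, positively signed where possible; linear
chromosomes oriented by smallest endpoint) make file output reproducible
and genome equality a plain set comparison.

BP(A, B) is built over the union gene set after excising *singletons* —
circular chromosomes consisting only of genes unique to one genome — which
enter the DCJ-indel distance as one indel each, separately.  Every vertex
has degree ≤ 1 per color, so components are alternating cycles and paths.
Open vertices (extremities of genes absent from one genome) are always
path ends.  Two degenerate conventions matter and were fixed by checking
them against direct completion enumeration:

* an isolated not-open vertex is an **even not-open path** (required for
  d(G, G) = 0);
* an isolated open vertex (a unique gene telomeric in its host genome) is
  an **even A-path** (resp. B-path): in any completion it receives exactly
  one new edge and remains a path endpoint, so it behaves as one open end
  plus one closed end.

## Distances

Equal content: d = n − c − p_even/2.  (The subtracted even-path term is
the form consistent with every worked example this package reproduces.)

Unequal content: the minimum of d_DCJ over completions is evaluated in
closed form from the component inventory.  Writing q = #AB-paths, a_o/a_e
for odd/even A-paths, b_o/b_e for B-paths, AA/BB for same-side open paths,
the optimal linking gains (in cycles-plus-half-even-paths, doubled)

    Δ2 = 2(AA + BB) + 2⌊q/2⌋ + min(a_o, a_e) + min(b_o, b_e)
         + [q odd and (a_o<a_e and b_o<b_e  or  a_o>a_e and b_o>b_e)],

because AA/BB-paths self-close into cycles, AB-paths close in pairs, odd
A-paths pair with even A-paths into even paths (same for B), and when q is
odd one A-/AB-/B-path triple absorbs the leftover — in the two
strict-inequality regimes the triple itself is an even path, worth the
extra half unit.  Then d_ind = n − c − p_even(not-open)/2 − Δ2/2 + sing.
This closed form is validated in the test suite against exhaustive
enumeration of all (2n_A−1)!!(2n_B−1)!! completions on hundreds of seeded
random pairs.

## The completion hypergraph and case rules

Open components are vertices; linkings that occur in optimal completions
are edges, in classes T1 (odd-A × even-A), T2 (odd-B × even-B), T3
(AB × AB), T4–T7 (same-parity same-side pairs), and triples T8–T11
(A-path × AB-path × B-path by parity).  Six exhaustive case rules on
(q parity, a_o vs a_e, b_o vs b_e) determine the active classes; on
boundary ties the lowest-numbered applicable case is used (the optima
coincide, which the enumeration oracle confirms).  Linking geometry is
forced: same-side pairs join their open ends with one edge of that side's
color, an AB pair closes into a cycle with one edge per color, and a
triple chains A-path → AB-path → B-path.

## Maximum Weight Intermediate Genome

Per candidate (merged, circularized) component, the best adjacency choice
is a maximum-weight non-crossing perfect chord matching, solved by
interval dynamic programming over the cyclic vertex order.  Split points
are restricted to the neighborhoods of positive-weight chord endpoints;
sliding a zero chord's endpoint across positions that touch no positive
chord only moves free vertices between faces of the chord partition
without changing any face parity, so the optimum is unchanged (verified
against exhaustive matching enumeration on cycles up to length 10, sparse
and dense weight tables).  Components with no positively weighted chord
short-circuit to an adjacent pairing — which corresponds to keeping one
child's own adjacencies in that region.

Chords to artificial circularization vertices encode telomeric
adjacencies and are weighted by the `TEL–x` entry (default 0); a chord
joining two artificial vertices of the same odd path carries no adjacency
and weight 0.

The component linking is chosen by a maximum-weight perfect matching over
the hypergraph's pair edges (exact blossom-based matching via networkx).
An odd number of AB-paths requires exactly one triple; two strategies are
implemented:

* **sweep** (default for ≤ 500 candidates): enumerate every candidate
  triple over all distance-preserving triple types for the case (case 3:
  T10, T8, T11; case 4: T9, T8, T11; case 5: T11; case 6: T8 — derived
  from the same linking calculus as Δ2), match the remaining components,
  and keep the best total including the triple's own chord score.  This
  attains the exact optimum in the single-triple regime, which the
  brute-force oracle confirms on every generated instance.
* **dummy** (fallback, and available as an explicit mode): add three
  zero-weight dummy vertices adjacent to the case's triple-type parity
  classes and solve one matching; the components matched to the dummies
  form the triple.  Fast, but blind to the triple's own score, hence only
  a heuristic; dummy edges carry a −10⁻⁹·(component size) penalty so ties
  resolve toward small triples deterministically.

In the multi-triple regimes (strict inequalities on both sides) at most
one triple is ever used, which preserves optimality of the completion but
not necessarily of the weight — there the heuristic is bounded above by
the oracle and that bound is what the tests assert.

Assembled chords give M′; circular chromosomes of M′ made purely of one
input's unique genes are stripped as artificial singletons S, and
M = M′ − S is returned.  Every output is checked against the defining
identity d_ind(A, M) + d_ind(M, B) = d_ind(A, B) at run time.

## Adjacency weights

Leaf tables are 0/1 adjacency indicators (telomeric adjacencies
included).  Internal weights follow the distance-weighted convex
combination w_α = (D_L·w_R + D_R·w_L)/(D_L + D_R): the closer child
counts more, matching the probability that a single change on one of the
two branches happened on the longer one.  For the node being
reconstructed the recursion runs on the tree *outside* it: prune the
node's subtree, drop the original root (suppressing the degree-2 join),
reroot at the former parent.  Two conventions the weighting procedure
itself leaves open:

* the root of the input tree has no outside; its weights are the
  recursion applied to the full tree at the root;
* when the pruned node hangs directly off the root, the rerooted tree is
  just the sibling subtree (for a 3-leaf tree the cherry ancestor is
  weighted by the outgroup leaf's indicators alone).

Zero or missing branch lengths are floored at 10⁻⁶ before the recursion.
Only adjacencies observed in at least one leaf are stored; everything
else is implicitly 0.

### Tie-breaking with a child prior

Where the outside weights are silent (e.g. adjacencies disrupted in all
outside leaves, or genes inserted below the node), the chord DP would
resolve ties arbitrarily.  The small-phylogeny driver therefore adds an
ε = 10⁻⁶ prior from the node's two children: an adjacency present in the
left child gains ε·D_R/(D_L+D_R) (and symmetrically), so unsupported
regions follow the likelier (closer) child.  ε is far below any supported
weight, so no informed decision is ever overridden.  In the simulation
study this choice is what brings the false-positive rate of unsupported
regions down to the sub-percent level; it can be disabled
(`ig_small_phylogeny(..., tie_break=False)`).

## Branch lengths

On the unrooted topology (root suppressed; n = 2k−3 edges), the 0/1 path
design M and the pairwise DCJ-indel distance vector d feed two
estimators: unweighted least squares (negative lengths clamped to zero
after solving — the constraint is applied post hoc, not during
optimization) and the Minimum Evolution LP (minimize Σw s.t. Mw ≥ d,
w ≥ 0; HiGHS).  Mapping back to the rooted tree splits the suppressed
root edge evenly between the root's children.  LP ties among optimal
vertices are solver-resolved; the objective value is deterministic.

## Simulator

Defaults are the study conditions: N = 12 leaves, n = 1000 genes, birth
rate 0.001, death rate 0 (a pure Yule process, restarted in the
zero-probability event of total extinction), branch lengths perturbed by
e^d with d ~ U[−2, 2], then rescaled so the maximum leaf-to-leaf path
equals the target diameter D ∈ {0.5, 1, 1.5, 2, 2.5}·n.  The root is one
linear chromosome 1..n; each edge applies round(length) events — a
reversal with probability 1−P, a deletion with P/2, an insertion with
P/2, P ∈ {0, 0.2, 0.4, 0.6}; indel lengths uniform on {1..I}, I ∈ {1, 5}.
Unstated sampling geometry was fixed as: reversal chromosome chosen
proportionally to gene count with a uniform contiguous interval;
deletions clipped at chromosome ends and never allowed to empty the
genome (resampled as an insertion); insertions of fresh ids at a uniform
position.  Reversals are intra-chromosomal.  The whole dataset is a pure
function of (config, seed).

What the simulator does *not* emulate: gene duplication, transpositions
as a distinct event class, unequal gene family sizes, assembly errors or
missing data.  Passing the simulation study therefore demonstrates
correct behavior under the generating model, not robustness to real-data
artifacts.

## Evaluation

Per internal node, TP% = |rec ∩ true|/|true| and FP% = |rec − true|/|rec|
over full adjacency sets (telomeric included); both are invariant to
chromosome order/orientation.  The DCJ-indel distance between true and
reconstructed genomes is reported alongside, with the caveat that it
rewards aggressive adjacency guessing (fragmentation is maximally
penalized), which is why TP/FP are the primary quality measures.

## Problem sizes and runtimes

The acceptance-level simulation check runs the full protocol at D = 0.5n,
I = 1 (20 replicates for each P, 80 datasets), reconstructing 11
ancestors of 12 leaves with ~1000 genes each in well under two minutes
total; the oracle-based checks run on hundreds of seeded instances with
≤ 10 genes, where exhaustive completion enumeration (≤ ~2000 completions)
and Catalan-bounded chord enumeration (cycles ≤ 16 vertices) are
feasible.  The chord DP is cubic in component size in the worst case but
effectively linear on the sparse weight tables produced by real leaf
sets.

## Known limitations

* Duplicated genes are unsupported (ids must be unique per genome).
* Even-path recombination scenarios are ignored in the IG
  characterization; IG membership is checked through the distance-sum
  identity, a necessary condition.
* The exact FPT search over many simultaneous triples is not implemented;
  exactness at small scale comes from enumeration, large scale uses the
  heuristic.
* Topology inference is out of scope — the tree is an input.
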