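# Methods

## Model and assumptions

The input is an undirected PPI network *G = (V, E)* without self-loops;
edge weights, when present, are interaction confidences (> 0). The flow
engine works on the column-stochastic matrix view of *G*: the canonical
flow matrix *M<sub>G</sub>* column-normalizes the weighted adjacency
matrix, so *M<sub>G</sub>(i, j)* is the probability that a random walk at
*j* steps to its neighbor *i*. The method assumes functional modules are
flow-coherent regions: repeated spreading (Regularize, *M·M<sub>R</sub>*)
and sharpening (Inflate, entrywise power with column renormalization)
concentrates each node's outgoing flow onto one attractor node, and nodes
sharing an attractor form a cluster.

The soft variant assumes further that *alternative* clusterings of the same
graph expose the overlap structure: penalizing nodes that have already
served as attractors (inflation exponent *r·β^x* for a node penalized *x*
times) forces later executions toward different attractors, and the union
of all executions' clusters covers overlapping and hierarchically nested
modules. Low-quality and redundant members of that union are removed by
post-processing rather than prevented during flow simulation.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| r | inflation exponent | 2.0 | > 1; larger → smaller, tighter clusters (4.5 is a sensible choice when small modules are the target) |
| b | balance exponent | 0.5 | ≥ 0; penalizes flow toward crowded attractors; 0 disables |
| t | number of executions | 30 | useful range 10–50; more executions → more candidate clusters |
| β | penalty ratio | 1.25 | ≥ 1; 1 disables the penalty (all executions identical) |
| qf | cluster quality function | density·√size | density alone favors tiny clusters on sparse networks; mean local clustering coefficient is offered but performs worst of the three |
| ω | quality threshold | 1.0 | depends on qf and network density; sweep it (the `sweep` command) to trade coverage against precision. With density·√size, 1.0 keeps any cluster at least as dense as a star of its size; tuned values on real interactomes typically land between 0.4 (dense, weighted) and 1.2 (sparse, unweighted) |
| p | redundancy threshold | 0.6 | NA above p removes the lower-quality cluster; range 0.3–0.8, higher → more overlap retained |
| θ | match threshold | 0.25 | NA level at which a cluster and a reference module count as matching; 1.0 = exact equality |
| prune threshold | sparsity cutoff | 1e−5 | entries below it are dropped after each inflation (column max always kept) |
| convergence tol | stopping residual | 1e−6 | max-abs change between successive flow matrices |

Information content of a reference term uses the natural log by default
(−ln(|g|/|root|)); the base is configurable (`--ic-log-base`) since term
corpora differ and the conventional cutoff (IC > 2) is base-dependent.

## Numerical choices

* **Balance mechanism.** The regularizer is rebuilt every inner iteration
  as *M<sub>G</sub>* with row *i* scaled by *mass(i)<sup>−b</sup>* and
  columns renormalized, where *mass(i)* is the number of columns whose
  current argmax is *i* (floored at 1). With b = 0 the canonical matrix is
  returned unchanged (exact, not approximate), which also serves as a test
  hook.
* **Penalty bookkeeping.** Counts are frozen during an execution and
  incremented once per execution for each attractor, so the first
  execution is exactly hard R-MCL.
* **Underflow guard.** Penalized exponents *r·β^x* grow geometrically; a
  column whose entries all underflow after exponentiation is replaced by a
  point mass on its pre-inflation maximum entry (logged at debug level)
  instead of raising.
* **No self-loops.** Faithful to the graph model, no self-loops are added,
  so period-2 flow oscillations are possible (e.g. a single isolated
  edge). A detected two-state cycle terminates the iteration with the
  column-normalized *average* of the two alternating states — the
  flip-flop equilibrium — which yields the expected fixed point (one
  2-node cluster for the single edge). Non-convergence at the iteration
  cap returns the current matrix with a warning, never an exception.
* **Attractors** are the nodes receiving some column's dominant flow
  (column argmax, ties toward the lower node index). A node with residual
  diagonal mass whose own flow departs elsewhere attracts nothing and is
  not counted. Clusters are the argmax fibers, so each execution returns a
  partition by construction.
* **Tie-breaks.** Column argmax ties resolve to the lowest node index;
  the redundancy scan orders clusters by (quality desc, size desc,
  lexicographic members), making output byte-for-byte reproducible and
  independent of input cluster order. Removal requires NA strictly
  greater than p; NA = p survives.
* **Duplicate edges** collapse to the maximum weight (confidence scores
  are evidence lower-bounded by their strongest source); duplicate pooled
  clusters collapse to their earliest execution before post-processing
  (NA = 1 would remove them anyway).
* **Min-max normalization** maps weights into [ε, 1] with ε = 0.01 rather
  than [0, 1], because a zero weight would silently delete the edge from
  the flow matrix.
* **IC before restriction, size after.** A term's information content is a
  property of the annotation corpus and is computed from the unrestricted
  term size; the minimum-size filter (≥ 3) applies after restricting the
  term to the network's proteins, since a term barely present in the
  network cannot be recovered from it.

## Synthetic data: what it emulates and what it does not

The generators plant modules with chosen internal edge probability, shared
members (overlaps and bridge nodes), optional weak parent edges around
strong child cliques, and uniform random inter-module noise edges; a
random Hamiltonian path keeps each sparse module connected. The
randomized benchmark (200 nodes, 20 modules, 30 % of nodes in ≥ 2 modules,
p_in = 0.9, noise = 5 % of module edges) reproduces, at desk scale, the
overlap statistics that motivate soft clustering. These sizes were chosen
so the full benchmark study (ten seeds, soft and hard clustering, an ω
sweep each) completes in about a minute.

Real interactomes differ in ways the generator does not model: heavy-tailed
degree distributions, assay-dependent correlated false positives/negatives,
module sizes spanning two orders of magnitude, and annotation truth that is
itself incomplete and hierarchical. Passing tests therefore demonstrate
that the algorithm recovers planted overlap/hierarchy structure and that
the soft variant dominates the hard one under controlled conditions — not
that a particular F-measure will be attained on any real network.

## Degenerate inputs and contracts

Empty networks, isolated nodes, self-loop-only files, non-positive weights
and malformed lines are rejected with specific errors; an empty cluster
list evaluates to all-zero metrics with a warning. t = 1 without
post-processing reproduces hard R-MCL exactly; β = 1 makes all executions
identical. Everything downstream of the generators is deterministic — the
engine itself uses no randomness.

## Known limitations

* The redundancy scan is greedy in quality order; it guarantees pairwise
  NA ≤ p among kept clusters but not a maximum-cardinality such set.
* The balance reweighting interacts with the penalty: under heavy
  penalties the flow may cycle through attractor configurations without
  meeting the residual tolerance, in which case the iteration cap applies
  (the returned clustering is still well-defined and, empirically, the
  pooled results are unaffected).
* Evaluation is all-pairs NA (clusters × terms); fine for desk-scale
  studies, quadratic in the worst case.
* Only edge-list input is supported; PSI-MI/BioGRID exports must be
  flattened to edge lists beforehand, and GO annotations must be
  pre-propagated to a two-column term–protein table.
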