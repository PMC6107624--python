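# Methods

## Scope

`ganet` implements the grouped-attachment (GA) family of random-graph
generators together with the topology measures used to evaluate them:
co-neighborness, the undirected 3–5-node graphlet census and the
directed triad census, the relative graphlet frequency (RGF) distance,
motif-spectrum correlation, degree assortativity, and a discrete
power-law fit of the degree distribution. A benchmark layer
parameterizes baseline models (Erdős–Rényi, Watts–Strogatz, scale-free
growth) and the GA variants from a real network and scores replicate
model networks against it.

## Measures

**Jaccard index of an edge.** For nodes u, v with neighborhoods Γ(u),
Γ(v), the package computes JC(u,v) = |Γ(u)∩Γ(v)| / |Γ(u)∪Γ(v)∖{u,v}|
by default. Removing the endpoints from the union means two adjacent
nodes are not penalized for being each other's neighbors; it is the
convention under which an edge whose endpoints share 3 of their 10
outside neighbors scores 0.3, and under which a complete graph scores
exactly 1 on every edge. The strict textbook form (endpoints kept,
3/12 on the same example) is available with `exclude_endpoints=False`.
Pairs with an empty neighbor union score 0 rather than NaN, so the
graph average below is always defined for graphs with at least one
edge.

**Co-neighborness** cn(G) is the mean of JC over all edges, each
unordered adjacent pair counted once. It is 0 exactly when the graph
has no triangle and 1 for complete graphs. Directed graphs are
measured on their underlying undirected simple graph; no directed
variant is defined.

**Graphlet and triad censuses.** Isomorphism classes are derived by
exhaustive enumeration: all labelled (di)graphs on k nodes are encoded
as edge bitmasks, the canonical form of a mask is the minimum over all
k! node permutations, and classes are ordered by canonical mask within
each size, sizes ascending. This yields 2, 6 and 21 connected
undirected classes on 3, 4 and 5 nodes (29 in total) and 16 directed
3-node classes, 13 of them weakly connected. Published motif
numberings differ between tools; spectra produced here are
self-consistent and the class table (`build_class_table`,
`graphlet_class_info`) documents the ordering, while all comparisons
(RGF distance, Pearson correlation) are invariant to a common
reordering. The census itself enumerates connected induced subgraphs
once each with the ESU algorithm and classifies them by a precomputed
mask → class lookup, so classification is O(k²) bit tests per
subgraph. Counting is exact (no subgraph sampling); a node-count guard
(10⁴ nodes at size 3, 4×10³ at size 4, 2×10³ at size 5) protects
against runaway enumeration and can be lifted explicitly. The directed
census delegates the counting to the standard triad census and maps
the result onto the canonical table; counts at the three weakly
disconnected triad classes are reported as zero, with the `connected`
mask marking those positions. A subset-enumeration brute-force census
(guarded at 15 nodes) serves as the independent oracle in the test
suite, alongside a cross-check against igraph's RAND-ESU counter at
full sampling.

**RGF distance.** F_i(G) = −ln(N_i(G)/T(G)) with T = Σ N_i, and
D(G,H) = Σ_{i=1..29} |F_i(G) − F_i(H)|. F_i is undefined at N_i = 0;
the package substitutes a pseudocount (default 1, T unchanged)
symmetrically in both profiles. Under a fixed pseudocount and the
natural-log convention D is a pseudometric (nonnegative, symmetric,
D(G,G)=0); absolute distances depend on both conventions, so only
values computed with the same settings are comparable, and distances
reported elsewhere with unknown conventions are not expected to be
bit-reproducible.

**Assortativity and power law.** Degree assortativity is Newman's
Pearson correlation of degrees across edge endpoints (both
orientations per undirected edge); regular graphs, where it is 0/0,
yield NaN with a warning instead of an error. The power-law fit is a
discrete maximum-likelihood estimate: for each candidate lower cutoff
xmin (every unique degree leaving ≥ 10 tail points) the exponent
maximizes the Hurwitz-zeta likelihood, and the cutoff minimizing the
Kolmogorov–Smirnov distance between empirical and fitted tail is kept.
The fit also reports whether the power law beats a geometric tail of
the same data by likelihood (`heavy_tail_plausible`); a False flag
marks exponent estimates from light-tailed sequences as unreliable.
The fitted (exponent, xmin) pair doubles as the (α, a) input of the
preferential generators when parameterizing from a real network.

## Grouped attachment

Inputs: node count n, edge probability p ∈ (0,1), groupness
q ∈ (p,1). Starting from one node, each repeat attaches a group F:

1. **Edge extension.** F starts as a single edge. While a Bernoulli(q)
   trial succeeds, a node is added and linked to each current member
   independently with probability q, with at least one link forced so
   F stays connected. The untruncated size is 2 + Geometric(1−q)
   (mean 2 + q/(1−q)) and the internal density is approximately q.
   A cap (default 50; the remaining node budget near the end) truncates
   the group so the output has exactly n nodes; the final group may
   be a single node.
2. **Selection.** Existing nodes are selected independently with
   probability p/q (clipped at 1).
3. **Wiring.** Every selected node is linked to every node of F with
   probability q, so a connecting edge appears with probability
   (p/q)·q = p while co-attached group members share their anchors —
   the mechanism that raises co-neighborness and motif recurrence as
   q grows. As q approaches p the groups degenerate and the wiring
   approaches an ER process at rate p.

**GA+R.** Plain GA targets density p only on the connecting edges;
group-internal edges (density ≈ q) push the total above p. The
revised variant replaces p with a per-repeat p′ chosen so the expected
edges added in the repeat equal p times the new node pairs created:

    p′ = [p(C(f,2) + g·f) − q·C(f,2)] / (g·f),  clipped to [0, q],

with g = |V_G|, f = |F|. Early repeats, where the dense group
dominates, clip to 0; a singleton final group falls back to p. The
balance equation is a per-repeat expectation argument, not an exact
finite-size inversion, so realized total density matches p to within
Monte-Carlo accuracy (the suite checks a 10% band at n=300, p=0.05,
q=0.6 over 50 seeds).

**GA+P / GA+RP.** The preferential variants replace Bernoulli
selection with a draw of round(|V_G|·p/q) distinct targets weighted by
deg^α + a (in-degree for directed graphs), sampled without replacement
via exponential keys (key_i = Exp(1)/w_i, smallest m win). α = 0
recovers uniform selection; large α concentrates on the hub. All-zero
weights (possible only at a = 0 before any edge exists) fall back to
uniform with a warning. Preferential selection makes high-degree nodes
absorb most connecting edges, which drives assortativity negative —
the scale-free signature the variants are designed to add.

**Direction.** The generators are natively undirected. When a directed
network is requested, each realized edge keeps both arcs with
probability `reciprocity` (default 0.25) and otherwise one uniformly
chosen arc. The default is a design choice: mutual dyads are required
for bidirectional triad motifs to appear at all, and 0.25 keeps them
present without dominating. Direction assignment is independent of the
attachment mechanism.

## Baselines

ER is G(n, p) at the measured density. Watts–Strogatz starts from a
ring lattice with `neighbors` links per side — set to round(|E|/|N|)
when matched to a target network — and rewires each edge with
probability 0.05 (edge count preserved). The scale-free generator
grows from a single node, each new node attaching m = round(|E|/|N|)
edges to targets drawn ∝ deg^α + a; m = 1 gives a tree, and α = 1 with
small a yields fitted exponents in the 2–3 band at n = 5000.

## Benchmark protocol

`sweep_q` estimates p from the target network, generates `replicates`
networks per grid value (default grid 0.1…0.9 step 0.1; values ≤ p
dropped with a warning) and returns the q minimizing the mean RGF
distance, ties broken toward the smaller, more ER-like value.
`compare_models` reports, per model, replicate mean ± sd of RGF
distance, co-neighborness and assortativity plus the mean motif
correlation (triad spectra when the target is directed, graphlet
spectra otherwise), running the q sweep internally for GA-family
entries when q is not supplied. All randomness derives from one
integer seed through per-replicate substreams; reports are
bit-reproducible. Replicate defaults are 10, matching the protocol of
10 repeats for undirected networks (100 for small directed ones);
5-node censuses on dense graphs dominate runtime, so replicates and
`max_size` are configurable.

## Problem sizes and numerical choices

The test suite exercises the stochastic claims at the study
conditions: density targeting and the cn-vs-q trend at n = 300,
p = 0.05 (50 and 30 seeds), the preferential-assortativity contrast at
n = 300 over 30 seeds, and exponent recovery at n = 5000. The
q self-recovery sweep uses a GA(q = 0.8) target at n = 100, p = 0.05
with 3 replicates per grid point — chosen so the exact 3–5-node census
over the full grid completes in about a minute while still recovering
q to within one grid step (verified across several seeds). Pseudocount
1 and natural logs are fixed conventions for RGF; Jaccard endpoint
exclusion is the default convention throughout.

## What the synthetic data does and does not show

Generated GA/ER/SW/SF networks are the package's own test bed: they
validate internal consistency (oracle equivalence, density targeting,
parameter recovery) and the qualitative mechanisms (q drives
co-neighborness, preferential selection drives disassortativity).
They do not establish that real biological or infrastructure networks
are well fit by any of these models: real networks carry degree
correlations, modular and spatial structure the generators do not
emulate. The edge-extension law and the p′ balance equation are this
package's own formulations of the grouped-attachment idea; other
implementations of the same idea may differ in the exact group-size
law and density correction, so externally reported RGF distances for
named networks are comparable only qualitatively.

## Known limitations

* Exact censuses are exponential in graphlet size; graphs beyond a few
  thousand nodes need the node-count guard lifted consciously and may
  be slow at size 5. No sampling estimator is provided.
* Directed analysis is limited to 3-node triads; 4/5-node directed
  motifs are out of scope.
* The power-law fit performs no bootstrap goodness-of-fit p-value, only
  the KS scan and the geometric likelihood comparison.
* `sweep_q` optimizes RGF distance only; motif correlation is reported
  but not optimized.
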