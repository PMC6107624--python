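# ganet

Grouped-attachment network models and motif topology measures.

Random-graph models are judged by which real-world properties they
reproduce. The classic generators — Erdős–Rényi (ER), Watts–Strogatz
small-world (SW), scale-free preferential attachment (SF) — reproduce
density, small-worldness or power-law degrees, but none of them
reproduces the *motif* content of real networks: the frequencies of
small induced subgraphs (graphlets) and the tendency of adjacent nodes
to share neighbors. `ganet` is a library + CLI for network scientists
and systems biologists who want to generate model networks that match
a real network's motif structure, and to quantify that match.

## The model and the measures

**Co-neighborness** of a graph G = (V, E) is the average edge-wise
Jaccard index

    cn(G) = (1/|E|) Σ_{(u,v)∈E} JC(u,v),
    JC(u,v) = |Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v) ∖ {u,v}|,

0 for triangle-free graphs, 1 for complete graphs.

**Grouped attachment (GA)** grows a graph with parameters (n, p, q),
0 < p < q < 1. Each repeat builds a small, dense group F (internal
density ≈ q, stochastic size with mean 2 + q/(1−q)), selects existing
nodes with probability p/q, and wires every selected node to every
group node with probability q — so connecting edges appear with
probability p overall while all of F shares the same anchors. High q
produces the shared-neighbor structure that populates triangles and
denser motifs; q → p degenerates to ER. Variants: **GA+R** replaces p
by a per-repeat p′ = [p(C(f,2)+gf) − q·C(f,2)]/(gf) (clipped to [0,q])
so the *total* density targets p; **GA+P** / **GA+RP** select
attachment targets ∝ deg^α + a (preferential attachment), which adds
scale-free, disassortative structure.

**Scoring.** Networks are compared by their 29-class census of
connected induced 3–5-node subgraphs via the relative graphlet
frequency distance

    D(G,H) = Σ_{i=1..29} |F_i(G) − F_i(H)|,   F_i(G) = −ln(N_i(G)/T(G)),

by Pearson correlation of motif spectra (directed 3-node triads for
directed networks), by co-neighborness, by Newman degree assortativity
r, and by a discrete power-law fit (MLE exponent with KS-selected
xmin).

## Worked example

Generate a "real" network from the GA model, then ask which model
family reproduces its motif structure:

```python
import ganet as G

real = G.ga_generate(G.GAParams(n=80, p=0.06, q=0.7, seed=21))
print("density=%.4f cn=%.4f" % (G.edge_density(real),
                                G.co_neighborness(real)))
rep = G.compare_models(real, models=("er", "sw", "ga"),
                       replicates=5, seed=7, q=0.7)
print(rep.round(3).to_string(index=False))
```

prints

```
density=0.0978 cn=0.2284
model  replicates   q  rgf_mean  rgf_sd  cn_mean  cn_sd  assortativity_mean  assortativity_sd  spectrum_corr_mean
   er           5 NaN    49.072   3.898    0.056  0.006              -0.026             0.064               0.960
   sw           5 NaN    30.548   1.604    0.420  0.005              -0.025             0.025               0.882
   ga           5 0.7    13.178   6.225    0.253  0.058               0.067             0.045               0.984
```

Read: ER matches the density but lands far away in graphlet content
(RGF distance 49) and shows almost no neighborhood sharing
(cn ≈ 0.06 vs 0.23 in the target); the small-world model overshoots
co-neighborness (0.42) through its lattice clustering; the GA model at
the matching groupness q = 0.7 reproduces both the co-neighborness and
the graphlet spectrum (lowest RGF distance, highest spectrum
correlation).

The same works from the shell on edge-list (`.tsv`) or Matrix Market
(`.mtx`) files:

```sh
ganet generate --model ga-r --n 500 --p 0.02 --q 0.8 --seed 1 --out net.tsv
ganet measure --in net.tsv --fit
ganet census --in net.tsv --out spectrum.tsv
ganet sweep-q --in net.tsv --replicates 5 --seed 1
ganet compare --in net.tsv --models er,sw,sf,ga,ga-r --seed 1
```

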