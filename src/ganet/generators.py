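"""Network generators: the grouped-attachment (GA) family and baselines.

Grouped attachment grows a graph by repeatedly attaching a small,
densely interconnected group *F* rather than a single node.  The model
takes a node count *n*, an edge probability *p* (0 < p < 1) and a
groupness probability *q* (p < q < 1).  Starting from one node, each
repeat

1. builds a group *F* by edge extension with density parameter q,
2. selects existing nodes independently with probability p/q,
3. wires every selected node to every node of *F* with probability q,

so a connecting edge appears with overall probability (p/q)·q = p while
all nodes of *F* attach to the *same* selected targets — co-attached
nodes share neighbors, which is what drives co-neighborness and motif
recurrence.  With q near p the construction degenerates towards an
Erdős–Rényi wiring; with high q the groups are near-cliques attached to
a few shared anchors.

Variants:

* **GA+R** replaces p by a per-repeat corrected p′ so the *total* edge
  density (group-internal edges included) targets p.  p′ solves the
  balance "expected edges added this repeat = p × new pairs added":
  p′ = [p(C(f,2) + g·f) − q·C(f,2)] / (g·f), clipped to [0, q].
* **GA+P** selects round(|V_G|·p/q) attachment targets weighted by
  deg^α + a (preferential attachment; in-degree when directed) instead
  of uniform Bernoulli selection.  **GA+RP** combines both.

Group construction (edge extension): F starts as a single edge; while a
Bernoulli(q) trial succeeds a node is added and wired to each existing
group member with probability q (at least one edge, keeping F
connected).  Untruncated group size is therefore 2 + Geometric(1−q)
with mean 2 + q/(1−q), and the internal density is approximately q.

Directed output is produced by orienting an undirected realization:
each edge keeps both arcs with probability ``reciprocity`` (default
0.25) and otherwise a uniformly chosen single arc.

Baselines follow the usual parameterizations: ER with edge probability
p; Watts–Strogatz with ``neighbors`` lattice links per side and rewiring
probability 0.05; a scale-free growth model adding one node with m
edges per step, targets drawn proportionally to deg^α + a.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

logger = logging.getLogger("ganet")

__all__ = [
    "GAParams",
    "generate_group",
    "revised_connect_prob",
    "preferential_select",
    "ga_generate",
    "er_generate",
    "sw_generate",
    "sf_generate",
    "fixture",
]

#: stochastic group sizes above this are truncated (mean is 2 + q/(1-q),
#: so the cap only bites in the q -> 1 limit)
DEFAULT_MAX_GROUP_SIZE = 50


@dataclass(frozen=True)
class GAParams:
    """Parameter bundle for the grouped-attachment family.

    n           target node count (exact in the output graph)
    p           edge probability, 0 < p < 1
    q           groupness probability, p < q < 1
    revised     GA+R total-density correction (use p' instead of p)
    preferential  GA+P weighted target selection (deg^alpha + attract)
    alpha       preferential-attachment power (>= 0)
    attract     initial attractiveness a (>= 0)
    directed    orient edges after generation
    reciprocity probability an oriented edge keeps both arcs
    max_group_size  truncation cap for the stochastic group size
    seed        RNG seed (int or numpy Generator); None draws fresh
    """

    n: int
    p: float
    q: float
    revised: bool = False
    preferential: bool = False
    alpha: float = 1.0
    attract: float = 1.0
    directed: bool = False
    reciprocity: float = 0.25
    max_group_size: int = DEFAULT_MAX_GROUP_SIZE
    seed: object = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 < self.p < self.q < 1:
            raise ValueError(
                f"need 0 < p < q < 1, got p={self.p}, q={self.q}")
        if self.alpha < 0 or self.attract < 0:
            raise ValueError("alpha and attract must be >= 0")
        if not 0 <= self.reciprocity <= 1:
            raise ValueError("reciprocity must be in [0, 1]")
        if self.max_group_size < 1:
            raise ValueError("max_group_size must be >= 1")

    def variant_name(self) -> str:
        base = "GA"
        if self.revised:
            base += "+R" if not self.preferential else "+RP"
        elif self.preferential:
            base += "+P"
        return base


def generate_group(q: float, rng: np.random.Generator,
                   max_size: int = DEFAULT_MAX_GROUP_SIZE) -> nx.Graph:
    """Edge-extension group: connected, internal density ~ q.

    Starts from a single edge; while Bernoulli(q) succeeds (and the cap
    allows) a node joins and links to each member with probability q,
    at least one link forced.  ``max_size=1`` yields a single node.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    f = nx.Graph()
    f.add_node(0)
    if max_size == 1:
        return f
    f.add_edge(0, 1)
    while f.number_of_nodes() < max_size and rng.random() < q:
        size = f.number_of_nodes()
        links = rng.random(size) < q
        if not links.any():
            links[rng.integers(size)] = True
        f.add_node(size)
        f.add_edges_from((int(i), size) for i in np.flatnonzero(links))
    return f


def revised_connect_prob(g_size: int, f_size: int, p: float, q: float) -> float:
    """GA+R connecting-edge probability p' targeting total density p.

    Balances expected edges added in one repeat (q·C(f,2) internal +
    p'·g·f connecting) against p times the number of new node pairs
    (C(f,2) + g·f), and clips the solution into [0, q] — early repeats,
    where the dense group dominates the new pairs, clip to 0.
    """
    if g_size < 1 or f_size < 1:
        raise ValueError("group sizes must be >= 1")
    if f_size == 1:
        return min(p, q)
    internal_pairs = f_size * (f_size - 1) / 2
    cross_pairs = g_size * f_size
    raw = (p * (internal_pairs + cross_pairs) - q * internal_pairs) / cross_pairs
    return float(min(max(raw, 0.0), q))


def preferential_select(degrees, m: int, alpha: float, attract: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Sample ``m`` distinct indices with weight deg^alpha + attract.

    Weighted sampling without replacement via exponential keys: index i
    gets key Exp(1)/w_i and the m smallest keys win.  All-zero weights
    fall back to uniform with a warning.
    """
    deg = np.asarray(degrees, dtype=float)
    if m > len(deg):
        raise ValueError(f"cannot select {m} from {len(deg)} nodes")
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    with np.errstate(over="ignore"):
        w = deg ** alpha + attract
    if not np.any(w > 0):
        logger.warning("all preferential weights are zero; sampling uniformly")
        w = np.ones_like(w)
    if m == len(deg):
        return np.arange(len(deg), dtype=np.int64)
    keys = rng.exponential(1.0, len(deg)) / w
    return np.sort(np.argpartition(keys, m)[:m]).astype(np.int64)


def _orient(g: nx.Graph, reciprocity: float,
            rng: np.random.Generator) -> nx.DiGraph:
    """Turn an undirected realization into a digraph."""
    d = nx.DiGraph()
    d.add_nodes_from(g.nodes)
    for u, v in g.edges:
        if rng.random() < reciprocity:
            d.add_edge(u, v)
            d.add_edge(v, u)
        elif rng.random() < 0.5:
            d.add_edge(u, v)
        else:
            d.add_edge(v, u)
    d.graph.update(g.graph)
    return d


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def ga_generate(params: GAParams) -> nx.Graph:
    """Generate a grouped-attachment network with exactly ``params.n`` nodes.

    The last group is truncated so the node count lands on n exactly.
    Output is reproducible given (params, integer seed).
    """
    rng = _as_rng(params.seed)
    g = nx.Graph()
    g.add_node(0)
    degrees = np.zeros(params.n, dtype=np.int64)

    while g.number_of_nodes() < params.n:
        n_g = g.number_of_nodes()
        remaining = params.n - n_g
        f = generate_group(params.q, rng,
                           max_size=min(params.max_group_size, remaining))
        n_f = f.number_of_nodes()

        p_eff = (revised_connect_prob(n_g, n_f, params.p, params.q)
                 if params.revised else params.p)
        sel_prob = min(p_eff / params.q, 1.0)

        if params.preferential:
            m = min(n_g, round(n_g * sel_prob))
            selected = preferential_select(
                degrees[:n_g], m, params.alpha, params.attract, rng)
        else:
            selected = np.flatnonzero(rng.random(n_g) < sel_prob)

        # merge F with fresh ids, then wire selected G nodes to F w.p. q
        offset = n_g
        g.add_nodes_from(offset + i for i in range(n_f))
        for a, b in f.edges:
            g.add_edge(offset + a, offset + b)
            degrees[offset + a] += 1
            degrees[offset + b] += 1
        if len(selected):
            hits = rng.random((len(selected), n_f)) < params.q
            for i, s in enumerate(selected):
                for j in np.flatnonzero(hits[i]):
                    g.add_edge(int(s), offset + int(j))
                    degrees[s] += 1
                    degrees[offset + j] += 1

    g.graph["model"] = params.variant_name()
    g.graph["params"] = replace(params, seed=None)
    if params.directed:
        return _orient(g, params.reciprocity, rng)
    return g


def er_generate(n: int, p: float, directed: bool = False,
                seed=None) -> nx.Graph:
    """Erdős–Rényi G(n, p)."""
    rng = _as_rng(seed)
    g = nx.fast_gnp_random_graph(n, p, seed=rng, directed=directed)
    g.graph["model"] = "ER"
    return g


def sw_generate(n: int, neighbors: int, rewire_p: float = 0.05,
                seed=None) -> nx.Graph:
    """Watts–Strogatz ring lattice with rewiring.

    ``neighbors`` nearest neighbors are linked on *each side* of the
    ring (lattice degree 2·neighbors), matching the convention in which
    the lattice neighborhood is set to |E|/|N| of a target network.
    """
    if neighbors < 1:
        raise ValueError("neighbors must be >= 1")
    rng = _as_rng(seed)
    g = nx.watts_strogatz_graph(n, 2 * neighbors, rewire_p, seed=rng)
    g.graph["model"] = "SW"
    return g


def sf_generate(n: int, m: int, alpha: float = 1.0, attract: float = 1.0,
                seed=None) -> nx.Graph:
    """Scale-free growth: each new node attaches m edges ∝ deg^alpha + a.

    Starts from a single node; while fewer than m nodes exist the new
    node links to all of them.  With alpha = 1 and small a the degree
    distribution develops a power-law tail with exponent between 2
    and 3.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = _as_rng(seed)
    g = nx.Graph()
    g.add_node(0)
    degrees = np.zeros(n, dtype=np.int64)
    for v in range(1, n):
        k = min(m, v)
        targets = preferential_select(degrees[:v], k, alpha, attract, rng)
        g.add_node(v)
        for t in targets:
            g.add_edge(int(t), v)
            degrees[t] += 1
            degrees[v] += 1
    g.graph["model"] = "SF"
    return g


def _two_hubs_graph() -> nx.Graph:
    """Two adjacent hubs with 3 shared, 3 A-only and 4 B-only neighbors."""
    edges = [("A", "B")]
    edges += [("A", x) for x in "CDE"] + [("B", x) for x in "CDE"]
    edges += [("A", x) for x in "FGH"]
    edges += [("B", x) for x in "IJKL"]
    g = nx.Graph(edges)
    order = {lab: i for i, lab in enumerate("ABCDEFGHIJKL")}
    g = nx.relabel_nodes(g, order)
    g.graph["labels"] = {i: lab for lab, i in order.items()}
    return g


def fixture(name: str, k: int | None = None) -> nx.Graph:
    """Deterministic toy graphs used in examples and tests.

    Names: ``two_hubs`` (the 12-node two-hub common-neighbor example:
    adjacent hubs A and B sharing neighbors C, D, E, with three A-only
    and four B-only neighbors), ``complete`` (K_k), ``trianglefree``
    (star on k nodes), ``k4_minus_edge``.  ``complete(5)``-style
    strings are also accepted.
    """
    if "(" in name:
        base, arg = name.rstrip(")").split("(")
        name, k = base.strip(), int(arg)
    if name == "two_hubs":
        return _two_hubs_graph()
    if name == "k4_minus_edge":
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        return g
    if k is None:
        raise ValueError(f"fixture {name!r} needs a size k")
    if name == "complete":
        return nx.complete_graph(k)
    if name == "trianglefree":
        return nx.star_graph(k - 1)
    raise ValueError(f"unknown fixture {name!r}")
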