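"""Exact induced-subgraph censuses.

Two spectra are produced:

* the undirected **graphlet census**: counts of connected induced
  subgraphs on 3-5 nodes, classified into the 29 isomorphism classes
  (2 on three nodes, 6 on four, 21 on five);
* the **triad census**: counts of directed 3-node induced subgraphs
  over the 16 isomorphism classes, 13 of which are weakly connected.

Isomorphism classes are derived from first principles: all labelled
(di)graphs on k nodes are enumerated as edge bitmasks, each mask is
mapped to its canonical form (the minimum mask over all node
permutations), and classes are ordered by canonical mask within each
size, sizes ascending.  The same enumeration yields a mask -> class
lookup table, so classifying an induced subgraph during the census is
a single array access.

``graphlet_census`` enumerates connected induced subgraphs with the
ESU algorithm (each vertex set visited exactly once);
``brute_force_census`` iterates all C(n,k) vertex subsets and is the
independent oracle the tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "GraphletClassTable",
    "MotifSpectrum",
    "build_class_table",
    "graphlet_census",
    "triad_census",
    "brute_force_census",
    "GRAPHLET_SIZES",
    "N_GRAPHLET_CLASSES",
    "N_TRIAD_CLASSES",
]

GRAPHLET_SIZES = (3, 4, 5)
N_GRAPHLET_CLASSES = 29
N_TRIAD_CLASSES = 16

# node-count guards against runaway exact enumeration
_NODE_GUARD = {3: 10_000, 4: 4_000, 5: 2_000}


def _positions(size: int, directed: bool):
    """Edge slots of a labelled k-node (di)graph, one bit each."""
    if directed:
        return [(i, j) for i in range(size) for j in range(size) if i != j]
    return list(combinations(range(size), 2))


def _is_connected_mask(mask: int, size: int, positions) -> bool:
    """Weak connectivity of the (di)graph encoded by ``mask``."""
    parent = list(range(size))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for bit, (i, j) in enumerate(positions):
        if mask >> bit & 1:
            parent[find(i)] = find(j)
    return len({find(v) for v in range(size)}) == 1


@lru_cache(maxsize=None)
def _class_data(size: int, directed: bool):
    """Canonical-form array over all masks, plus sorted class info.

    Returns (canon, reps, connected, class_of) where ``canon[mask]`` is
    the canonical mask, ``reps`` the sorted canonical representatives,
    ``connected`` their weak-connectivity flags and ``class_of[mask]``
    the class id (index into reps) of every labelled mask.
    """
    positions = _positions(size, directed)
    m = len(positions)
    pos_index = {pos: b for b, pos in enumerate(positions)}
    perm_maps = []
    for perm in permutations(range(size)):
        pm = []
        for (i, j) in positions:
            tgt = (perm[i], perm[j])
            if not directed:
                tgt = (min(tgt), max(tgt))
            pm.append(pos_index[tgt])
        perm_maps.append(pm)

    canon = np.empty(1 << m, dtype=np.int64)
    for mask in range(1 << m):
        best = mask
        for pm in perm_maps:
            new = 0
            mm = mask
            b = 0
            while mm:
                if mm & 1:
                    new |= 1 << pm[b]
                mm >>= 1
                b += 1
            if new < best:
                best = new
        canon[mask] = best

    reps = sorted(set(canon.tolist()))
    rep_index = {rep: i for i, rep in enumerate(reps)}
    connected = tuple(_is_connected_mask(r, size, positions) for r in reps)
    class_of = np.array([rep_index[c] for c in canon.tolist()], dtype=np.int64)
    return canon, tuple(reps), connected, class_of


@dataclass(frozen=True)
class GraphletClassTable:
    """Canonical representatives and ordering of k-node isomorphism classes.

    Undirected tables keep only connected classes (2/6/21 for k=3/4/5);
    the directed 3-node table keeps all 16 classes with a connectivity
    flag, so triad spectra have the full census length.
    """

    size: int
    directed: bool
    representatives: tuple[int, ...]
    connected: tuple[bool, ...]
    index: dict = field(repr=False)

    def __len__(self):
        return len(self.representatives)

    def representative_graph(self, class_id: int) -> nx.Graph:
        """Build the class representative as a networkx (di)graph."""
        mask = self.representatives[class_id]
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.size))
        for bit, pos in enumerate(_positions(self.size, self.directed)):
            if mask >> bit & 1:
                g.add_edge(*pos)
        return g


def build_class_table(size: int, directed: bool = False) -> GraphletClassTable:
    """Enumerate and canonically order the k-node isomorphism classes."""
    if directed and size != 3:
        raise ValueError("directed class tables are only defined for size 3")
    if size not in GRAPHLET_SIZES:
        raise ValueError(f"size must be in {GRAPHLET_SIZES}, got {size}")
    _, reps, connected, _ = _class_data(size, directed)
    if not directed:
        reps, connected = (
            tuple(r for r, c in zip(reps, connected) if c),
            tuple(c for c in connected if c),
        )
    return GraphletClassTable(
        size=size,
        directed=directed,
        representatives=reps,
        connected=connected,
        index={rep: i for i, rep in enumerate(reps)},
    )


@lru_cache(maxsize=None)
def _connected_lookup(size: int):
    """mask -> global 29-class id (or -1 if disconnected), plus offset."""
    offset = sum(len(build_class_table(s)) for s in GRAPHLET_SIZES if s < size)
    _, reps, connected, class_of = _class_data(size, False)
    local = np.full(len(reps), -1, dtype=np.int64)
    nxt = 0
    for i, c in enumerate(connected):
        if c:
            local[i] = offset + nxt
            nxt += 1
    return local[class_of]


@lru_cache(maxsize=None)
def graphlet_class_info():
    """(size, canonical mask) per global class id, in census order."""
    info = []
    for s in GRAPHLET_SIZES:
        info.extend((s, rep) for rep in build_class_table(s).representatives)
    return tuple(info)


@dataclass
class MotifSpectrum:
    """Vector of induced-subgraph counts indexed by canonical class.

    ``kind`` is ``"undirected-graphlet"`` (length 29, sizes 3-5, all
    classes connected) or ``"directed-triad"`` (length 16; counts at
    disconnected classes are zeroed by :func:`triad_census` and the
    ``connected`` mask identifies them).
    """

    kind: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = {
            "undirected-graphlet": N_GRAPHLET_CLASSES,
            "directed-triad": N_TRIAD_CLASSES,
        }
        if self.kind not in expected:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if len(self.counts) != expected[self.kind]:
            raise ValueError(
                f"{self.kind} spectrum must have length {expected[self.kind]}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def connected(self) -> np.ndarray:
        if self.kind == "undirected-graphlet":
            return np.ones(N_GRAPHLET_CLASSES, dtype=bool)
        return np.array(build_class_table(3, directed=True).connected)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        rows = ["# ganet motif spectrum\t" + self.kind,
                "class_id\tsize\tcanonical_mask\tcount"]
        if self.kind == "undirected-graphlet":
            info = graphlet_class_info()
        else:
            t = build_class_table(3, directed=True)
            info = [(3, rep) for rep in t.representatives]
        for i, ((s, rep), c) in enumerate(zip(info, self.counts)):
            rows.append(f"{i}\t{s}\t{rep}\t{int(c)}")
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "MotifSpectrum":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# ganet motif spectrum"):
            raise ValueError(f"{path}: not a ganet spectrum file")
        kind = lines[0].split("\t")[1].strip()
        counts = [int(ln.split("\t")[3]) for ln in lines[2:] if ln.strip()]
        return cls(kind=kind, counts=np.array(counts))


# ---------------------------------------------------------------------------
# ESU census (undirected graphlets)
# ---------------------------------------------------------------------------


def _adjacency(g: nx.Graph):
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    return [frozenset(idx[u] for u in g[v]) for v in nodes]


def _esu_count(adj, k: int, lookup, counts, pair_bit) -> None:
    """Wernicke's ESU: visit each connected induced k-subset once."""
    n = len(adj)

    def classify(sub):
        mask = 0
        for a, i in enumerate(sub):
            ai = adj[i]
            for b in range(a + 1, k):
                if sub[b] in ai:
                    mask |= pair_bit[a][b]
        cls = lookup[mask]
        counts[cls] += 1

    def extend(sub, ext, v, closed):
        if len(sub) == k - 1:
            for w in ext:
                classify(sub + [w])
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {u for u in adj[w] if u > v and u not in closed}
            extend(sub + [w], new_ext, v, closed | adj[w] | {w})

    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        if k == 1:
            continue
        extend([v], ext, v, adj[v] | {v})


def graphlet_census(g: nx.Graph, max_size: int = 5,
                    node_guard: bool = True) -> MotifSpectrum:
    """Count connected induced 3..``max_size``-node subgraphs of ``g``.

    Returns the full 29-class spectrum; classes of sizes beyond
    ``max_size`` stay zero.  Directed input is rejected (use
    :func:`triad_census`).  ``node_guard`` bounds the node count per
    size to keep exact enumeration tractable; pass False to override.
    """
    if g.is_directed():
        raise TypeError("graphlet_census is undirected; use triad_census "
                        "for directed 3-node motifs")
    if max_size not in GRAPHLET_SIZES:
        raise ValueError(f"max_size must be in {GRAPHLET_SIZES}")
    n = g.number_of_nodes()
    if n < max_size:
        raise ValueError(f"graph has {n} nodes; need at least {max_size}")
    adj = _adjacency(g)
    counts = np.zeros(N_GRAPHLET_CLASSES, dtype=np.int64)
    for k in GRAPHLET_SIZES:
        if k > max_size:
            break
        if node_guard and n > _NODE_GUARD[k]:
            raise ValueError(
                f"{n} nodes exceeds the size-{k} census guard "
                f"({_NODE_GUARD[k]}); pass node_guard=False to force"
            )
        pair_bit = [[0] * k for _ in range(k)]
        for b, (i, j) in enumerate(_positions(k, False)):
            pair_bit[i][j] = pair_bit[j][i] = 1 << b
        _esu_count(adj, k, _connected_lookup(k), counts, pair_bit)
    return MotifSpectrum(kind="undirected-graphlet", counts=counts)


# ---------------------------------------------------------------------------
# Directed triad census
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _triad_name_map():
    """networkx triad-census name -> canonical class id."""
    table = build_class_table(3, directed=True)
    canon, _, _, class_of = _class_data(3, True)
    positions = _positions(3, True)
    pos_index = {pos: b for b, pos in enumerate(positions)}
    mapping = {}
    for name in nx.algorithms.triads.TRIAD_NAMES:
        tri = nx.triad_graph(name)
        order = {v: i for i, v in enumerate(sorted(tri.nodes))}
        mask = 0
        for u, v in tri.edges:
            mask |= 1 << pos_index[(order[u], order[v])]
        mapping[name] = int(class_of[mask])
    return mapping


def triad_census(g: nx.DiGraph) -> MotifSpectrum:
    """Census of directed 3-node induced subgraphs (16 classes).

    Counts at the three weakly disconnected classes (empty triad,
    single arc, single mutual dyad) are reported as zero so the
    spectrum reflects connected motifs only; the ``connected`` mask of
    the result identifies the zeroed positions.
    """
    if not g.is_directed():
        raise TypeError("triad_census needs a directed graph; use "
                        "graphlet_census for undirected input")
    if g.number_of_nodes() < 3:
        raise ValueError("triad census needs at least 3 nodes")
    raw = nx.triadic_census(g)
    counts = np.zeros(N_TRIAD_CLASSES, dtype=np.int64)
    for name, c in raw.items():
        counts[_triad_name_map()[name]] += c
    table = build_class_table(3, directed=True)
    counts[~np.array(table.connected)] = 0
    return MotifSpectrum(kind="directed-triad", counts=counts)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_census(g: nx.Graph, size: int = 5) -> MotifSpectrum:
    """Subset-enumeration reference census (test oracle, n <= 15).

    Undirected: counts connected induced subgraphs of exactly ``size``
    nodes into the 29-class spectrum (other sizes left zero).
    Directed (size must be 3): full 16-class triad counts, including
    the disconnected classes.
    """
    n = g.number_of_nodes()
    if n > 15:
        raise ValueError(f"brute force census is guarded at 15 nodes, got {n}")
    directed = g.is_directed()
    if directed and size != 3:
        raise ValueError("directed brute force census only supports size 3")
    if size not in GRAPHLET_SIZES:
        raise ValueError(f"size must be in {GRAPHLET_SIZES}")
    if n < size:
        raise ValueError(f"graph has {n} nodes; need at least {size}")

    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    if directed:
        adj_out = [frozenset(idx[u] for u in g.successors(v)) for v in nodes]
        counts = np.zeros(N_TRIAD_CLASSES, dtype=np.int64)
        _, _, _, class_of = _class_data(3, True)
        positions = _positions(3, True)
        for sub in combinations(range(n), 3):
            mask = 0
            for b, (i, j) in enumerate(positions):
                if sub[j] in adj_out[sub[i]]:
                    mask |= 1 << b
            counts[class_of[mask]] += 1
        return MotifSpectrum(kind="directed-triad", counts=counts)

    adj = [frozenset(idx[u] for u in g[v]) for v in nodes]
    counts = np.zeros(N_GRAPHLET_CLASSES, dtype=np.int64)
    lookup = _connected_lookup(size)
    positions = _positions(size, False)
    for sub in combinations(range(n), size):
        mask = 0
        for b, (i, j) in enumerate(positions):
            if sub[j] in adj[sub[i]]:
                mask |= 1 << b
        cls = lookup[mask]
        if cls >= 0:
            counts[cls] += 1
    return MotifSpectrum(kind="undirected-graphlet", counts=counts)
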