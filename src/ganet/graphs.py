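"""Graph container conventions and edge-list / Matrix Market I/O.

Graphs are plain :class:`networkx.Graph` / :class:`networkx.DiGraph`
objects with contiguous integer node ids ``0..n-1``.  Original node
labels from an input file are kept in ``G.graph["labels"]`` (a dict
``node id -> original label``) so fixtures and real-network nodes stay
addressable by name.  All graphs are simple: no self-loops, no parallel
edges; offending input rows are dropped with a warning rather than
rejected, because published edge lists routinely contain them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import scipy.io
import scipy.sparse

logger = logging.getLogger("ganet")

__all__ = [
    "GraphFormatError",
    "EmptyGraphError",
    "read_edge_list",
    "read_matrix_market",
    "write_edge_list",
    "as_undirected",
    "labels_of",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


class EmptyGraphError(GraphFormatError):
    """Raised when an input file contains no nodes at all."""


def _finalize(g: nx.Graph, labels: list) -> nx.Graph:
    """Relabel first-seen-order labels to contiguous ints, keep side map."""
    mapping = {lab: i for i, lab in enumerate(labels)}
    h = nx.relabel_nodes(g, mapping, copy=True)
    h.graph["labels"] = {i: lab for lab, i in mapping.items()}
    return h


def labels_of(g: nx.Graph) -> dict:
    """Node-id -> original-label map (identity if the graph has none)."""
    return g.graph.get("labels", {v: v for v in g.nodes})


def as_undirected(g: nx.Graph) -> nx.Graph:
    """Underlying undirected simple graph (identity for undirected input)."""
    if g.is_directed():
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from(g.edges)
        h.graph.update(g.graph)
        return h
    return g


def read_edge_list(path, directed: bool = False) -> nx.Graph:
    """Read a whitespace-separated two-column edge list.

    Lines starting with ``#`` or ``%`` are comments; ``# isolated: X``
    comments written by :func:`write_edge_list` restore isolated nodes.
    Self-loops and repeated pairs are dropped with a warning.  Raises
    :class:`GraphFormatError` on malformed lines (naming the line
    number) and :class:`EmptyGraphError` on an input with no nodes.
    """
    path = Path(path)
    g = nx.DiGraph() if directed else nx.Graph()
    labels: list = []
    seen: dict = {}

    def node(tok):
        if tok not in seen:
            seen[tok] = len(labels)
            labels.append(tok)
        return tok

    n_loops = n_dups = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(("#", "%")):
                if line.startswith("# isolated:"):
                    tok = line.split(":", 1)[1].strip()
                    if tok:
                        g.add_node(node(tok))
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated "
                    f"tokens, got {len(parts)}: {line!r}"
                )
            u, v = node(parts[0]), node(parts[1])
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dups)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError(f"{path}: no nodes found")
    return _finalize(g, labels)


def read_matrix_market(path) -> nx.Graph:
    """Read a Matrix Market coordinate file as a graph.

    ``symmetric`` / ``skew-symmetric`` storage yields an undirected
    graph, ``general`` a directed one.  Indices are converted from the
    file's 1-based convention to 0-based node ids; nonzero magnitude
    marks an edge; diagonal entries (self-loops) are dropped.
    """
    path = Path(path)
    try:
        rows, cols, _entries, fmt, _field, symm = scipy.io.mminfo(path)
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise GraphFormatError(f"{path}: {exc}") from exc
    if fmt != "coordinate":
        raise GraphFormatError(f"{path}: expected coordinate format, got {fmt!r}")
    if rows != cols:
        raise GraphFormatError(
            f"{path}: adjacency matrix must be square, got {rows}x{cols}"
        )
    directed = symm == "general"
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(rows))
    coo = scipy.sparse.coo_array(mat)
    n_loops = 0
    for i, j in zip(coo.row, coo.col):
        if i == j:
            n_loops += 1
            continue
        g.add_edge(int(i), int(j))
    if n_loops:
        logger.warning("%s: dropped %d diagonal entr(ies)", path, n_loops)
    g.graph["labels"] = {v: v + 1 for v in g.nodes}  # file was 1-based
    return g


def write_edge_list(g: nx.Graph, path, header: str | None = None) -> None:
    """Write a two-column edge list using the graph's original labels.

    Round-trips through :func:`read_edge_list`: isolated nodes are
    recorded as ``# isolated:`` comments, directed edges one arc per
    line.  ``header`` (e.g. generator provenance) is emitted as leading
    ``#`` comment lines.
    """
    path = Path(path)
    lab = labels_of(g)
    with path.open("w") as fh:
        fh.write("# ganet edge list"
                 f" directed={g.is_directed()}"
                 f" nodes={g.number_of_nodes()} edges={g.number_of_edges()}\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        connected = set()
        for u, v in g.edges:
            connected.add(u)
            connected.add(v)
            fh.write(f"{lab[u]}\t{lab[v]}\n")
        for v in g.nodes:
            if v not in connected:
                fh.write(f"# isolated: {lab[v]}\n")
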