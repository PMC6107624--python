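"""Edge-similarity indices and whole-graph statistics.

Core quantities
---------------
Common neighbors    CN(u,v) = |Γ(u) ∩ Γ(v)|
Jaccard index       JC(u,v) = |Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v) \\ {u,v}|
Co-neighborness     cn(G)   = (1/|E|) Σ_{(u,v)∈E} JC(u,v)

Co-neighborness averages the edge-wise Jaccard index over all edges:
it is 0 exactly when the graph is triangle-free and 1 for a complete
graph.  By default the two endpoints are removed from the neighbor
union, which matches the worked convention that an edge whose endpoints
share 3 of 10 outside neighbors scores 3/10; the textbook Jaccard
(endpoints included, 3/12 on the same graph) is available with
``exclude_endpoints=False``.

Directed graphs are measured on their underlying undirected graph —
neighborhood overlap has no standard directed analogue here.

Degree assortativity is Newman's Pearson correlation of degrees across
edge endpoints.  The power-law fit is a discrete maximum-likelihood
estimate with the lower cutoff ``xmin`` chosen by a Kolmogorov–Smirnov
goodness-of-fit scan (Clauset–Shalizi–Newman recipe), reused here both
as the degree-distribution exponent α and as the attractiveness offset
``a`` when parameterizing growth models from a real network.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special

from .graphs import as_undirected

logger = logging.getLogger("ganet")

__all__ = [
    "UndefinedMeasureError",
    "PowerLawFitError",
    "PowerLawFit",
    "NetworkParams",
    "common_neighbors",
    "jaccard_index",
    "co_neighborness",
    "edge_density",
    "degree_assortativity",
    "fit_power_law",
    "estimate_params",
]


class UndefinedMeasureError(ValueError):
    """A measure is undefined on this graph (e.g. cn of an edgeless graph)."""


class PowerLawFitError(RuntimeError):
    """The degree sequence does not admit a power-law fit."""


def _neighbor_sets(g: nx.Graph, u, v):
    g = as_undirected(g)
    for w in (u, v):
        if w not in g:
            raise KeyError(f"node {w!r} not in graph")
    if u == v:
        raise ValueError("u and v must be distinct")
    return set(g[u]), set(g[v])


def common_neighbors(g: nx.Graph, u, v) -> int:
    """Number of nodes adjacent to both ``u`` and ``v``."""
    gu, gv = _neighbor_sets(g, u, v)
    return len(gu & gv)


def jaccard_index(g: nx.Graph, u, v, exclude_endpoints: bool = True) -> float:
    """Neighborhood Jaccard similarity of ``u`` and ``v`` in [0, 1].

    With ``exclude_endpoints`` (default) the endpoints themselves are
    removed from the union, so two adjacent nodes are not penalized for
    being each other's neighbors.  An empty union scores 0.
    """
    gu, gv = _neighbor_sets(g, u, v)
    union = gu | gv
    if exclude_endpoints:
        union -= {u, v}
    if not union:
        return 0.0
    return len(gu & gv) / len(union)


def co_neighborness(g: nx.Graph, exclude_endpoints: bool = True) -> float:
    """Mean edge-wise Jaccard index over all edges of ``g``.

    Each unordered adjacent pair counts once (directed input is
    collapsed to its underlying undirected graph first).
    """
    h = as_undirected(g)
    if h.number_of_edges() == 0:
        raise UndefinedMeasureError("co-neighborness needs at least one edge")
    adj = {v: set(h[v]) for v in h}
    total = 0.0
    for u, v in h.edges:
        gu, gv = adj[u], adj[v]
        union = len(gu | gv) - (2 if exclude_endpoints else 0)
        if union > 0:
            total += len(gu & gv) / union
    return total / h.number_of_edges()


def edge_density(g: nx.Graph) -> float:
    """|E| over the number of possible node pairs (ordered if directed)."""
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedMeasureError("edge density needs at least two nodes")
    return nx.density(g)


def degree_assortativity(g: nx.Graph) -> float:
    """Newman degree assortativity r in [-1, 1].

    Directed input is measured on the underlying undirected graph; each
    undirected edge contributes both orientations.  Returns NaN (with a
    warning) when the endpoint degrees have zero variance, e.g. on a
    cycle, where the correlation is undefined.
    """
    h = as_undirected(g)
    if h.number_of_edges() < 2:
        raise UndefinedMeasureError("assortativity needs at least two edges")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(h)
    if not math.isfinite(r):
        logger.warning("degree assortativity undefined (zero degree variance)")
        return float("nan")
    return float(r)


# ---------------------------------------------------------------------------
# Discrete power-law fit (Clauset-style MLE with KS-selected xmin)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law fit P(X = x) ∝ x^-exponent for x ≥ xmin.

    ``heavy_tail_plausible`` compares the power-law likelihood against a
    geometric (exponentially decaying) fit of the same tail: False flags
    a degree sequence whose tail decays too fast for a power law.
    """

    exponent: float
    xmin: int
    log_likelihood: float
    ks_distance: float
    n_tail: int
    heavy_tail_plausible: bool

    def __post_init__(self):
        if not self.exponent > 1:
            raise PowerLawFitError(f"exponent must exceed 1, got {self.exponent}")
        if self.xmin < 1:
            raise PowerLawFitError(f"xmin must be >= 1, got {self.xmin}")


def _pl_negloglik(alpha: float, x: np.ndarray, xmin: int) -> float:
    return len(x) * math.log(special.zeta(alpha, xmin)) + alpha * np.log(x).sum()


def _fit_tail(x: np.ndarray, xmin: int):
    """MLE exponent and KS distance for the tail x >= xmin."""
    res = optimize.minimize_scalar(
        _pl_negloglik, bounds=(1.0001, 12.0), args=(x, xmin), method="bounded"
    )
    alpha = float(res.x)
    xs = np.arange(xmin, x.max() + 1)
    pmf = xs ** (-alpha) / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(x), xs, side="right") / len(x)
    ks = float(np.abs(emp - cdf).max())
    return alpha, -float(res.fun), ks


def _geometric_loglik(x: np.ndarray, xmin: int) -> float:
    # geometric on {xmin, xmin+1, ...}: MLE success prob from the tail mean
    shifted = x - xmin
    p = 1.0 / (shifted.mean() + 1.0)
    return float(len(x) * math.log(p) + shifted.sum() * math.log1p(-p))


def fit_power_law(degrees, xmin: int | None = None, min_tail: int = 10) -> PowerLawFit:
    """Fit a discrete power law to a degree sequence.

    Zero degrees are ignored.  When ``xmin`` is not given, every unique
    degree leaving at least ``min_tail`` tail observations is tried and
    the one minimizing the KS distance between the empirical and fitted
    tail distributions is kept.

    Raises ``ValueError`` on fewer than 10 positive degrees and
    :class:`PowerLawFitError` on a constant sequence.
    """
    x = np.asarray(list(degrees), dtype=float)
    x = x[x > 0]
    if len(x) < 10:
        raise ValueError(f"need at least 10 positive degrees, got {len(x)}")
    if np.all(x == x[0]):
        raise PowerLawFitError("all degrees equal; no distribution to fit")
    x = x.astype(np.int64)

    candidates = [int(xmin)] if xmin is not None else [
        int(c) for c in np.unique(x)[:-1]
        if (x >= c).sum() >= min_tail
    ]
    if not candidates:
        raise PowerLawFitError("no viable xmin candidate leaves enough tail")

    best = None
    for c in candidates:
        tail = x[x >= c]
        alpha, loglik, ks = _fit_tail(tail, c)
        if best is None or ks < best[3]:
            best = (c, alpha, loglik, ks, len(tail))
    c, alpha, loglik, ks, n_tail = best
    tail = x[x >= c]
    plausible = loglik > _geometric_loglik(tail, c)
    if not plausible:
        logger.warning(
            "power-law fit (alpha=%.2f, xmin=%d) is outperformed by a "
            "geometric tail; exponent estimate is unreliable", alpha, c,
        )
    return PowerLawFit(
        exponent=alpha, xmin=c, log_likelihood=loglik,
        ks_distance=ks, n_tail=n_tail, heavy_tail_plausible=plausible,
    )


# ---------------------------------------------------------------------------
# Parameter estimation from a real network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkParams:
    """Generator inputs measured from a network.

    ``alpha`` is the fitted power-law exponent of the degree
    distribution and ``attractiveness`` the fitted lower cutoff, reused
    as the initial-attractiveness offset of preferential generators.
    """

    n_nodes: int
    n_edges: int
    density: float
    alpha: float
    attractiveness: int

    @property
    def mean_degree_per_step(self) -> int:
        """round(|E|/|N|): edges per added node for growth/lattice models."""
        return max(1, round(self.n_edges / self.n_nodes))


def estimate_params(g: nx.Graph) -> NetworkParams:
    """Measure |N|, |E|, density p, power-law exponent α and cutoff a."""
    if g.number_of_nodes() < 10:
        raise ValueError("parameter estimation needs at least 10 nodes")
    try:
        fit = fit_power_law([d for _, d in as_undirected(g).degree()])
        alpha, xmin = fit.exponent, fit.xmin
    except PowerLawFitError as exc:
        logger.warning("degree distribution admits no power-law fit (%s); "
                       "reporting alpha=NaN", exc)
        alpha, xmin = float("nan"), 1
    return NetworkParams(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        density=edge_density(g),
        alpha=alpha,
        attractiveness=xmin,
    )
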