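"""Pairwise association inference and co-occurrence network topology.

Networks are built by thresholding pairwise Spearman (or Pearson)
correlations between taxa on normalized abundances: an edge requires both a
strong coefficient (|rho| above a threshold, default 0.6) and a
Benjamini-Hochberg q-value below a significance cutoff (default 0.05).
Only taxa incident to at least one retained edge become network members.

The topology suite computes the ten per-network summary metrics used to
compare condition-specific networks: Freeman degree centralization,
connected-component count, connectance, edge count, giant component size,
Kleinberg hub count, the Kolmogorov-Smirnov distance of the degree
distribution to a fitted discrete power law, mean degree, Walktrap/
Newman-Girvan modularity, and node count. Edge signs are stored on the
network but ignored by every topology metric: topology is computed on the
combined signed graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountTable, Network, TableError
from .diversity import NormalizedTable

logger = logging.getLogger(__name__)

TOPOLOGY_COLUMNS = (
    "centralization_degree",
    "cluster_count",
    "connectance",
    "edge_count",
    "giant_component_size",
    "hub_count",
    "ks_stat",
    "mean_degree",
    "modularity",
    "node_count",
)


# ---------------------------------------------------------------------------
# Association inference
# ---------------------------------------------------------------------------


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 (per row/taxon across samples)."""
    return stats.rankdata(x, axis=1)


def pairwise_associations(
    nt: NormalizedTable | CountTable, method: str = "spearman"
) -> pd.DataFrame:
    """All-pairs correlation between taxa.

    Spearman transforms each taxon's abundances to average ranks and then
    computes the product-moment correlation; Pearson correlates values
    directly. Two-sided p-values use the t approximation with n - 2 degrees
    of freedom; q-values are Benjamini-Hochberg over all tested pairs of
    this run. Zero-variance taxa are excluded from testing (logged).
    """
    if method not in ("spearman", "pearson"):
        raise TableError(f"unknown association method {method!r}")
    values = nt.values if isinstance(nt, NormalizedTable) else nt.counts.astype(float)
    taxa = list(nt.taxon_ids)
    n = values.shape[1]
    if n < 4:
        raise TableError("association inference requires at least 4 samples")
    if len(taxa) < 2:
        raise TableError("association inference requires at least 2 taxa")

    variances = values.var(axis=1)
    keep = variances > 0
    if not keep.all():
        logger.warning(
            "excluding %d zero-variance taxa from association testing",
            int((~keep).sum()),
        )
    idx = np.flatnonzero(keep)
    data = values[idx]
    if method == "spearman":
        data = _rank_columns(data)
    corr = np.corrcoef(data)
    corr = np.clip(corr, -1.0, 1.0)

    iu, ju = np.triu_indices(len(idx), k=1)
    r = corr[iu, ju]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    q = bh_fdr(p)

    ti = [taxa[idx[i]] for i in iu]
    tj = [taxa[idx[j]] for j in ju]
    return pd.DataFrame(
        {
            "taxon_i": ti,
            "taxon_j": tj,
            "method": method,
            "coefficient": r,
            "p": p,
            "q": q,
            "sign": np.where(r >= 0, 1, -1),
        }
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise TableError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_network(
    assocs: pd.DataFrame,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.05,
) -> Network:
    """Threshold associations into a co-occurrence network.

    Edges are pairs with |coefficient| > rho_threshold and q < q_threshold;
    nodes are the endpoints of retained edges only.
    """
    kept = assocs[
        (assocs["coefficient"].abs() > rho_threshold) & (assocs["q"] < q_threshold)
    ]
    return Network.from_edges(
        (r.taxon_i, r.taxon_j, r.coefficient, r.p, r.q) for r in kept.itertuples()
    )


# ---------------------------------------------------------------------------
# Topology metrics
# ---------------------------------------------------------------------------


@dataclass
class TopologySummary:
    """The ten per-network topology metrics."""

    centralization_degree: float
    cluster_count: int
    connectance: float
    edge_count: int
    giant_component_size: int
    hub_count: int
    ks_stat: float
    mean_degree: float
    modularity: float
    node_count: int

    def to_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in TOPOLOGY_COLUMNS})


def centralization_degree(net: Network) -> float:
    """Freeman degree centralization: sum(d_max - d_i) / ((N-1)(N-2)).

    Zero for any regular graph, one for a star. By convention 0 for fewer
    than three nodes (logged).
    """
    n = net.node_count
    if n < 3:
        logger.warning("centralization undefined for %d node(s); returning 0", n)
        return 0.0
    degrees = np.array([d for _, d in net.graph.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def walktrap_communities(net: Network, walk_steps: int = 4) -> dict[str, int]:
    """Walktrap community assignment, per connected component.

    Runs the Pons-Latapy random-walk agglomeration on each connected
    component and cuts each merge tree at its maximum-modularity level, so
    nodes in different components never share a community.
    """
    partition: dict[str, int] = {}
    next_label = 0
    for comp in sorted(nx.connected_components(net.graph), key=lambda c: sorted(c)[0]):
        nodes = sorted(comp)
        if len(nodes) == 1:
            partition[nodes[0]] = next_label
            next_label += 1
            continue
        sub = net.graph.subgraph(nodes)
        g = ig.Graph()
        g.add_vertices(nodes)
        g.add_edges([(u, v) for u, v in sub.edges()])
        clustering = g.community_walktrap(steps=walk_steps).as_clustering()
        for cluster in clustering:
            for vid in cluster:
                partition[g.vs[vid]["name"]] = next_label
            next_label += 1
    return partition


def modularity(net: Network, partition: dict[str, int]) -> float:
    """Newman-Girvan modularity of a node partition.

    Q = sum_c [m_c/m - (D_c/2m)^2] with m total edges, m_c intra-community
    edges, and D_c the total degree of community c. NaN for an edgeless
    graph.
    """
    m = net.edge_count
    if m == 0:
        return float("nan")
    missing = [v for v in net.graph.nodes if v not in partition]
    if missing:
        raise TableError(f"partition does not cover nodes: {missing[:5]}")
    intra: dict[int, int] = {}
    degree_tot: dict[int, int] = {}
    for u, v in net.graph.edges:
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0) + 1
    for node, d in net.graph.degree():
        c = partition[node]
        degree_tot[c] = degree_tot.get(c, 0) + d
    q = 0.0
    for c, d_c in degree_tot.items():
        q += intra.get(c, 0) / m - (d_c / (2 * m)) ** 2
    return q


def hub_scores(
    net: Network, tol: float = 1e-10, max_iter: int = 1_000_000
) -> dict[str, float]:
    """Kleinberg HITS hub scores on the undirected graph.

    For a symmetric adjacency matrix the hub vector (the dominant
    eigenvector of A A^T) coincides with the dominant eigenvector of A.
    It is computed by power iteration on the shifted matrix A + I (same
    eigenvectors; the shift prevents oscillation on bipartite components)
    from the uniform vector, with sup-norm scaling each step so the
    maximum score is 1. On a disconnected graph whose components share the
    spectral radius the uniform start converges to the symmetric limit,
    e.g. every node of two disjoint triangles scores 1.
    """
    nodes = sorted(net.graph.nodes)
    if net.edge_count == 0:
        return {}
    a = nx.to_numpy_array(net.graph, nodelist=nodes, weight=None)
    a += np.eye(len(nodes))
    x = np.ones(len(nodes))
    for _ in range(max_iter):
        y = a @ x
        y /= y.max()
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    return dict(zip(nodes, x))


def hub_count(scores: dict[str, float], threshold: float = 0.2) -> int:
    """Number of nodes with hub score strictly greater than the threshold."""
    return sum(1 for s in scores.values() if s > threshold)


@dataclass
class PowerLawFit:
    """Discrete power-law fit of a degree sequence."""

    alpha: float
    xmin: int
    ks_stat: float
    defined: bool


def _powerlaw_cdf_tail(alpha: float, xmin: int, xs: np.ndarray) -> np.ndarray:
    """CDF of the zeta distribution truncated at xmin, evaluated at xs."""
    z = special.zeta(alpha, xmin)
    return 1.0 - special.zeta(alpha, xs + 1.0) / z


def power_law_fit(degrees) -> PowerLawFit:
    """Clauset-style discrete power-law MLE with KS-optimal xmin.

    For each candidate xmin, the exponent maximizes the zeta likelihood on
    degrees >= xmin; the chosen xmin minimizes the KS distance between the
    empirical and fitted tail CDFs. Undefined (``defined=False``) when the
    input has fewer than two distinct degree values, as for regular graphs.
    """
    degrees = np.asarray([d for d in degrees if d > 0], dtype=int)
    if degrees.size == 0 or np.unique(degrees).size < 2:
        return PowerLawFit(float("nan"), 0, float("nan"), False)
    candidates = np.unique(degrees)[:-1]  # need >= 2 distinct values in tail
    best: PowerLawFit | None = None
    for xmin in candidates:
        tail = degrees[degrees >= xmin]
        if np.unique(tail).size < 2:
            continue

        def neg_loglik(alpha: float) -> float:
            return float(
                tail.size * math.log(special.zeta(alpha, xmin))
                + alpha * np.log(tail).sum()
            )

        res = _minimize_alpha(neg_loglik)
        ks = _ks_distance(tail, res, int(xmin))
        if best is None or ks < best.ks_stat:
            best = PowerLawFit(res, int(xmin), ks, True)
    assert best is not None
    return best


def _minimize_alpha(neg_loglik) -> float:
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_loglik, bounds=(1.000001, 12.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, tail.max() + 1)
    fitted = _powerlaw_cdf_tail(alpha, xmin, xs.astype(float))
    ecdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    return float(np.abs(ecdf - fitted).max())


def summarize_topology(
    net: Network, hub_threshold: float = 0.2, walk_steps: int = 4
) -> TopologySummary:
    """Compute the full ten-metric topology summary of a network."""
    n = net.node_count
    e = net.edge_count
    components = list(nx.connected_components(net.graph))
    giant = max((len(c) for c in components), default=0)
    connectance = 2 * e / (n * (n - 1)) if n >= 2 else float("nan")
    mean_degree = 2 * e / n if n > 0 else float("nan")
    partition = walktrap_communities(net, walk_steps)
    fit = power_law_fit([d for _, d in net.graph.degree()])
    return TopologySummary(
        centralization_degree=centralization_degree(net),
        cluster_count=len(components),
        connectance=connectance,
        edge_count=e,
        giant_component_size=giant,
        hub_count=hub_count(hub_scores(net), hub_threshold),
        ks_stat=fit.ks_stat if fit.defined else float("nan"),
        mean_degree=mean_degree,
        modularity=modularity(net, partition),
        node_count=n,
    )


# ---------------------------------------------------------------------------
# Cross-method ranking comparison
# ---------------------------------------------------------------------------


def friedman_rank_test(values: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman rank sum test across methods (columns) over conditions (rows).

    Ranks within each condition use average ranks for ties, with the
    standard tie-corrected chi-square statistic on k - 1 degrees of
    freedom. Completely tied data yield statistic 0 and p = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise TableError("friedman test needs >= 2 conditions and >= 2 methods")
    if np.isnan(x).any():
        raise TableError("friedman test does not accept missing cells")
    n, k = x.shape
    ranks = stats.rankdata(x, axis=1)
    col_sums = ranks.sum(axis=0)
    mean_rank_sum = n * (k + 1) / 2
    numerator = (k - 1) * ((col_sums - mean_rank_sum) ** 2).sum()
    denominator = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4
    if denominator == 0:
        return 0.0, 1.0
    statistic = numerator / denominator
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p
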