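"""Phenotype-taxon networks and composite-centrality prioritization.

A phenotype-taxon network couples one continuous phenotype (an edaphic or
agronomic measure) to a microbial co-occurrence network. Taxa predictive of
the phenotype are selected by cross-validated lasso regression; an ordinary
least-squares refit (a Gaussian identity-link GLM) then supplies the sign
and a p-value for each retained phenotype-taxon edge; finally the signed
edges are overlaid on the supplied taxon-taxon co-occurrence network.

Nodes are prioritized with three per-node metrics: the within-module degree
z-score and the participation coefficient (the Guimera-Amaral modularity
roles, computed on the taxon-taxon subgraph with communities from
Walktrap), and the Kleinberg hub score. Each metric is min-max normalized
across the network's nodes and averaged with equal weights into a composite
centrality in [0, 1]. Taxa are then ranked by mean composite score over the
phenotype networks in which they appear, after a prevalence filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .io import Network, TableError
from .diversity import NormalizedTable
from .network import pairwise_associations, walktrap_communities, hub_scores

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Lasso selection and GLM directionality
# ---------------------------------------------------------------------------


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Select phenotype-predictive taxa by cross-validated lasso.

    ``X`` holds per-sample taxon abundances (samples x taxa); predictors
    are standardized internally. The L1 penalty is chosen at the minimum
    cross-validated mean squared error with seed-controlled fold
    assignment. Returns the nonzero-coefficient taxa with their lasso
    coefficients (on the standardized scale).
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 8:
        raise TableError("lasso selection requires at least 8 samples")
    if np.std(y) == 0:
        logger.warning("constant response; lasso selects no taxa")
        return pd.DataFrame(columns=["taxon_id", "coefficient"])
    sd = X.std(axis=0, ddof=0).replace(0, 1.0)
    Xs = (X - X.mean(axis=0)) / sd
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=50_000)
    model.fit(Xs.to_numpy(), y)
    coefs = model.coef_
    nz = np.flatnonzero(coefs != 0)
    return pd.DataFrame(
        {"taxon_id": [X.columns[i] for i in nz], "coefficient": coefs[nz]}
    )


def fit_glm(
    X_selected: pd.DataFrame,
    y: np.ndarray,
    lasso_coefficients: pd.Series | None = None,
) -> pd.DataFrame:
    """OLS refit (Gaussian identity-link GLM) over the selected taxa.

    Returns per-taxon coefficient, sign, and two-sided t-test p-value.
    Collinear columns are dropped; if the sample count cannot support the
    selection, the weakest lasso coefficients are truncated first (logged).
    """
    y = np.asarray(y, dtype=float)
    cols = list(X_selected.columns)
    if not cols:
        raise TableError("fit_glm requires a non-empty selection")
    n = len(X_selected)
    if n <= len(cols) + 1:
        if lasso_coefficients is None:
            raise TableError(f"{n} samples cannot support {len(cols)} predictors")
        order = lasso_coefficients.abs().sort_values(ascending=False).index
        cols = [c for c in order if c in cols][: max(1, n - 2)]
        logger.warning("selection truncated to %d strongest lasso taxa", len(cols))
    X = X_selected[cols].to_numpy(dtype=float)
    # drop collinear columns left-to-right
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), trial])) == len(keep) + 2:
            keep.append(j)
        else:
            logger.warning("dropping collinear predictor %r", cols[j])
    cols = [cols[j] for j in keep]
    X = X[:, keep]

    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    df = n - design.shape[1]
    if df <= 0:
        raise TableError("no residual degrees of freedom for the GLM refit")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)
    return pd.DataFrame(
        {
            "taxon_id": cols,
            "coefficient": beta[1:],
            "sign": np.where(beta[1:] >= 0, 1, -1),
            "p": pvals[1:],
        }
    )


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTaxonNetwork:
    """Taxon co-occurrence graph plus one phenotype node with signed edges."""

    graph: nx.Graph
    phenotype_name: str

    @property
    def taxa(self) -> list[str]:
        return sorted(
            v for v, d in self.graph.nodes(data=True) if d.get("kind") == "taxon"
        )

    def taxon_subgraph(self) -> Network:
        return Network(self.graph.subgraph(self.taxa).copy())


def assemble_phona(
    cooc: Network,
    glm_edges: pd.DataFrame,
    phenotype_name: str,
    prevalence: pd.Series | None = None,
) -> PhenotypeTaxonNetwork:
    """Overlay GLM-signed phenotype edges on a co-occurrence network.

    Nodes are the co-occurrence network's taxa, plus any selected taxa
    absent from it, plus one phenotype node. Taxon-taxon edges are copied
    verbatim from the co-occurrence network; no new taxon-taxon edge is
    ever introduced. An empty selection yields an isolated phenotype node.
    """
    g = nx.Graph()
    for v in cooc.graph.nodes:
        g.add_node(v, kind="taxon")
    g.add_edges_from(cooc.graph.edges(data=True))
    for r in glm_edges.itertuples():
        g.add_node(r.taxon_id, kind="taxon")
    if phenotype_name in g.nodes:
        raise TableError(f"phenotype name {phenotype_name!r} collides with a taxon")
    g.add_node(phenotype_name, kind="phenotype")
    for r in glm_edges.itertuples():
        g.add_edge(
            phenotype_name,
            r.taxon_id,
            coefficient=float(r.coefficient),
            p=float(r.p),
            sign=int(r.sign),
            kind="phenotype",
        )
    if prevalence is not None:
        for v, d in g.nodes(data=True):
            if d["kind"] == "taxon" and v in prevalence.index:
                g.nodes[v]["prevalence"] = float(prevalence[v])
    return PhenotypeTaxonNetwork(g, phenotype_name)


# ---------------------------------------------------------------------------
# Modularity roles and composite centrality
# ---------------------------------------------------------------------------


def within_module_z(net: Network, partition: dict[str, int]) -> dict[str, float]:
    """Within-module degree z-score (Guimera-Amaral connectivity).

    z_i standardizes node i's within-module degree against its module's
    mean and population standard deviation; modules with zero spread (and
    singletons) yield z = 0.
    """
    _check_partition(net, partition)
    kappa = {
        v: sum(1 for u in net.graph.neighbors(v) if partition[u] == partition[v])
        for v in net.graph.nodes
    }
    z: dict[str, float] = {}
    modules: dict[int, list[str]] = {}
    for v, c in partition.items():
        modules.setdefault(c, []).append(v)
    for members in modules.values():
        vals = np.array([kappa[v] for v in members], dtype=float)
        sd = vals.std()  # population sd
        mean = vals.mean()
        for v in members:
            z[v] = float((kappa[v] - mean) / sd) if sd > 0 else 0.0
    return z


def participation_coefficient(net: Network, partition: dict[str, int]) -> dict[str, float]:
    """P_i = 1 - sum_s (kappa_is / k_i)^2 over modules s; 0 for isolated nodes."""
    _check_partition(net, partition)
    out: dict[str, float] = {}
    for v in net.graph.nodes:
        k = net.graph.degree(v)
        if k == 0:
            out[v] = 0.0
            continue
        per_module: dict[int, int] = {}
        for u in net.graph.neighbors(v):
            c = partition[u]
            per_module[c] = per_module.get(c, 0) + 1
        out[v] = float(1.0 - sum((m / k) ** 2 for m in per_module.values()))
    return out


def _check_partition(net: Network, partition: dict[str, int]) -> None:
    missing = [v for v in net.graph.nodes if v not in partition]
    if missing:
        raise TableError(f"partition does not cover nodes: {missing[:5]}")


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def composite_score(
    z: dict[str, float], p: dict[str, float], hub: dict[str, float]
) -> pd.DataFrame:
    """Equal-weight composite of min-max normalized (z, P, hub) per node.

    A metric constant across all nodes normalizes to 0.5 everywhere so an
    uninformative metric pulls no node toward either extreme.
    """
    nodes = sorted(z)
    if set(p) != set(nodes) or set(hub) != set(nodes):
        raise TableError("z, P, and hub must cover the same node set")
    zv = np.array([z[v] for v in nodes])
    pv = np.array([p[v] for v in nodes])
    hv = np.array([hub[v] for v in nodes])
    zn, pn, hn = _minmax(zv), _minmax(pv), _minmax(hv)
    return pd.DataFrame(
        {
            "node": nodes,
            "within_module_z": zv,
            "participation": pv,
            "hub": hv,
            "z_norm": zn,
            "participation_norm": pn,
            "hub_norm": hn,
            "composite": (zn + pn + hn) / 3.0,
        }
    ).set_index("node")


def score_network(pt: PhenotypeTaxonNetwork, walk_steps: int = 4) -> pd.DataFrame:
    """Composite centrality for every taxon node of a phenotype network.

    Modularity roles (z, P) come from Walktrap communities of the
    taxon-taxon subgraph; the phenotype node is excluded throughout, since
    the roles describe microbial structure.
    """
    sub = pt.taxon_subgraph()
    if sub.node_count == 0:
        return pd.DataFrame(
            columns=[
                "within_module_z", "participation", "hub",
                "z_norm", "participation_norm", "hub_norm", "composite",
            ]
        )
    partition = walktrap_communities(sub, walk_steps)
    z = within_module_z(sub, partition)
    p = participation_coefficient(sub, partition)
    hub = hub_scores(sub)
    for v in sub.graph.nodes:  # isolated taxa get hub score 0
        hub.setdefault(v, 0.0)
    return composite_score(z, p, hub)


# ---------------------------------------------------------------------------
# Prioritization
# ---------------------------------------------------------------------------


def prioritize(
    scores_by_network: dict[str, pd.DataFrame],
    prevalence: pd.Series,
    min_prevalence: float = 0.2,
    top_k: int = 20,
) -> pd.DataFrame:
    """Rank taxa by mean composite centrality across phenotype networks.

    Taxa below the prevalence filter are dropped. The default mean averages
    over the networks in which a taxon appears (appearance count reported);
    a zero-filled mean over all networks is reported alongside. Ties break
    by descending prevalence then identifier.
    """
    if not scores_by_network:
        raise TableError("prioritize requires at least one scored network")
    n_networks = len(scores_by_network)
    per_taxon: dict[str, list[float]] = {}
    for scores in scores_by_network.values():
        for taxon, row in scores.iterrows():
            per_taxon.setdefault(taxon, []).append(float(row["composite"]))
    rows = []
    for taxon, values in per_taxon.items():
        prev = float(prevalence.get(taxon, 0.0))
        if prev < min_prevalence:
            continue
        rows.append(
            {
                "taxon_id": taxon,
                "mean_composite": float(np.mean(values)),
                "mean_composite_zero_filled": float(np.sum(values) / n_networks),
                "n_networks": len(values),
                "prevalence": prev,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "taxon_id", "mean_composite", "mean_composite_zero_filled",
            "n_networks", "prevalence",
        ],
    )
    report = report.sort_values(
        by=["mean_composite", "prevalence", "taxon_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    if len(report) < top_k:
        logger.warning("only %d taxa survive the prevalence filter", len(report))
    return report.head(top_k)


def node_phenotype_associations(
    nt: NormalizedTable,
    taxa: list[str],
    phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman associations among top taxa and between taxa and phenotypes.

    ``phenotypes`` is a wide table (sample_id + one column per phenotype)
    aligned to the normalized table's samples. Constant phenotypes are
    excluded from testing (logged by the association machinery). Adds a
    ``pair_type`` column: taxon-taxon, taxon-phenotype, or
    phenotype-phenotype.
    """
    idx = [nt.taxon_ids.index(t) for t in taxa]
    ph = phenotypes.set_index("sample_id").loc[nt.sample_ids]
    names = list(taxa) + list(ph.columns)
    values = np.vstack([nt.values[idx], ph.to_numpy(dtype=float).T])
    combined = NormalizedTable(names, list(nt.sample_ids), values,
                               np.ones(len(nt.sample_ids)), "mixed")
    assoc = pairwise_associations(combined, method="spearman")
    phen = set(ph.columns)

    def pair_type(r):
        k = (r.taxon_i in phen) + (r.taxon_j in phen)
        return ("taxon-taxon", "taxon-phenotype", "phenotype-phenotype")[k]

    assoc["pair_type"] = [pair_type(r) for r in assoc.itertuples()]
    return assoc
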