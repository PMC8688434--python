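"""Node-level topological features and the power-law scale-freeness check.

Thirteen per-gene attributes are computed on the undirected network: degree,
average nearest neighbor degree (K_nn), PageRank, eccentricity, eigenvector
centrality, betweenness, closeness, strength, hub score, coreness, subgraph
centrality, Burt's constraint, and the local clustering coefficient
(transitivity).  K_nn of node *i* is the mean degree of its neighbors,

    K_nn(i) = (1/k(i)) * sum_{j in N(i)} k(j),

the statistic this package is organized around.  Undefined values (isolated
nodes, degree < 2 clustering, ...) are recorded as missing (NaN), never as
infinities.

Scale-freeness is checked by ordinary least squares on the log-log degree
distribution, P_deg(k) ∝ k^(−γ), reporting the exponent γ and R².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .grn_io import GeneNetwork

logger = logging.getLogger(__name__)

#: Canonical feature column order of the output table.
FEATURE_COLUMNS = [
    "degree",
    "knn",
    "page_rank",
    "eccentricity",
    "eigenvector_centrality",
    "betweenness",
    "closeness",
    "strength",
    "hub_score",
    "coreness",
    "subgraph_centrality",
    "burt_constraint",
    "transitivity_local",
]


class DegenerateDegreeDistributionError(ValueError):
    """Raised when fewer than 3 distinct non-zero degree classes exist."""


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power-law fit of a degree distribution.

    ``gamma`` is the (positive) exponent of P_deg(k) ∝ k^(−γ); ``r_squared``
    the coefficient of determination of the log-log regression;
    ``fit_points`` the (log k, log P) pairs the line was fitted through.
    """

    gamma: float
    r_squared: float
    n_degree_classes: int
    fit_points: tuple[tuple[float, float], ...]


def average_neighbor_degree(graph: nx.Graph) -> dict[str, float]:
    """K_nn per node, straight from the definition; NaN for isolated nodes."""
    deg = dict(graph.degree())
    knn: dict[str, float] = {}
    for node in graph.nodes:
        k = deg[node]
        if k == 0:
            knn[node] = math.nan
        else:
            knn[node] = sum(deg[j] for j in graph.neighbors(node)) / k
    return knn


def burt_constraint(graph: nx.Graph) -> dict[str, float]:
    """Burt's structural-constraint index, vectorized for unweighted graphs.

    With proportional tie strengths p_ij = A_ij / k_i, the constraint of i is
    sum over its neighbors j of (p_ij + sum_q p_iq p_qj)^2.  NaN for isolated
    nodes.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    p = sp.diags(inv) @ adj  # row-normalized ties
    m = p + p @ p
    masked = m.multiply(adj > 0)  # only j in N(i) contribute
    constraint = np.asarray(masked.multiply(masked).sum(axis=1)).ravel()
    constraint[deg == 0] = np.nan
    return dict(zip(nodes, constraint))


def _per_component(graph: nx.Graph, fn) -> dict:
    out: dict = {}
    for comp in nx.connected_components(graph):
        out.update(fn(graph.subgraph(comp)))
    return out


def compute_node_features(
    network: GeneNetwork, *, pagerank_damping: float = 0.85
) -> pd.DataFrame:
    """Compute the 13-attribute feature table, one row per gene.

    Eccentricity and closeness are computed within each connected component;
    betweenness is unnormalized; hub scores are scaled so the largest is 1.
    Returns a DataFrame indexed by ``gene_id`` with :data:`FEATURE_COLUMNS`
    plus a ``role`` column.
    """
    graph = network.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute features of an empty network")
    if not nx.is_connected(graph):
        logger.info(
            "network %s is disconnected (%d components); eccentricity/closeness "
            "computed per component",
            network.name,
            nx.number_connected_components(graph),
        )

    deg = dict(graph.degree())
    n = graph.number_of_nodes()

    def _eigenvector(sub: nx.Graph) -> dict:
        if sub.number_of_edges() == 0:
            return {v: 0.0 for v in sub.nodes}
        if sub.number_of_nodes() == 2:  # single edge: uniform unit vector
            return {v: 1.0 / math.sqrt(2) for v in sub.nodes}
        return {v: abs(float(x)) for v, x in nx.eigenvector_centrality_numpy(sub).items()}

    eigen = _per_component(graph, _eigenvector)
    max_eig = max(eigen.values()) if eigen else 0.0
    hub = {v: (e / max_eig if max_eig > 0 else 0.0) for v, e in eigen.items()}

    clustering = nx.clustering(graph)

    table = {
        "degree": deg,
        "knn": average_neighbor_degree(graph),
        "page_rank": nx.pagerank(graph, alpha=pagerank_damping),
        "eccentricity": _per_component(graph, nx.eccentricity),
        "eigenvector_centrality": eigen,
        "betweenness": nx.betweenness_centrality(graph, normalized=False),
        "closeness": nx.closeness_centrality(graph, wf_improved=False),
        "strength": {v: float(k) for v, k in deg.items()},
        "hub_score": hub,
        "coreness": nx.core_number(graph),
        "subgraph_centrality": nx.subgraph_centrality(graph) if n > 1 else {v: 1.0 for v in graph.nodes},
        "burt_constraint": burt_constraint(graph),
        "transitivity_local": {
            v: (c if deg[v] >= 2 else math.nan) for v, c in clustering.items()
        },
    }

    df = pd.DataFrame(table, columns=FEATURE_COLUMNS).astype(float)
    # isolated nodes have no distances
    df.loc[df["degree"] == 0, "closeness"] = np.nan
    df["role"] = pd.Series(network.roles)
    df.index.name = "gene_id"
    df = df.sort_index()
    # replace any stray infinities by missing, per the learning contract
    df[FEATURE_COLUMNS] = df[FEATURE_COLUMNS].replace([np.inf, -np.inf], np.nan)
    return df


def write_feature_table(features: pd.DataFrame, path) -> None:
    """CSV export with missing values as empty fields."""
    features.to_csv(path, na_rep="")


def _degree_counts(source) -> dict[int, int]:
    if isinstance(source, GeneNetwork):
        degrees: Iterable[int] = [d for _, d in source.graph.degree()]
    elif isinstance(source, nx.Graph):
        degrees = [d for _, d in source.degree()]
    elif isinstance(source, Mapping):
        # counts may be fractional (e.g. an exact analytic histogram)
        return {int(k): float(c) for k, c in source.items() if int(k) > 0 and c > 0}
    else:
        degrees = list(source)
    counts: dict[int, int] = {}
    for d in degrees:
        if d > 0:
            counts[d] = counts.get(d, 0) + 1
    return counts


def fit_power_law(source) -> PowerLawFit:
    """OLS fit of log P_deg(k) against log k over non-empty degree classes.

    ``source`` may be a :class:`~grntopo.grn_io.GeneNetwork`, a bare
    ``networkx.Graph``, a ``{degree: count}`` mapping, or an iterable of node
    degrees.  Degree-zero nodes are ignored.  Raises
    :class:`DegenerateDegreeDistributionError` for fewer than 3 distinct
    non-zero degree classes.
    """
    counts = _degree_counts(source)
    if len(counts) < 3:
        raise DegenerateDegreeDistributionError(
            f"degenerate degree distribution: {len(counts)} non-zero degree "
            "class(es), need at least 3 to fit a power law"
        )
    total = sum(counts.values())
    ks = np.array(sorted(counts), dtype=float)
    prob = np.array([counts[int(k)] / total for k in ks])
    x = np.log(ks)
    y = np.log(prob)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(
        gamma=float(-slope),
        r_squared=float(r2),
        n_degree_classes=len(counts),
        fit_points=tuple(zip(x.tolist(), y.tolist())),
    )
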