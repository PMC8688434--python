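import math

import networkx as nx
import numpy as np
import pytest

from grntopo.grn_io import GeneNetwork, RegulatoryInteraction, build_network
from grntopo.synthetic_data import SyntheticGRNConfig, generate_synthetic_grn
from grntopo.topology import (
    DegenerateDegreeDistributionError,
    FEATURE_COLUMNS,
    average_neighbor_degree,
    burt_constraint,
    compute_node_features,
    fit_power_law,
)


def _wrap(graph: nx.Graph, name="g") -> GeneNetwork:
    roles = {n: "target" for n in graph.nodes}
    return GeneNetwork(graph=graph, roles=roles, name=name)


def brute_force_knn(graph: nx.Graph) -> dict:
    out = {}
    for i in graph.nodes:
        nbrs = list(graph.neighbors(i))
        if not nbrs:
            out[i] = math.nan
            continue
        total = 0
        for j in nbrs:
            total += sum(1 for _ in graph.neighbors(j))
        out[i] = total / len(nbrs)
    return out


def test_star_center_and_leaf_knn():
    feats = compute_node_features(_wrap(nx.star_graph(4)))
    assert feats.loc[0, "degree"] == 4 and feats.loc[0, "knn"] == 1.0
    assert all(feats.loc[i, "knn"] == 4.0 for i in range(1, 5))


def test_two_star_hub_knn(two_star):
    feats = compute_node_features(two_star)
    assert feats.loc["R1", "knn"] == pytest.approx(1.8)
    assert feats.loc["R2", "knn"] == pytest.approx(1.8)


def test_pagerank_sums_to_one_and_triangle_symmetry():
    feats = compute_node_features(_wrap(nx.complete_graph(3)))
    assert feats["page_rank"].sum() == pytest.approx(1.0, abs=1e-9)
    assert (feats["transitivity_local"] == 1.0).all()
    assert (feats["betweenness"] == 0.0).all()


def test_knn_matches_brute_force_on_random_graphs():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(2, 31))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.5)), seed=int(rng.integers(1 << 30)))
        ours = average_neighbor_degree(g)
        oracle = brute_force_knn(g)
        for node in g.nodes:
            if math.isnan(oracle[node]):
                assert math.isnan(ours[node])
            else:
                assert ours[node] == oracle[node]


def test_adding_degree_one_neighbor_updates_knn():
    g = nx.star_graph(4).copy()
    k = g.degree(0)
    s = sum(g.degree(j) for j in g.neighbors(0))
    g.add_edge(0, "new")
    ours = average_neighbor_degree(g)
    assert ours[0] == (s + 1) / (k + 1)


def test_burt_constraint_matches_networkx():
    rng = np.random.default_rng(7)
    for _ in range(10):
        g = nx.gnp_random_graph(int(rng.integers(4, 20)), 0.4, seed=int(rng.integers(1 << 30)))
        ours = burt_constraint(g)
        ref = nx.constraint(g)
        for node in g.nodes:
            if math.isnan(ours[node]):
                assert math.isnan(ref[node])
            else:
                assert ours[node] == pytest.approx(ref[node], abs=1e-9)


def test_centralities_match_igraph_oracle():
    """Spot-check degree/knn/coreness/eccentricity against python-igraph."""
    igraph = pytest.importorskip("igraph")
    g = nx.gnp_random_graph(25, 0.2, seed=5)
    if not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        g = nx.convert_node_labels_to_integers(g)
    ig = igraph.Graph(n=g.number_of_nodes(), edges=list(g.edges))
    feats = compute_node_features(_wrap(g))
    assert list(feats["degree"]) == ig.degree()
    assert list(feats["coreness"]) == ig.coreness()
    assert list(feats["eccentricity"]) == [float(e) for e in ig.eccentricity()]
    knn_ig = ig.knn()[0]
    assert np.allclose(list(feats["knn"]), knn_ig)


def test_isolated_node_features_are_missing_not_infinite():
    net = build_network(
        [RegulatoryInteraction("L", "L"), RegulatoryInteraction("A", "B")]
    )
    feats = compute_node_features(net)
    assert math.isnan(feats.loc["L", "knn"])
    assert math.isnan(feats.loc["L", "closeness"])
    assert np.isfinite(feats[FEATURE_COLUMNS].to_numpy(dtype=float)).sum() > 0
    assert not np.isinf(feats[FEATURE_COLUMNS].to_numpy(dtype=float)).any()


def test_feature_table_has_all_13_attributes(two_star):
    feats = compute_node_features(two_star)
    assert list(feats.columns) == FEATURE_COLUMNS + ["role"]
    assert len(FEATURE_COLUMNS) == 13


def test_regulators_are_hubs_on_synthetic_grns():
    net = generate_synthetic_grn(SyntheticGRNConfig(seed=0, n_growth_steps=800))
    deg = dict(net.graph.degree())
    regs = [deg[g] for g, r in net.roles.items() if r == "regulator"]
    tars = [deg[g] for g, r in net.roles.items() if r == "target"]
    assert np.mean(regs) > np.mean(tars)


def test_power_law_exact_recovery():
    counts = {k: 1_000_000 * k ** -2.5 for k in range(1, 51)}
    fit = fit_power_law(counts)
    assert fit.gamma == pytest.approx(2.5, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_power_law_degenerate_regular_graph():
    with pytest.raises(DegenerateDegreeDistributionError):
        fit_power_law(_wrap(nx.cycle_graph(10)))


def test_power_law_on_preferential_attachment():
    fit = fit_power_law(nx.barabasi_albert_graph(2000, 2, seed=0))
    assert fit.r_squared >= 0.8
    assert 1.5 <= fit.gamma <= 3.5
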