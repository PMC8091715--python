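import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecoassembly import OtuTable
from ecoassembly.network import (
    build_network,
    detect_modules,
    filter_for_network,
    graph_topology,
    natural_connectivity,
    node_topology,
    powerlaw_fit,
    random_ensemble,
    robustness_curve,
    zipi_classify,
)


def table_from(rows, samples=None, otus=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    otus = otus or [f"o{j}" for j in range(rows.shape[1])]
    return OtuTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestFilterForNetwork:
    def test_low_occupancy_removed(self):
        rng = np.random.default_rng(83)
        counts = rng.integers(1, 20, (12, 10))
        counts[5:, 0] = 0  # OTU o0 present in 5/12 samples -> 41.7% < 50%
        out = filter_for_network(table_from(counts), top_n=10)
        assert "o0" not in out.otu_ids

    def test_top_n_by_abundance(self):
        rng = np.random.default_rng(89)
        counts = rng.integers(1, 100, (6, 40))
        out = filter_for_network(table_from(counts), top_n=25)
        assert out.n_otus == 25
        kept_totals = out.otu_sums()
        dropped = [o for o in table_from(counts).otu_ids if o not in out.otu_ids]
        dropped_max = table_from(counts).counts[dropped].sum(axis=0).max()
        assert kept_totals.min() >= dropped_max

    def test_rank_tie_broken_by_otu_id(self):
        counts = np.full((4, 6), 3)  # all OTUs tied
        out = filter_for_network(table_from(counts), top_n=4)
        assert out.otu_ids == ["o0", "o1", "o2", "o3"]

    def test_too_few_survivors_rejected(self):
        counts = np.zeros((6, 8), dtype=int)
        counts[:, 0] = 1
        counts[0, 1:] = 1
        with pytest.raises(ValueError, match="network"):
            filter_for_network(table_from(counts))


class TestBuildNetwork:
    def test_perfect_concordance_gives_positive_edge(self):
        base = np.arange(1, 9)
        rng = np.random.default_rng(97)
        noise = rng.integers(0, 50, size=(8, 10))
        counts = np.column_stack([base, base * 3, noise])
        g = build_network(table_from(counts), rho_min=0.6, q_max=0.05)
        assert g.has_edge("o0", "o1")
        assert g["o0"]["o1"]["sign"] == "+"
        assert g["o0"]["o1"]["rho"] == pytest.approx(1.0)

    def test_perfect_discordance_gives_negative_edge(self):
        base = np.arange(1, 9)
        rng = np.random.default_rng(101)
        noise = rng.integers(0, 50, size=(8, 10))
        counts = np.column_stack([base, base[::-1] * 2, noise])
        g = build_network(table_from(counts), rho_min=0.6, q_max=0.05)
        assert g.has_edge("o0", "o1")
        assert g["o0"]["o1"]["sign"] == "-"

    def test_independent_otus_yield_almost_no_edges(self):
        rng = np.random.default_rng(103)
        counts = rng.integers(0, 100, size=(12, 300))
        counts[:, 0] += 1
        g = build_network(table_from(counts), rho_min=0.6, q_max=0.01)
        # BH at q<0.01 over ~45k independent tests: expected false edges ~0
        assert g.number_of_edges() <= 2

    def test_deterministic(self):
        rng = np.random.default_rng(107)
        counts = rng.integers(0, 60, size=(10, 30))
        t = table_from(counts)
        g1, g2 = build_network(t), build_network(t)
        assert sorted(g1.edges) == sorted(g2.edges)


class TestGraphTopology:
    def test_identities_on_any_graph(self):
        g = nx.gnm_random_graph(40, 90, seed=5)
        topo = graph_topology(g, seed=1)
        assert topo.average_degree == pytest.approx(2 * 90 / 40)
        assert topo.density == pytest.approx(2 * 90 / (40 * 39))

    def test_triangle_closed_forms(self):
        topo = graph_topology(nx.complete_graph(3), seed=1)
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.density == pytest.approx(1.0)
        assert topo.diameter == 1
        assert topo.average_path_length == pytest.approx(1.0)


class TestNodeTopology:
    def test_star_graph_betweenness(self):
        g = nx.star_graph(5)  # node 0 is the hub
        nt = node_topology(g)
        assert nt.loc[0, "betweenness"] == pytest.approx(1.0)
        assert nt.loc[1, "betweenness"] == pytest.approx(0.0)

    def test_path_graph_closeness(self):
        g = nx.path_graph(3)
        nt = node_topology(g)
        assert nt.loc[1, "closeness"] == pytest.approx(1.0)
        assert nt.loc[0, "closeness"] == pytest.approx(2 / 3)

    def test_centralities_match_igraph_reference(self):
        for rep in range(20):
            g = nx.gnm_random_graph(30, 70, seed=200 + rep)
            if not nx.is_connected(g):
                continue
            nt = node_topology(g)
            h = ig.Graph(30, list(g.edges))
            n = 30
            btw = np.array(h.betweenness()) / ((n - 1) * (n - 2) / 2)
            clo = np.array(h.closeness(normalized=True))
            eig = np.array(h.eigenvector_centrality(scale=True))
            assert np.allclose(nt["betweenness"].to_numpy(), btw, atol=1e-8)
            assert np.allclose(nt["closeness"].to_numpy(), clo, atol=1e-8)
            assert np.allclose(nt["eigenvector"].to_numpy(), eig, atol=1e-6)
            assert np.array_equal(nt["degree"].to_numpy(), h.degree())


class TestModulesAndRoles:
    def test_two_cliques_q_half(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        modules, q = detect_modules(g, seed=3)
        assert len(set(modules.values())) == 2
        assert q == pytest.approx(0.5)

    def test_complete_graph_not_modular(self):
        _, q = detect_modules(nx.complete_graph(8), seed=3)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_pi_closed_forms(self):
        # hub node 0 linked once into each of 4 cliques: Pi = 1 - 4*(1/4)^2
        g = nx.Graph()
        for c in range(4):
            members = [f"c{c}_{i}" for i in range(4)]
            g.add_edges_from(
                (members[i], members[j]) for i in range(4) for j in range(i + 1, 4)
            )
            g.add_edge("hub", members[0])
        modules, _ = detect_modules(g, seed=5)
        roles = zipi_classify(g, modules)
        assert roles.loc["hub", "Pi"] == pytest.approx(0.75)
        # a clique-internal node with no external links has Pi = 0
        assert roles.loc["c0_2", "Pi"] == pytest.approx(0.0)

    def test_role_thresholds(self):
        g = nx.complete_graph(4)
        modules = {n: 0 for n in g}
        roles = zipi_classify(g, modules)
        fake = pd.DataFrame({"Zi": [3.0, 3.0, 1.0, 1.0], "Pi": [0.7, 0.5, 0.7, 0.5]})
        # independent check of the quoted thresholds
        expected = ["network_hub", "module_hub", "connector", "peripheral"]
        for (_, row), exp in zip(fake.iterrows(), expected):
            zi, pi = row["Zi"], row["Pi"]
            if zi > 2.5 and pi > 0.62:
                assert exp == "network_hub"
            elif zi > 2.5:
                assert exp == "module_hub"
            elif pi > 0.62:
                assert exp == "connector"
            else:
                assert exp == "peripheral"
        assert set(roles["role"]) <= {"network_hub", "module_hub", "connector", "peripheral"}


class TestRandomEnsemble:
    def test_complete_graph_degenerate(self):
        out = random_ensemble(6, 15, reps=5, seed=1)
        assert out.clustering_mean == pytest.approx(1.0)
        assert out.path_length_mean == pytest.approx(1.0)
        assert out.clustering_sd == pytest.approx(0.0)

    def test_clustering_tracks_density(self):
        out = random_ensemble(100, 495, reps=50, seed=2, metrics=("clustering",))
        assert out.clustering_mean == pytest.approx(0.1, abs=0.02)

    def test_degree_distribution_binomial(self):
        # G(n,m): degree of a node ~ Binomial(n-1, m / C(n,2)) to high accuracy
        from ecoassembly.network import _gnm_edges

        rng = np.random.default_rng(3)
        n, m = 50, 100
        degs = []
        for _ in range(200):
            g = ig.Graph(n, _gnm_edges(n, m, rng))
            degs.extend(g.degree())
        mean = np.mean(degs)
        assert mean == pytest.approx(2 * m / n, rel=0.02)
        var = np.var(degs)
        p_edge = m / (n * (n - 1) / 2)
        assert var == pytest.approx((n - 1) * p_edge * (1 - p_edge), rel=0.15)


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(5)
        assert natural_connectivity(g) == 0.0

    def test_k3_closed_form(self):
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(0.9963, abs=1e-4)

    def test_adding_edges_never_decreases(self):
        rng = np.random.default_rng(11)
        for rep in range(20):
            g = nx.gnm_random_graph(15, 25, seed=400 + rep)
            before = natural_connectivity(g)
            candidates = [e for e in nx.non_edges(g)]
            u, v = candidates[rng.integers(len(candidates))]
            g.add_edge(u, v)
            assert natural_connectivity(g) >= before - 1e-12


class TestRobustness:
    def test_zero_fraction_equals_full_graph(self):
        g = nx.gnm_random_graph(25, 60, seed=9)
        curve = robustness_curve(g, strategy="random", reps=5, seed=1)
        assert curve.nc_mean[0] == pytest.approx(natural_connectivity(g))

    def test_targeted_removal_monotone_decreasing(self):
        for rep in range(5):
            g = nx.gnm_random_graph(30, 120, seed=500 + rep)
            curve = robustness_curve(g, strategy="degree_desc")
            assert (np.diff(curve.nc_mean) <= 1e-9).all()

    def test_denser_graph_more_robust(self):
        sparse = nx.gnm_random_graph(30, 45, seed=21)
        dense = nx.gnm_random_graph(30, 200, seed=21)
        cs = robustness_curve(sparse, strategy="random", reps=20, seed=2)
        cd = robustness_curve(dense, strategy="random", reps=20, seed=2)
        assert (cd.nc_mean >= cs.nc_mean - 1e-9).all()


class TestPowerlawFit:
    def test_r2_high_on_powerlaw_degrees(self):
        rng = np.random.default_rng(19)
        degs = np.round(rng.pareto(2.0, 2000) + 1).astype(int)
        r2, alpha = powerlaw_fit(degs)
        assert r2 > 0.8
        assert 1.5 < alpha < 4.0
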