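"""Network generation and network-constrained transmission."""

import numpy as np
import pytest

from cultne import (Graph, Population, barabasi_albert, erdos_renyi,
                    network_step, read_edgelist, watts_strogatz)


class TestGraphContainer:
    def test_rejects_self_loops_and_duplicates(self):
        with pytest.raises(ValueError, match="self-loops"):
            Graph.from_edges(3, [(0, 0)])
        with pytest.raises(ValueError, match="duplicate"):
            Graph.from_edges(3, [(0, 1), (1, 0)])

    def test_adjacency_is_symmetric(self):
        g = Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        nxg = g.to_networkx()
        for u, v in nxg.edges:
            assert u in list(nxg.neighbors(v))
        assert g.degrees.tolist() == [1, 2, 2, 1]

    def test_edgelist_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        g = erdos_renyi(30, 0.2, rng)
        path = tmp_path / "graph.edges"
        g.write_edgelist(path)
        g2 = read_edgelist(path, n=30)
        assert np.array_equal(np.sort(g.edge_list(), axis=0),
                              np.sort(g2.edge_list(), axis=0))

    def test_graphml_export(self, tmp_path):
        g = Graph.from_edges(3, [(0, 1), (1, 2)])
        path = tmp_path / "graph.graphml"
        g.write_graphml(path)
        assert path.read_text().startswith("<?xml")


class TestErdosRenyi:
    def test_boundaries(self):
        rng = np.random.default_rng(1)
        assert erdos_renyi(20, 0.0, rng).n_edges == 0
        assert erdos_renyi(10, 1.0, rng).n_edges == 45  # N(N-1)/2 possible ties

    def test_mean_degree(self):
        """p = 0.1, N = 1000: mean degree ~ (N-1)p = 99.9."""
        rng = np.random.default_rng(2)
        means = [erdos_renyi(1000, 0.1, rng).degrees.mean() for _ in range(3)]
        assert np.mean(means) == pytest.approx(99.9, abs=1.0)

    def test_invalid_p(self):
        with pytest.raises(ValueError, match="p"):
            erdos_renyi(10, 1.2, np.random.default_rng(0))


class TestBarabasiAlbert:
    @pytest.mark.parametrize("n", [3, 10, 200])
    def test_edge_count_exact(self, n):
        g = barabasi_albert(n, 1.0, np.random.default_rng(3))
        assert g.n_edges == 2 * (n - 2) + 1

    def test_uniform_attachment_is_light_tailed(self):
        g = barabasi_albert(1000, 0.0, np.random.default_rng(4))
        assert g.degrees.max() < 100

    def test_superlinear_attachment_forms_star(self):
        """Strong preferential attachment concentrates nearly all edges on
        one hub."""
        g = barabasi_albert(1000, 3.0, np.random.default_rng(5))
        assert g.degrees.max() > 0.9 * 1000

    def test_degree_variance_grows_with_attachment_power(self):
        rng = np.random.default_rng(6)
        v = [barabasi_albert(500, pi, rng).degrees.var() for pi in (0.0, 1.0, 3.0)]
        assert v[0] < v[1] < v[2]

    def test_connected(self):
        import networkx as nx
        g = barabasi_albert(200, 1.0, np.random.default_rng(7))
        assert nx.is_connected(g.to_networkx())

    def test_too_small(self):
        with pytest.raises(ValueError):
            barabasi_albert(2, 1.0, np.random.default_rng(0))


class TestWattsStrogatz:
    def test_ring_lattice(self):
        g = watts_strogatz(50, 3, 0.0, np.random.default_rng(8))
        assert set(g.degrees) == {6}  # 2K each
        assert g.n_edges == 50 * 3

    def test_edge_count_preserved_under_full_rewiring(self):
        g = watts_strogatz(100, 4, 1.0, np.random.default_rng(9))
        assert g.n_edges == 400

    def test_expected_rewired_edges(self):
        """N = 1000, K = 4, p_r = 0.01: ~40 of 4000 edges leave the lattice."""
        g = watts_strogatz(1000, 4, 0.01, np.random.default_rng(10))
        edges = g.edge_list()
        span = np.abs(edges[:, 0] - edges[:, 1])
        span = np.minimum(span, 1000 - span)
        rewired = int((span > 4).sum())
        assert 10 <= rewired <= 80  # Binomial(4000, 0.01) mass

    def test_invalid_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            watts_strogatz(10, 5, 0.1, rng)
        with pytest.raises(ValueError, match="p_r"):
            watts_strogatz(10, 2, 1.5, rng)


class TestNetworkStep:
    def test_star_topology(self):
        """mu = 0 on a star: leaves copy the hub (hub influence N-1), the hub
        copies some leaf."""
        n = 5
        g = Graph.from_edges(n, [(0, i) for i in range(1, n)])
        pop = Population(np.arange(10, 10 + n), 15)
        rng = np.random.default_rng(11)
        new, oc = network_step(pop, g, 0.0, rng)
        assert np.all(new.variants[1:] == pop.variants[0])
        assert new.variants[0] in pop.variants[1:]
        assert oc.counts[0] == n - 1

    def test_single_variant_unchanged(self):
        g = erdos_renyi(30, 0.2, np.random.default_rng(12))
        pop = Population.monomorphic(30, label=2)
        new, oc = network_step(pop, g, 0.0, np.random.default_rng(13))
        assert np.all(new.variants == 2)

    def test_isolated_nodes_retain_variant_and_conserve_counts(self):
        g = Graph.from_edges(4, [(0, 1)])  # nodes 2, 3 isolated
        pop = Population(np.array([0, 1, 2, 3]), 4)
        rng = np.random.default_rng(14)
        new, oc = network_step(pop, g, 0.0, rng)
        assert new.variants[2] == 2 and new.variants[3] == 3
        assert oc.counts.sum() + oc.n_innovators == 4

    def test_size_mismatch(self):
        g = Graph.from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="node count"):
            network_step(Population.all_distinct(4), g, 0.0,
                         np.random.default_rng(0))

    def test_complete_graph_matches_self_excluded_unbiased_variance(self):
        """On the complete graph each learner copies uniformly among the
        other N-1 individuals: influence variance ~ 1 - 1/(N-1)."""
        n, gens = 200, 1500
        g = erdos_renyi(n, 1.0, np.random.default_rng(15))
        pop = Population.all_distinct(n)
        rng = np.random.default_rng(16)
        v = np.empty(gens)
        for i in range(gens):
            pop, oc = network_step(pop, g, 0.0, rng)
            v[i] = oc.counts.var()
        assert v.mean() == pytest.approx(1 - 1 / (n - 1), abs=0.02)

    def test_influence_variance_tracks_degree_variance(self):
        """Across topologies, more heterogeneous degrees mean more
        heterogeneous cultural influence."""
        n, gens = 300, 400
        rng = np.random.default_rng(17)
        graphs = {
            "ws": watts_strogatz(n, 4, 0.01, rng),   # near-constant degree
            "er": erdos_renyi(n, 8 / (n - 1), rng),  # Poisson-ish degree
            "ba": barabasi_albert(n, 1.0, rng),      # heavy-tailed degree
        }
        influence_var = {}
        for name, g in graphs.items():
            pop = Population.all_distinct(n)
            acc = np.empty(gens)
            for i in range(gens):
                pop, oc = network_step(pop, g, 0.0, rng)
                acc[i] = oc.counts.var()
            influence_var[name] = acc.mean()
        dv = {k: graphs[k].degrees.var() for k in graphs}
        assert dv["ws"] < dv["er"] < dv["ba"]
        assert influence_var["ws"] < influence_var["er"] < influence_var["ba"]
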