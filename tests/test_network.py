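import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from otukit.network import (
    ParameterError,
    build_network,
    correlation_matrix,
    keystones,
    louvain_partition,
    modularity_of,
    module_niche_preference,
    select_network_taxa,
    topology,
)
from otukit.normalize import AbundanceTable
from otukit.tables_io import ValidationError


def rel_table(values, sample_prefix="s", taxa=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"g{j}" for j in range(values.shape[1])]
    return AbundanceTable([f"{sample_prefix}{i}" for i in range(values.shape[0])],
                          taxa, values, "relative")


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Count shortest paths through each node by explicit enumeration."""
    bc = {v: 0.0 for v in g}
    nodes = list(g)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def floyd_warshall_apl_nd(g: nx.Graph) -> tuple[float, float]:
    nodes = list(g)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    iu = np.triu_indices(n, 1)
    finite = dist[iu][np.isfinite(dist[iu])]
    return float(finite.mean()), float(finite.max())


# ---------------------------------------------------------------------------


class TestSelectNetworkTaxa:
    def test_threshold_excludes_low_abundance(self):
        vals = np.array([[0.0004, 0.9996], [0.0004, 0.9996]])
        kept = select_network_taxa(rel_table(vals), scope="overall", threshold=0.0005)
        assert kept == ["g1"]

    def test_boundary_is_strict(self):
        vals = np.array([[0.0005, 0.9995]] * 3)
        kept = select_network_taxa(rel_table(vals), scope="overall", threshold=0.0005)
        assert "g0" not in kept

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.ones(6) * 0.5, size=10)
        t = rel_table(vals)
        thr = 0.05
        kept = select_network_taxa(t, scope="overall", threshold=thr)
        expected = [g for j, g in enumerate(t.taxon_ids) if vals[:, j].mean() > thr]
        assert kept == expected

    def test_niche_scope(self):
        vals = np.array([[0.9, 0.1], [0.9, 0.1], [0.1, 0.9], [0.1, 0.9]])
        niches = ["air", "air", "rock", "rock"]
        kept = select_network_taxa(rel_table(vals), niches=niches, scope="air",
                                   threshold=0.5)
        assert kept == ["g0"]

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            select_network_taxa(rel_table(np.ones((3, 2)) / 2), threshold=1.5)


class TestCorrelationMatrix:
    def test_self_correlation(self):
        rng = np.random.default_rng(1)
        rho, p = correlation_matrix(rel_table(rng.random((8, 3))))
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(np.diag(p), 0.0)

    def test_antimonotone_pair(self):
        x = np.arange(1.0, 9.0)
        vals = np.column_stack([x, 10.0 - x])
        rho, p = correlation_matrix(rel_table(vals))
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_midrank_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.random((10, 20))
        vals[:, 3] = np.round(vals[:, 3], 1)  # introduce ties
        rho, _ = correlation_matrix(rel_table(vals))
        for i, j in [(0, 1), (3, 7), (12, 19), (3, 4)]:
            oracle = np.corrcoef(rankdata(vals[:, i]), rankdata(vals[:, j]))[0, 1]
            assert rho.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_constant_genus_nan(self):
        vals = np.column_stack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        rho, p = correlation_matrix(rel_table(vals))
        assert np.isnan(rho.iloc[0, 1])
        g = build_network(rho, p, rho_min=0.1, p_max=0.9, fdr=False)
        assert "g0" not in g


class TestBuildNetwork:
    def _matrices(self, rho01, q01):
        taxa = ["a", "b", "c"]
        rho = pd.DataFrame(np.eye(3), index=taxa, columns=taxa)
        p = pd.DataFrame(np.zeros((3, 3)), index=taxa, columns=taxa)
        rho.iloc[0, 1] = rho.iloc[1, 0] = rho01
        p.iloc[0, 1] = p.iloc[1, 0] = q01
        p.iloc[0, 2] = p.iloc[2, 0] = 0.9
        p.iloc[1, 2] = p.iloc[2, 1] = 0.9
        return rho, p

    def test_passing_edge_present(self):
        rho, p = self._matrices(0.61, 0.005)
        g = build_network(rho, p, fdr=False)
        assert g.has_edge("a", "b")

    def test_failing_p_edge_absent(self):
        rho, p = self._matrices(0.7, 0.02)
        g = build_network(rho, p, fdr=False)
        assert not g.has_edge("a", "b")

    def test_negative_rho_excluded_by_default(self):
        rho, p = self._matrices(-0.8, 0.001)
        g = build_network(rho, p, fdr=False)
        assert not g.has_edge("a", "b")
        g2 = build_network(rho, p, fdr=False, absolute=True)
        assert g2.has_edge("a", "b")

    def test_isolated_nodes_dropped(self):
        rho, p = self._matrices(0.9, 0.001)
        g = build_network(rho, p, fdr=False)
        assert set(g.nodes) == {"a", "b"}

    def test_fdr_uses_bh(self):
        rng = np.random.default_rng(3)
        n = 12
        taxa = [f"g{i}" for i in range(n)]
        rho = pd.DataFrame(np.full((n, n), 0.9), index=taxa, columns=taxa)
        raw = rng.random((n, n)) * 0.05
        raw = (raw + raw.T) / 2
        p = pd.DataFrame(raw, index=taxa, columns=taxa)
        from otukit.indicators import benjamini_hochberg

        iu = np.triu_indices(n, 1)
        q = benjamini_hochberg(p.to_numpy()[iu])
        expected_edges = int((q < 0.01).sum())
        g = build_network(rho, p, rho_min=0.6, p_max=0.01, fdr=True)
        assert g.number_of_edges() == expected_edges


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        topo = topology(g, seed=0)
        assert topo.clustering_coefficient == pytest.approx(1.0)
        assert topo.average_path_length == pytest.approx(1.0)
        assert topo.diameter == 1
        assert topo.average_degree == pytest.approx(2.0)
        assert all(v == 0 for v in topo.betweenness.values())

    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        topo = topology(g, seed=0)
        assert topo.betweenness["B"] == pytest.approx(1.0)
        assert topo.average_path_length == pytest.approx(4 / 3)
        assert topo.diameter == 2

    def test_two_triangles_modularity(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        partition = {n: (0 if n < 3 else 1) for n in g}
        assert modularity_of(g, partition) == pytest.approx(0.5)

    def test_single_community_modularity_zero(self):
        g = nx.erdos_renyi_graph(10, 0.4, seed=1)
        partition = {n: 0 for n in g}
        assert modularity_of(g, partition) == pytest.approx(0.0, abs=1e-12)

    def test_louvain_q_matches_direct_formula(self):
        g = nx.planted_partition_graph(3, 8, 0.8, 0.05, seed=2)
        partition = louvain_partition(g, seed=0)
        q = modularity_of(g, partition)
        # direct evaluation: Q = sum_c (e_c/m - (d_c/2m)^2)
        m = g.number_of_edges()
        comms = {}
        for node, c in partition.items():
            comms.setdefault(c, set()).add(node)
        q_direct = 0.0
        for nodes in comms.values():
            e_c = g.subgraph(nodes).number_of_edges()
            d_c = sum(dict(g.degree(nodes)).values())
            q_direct += e_c / m - (d_c / (2 * m)) ** 2
        assert q == pytest.approx(q_direct, abs=1e-12)

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(4)
        checked = 0
        trial = 0
        while checked < 50:
            trial += 1
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            if not nx.is_connected(g) or g.number_of_edges() == 0:
                continue
            topo = topology(g, seed=0)
            oracle = brute_force_betweenness(g)
            for v in g:
                assert topo.betweenness[v] == pytest.approx(oracle[v], abs=1e-9)
            checked += 1

    def test_apl_nd_match_floyd_warshall(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g = nx.gnp_random_graph(int(rng.integers(10, 30)), 0.15,
                                    seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            topo = topology(g, seed=0)
            apl, nd = floyd_warshall_apl_nd(g)
            assert topo.average_path_length == pytest.approx(apl, abs=1e-12)
            assert topo.diameter == pytest.approx(nd)

    def test_empty_graph_errors(self):
        with pytest.raises(ValidationError):
            topology(nx.Graph(), seed=0)

    def test_ad_identity(self):
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        g.remove_nodes_from(list(nx.isolates(g)))
        topo = topology(g, seed=0)
        assert topo.average_degree == pytest.approx(2 * topo.n_edges / topo.n_nodes)


class TestKeystones:
    def test_star_center_top(self):
        g = nx.star_graph(4)  # center 0, four leaves
        topo = topology(g, seed=0)
        report = keystones(topo, k=3)
        assert report.index[0] == 0
        assert report.iloc[0]["betweenness"] == pytest.approx(6.0)  # (n-1)(n-2)/2

    def test_tie_break_by_degree_then_label(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        topo = topology(g, seed=0)
        report = keystones(topo, k=7)
        # all BC zero; K4 nodes (degree 3) come first, label-sorted within
        assert list(report["degree"])[:4] == [3, 3, 3, 3]
        assert list(report.index[:4]) == ["n3", "n4", "n5", "n6"]

    def test_k_truncated(self):
        g = nx.complete_graph(3)
        topo = topology(g, seed=0)
        assert len(keystones(topo, k=10)) == 3


class TestModuleNichePreference:
    def test_majority_and_conservation(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g})
        topo = topology(g, seed=0)
        # genera g0-g2 peak in sediment, g3-g5 in air
        vals = np.zeros((4, 6))
        vals[0, :3] = 0.01  # air sample
        vals[1, :3] = 0.30  # sediment sample
        vals[0, 3:] = 0.30
        vals[1, 3:] = 0.01
        vals[2] = vals[1]
        vals[3] = vals[0]
        t = rel_table(vals, taxa=[f"g{i}" for i in range(6)])
        niches = ["air", "sediment", "sediment", "air"]
        pref = module_niche_preference(topo, t, niches)
        assert (pref["module_size"] == pref.drop(
            columns=["module_size", "majority_niche"]).sum(axis=1)).all()
        majorities = set(pref["majority_niche"])
        assert majorities == {"air", "sediment"}

    def test_missing_profile_errors(self):
        g = nx.complete_graph(3)
        g = nx.relabel_nodes(g, {i: f"x{i}" for i in g})
        topo = topology(g, seed=0)
        t = rel_table(np.ones((4, 2)) / 2, taxa=["x0", "x1"])
        with pytest.raises(ValidationError):
            module_niche_preference(topo, t, ["air", "air", "rock", "rock"])
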