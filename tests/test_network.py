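"""Differential-network stage: exact Spearman, r-to-z edges, topology."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from dcoex.network import (
    build_network,
    fisher_z_change,
    read_sif,
    spearman_with_exact_p,
    topology,
    annotate_and_export,
)


class TestSpearmanExact:
    def test_perfect_monotone_n5(self):
        rho, p = spearman_with_exact_p([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_anti_monotone_symmetry(self):
        rho, p = spearman_with_exact_p([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 120)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_with_exact_p([1, 1, 1, 1], [1, 2, 3, 4])

    def test_null_calibration_on_discrete_support(self):
        """Permutation p-values are super-uniform: P(p <= a) <= a, with
        equality on the support points."""
        # exact p-value support for distinct ranks at n = 5
        base = np.arange(5, dtype=float)
        rhos = sorted(
            {round(abs(np.corrcoef(base, np.array(p))[0, 1]), 12)
             for p in itertools.permutations(base)}
        )
        all_abs = [abs(np.corrcoef(base, np.array(p))[0, 1])
                   for p in itertools.permutations(base)]
        support = sorted(
            {np.mean([a >= r - 1e-12 for a in all_abs]) for r in rhos}
        )
        hits = {0.05: 0, 0.2: 0}
        n_sim = 400
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            _, p = spearman_with_exact_p(rng.normal(size=5), rng.normal(size=5))
            for a in hits:
                hits[a] += p <= a
        for a, h in hits.items():
            attainable = max([p for p in support if p <= a], default=0.0)
            assert h / n_sim == pytest.approx(attainable, abs=3 * math.sqrt(a / n_sim))

    def test_ties_use_midranks(self):
        rho, _ = spearman_with_exact_p([1, 1, 2, 3], [1, 2, 3, 4])
        from scipy import stats
        assert rho == pytest.approx(stats.spearmanr([1, 1, 2, 3], [1, 2, 3, 4]).statistic)


class TestFisherZ:
    def test_no_change(self):
        z, p = fisher_z_change(0.9, 10, 0.9, 10)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        z, p = fisher_z_change(0.9, 5, -0.5, 5)
        assert z == pytest.approx(math.atanh(0.9) - math.atanh(-0.5), abs=1e-6)
        assert 0 < p < 0.1

    def test_antisymmetric_under_group_swap(self):
        z1, p1 = fisher_z_change(0.8, 6, 0.2, 8)
        z2, p2 = fisher_z_change(0.2, 8, 0.8, 6)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_unit_correlation_clamped(self):
        z, p = fisher_z_change(1.0, 5, 0.0, 5)
        assert math.isfinite(z)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_change(0.5, 3, 0.5, 10)


class TestBuildNetwork:
    def test_curated_union_novel_counts(self, network_demo):
        expr, groups, curated = network_demo
        G = build_network(expr, groups, curated)
        sources = [d["source"] for _, _, d in G.edges(data=True)]
        assert sources.count("curated") == 55
        assert sources.count("novel") == 22
        assert G.number_of_edges() == 77

    def test_novel_rule_off_reproduces_curated_exactly(self, network_demo):
        expr, groups, curated = network_demo
        G = build_network(expr, groups, curated, include_novel=False)
        assert G.number_of_edges() == 55
        curated_pairs = {frozenset((s, t)) for s, _, t in curated}
        assert {frozenset(e) for e in G.edges} == curated_pairs

    def test_empty_inputs_give_edgeless_graph(self, network_demo, rng):
        expr, groups, _ = network_demo
        noise = expr + rng.normal(0, 0.3, expr.shape)  # break exact monotonicity
        G = build_network(noise, groups, [], rho_min=1.1)
        assert G.number_of_edges() == 0
        rep, _ = topology(G)
        assert rep.n_components == G.number_of_nodes()

    def test_curated_pair_passing_rule_stays_single_curated_edge(self, network_demo):
        expr, groups, _ = network_demo
        # CTSC-CTSD is curated AND perfectly correlated in the control arm
        G = build_network(expr, groups, [("CTSC", "pp", "CTSD")])
        assert G.number_of_edges() >= 1
        assert G.edges[("CTSC", "CTSD")]["source"] == "curated"

    def test_unknown_curated_gene_dropped_and_counted(self, network_demo):
        expr, groups, _ = network_demo
        G = build_network(expr, groups, [("APP", "pp", "NOSUCHGENE")],
                          include_novel=False)
        assert G.graph["n_curated_dropped"] == 1
        assert G.number_of_edges() == 0

    def test_zero_change_when_groups_identical(self, network_demo):
        expr, groups, _ = network_demo
        ctrl_cols = groups.index[groups == "control"]
        case_cols = groups.index[groups == "case"]
        mirrored = expr.copy()
        mirrored[case_cols] = expr[ctrl_cols].to_numpy()
        G = build_network(mirrored, groups, [("APP", "pp", "MAPT")])
        for _, _, d in G.edges(data=True):
            assert d["z_change"] == pytest.approx(0.0, abs=1e-9)

    def test_edge_significance_class_rule(self, network_demo):
        expr, groups, curated = network_demo
        G = build_network(expr, groups, curated)
        for _, _, d in G.edges(data=True):
            expected = "solid" if min(d["p_g1"], d["p_g2"]) < 0.05 else "dashed"
            assert d["significance_class"] == expected


def brute_topology(G):
    """Independent oracle: BFS distances and shortest-path counting."""
    nodes = list(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = np.full((n, n), INF)
    for v in nodes:
        dist[idx[v], idx[v]] = 0.0
        frontier = [v]
        d = 0
        seen = {v}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in G.neighbors(u):
                    if w not in seen:
                        seen.add(w)
                        dist[idx[v], idx[w]] = d
                        nxt.append(w)
            frontier = nxt

    # shortest-path counts sigma[s][t] via DP over increasing distance
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1
        order = sorted(range(n), key=lambda t: dist[s, t])
        for t in order:
            if t == s or dist[s, t] == INF:
                continue
            sigma[s, t] = sum(
                sigma[s, idx[w]]
                for w in G.neighbors(nodes[t])
                if dist[s, idx[w]] == dist[s, t] - 1
            )

    betweenness = {}
    for v in nodes:
        i = idx[v]
        total = 0.0
        for s in range(n):
            for t in range(n):
                if s == t or s == i or t == i:
                    continue
                if dist[s, t] == INF or sigma[s, t] == 0:
                    continue
                if dist[s, i] + dist[i, t] == dist[s, t]:
                    total += sigma[s, i] * sigma[i, t] / sigma[s, t]
        betweenness[v] = total / 2 / ((n - 1) * (n - 2) / 2) if n > 2 else 0.0

    closeness = {}
    for v in nodes:
        ds = [dist[idx[v], t] for t in range(n) if t != idx[v] and dist[idx[v], t] < INF]
        closeness[v] = len(ds) / sum(ds) if ds and sum(ds) > 0 else 0.0

    clustering = {}
    for v in nodes:
        nbrs = list(G.neighbors(v))
        k = len(nbrs)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b))
        clustering[v] = 2 * links / (k * (k - 1))

    finite = dist[(dist > 0) & (dist < INF)]
    cpl = finite.mean() if finite.size else float("nan")
    return betweenness, closeness, clustering, cpl


class TestTopology:
    @pytest.mark.parametrize("seed", range(6))
    def test_metrics_match_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        G = nx.gnp_random_graph(n, 0.45, seed=seed)
        if not nx.is_connected(G):
            G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        rep, nodes = topology(G)
        bet, clo, clu, cpl = brute_topology(G)
        for v in G.nodes:
            assert nodes.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)
            assert nodes.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-9)
            assert nodes.loc[v, "clustering"] == pytest.approx(clu[v], abs=1e-9)
        assert rep.char_path_length == pytest.approx(cpl)

    @pytest.mark.parametrize("seed", range(4))
    def test_density_and_neighbor_identities(self, seed):
        G = nx.gnp_random_graph(10, 0.4, seed=seed)
        rep, _ = topology(G)
        n, e = G.number_of_nodes(), G.number_of_edges()
        assert rep.density == pytest.approx(2 * e / (n * (n - 1)))
        assert rep.avg_neighbors == pytest.approx(2 * e / n)
        if rep.n_components == 1:
            assert rep.radius <= rep.diameter <= 2 * rep.radius

    def test_disconnected_graph_flagged(self):
        G = nx.Graph()
        G.add_edges_from([("a", "b"), ("c", "d")])
        rep, _ = topology(G)
        assert rep.n_components == 2
        assert "disconnected" in rep.flags

    def test_hub_closeness_construction(self):
        # hub adjacent to 17 of 22 others; remaining 5 at distance 2
        G = nx.Graph()
        G.add_edge("hub", "n1")
        for i in range(2, 18):
            G.add_edge("hub", f"n{i}")
        for i in range(18, 23):
            G.add_edge("n1", f"n{i}")
        _, nodes = topology(G)
        assert nodes.loc["hub", "closeness"] == pytest.approx(22 / 27)


class TestExport:
    def test_graphml_round_trip_and_encodings(self, network_demo, tmp_path):
        import pandas as pd
        from dcoex import run_de
        from dcoex.modules import fit_pca

        expr, groups, curated = network_demo
        jitter = np.random.default_rng(5).normal(0, 1e-9, expr.shape)
        de = run_de(expr + np.abs(jitter), groups, outlier_rule=None)
        G = build_network(expr, groups, curated)
        pca = fit_pca(np.log2(expr), n_retained=2)
        paths = annotate_and_export(G, de, pca.loadings.iloc[:, :2], tmp_path)
        assert all(p.exists() for p in paths.values())

        back = nx.read_graphml(paths["graphml"])
        assert set(back.nodes) == set(G.nodes)
        assert back.number_of_edges() == G.number_of_edges()
        for node in G.nodes:
            # direction class mirrors the sign of log2 fold change
            if "log2fc" in G.nodes[node]:
                l2 = G.nodes[node]["log2fc"]
                expect = "up" if l2 > 0 else ("down" if l2 < 0 else "flat")
                assert G.nodes[node]["direction_class"] == expect
            assert back.nodes[node]["degree"] == G.nodes[node]["degree"]

        sif_back = read_sif(paths["sif"])
        assert len(sif_back) == G.number_of_edges()
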