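import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pahsoil import community, network, synth
from pahsoil.community import AbundanceTable


def _rel_table(matrix, sample_prefix="s"):
    data = pd.DataFrame(
        matrix,
        index=[f"g{i + 1}" for i in range(len(matrix))],
        columns=[f"{sample_prefix}{j + 1}" for j in range(len(matrix[0]))],
    )
    data = data / data.sum(axis=0)
    tax = pd.Series(
        [f"k__Bacteria;p__P;c__;o__;f__;g__Genus{i + 1}" for i in range(len(matrix))],
        index=data.index,
    )
    return AbundanceTable(data=data, taxonomy=tax, mode="relative")


class TestFilterTaxa:
    def _table(self):
        # g1: abundant, 2 samples only; g2: rare but everywhere;
        # g3: abundant and prevalent
        data = pd.DataFrame(
            {
                f"s{j}": col
                for j, col in enumerate(
                    np.array([
                        [0.5, 0.5, 0, 0, 0, 0, 0, 0, 0, 0],
                        [1e-4] * 10,
                        [0.3] * 10,
                    ]).T.tolist(),
                    start=1,
                )
            },
            index=["g1", "g2", "g3"],
        )
        # pad with a filler genus so columns sum to 1
        data.loc["g4"] = 1.0 - data.sum(axis=0)
        tax = pd.Series(
            [f"k__;p__;c__;o__;f__;g__G{i}" for i in range(1, 5)], index=data.index
        )
        return AbundanceTable(data=data, taxonomy=tax, mode="relative")

    def test_prevalence_rule_removes_sparse_taxon(self):
        out = network.filter_taxa(self._table())
        assert "g1" not in out.data.index

    def test_abundance_rule_removes_rare_taxon(self):
        out = network.filter_taxa(self._table())
        assert "g2" not in out.data.index

    def test_hand_oracle_on_fixture(self):
        # cumulative fractions: g1 1/10, g2 1e-3/10, g3 3/10, g4 rest
        # prevalence: g1 in 2, others in 10
        out = network.filter_taxa(self._table())
        assert set(out.data.index) == {"g3", "g4"}

    def test_empty_result_advises(self):
        t = _rel_table([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="threshold"):
            network.filter_taxa(t, min_prevalence=5)

    def test_counts_mode_rejected(self, toy_table):
        with pytest.raises(ValueError, match="relative"):
            network.filter_taxa(toy_table)


def _naive_network(table, r_thr=0.6, p_thr=0.01):
    """Exhaustive all-pairs oracle using scipy directly."""
    edges = {}
    taxa = list(table.data.index)
    for a, b in itertools.combinations(taxa, 2):
        r, p = stats.spearmanr(table.data.loc[a], table.data.loc[b])
        if abs(r) > r_thr and p < p_thr:
            edges[(a, b)] = r
    return edges


class TestBuildNetwork:
    def test_identical_rank_profiles_give_positive_unit_edge(self, rng):
        base = rng.random(10)
        t = _rel_table([base, base * 3, rng.random(10)])
        net = network.build_network(t)
        assert net.graph.has_edge("g1", "g2")
        d = net.graph.edges["g1", "g2"]
        assert d["r"] == pytest.approx(1.0)
        assert d["sign"] == "positive"

    def test_matches_exhaustive_oracle_on_fixtures(self, rng):
        for trial in range(5):
            X = rng.random((8, 12))
            X[1] = X[0] * 2 + rng.normal(scale=0.05, size=12)  # plant an edge
            X[3] = 1.2 - X[2] * 0.9 + rng.normal(scale=0.05, size=12)
            t = _rel_table(np.abs(X))
            net = network.build_network(t)
            oracle = _naive_network(t)
            got = {
                tuple(sorted((u, v))): d["r"]
                for u, v, d in net.graph.edges(data=True)
            }
            assert set(got) == {tuple(sorted(k)) for k in oracle}
            for k, r in oracle.items():
                assert got[tuple(sorted(k))] == pytest.approx(r, abs=1e-12)

    def test_negative_edge_sign_recorded(self, rng):
        up = np.linspace(0.1, 1.0, 10)
        t = _rel_table([up, up[::-1], rng.random(10)])
        net = network.build_network(t)
        assert net.graph.edges["g1", "g2"]["sign"] == "negative"

    def test_independent_genera_sparse_at_thresholds(self, rng):
        dens = []
        for _ in range(20):
            t = _rel_table(rng.random((20, 30)))
            net = network.build_network(t)
            n = net.n_nodes
            dens.append(net.n_edges / (n * (n - 1) / 2))
        assert np.mean(dens) < 0.05

    def test_constant_row_excluded_with_warning(self, rng):
        X = rng.random((3, 10))
        X = X / X.sum(axis=0) * 0.75  # three rows totalling 0.75 per sample
        X = np.vstack([X, np.full(10, 0.25)])  # constant fourth row
        data = pd.DataFrame(
            X, index=["g1", "g2", "g3", "g4"],
            columns=[f"s{j}" for j in range(10)],
        )
        t = AbundanceTable(
            data=data,
            taxonomy=pd.Series(["k__;p__;c__;o__;f__;g__X"] * 4, index=data.index),
            mode="relative",
        )
        with pytest.warns(UserWarning, match="constant"):
            net = network.build_network(t)
        assert "g4" not in net.graph.nodes

    def test_too_few_samples_rejected(self, rng):
        t = _rel_table(rng.random((5, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            network.build_network(t)

    def test_top_n_preselection(self, rng):
        t = _rel_table(rng.random((10, 12)))
        net = network.build_network(t, top_n_by_abundance=4)
        assert net.n_nodes == 4


class TestTopology:
    def test_triangle_closed_form(self):
        topo = network.network_topology(nx.complete_graph(3))
        assert topo.average_degree == pytest.approx(2.0)
        assert topo.clustering_coefficient == pytest.approx(1.0)
        assert topo.average_path_length == pytest.approx(1.0)

    def test_path_graph_hand_enumeration(self):
        topo = network.network_topology(nx.path_graph(3))
        assert topo.clustering_coefficient == 0
        assert topo.average_path_length == pytest.approx(4 / 3)

    def test_positive_edge_fraction_from_construction(self, rng):
        g = nx.Graph()
        for i in range(57):
            g.add_edge(f"p{i}", f"q{i}", sign="positive")
        for i in range(44):
            g.add_edge(f"n{i}", f"m{i}", sign="negative")
        net_frac = network.network_topology(g).positive_edge_fraction
        assert net_frac == pytest.approx(100 * 57 / 101)

    def test_edgeless_graph_undefined_markers(self):
        g = nx.empty_graph(4)
        topo = network.network_topology(g)
        assert np.isnan(topo.average_path_length)
        assert np.isnan(topo.clustering_coefficient)

    def test_average_degree_identity(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=4)
        topo = network.network_topology(g)
        assert topo.average_degree == pytest.approx(2 * 60 / 30)


class TestModules:
    def test_two_clique_partition_and_q(self, two_clique_graph):
        assignment, q = network.detect_modules(two_clique_graph, seed=0)
        assert q == pytest.approx(12 / 13 - 0.5, abs=1e-12)
        left = {assignment[i] for i in range(4)}
        right = {assignment[i] for i in range(4, 8)}
        assert len(left) == len(right) == 1 and left != right

    def test_complete_graph_single_module(self):
        assignment, q = network.detect_modules(nx.complete_graph(8), seed=1)
        assert len(set(assignment.values())) == 1
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_planted_three_blocks_recovered(self):
        hits = 0
        n_trials = 25
        for s in range(n_trials):
            g = nx.planted_partition_graph(3, 30, 0.5, 0.01, seed=s)
            assignment, q = network.detect_modules(g, seed=s)
            if len(set(assignment.values())) == 3 and q > 0.4:
                hits += 1
        assert hits >= round(0.95 * n_trials)

    def test_q_bounds_and_beats_random_partition(self, two_clique_graph, rng):
        _, q = network.detect_modules(two_clique_graph, seed=2)
        assert -0.5 <= q <= 1
        random_labels = rng.integers(0, 2, size=8)
        parts = [
            {n for n, lab in zip(two_clique_graph, random_labels) if lab == k}
            for k in (0, 1)
        ]
        parts = [p for p in parts if p]
        q_rand = nx.community.modularity(two_clique_graph, parts)
        assert q_rand <= q + 1e-12


class TestNullEnsemble:
    def test_replicates_have_exact_size(self):
        null = network.er_null_ensemble(30, 45, n_replicates=20, seed=3)
        assert (null.replicates["n_nodes"] == 30).all()
        assert (null.replicates["n_edges"] == 45).all()
        assert np.allclose(null.replicates["average_degree"], 3.0)

    def test_gnm_simple_graphs(self):
        # uniform G(n, m): no self-loops, no duplicate edges, exactly m edges
        for s in range(10):
            g = nx.gnm_random_graph(20, 40, seed=s)
            assert g.number_of_edges() == 40
            assert all(u != v for u, v in g.edges)

    def test_saturated_ensemble_has_zero_variance(self):
        null = network.er_null_ensemble(6, 15, n_replicates=5, seed=1)
        assert null.replicates["clustering_coefficient"].std() == 0
        assert (null.replicates["clustering_coefficient"] == 1.0).all()

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            network.er_null_ensemble(5, 11, n_replicates=2)

    def test_mean_clustering_matches_edge_density(self):
        null = network.er_null_ensemble(100, 200, n_replicates=200, seed=5)
        mean_c = null.replicates["clustering_coefficient"].mean()
        assert mean_c == pytest.approx(2 * 200 / (100 * 99), abs=0.01)


class TestSmallWorld:
    def test_self_null_shows_no_systematic_excess(self):
        null = network.er_null_ensemble(40, 80, n_replicates=60, seed=6)
        flagged = 0
        reps = 20
        for i in range(reps):
            g = nx.gnm_random_graph(40, 80, seed=1000 + i)
            real = network.network_topology(g, seed=i)
            verdict = network.small_world_assessment(real, null)
            zs = [
                abs(verdict["metrics"][m]["z"])
                for m in ("modularity", "clustering_coefficient")
                if np.isfinite(verdict["metrics"][m]["z"])
            ]
            if any(z >= 3 for z in zs):
                flagged += 1
        assert flagged <= max(1, round(0.05 * reps))

    def test_two_clique_fixture_beats_null(self, two_clique_graph):
        real = network.network_topology(two_clique_graph, seed=0)
        null = network.er_null_ensemble(8, 13, n_replicates=100, seed=0)
        verdict = network.small_world_assessment(real, null)
        assert verdict["metrics"]["clustering_coefficient"]["exceeds_null"]
        assert verdict["metrics"]["modularity"]["exceeds_null"]
        assert verdict["small_world_and_modular"]

    def test_average_degree_noninformative(self, two_clique_graph):
        real = network.network_topology(two_clique_graph, seed=0)
        null = network.er_null_ensemble(8, 13, n_replicates=10, seed=0)
        verdict = network.small_world_assessment(real, null)
        assert "identical by construction" in verdict["metrics"]["average_degree"]["note"]

    def test_mismatched_null_rejected(self, two_clique_graph):
        real = network.network_topology(two_clique_graph, seed=0)
        null = network.er_null_ensemble(9, 13, n_replicates=5, seed=0)
        with pytest.raises(ValueError, match="real"):
            network.small_world_assessment(real, null)


def _brute_betweenness(g):
    """All-pairs shortest-path enumeration (BFS layers + DFS path counting)."""
    nodes = list(g.nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            score[v] += frac
    return score


class TestKeystones:
    def _net_from_graph(self, g):
        gg = nx.Graph()
        for n in g.nodes:
            gg.add_node(str(n), lineage=f"k__;p__;c__;o__;f__;g__Gen{n}",
                        genus=f"Gen{n}", mean_abundance=0.1)
        for u, v in g.edges:
            gg.add_edge(str(u), str(v), r=0.9, p=0.001, sign="positive")
        return network.CooccurrenceNetwork(gg, 0.6, 0.01, ())

    def test_star_hub_maximal_leaves_zero(self):
        net = self._net_from_graph(nx.star_graph(5))
        ranked = network.keystone_taxa(net, top_k=6)
        assert ranked.loc[0, "taxon_id"] == "0"
        assert (ranked.loc[1:, "betweenness"] == 0).all()

    def test_path_center_ranks_first(self):
        net = self._net_from_graph(nx.path_graph(3))
        ranked = network.keystone_taxa(net, top_k=3)
        assert ranked.loc[0, "taxon_id"] == "1"

    def test_matches_brute_force_enumeration(self, rng):
        g = nx.gnm_random_graph(8, 14, seed=9)
        net = self._net_from_graph(g)
        ranked = network.keystone_taxa(net, top_k=8)
        brute = _brute_betweenness(g)
        order_brute = sorted(brute, key=lambda n: (-brute[n], str(n)))
        # compare full ranking where scores differ; ties may reorder
        got_scores = dict(zip(ranked["taxon_id"], ranked["betweenness"]))
        norm = (8 - 1) * (8 - 2) / 2
        for n in g.nodes:
            assert got_scores[str(n)] == pytest.approx(brute[n] / norm, abs=1e-12)
        for a, b in zip(order_brute, order_brute[1:]):
            if brute[a] > brute[b]:
                pos = {t: i for i, t in enumerate(ranked["taxon_id"])}
                assert pos[str(a)] < pos[str(b)]

    def test_unclassified_exclusion(self):
        g = nx.path_graph(3)
        gg = nx.Graph()
        for n in g.nodes:
            genus = "" if n == 1 else f"Gen{n}"
            gg.add_node(str(n), genus=genus, lineage="")
        for u, v in g.edges:
            gg.add_edge(str(u), str(v))
        net = network.CooccurrenceNetwork(gg, 0.6, 0.01, ())
        ranked = network.keystone_taxa(net, top_k=3, exclude_unclassified=True)
        assert "1" not in set(ranked["taxon_id"])

    def test_topk_truncation_warns(self):
        net = self._net_from_graph(nx.path_graph(4))
        with pytest.warns(UserWarning, match="truncat"):
            ranked = network.keystone_taxa(net, top_k=10)
        assert len(ranked) == 4

    def test_no_component_big_enough(self):
        net = self._net_from_graph(nx.empty_graph(3))
        with pytest.raises(ValueError, match="component"):
            network.keystone_taxa(net)


def test_export_roundtrip(tmp_path, rng):
    t = _rel_table(rng.random((6, 10)))
    net = network.build_network(t, r_threshold=0.3, p_threshold=0.5)
    modules, _ = network.detect_modules(net.graph, seed=0)
    network.export_network(net, tmp_path / "net", modules=modules)
    g2 = nx.read_graphml(tmp_path / "net.graphml")
    assert g2.number_of_nodes() == net.n_nodes
    assert g2.number_of_edges() == net.n_edges
    assert (tmp_path / "net.gexf").exists()
    edges = pd.read_csv(tmp_path / "net_edges.csv")
    assert len(edges) == net.n_edges
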