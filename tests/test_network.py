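"""Network parsing, node-set statistics, permutation nulls, hub/bottleneck classes."""

import itertools

import networkx as nx
import numpy as np
import pytest

from proteonet import synthetic
from proteonet.network import (
    STAT_NAMES,
    NetworkStatsEngine,
    NullDistribution,
    classify_hub_bottleneck,
    empirical_pvalue,
    induce_lcc_subgraph,
    node_set_significance,
    permutation_null,
    read_string_links,
    set_statistics,
)


class TestStringParser:
    def _write(self, tmp_path, lines, name="links.txt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_integer_scale_and_threshold_inclusive(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                "protein1 protein2 combined_score",
                "a b 499",
                "a c 500",
                "c d 999",
            ],
        )
        g = read_string_links(p, 0.5)
        assert set(g.edges) == {("a", "c"), ("c", "d")}
        assert g.edges["a", "c"]["combined_score"] == pytest.approx(0.5)
        assert g.graph["score_scale"] == 1000.0

    def test_decimal_scale_autodetected(self, tmp_path):
        p = self._write(tmp_path, ["protein1 protein2 combined_score", "a b 0.9", "b c 0.2"])
        g = read_string_links(p, 0.5)
        assert set(g.edges) == {("a", "b")}
        assert g.graph["score_scale"] == 1.0

    def test_headerless_first_line_is_data(self, tmp_path):
        p = self._write(tmp_path, ["a b 900", "b c 800"])
        g = read_string_links(p, 0.5)
        assert g.number_of_edges() == 2

    def test_self_loops_dropped_and_counted(self, tmp_path):
        p = self._write(tmp_path, ["protein1 protein2 combined_score", "a a 900", "a b 900"])
        g = read_string_links(p, 0.5)
        assert set(g.edges) == {("a", "b")}
        assert g.graph["self_loops_dropped"] == 1

    def test_duplicate_rows_collapse(self, tmp_path):
        p = self._write(tmp_path, ["protein1 protein2 combined_score", "a b 900", "b a 900"])
        g = read_string_links(p, 0.5)
        assert g.number_of_edges() == 1

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = self._write(tmp_path, ["protein1 protein2 combined_score", "a b 900", "broken"])
        with pytest.raises(ValueError, match="line 3"):
            read_string_links(p)

    def test_unknown_score_scale_rejected(self, tmp_path):
        p = self._write(tmp_path, ["protein1 protein2 combined_score", "a b 5000"])
        with pytest.raises(ValueError, match="scale"):
            read_string_links(p)

    def test_gzip_roundtrip(self, tmp_path):
        import gzip

        p = tmp_path / "links.txt.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("protein1 protein2 combined_score\na b 900\n")
        assert read_string_links(p).number_of_edges() == 1


class TestInducedLCC:
    def test_largest_component_kept(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y"), ("q", "r")])
        lcc = induce_lcc_subgraph(g, ["a", "b", "c", "x", "y", "zzz"])
        assert set(lcc.nodes) == {"a", "b", "c"}
        assert lcc.graph["n_absent"] == 1  # zzz
        assert lcc.graph["n_outside_lcc"] == 2  # x, y

    def test_size_tie_breaks_to_smallest_node(self):
        g = nx.Graph([("b", "c"), ("a", "d")])
        lcc = induce_lcc_subgraph(g, ["a", "b", "c", "d"])
        assert set(lcc.nodes) == {"a", "d"}

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="none of the requested"):
            induce_lcc_subgraph(nx.Graph([("a", "b")]), ["x"])


class TestSetStatistics:
    def test_path_graph_endpoints(self):
        # a - b - c: endpoints have degree 1, distance 2 via b, no induced edge
        g = nx.path_graph(["a", "b", "c"])
        s = set_statistics(g, ["a", "c"])
        assert s.mean_degree == pytest.approx(1.0)
        assert s.mean_shortest_path == pytest.approx(2.0)
        assert s.lcc_size == 1
        assert s.mean_betweenness == pytest.approx(0.0)

    def test_path_graph_middle_is_bottleneck(self):
        g = nx.path_graph(["a", "b", "c"])
        s = set_statistics(g, ["a", "b"])
        # normalised betweenness of b in a 3-path is 1; of a is 0
        assert s.mean_betweenness == pytest.approx(0.5)
        assert s.lcc_size == 2
        assert s.mean_shortest_path == pytest.approx(1.0)

    def test_paths_run_through_the_full_network(self):
        # square a-b-c-d-a; the set {a, c} is connected only via b or d
        g = nx.cycle_graph(["a", "b", "c", "d"])
        s = set_statistics(g, ["a", "c"])
        assert s.mean_shortest_path == pytest.approx(2.0)
        assert s.lcc_size == 1

    def test_disconnected_network_rejected(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError, match="connected"):
            set_statistics(g, ["a", "b"])

    def test_singleton_set_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            set_statistics(nx.path_graph(["a", "b", "c"]), ["a"])

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="not in network"):
            set_statistics(nx.path_graph(["a", "b", "c"]), ["a", "zzz"])

    def test_agrees_with_networkx_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(0)
        checked = 0
        for seed in range(50):
            g = nx.gnp_random_graph(8, 0.35, seed=seed)
            if not nx.is_connected(g):
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            engine = NetworkStatsEngine(g)
            nodes = sorted(g.nodes)
            size = int(rng.integers(2, 6))
            s = [nodes[i] for i in rng.choice(len(nodes), size=size, replace=False)]
            got = engine.set_statistics(s)
            # oracles straight from networkx
            assert got.mean_degree == pytest.approx(np.mean([g.degree(v) for v in s]))
            bc = nx.betweenness_centrality(g, normalized=True)
            assert got.mean_betweenness == pytest.approx(np.mean([bc[v] for v in s]))
            dists = [
                nx.shortest_path_length(g, u, v)
                for u, v in itertools.permutations(s, 2)
            ]
            assert got.mean_shortest_path == pytest.approx(np.mean(dists))
            comp = max(nx.connected_components(g.subgraph(s)), key=len)
            assert got.lcc_size == len(comp)
            checked += 1
        assert checked >= 30  # most ER(8, 0.35) draws are connected


class TestEmpiricalP:
    def _null(self, samples, tail="upper"):
        return NullDistribution("mean_degree", np.asarray(samples, dtype=float), tail)

    def test_add_one_upper(self):
        assert empirical_pvalue(self._null([1, 2, 3, 4]), 4.0) == pytest.approx(2 / 5)

    def test_raw_upper(self):
        assert empirical_pvalue(self._null([1, 2, 3, 4]), 4.0, add_one=False) == pytest.approx(1 / 4)

    def test_lower_tail(self):
        assert empirical_pvalue(self._null([1, 2, 3, 4], tail="lower"), 1.0) == pytest.approx(2 / 5)

    def test_never_zero_with_add_one(self):
        assert empirical_pvalue(self._null([1, 2, 3]), 100.0) == pytest.approx(1 / 4)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_pvalue(self._null([]), 1.0)

    def test_invalid_tail_rejected(self):
        with pytest.raises(ValueError, match="tail"):
            empirical_pvalue(self._null([1.0]), 1.0, tail="both")


def er_network(seed=0, n=300, p=0.03):
    g = nx.gnp_random_graph(n, p, seed=seed)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp).copy()


class TestPermutationNull:
    def test_deterministic_for_fixed_seed(self):
        g = er_network(1)
        a = permutation_null(g, 10, n_samples=200, seed=7)
        b = permutation_null(g, 10, n_samples=200, seed=7)
        for name in STAT_NAMES:
            np.testing.assert_array_equal(a[name].samples, b[name].samples)

    def test_null_mean_degree_matches_network_average(self):
        g = er_network(2)
        nulls = permutation_null(g, 20, n_samples=1000, seed=0)
        avg = np.mean([d for _, d in g.degree])
        sem = np.std([d for _, d in g.degree]) / np.sqrt(20)
        assert abs(nulls["mean_degree"].samples.mean() - avg) < 4 * sem / np.sqrt(10)

    def test_set_size_exceeding_network_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(ValueError, match="exceeds"):
            permutation_null(g, 4, n_samples=10)

    def test_random_sets_are_calibrated(self):
        """P(P <= 0.05) for random query sets must sit near 0.05 for all stats."""
        g = er_network(3)
        engine = NetworkStatsEngine(g)
        nulls = permutation_null(g, 15, n_samples=2000, seed=0, engine=engine)
        rng = np.random.default_rng(42)
        hits = {name: 0 for name in STAT_NAMES}
        n_queries = 200
        for _ in range(n_queries):
            idx = rng.choice(len(engine.nodes), size=15, replace=False)
            vals = dict(zip(STAT_NAMES, np.array(engine.stats_for_indices(idx), dtype=float)[[0, 1, 2, 3]]))
            for name in STAT_NAMES:
                if empirical_pvalue(nulls[name], vals[name]) <= 0.05:
                    hits[name] += 1
        for name in STAT_NAMES:
            assert 0.01 <= hits[name] / n_queries <= 0.10, name

    def test_planted_central_set_is_significant(self):
        cfg = synthetic.SyntheticConfig(n_nodes=300, edge_param=0.03, planted_central=12, seed=5)
        g, truth = synthetic.generate_network(cfg)
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
        central = sorted(truth.planted_central_set & set(g.nodes))
        _, pvals = node_set_significance(g, central, n_samples=2000, seed=0)
        assert pvals["mean_degree"] <= 0.005
        assert pvals["mean_betweenness"] <= 0.005
        assert pvals["mean_shortest_path"] <= 0.05


class TestHubBottleneck:
    def test_star_centre_is_hub_bottleneck(self):
        g = nx.star_graph(20)
        table = classify_hub_bottleneck(g)
        assert table.loc[0, "class"] == "hub-bottleneck"
        assert (table.drop(index=0)["class"] == "neither").all()

    def test_regular_graph_has_no_hubs(self):
        # cycle: every node identical, strict > the 90th percentile never holds
        g = nx.cycle_graph(20)
        table = classify_hub_bottleneck(g)
        assert (table["class"] == "neither").all()

    def test_barbell_bridge_is_nonhub_bottleneck(self):
        # two K6 cliques joined by a path: path nodes carry all traffic but
        # have low degree
        g = nx.barbell_graph(6, 3)
        table = classify_hub_bottleneck(g)
        # node 7 is the middle of the bridge: maximal betweenness, degree 2
        assert table.loc[7, "class"] == "nonhub-bottleneck"
        # clique-interior nodes lie on no shortest paths
        assert (table.loc[[0, 1, 2, 3, 4], "class"] == "neither").all()

    def test_hub_fraction_bounded_by_percentile(self):
        g = er_network(4)
        table = classify_hub_bottleneck(g, percentile=90.0)
        frac_hub = (table["class"].isin(["hub-bottleneck", "hub-nonbottleneck"])).mean()
        assert frac_hub <= 0.101
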