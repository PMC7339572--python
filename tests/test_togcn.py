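import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stagewise import assign_levels, build_gcn, choose_seed, pcc_matrix, robustness
from stagewise.togcn import level_spearman
from stagewise.types import CoexpressionNetwork, StageProfiles

from _oracles import bfs_levels_oracle


def _profiles(rows: dict[str, list[float]]) -> StageProfiles:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = list(range(1, df.shape[1] + 1))
    return StageProfiles(profile=df)


class TestPCCMatrix:
    def test_perfect_linear(self):
        C = pcc_matrix(_profiles({"a": [1, 2, 3, 4, 5], "b": [2, 4, 6, 8, 10]}))
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_anti_correlation(self):
        C = pcc_matrix(_profiles({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]}))
        assert C.loc["a", "b"] == pytest.approx(-1.0)

    def test_textbook_formula(self):
        x, y = np.array([1, 2, 3, 4, 5.0]), np.array([1, 3, 2, 5, 4.0])
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        C = pcc_matrix(_profiles({"a": list(x), "b": list(y)}))
        assert C.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_flagged(self):
        C = pcc_matrix(_profiles({"a": [1, 2, 3, 4, 5], "b": [2, 2, 2, 2, 2]}))
        assert np.isnan(C.loc["a", "b"])
        assert C.loc["b", "b"] == 1.0  # diagonal stays defined

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        prof = _profiles({f"g{i}": list(rng.normal(size=5)) for i in range(20)})
        C = pcc_matrix(prof).to_numpy()
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert np.nanmax(np.abs(C)) <= 1.0

    def test_too_few_stages(self):
        with pytest.raises(ValueError, match="T >= 3"):
            pcc_matrix(_profiles({"a": [1, 2], "b": [2, 1]}))


class TestBuildGCN:
    def test_triangle(self):
        prof = _profiles(
            {"a": [1, 2, 3, 4, 5], "b": [1.1, 2, 3, 4, 5.2], "c": [1, 2.1, 3, 4.1, 5]}
        )
        net = build_gcn(pcc_matrix(prof), cutoff=0.91)
        assert net.n_edges == 3

    def test_exact_cutoff_edge_kept(self):
        pcc = pd.DataFrame(
            [[1.0, 0.91], [0.91, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        net = build_gcn(pcc, cutoff=0.91)
        assert net.graph.has_edge("a", "b")  # >= convention

    def test_cutoff_one_no_perfect_pairs(self):
        prof = _profiles({"a": [1, 2, 3, 4, 5], "b": [1, 3, 2, 5, 4]})
        net = build_gcn(pcc_matrix(prof), cutoff=1.0)
        assert net.n_edges == 0
        assert set(net.nodes) == {"a", "b"}  # isolated nodes retained

    def test_negative_and_nan_excluded(self):
        prof = _profiles(
            {"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1], "c": [2, 2, 2, 2, 2]}
        )
        net = build_gcn(pcc_matrix(prof), cutoff=0.5)
        assert net.n_edges == 0

    def test_raising_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(4)
        prof = _profiles({f"g{i}": list(rng.normal(size=5)) for i in range(15)})
        C = pcc_matrix(prof)
        low = set(map(frozenset, build_gcn(C, 0.3).graph.edges))
        high = set(map(frozenset, build_gcn(C, 0.7).graph.edges))
        assert high <= low


def _results(rows):
    return pd.DataFrame(rows, columns=["gene", "direction", "DE", "p_value"])


class TestChooseSeed:
    def test_minimal_de_wins(self):
        res = _results(
            [
                ("a", "descending", 2, 0.01),
                ("b", "descending", 0, 0.01),
                ("c", "descending", 3, 0.01),
            ]
        )
        assert choose_seed(res, {"a", "b", "c"}) == "b"

    def test_p_value_tiebreak(self):
        res = _results(
            [("a", "descending", 0, 0.02), ("b", "descending", 0, 0.01)]
        )
        assert choose_seed(res, {"a", "b"}) == "b"

    def test_lexicographic_tiebreak(self):
        res = _results(
            [("b", "descending", 0, 0.01), ("a", "descending", 0, 0.01)]
        )
        assert choose_seed(res, {"a", "b"}) == "a"

    def test_no_descending_tf_errors(self):
        res = _results([("a", "ascending", 0, 0.01)])
        with pytest.raises(ValueError, match="supply a seed"):
            choose_seed(res, {"a"})


def _net_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(((u, v, {"pcc": 0.95}) for u, v in edges))
    return CoexpressionNetwork(graph=g, cutoff=0.91)


class TestAssignLevels:
    def test_chain(self):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        la = assign_levels(net, "a")
        assert la.levels == {"a": 1, "b": 2, "c": 3, "d": 4}

    def test_star(self):
        net = _net_from_edges([("hub", f"leaf{i}") for i in range(5)])
        la = assign_levels(net, "hub")
        assert la.levels["hub"] == 1
        assert all(la.levels[f"leaf{i}"] == 2 for i in range(5))

    def test_unreachable_reported(self):
        net = _net_from_edges([("a", "b")], nodes=["c"])
        la = assign_levels(net, "a")
        assert la.unreachable == {"c"}
        assert "c" not in la.levels

    def test_missing_seed_errors(self):
        net = _net_from_edges([("a", "b")])
        with pytest.raises(ValueError, match="not a node"):
            assign_levels(net, "zzz")

    def test_random_graphs_match_shortest_path_oracle(self):
        """Levels equal Floyd-Warshall distance + 1 on 100 random connected
        graphs of up to 30 nodes."""
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(3, 31))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
            # stitch components into one connected graph
            comps = [sorted(c) for c in nx.connected_components(g)]
            for c1, c2 in zip(comps, comps[1:]):
                g.add_edge(c1[0], c2[0])
            mapping = {i: f"t{i}" for i in g.nodes}
            g = nx.relabel_nodes(g, mapping)
            nx.set_edge_attributes(g, 0.95, "pcc")
            net = CoexpressionNetwork(graph=g, cutoff=0.91)
            seed = f"t{int(rng.integers(n))}"
            la = assign_levels(net, seed)
            adjacency = {v: set(g.neighbors(v)) for v in g.nodes}
            assert la.levels == bfs_levels_oracle(adjacency, seed), f"trial {trial}"

    def test_raising_cutoff_never_lowers_levels(self):
        rng = np.random.default_rng(8)
        prof = _profiles({f"g{i}": list(rng.normal(size=5)) for i in range(12)})
        C = pcc_matrix(prof)
        lo = build_gcn(C, 0.2)
        hi = build_gcn(C, 0.5)
        seed = "g0"
        la_lo, la_hi = assign_levels(lo, seed), assign_levels(hi, seed)
        assert set(la_hi.levels) <= set(la_lo.levels)  # reachability shrinks
        for v, l in la_hi.levels.items():
            assert l >= la_lo.levels[v]


class TestRobustness:
    def _setup_path(self):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        pcc = pd.DataFrame(0.95, index=list("abcd"), columns=list("abcd"))
        pcc.loc["a", "b"] = pcc.loc["b", "a"] = 0.995
        np.fill_diagonal(pcc.values, 1.0)
        res = pd.DataFrame(
            {
                "gene": list("abcd"),
                "direction": "descending",
                "DE": [0, 1, 9, 9],
                "p_value": 0.01,
            }
        )
        return net, pcc, res

    def test_adjacent_seed_report(self):
        net, pcc, res = self._setup_path()
        primary = assign_levels(net, "a")
        report = robustness(net, primary, res, pcc, pcc_min=0.99, de_max=4)
        assert list(report["alt_seed"]) == ["b"]
        # seeding from b gives levels (a,b,c,d)=(2,1,2,3) against (1,2,3,4):
        # tied ranks (2.5,1,2.5,4) vs (1,2,3,4) -> rho = 3/sqrt(22.5)
        assert report["spearman_vs_primary"].iloc[0] == pytest.approx(3 / np.sqrt(22.5))
        assert report["n_shared"].iloc[0] == 4

    def test_identity_seed_excluded_but_identical_assignment(self):
        net, pcc, res = self._setup_path()
        primary = assign_levels(net, "a")
        again = assign_levels(net, "a")
        rho, n = level_spearman(primary, again)
        assert rho == pytest.approx(1.0) and n == 4

    def test_no_qualifying_seed_empty_report(self):
        net, pcc, res = self._setup_path()
        primary = assign_levels(net, "a")
        report = robustness(net, primary, res, pcc, pcc_min=0.999, de_max=4)
        assert report.empty
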