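"""Pearson correlation edges, k-core decomposition and gene ranking."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ogdrseq import (
    CoexpressionNetwork,
    ExpressionMatrix,
    ValidationError,
    build_network,
    kcore_decompose,
    pearson_with_p,
    rank_core_genes,
)

from oracles import kcore_brute, pearson_exact


def em_from_profiles(profiles: dict[str, list[float]]) -> ExpressionMatrix:
    """Expression matrix whose log2(RPKM+1) profiles equal the given vectors."""
    rpkm = {g: np.exp2(np.asarray(v, float)) - 1.0 for g, v in profiles.items()}
    df = pd.DataFrame(rpkm).T
    df.columns = [f"S{i + 1}" for i in range(df.shape[1])]
    return ExpressionMatrix(rpkm=df)


class TestPearson:
    def test_affine_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p = pearson_with_p(x, 2 * x + 3)
        assert r == 1.0 and p == 0.0

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, -x)
        assert r == -1.0 and p == 0.0

    def test_matches_direct_formula(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        sxy, sxx, syy = pearson_exact(x, y)
        r_exact = float(sxy) / math.sqrt(float(sxx) * float(syy))
        t = abs(r_exact) * math.sqrt(3 / (1 - r_exact**2))
        p_exact = 2 * stats.t.sf(t, 3)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(r_exact, rel=1e-10)
        assert p == pytest.approx(p_exact, rel=1e-10)

    @given(st.integers(0, 500))
    def test_random_profiles_match_formula(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 30))
        x = rng.normal(size=L)
        y = rng.normal(size=L)
        r, p = pearson_with_p(x, y)
        n = len(x)
        r_direct = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2)))
        t = abs(r_direct) * math.sqrt((n - 2) / (1 - r_direct**2))
        assert r == pytest.approx(r_direct, rel=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(t, n - 2), rel=1e-8)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1.0, 2.0], [3.0, 4.0])


class TestBuildNetwork:
    def test_constant_profiles_have_no_edges(self):
        em = em_from_profiles({"a": [1, 1, 1, 1], "b": [1, 1, 1, 1], "c": [0, 1, 2, 3]})
        net = build_network(em, {"a", "b", "c"})
        assert net.n_edges == 0
        assert net.degree == {"a": 0, "b": 0, "c": 0}

    def test_forced_triangle_from_perfect_correlation(self):
        em = em_from_profiles({
            "g1": [0, 1, 2, 3, 4],
            "g2": [0, 1, 2, 3, 4],
            "g3": [4, 3, 2, 1, 0],
        })
        net = build_network(em, {"g1", "g2", "g3"}, r_min=0.9)
        assert net.edges == [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]
        assert net.core_number == {"g1": 2, "g2": 2, "g3": 2}
        # anti-correlated edges keep their sign
        assert net.graph.edges[("g1", "g3")]["r"] == pytest.approx(-1.0)

    def test_isolated_nodes_retained(self):
        rng = np.random.default_rng(0)
        em = em_from_profiles({
            "a": [0, 1, 2, 3, 4],
            "b": [0, 1, 2, 3, 4],
            "c": list(rng.normal(size=5)),
        })
        net = build_network(em, {"a", "b", "c"}, r_min=0.999)
        assert set(net.nodes) == {"a", "b", "c"}

    def test_fewer_than_three_samples_rejected(self):
        em = em_from_profiles({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValidationError):
            build_network(em, {"a", "b"})

    def test_unknown_gene_rejected(self):
        em = em_from_profiles({"a": [1, 2, 3]})
        with pytest.raises(ValidationError):
            build_network(em, {"a", "nope"})

    def test_order_invariance_and_degree_sum(self, rng):
        profiles = {f"g{i:02d}": list(rng.normal(size=8)) for i in range(25)}
        em = em_from_profiles(profiles)
        net1 = build_network(em, list(profiles), r_min=0.5, p_max=0.5)
        net2 = build_network(em, list(reversed(list(profiles))), r_min=0.5, p_max=0.5)
        assert net1.edges == net2.edges
        assert sum(net1.degree.values()) == 2 * net1.n_edges
        for v in net1.degree:
            assert net1.core_number[v] <= net1.degree[v]


class TestKcore:
    def _wrap(self, g: nx.Graph) -> CoexpressionNetwork:
        net = CoexpressionNetwork(graph=g)
        net.degree = {v: int(d) for v, d in g.degree()}
        return net

    def test_triangle_with_pendant(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        core = kcore_decompose(self._wrap(g))
        assert core == {"a": 2, "b": 2, "c": 2, "d": 1}

    def test_empty_and_edgeless(self):
        assert kcore_decompose(self._wrap(nx.Graph())) == {}
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        assert kcore_decompose(self._wrap(g)) == {"x": 0, "y": 0}

    @given(st.integers(0, 200))
    def test_matches_brute_force_peeling_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        p = float(rng.uniform(0.02, 0.4))
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        core = kcore_decompose(self._wrap(g))
        assert core == kcore_brute(g)
        # the k-core induced subgraph has min degree >= k, for every realized k
        for k in set(core.values()):
            sub = g.subgraph([v for v, c in core.items() if c >= k])
            if sub.number_of_nodes():
                assert all(d >= k for _, d in sub.degree()) or k == 0

    def test_edge_removal_never_raises_core(self):
        rng = np.random.default_rng(99)
        g = nx.fast_gnp_random_graph(30, 0.2, seed=7)
        core = kcore_brute(g)
        for edge in list(g.edges)[:10]:
            g2 = g.copy()
            g2.remove_edge(*edge)
            core2 = kcore_brute(g2)
            assert all(core2[v] <= core[v] for v in g.nodes)


class TestRankCoreGenes:
    def _net(self, g: nx.Graph) -> CoexpressionNetwork:
        net = CoexpressionNetwork(graph=g)
        net.degree = {v: int(d) for v, d in g.degree()}
        net.core_number = kcore_decompose(net)
        return net

    def test_star_hub_first(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {0: "hub", **{i: f"leaf{i}" for i in range(1, 6)}})
        assert rank_core_genes(self._net(g), 1) == ["hub"]

    def test_two_triangles_tie_break_by_gene_id(self):
        g = nx.Graph([("b", "c"), ("c", "d"), ("b", "d"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        assert rank_core_genes(self._net(g), 6) == ["b", "c", "d", "x", "y", "z"]

    @given(st.integers(0, 100))
    def test_agrees_with_independent_resort(self, seed):
        g = nx.fast_gnp_random_graph(20, 0.25, seed=seed)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        net = self._net(g)
        got = rank_core_genes(net, 20)
        brute_core = kcore_brute(g)
        want = sorted(g.nodes, key=lambda v: (-brute_core[v], -g.degree(v), v))
        assert got == want

    def test_top_must_be_positive(self):
        with pytest.raises(ValidationError):
            rank_core_genes(self._net(nx.Graph()), 0)
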