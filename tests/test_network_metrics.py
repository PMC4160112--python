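"""Centrality and assortativity against closed forms and brute force."""

import math

import networkx as nx
import numpy as np
import pytest

import polydomy as pm
from conftest import (
    brute_force_centralities,
    graph_with_strengths,
    random_connected_graph,
)
from polydomy.network_metrics import (
    closeness,
    degree_and_weighted_degree,
    newman_assortativity,
    node_betweenness,
    strength_graph,
    trail_betweenness,
)


def _path_graph():
    g = nx.Graph()
    g.add_edge("a", "b", strength=2.0)
    g.add_edge("b", "c", strength=3.0)
    return g


class TestClosedForms:
    def test_star_centre_degree_and_closeness(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "strength")
        deg = degree_and_weighted_degree(g)
        assert deg[0] == (4, 4.0)
        clo, per_comp = closeness(g)
        assert clo[0] == pytest.approx(1.0)
        assert not per_comp

    def test_path_graph_betweenness_and_closeness(self):
        g = _path_graph()
        bet = node_betweenness(g)
        assert bet["b"] == pytest.approx(1.0)
        assert bet["a"] == bet["c"] == 0.0
        clo, _ = closeness(g)
        assert clo["a"] == pytest.approx(2.0 / 3.0)
        deg = degree_and_weighted_degree(g)
        assert deg["b"] == (2, 5.0)

    def test_path_graph_edge_betweenness(self):
        ebet = trail_betweenness(_path_graph())
        assert ebet[("a", "b")] == pytest.approx(2.0)  # pairs {a,b}, {a,c}
        assert ebet[("b", "c")] == pytest.approx(2.0)

    def test_complete_graph_has_no_intermediaries(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 1.0, "strength")
        assert all(v == 0.0 for v in node_betweenness(g).values())

    def test_bridge_edge_has_maximal_betweenness(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            g.add_edge(a, b, strength=1.0)
        ebet = trail_betweenness(g)
        assert ebet[(2, 3)] == max(ebet.values())

    def test_isolated_nest_flagged(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", strength=1.0)
        clo, per_comp = closeness(g)
        assert per_comp
        assert math.isnan(clo["c"])


class TestBruteForceOracle:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_centralities_match_enumeration(self, weighted):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            n, edges, strengths = random_connected_graph(rng)
            g = graph_with_strengths(n, edges, strengths)
            dist = (
                {e: 1.0 / s for e, s in strengths.items()}
                if weighted
                else {e: 1.0 for e in strengths}
            )
            ex_bet, ex_ebet, ex_clo = brute_force_centralities(
                list(range(n)), edges, dist
            )
            bet = node_betweenness(g, weighted=weighted)
            ebet = trail_betweenness(g, weighted=weighted)
            clo, _ = closeness(g, weighted=weighted)
            for v in range(n):
                assert bet[v] == pytest.approx(ex_bet[v], abs=1e-9)
                assert clo[v] == pytest.approx(ex_clo[v], abs=1e-9)
            for e in ex_ebet:
                assert ebet[e] == pytest.approx(ex_ebet[e], abs=1e-9)

    def test_unweighted_recovered_from_equal_strengths(self):
        rng = np.random.default_rng(7)
        n, edges, strengths = random_connected_graph(rng)
        g = graph_with_strengths(n, edges, {e: 0.5 for e in strengths})
        assert node_betweenness(g, weighted=True) == pytest.approx(
            node_betweenness(g, weighted=False)
        )
        w_clo, _ = closeness(g, weighted=True)
        u_clo, _ = closeness(g, weighted=False)
        # distances scale by 1/0.5 = 2, so closeness scales by 1/2
        for v in g.nodes:
            assert w_clo[v] == pytest.approx(u_clo[v] / 2.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        n, edges, strengths = random_connected_graph(rng)
        g = graph_with_strengths(n, edges, strengths)
        mapping = {i: f"x{i}" for i in range(n)}
        h = nx.relabel_nodes(g, mapping)
        bet_g = node_betweenness(g, weighted=True)
        bet_h = node_betweenness(h, weighted=True)
        for v in range(n):
            assert bet_h[mapping[v]] == pytest.approx(bet_g[v])

    def test_neglog_transform_requires_substrength_one(self):
        g = nx.Graph()
        g.add_edge(0, 1, strength=2.0)  # -log(2) < 0: invalid distance
        with pytest.raises(pm.DomainError):
            strength_graph(g, transform="neglog")
        g2 = nx.Graph()
        g2.add_edge(0, 1, strength=0.5)
        assert strength_graph(g2, transform="neglog")[0][1][
            "_distance"
        ] == pytest.approx(math.log(2))


def _edge_pearson(pairs, weights=None):
    """Direct symmetrised (optionally weighted) edge-list Pearson."""
    x = np.array([a for a, b in pairs] + [b for a, b in pairs], dtype=float)
    y = np.array([b for a, b in pairs] + [a for a, b in pairs], dtype=float)
    if weights is None:
        return float(np.corrcoef(x, y)[0, 1])
    w = np.concatenate([weights, weights]).astype(float)
    w = w / w.sum()
    mx, my = w @ x, w @ y
    return float(
        (w @ ((x - mx) * (y - my)))
        / math.sqrt((w @ ((x - mx) ** 2)) * (w @ ((y - my) ** 2)))
    )


class TestAssortativity:
    def test_perfect_assortment(self):
        g = nx.Graph()
        g.add_edge("a", "b", strength=1.0)
        g.add_edge("c", "d", strength=1.0)
        vals = {"a": 1.0, "b": 1.0, "c": 5.0, "d": 5.0}
        assert newman_assortativity(g, vals).r == pytest.approx(1.0)

    def test_perfect_disassortment(self):
        g = nx.Graph()
        g.add_edge("a", "b", strength=1.0)
        g.add_edge("c", "d", strength=1.0)
        vals = {"a": 1.0, "b": 5.0, "c": 5.0, "d": 1.0}
        assert newman_assortativity(g, vals).r == pytest.approx(-1.0)

    def test_matches_direct_edge_list_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n, edges, strengths = random_connected_graph(rng)
            g = graph_with_strengths(n, edges, strengths)
            vals = {v: float(rng.normal()) for v in range(n)}
            res = newman_assortativity(g, vals)
            pairs = [(vals[a], vals[b]) for a, b in edges]
            assert res.r == pytest.approx(_edge_pearson(pairs))
            w = np.array([strengths[tuple(sorted(e))] for e in edges])
            res_w = newman_assortativity(g, vals, weighted=True)
            assert res_w.r == pytest.approx(_edge_pearson(pairs, w))

    def test_matches_networkx_numeric_assortativity(self):
        rng = np.random.default_rng(12)
        n, edges, strengths = random_connected_graph(rng)
        g = graph_with_strengths(n, edges, strengths)
        vals = {v: float(rng.integers(1, 6)) for v in range(n)}
        nx.set_node_attributes(g, vals, "attr")
        expected = nx.numeric_assortativity_coefficient(g, "attr")
        assert newman_assortativity(g, vals).r == pytest.approx(expected)

    def test_affine_invariance(self):
        # both edge endpoints receive the same transform, so r is
        # invariant under any affine map with non-zero scale (a negative
        # scale flips the sign of both coordinates and cancels)
        rng = np.random.default_rng(3)
        n, edges, strengths = random_connected_graph(rng)
        g = graph_with_strengths(n, edges, strengths)
        vals = {v: float(rng.normal()) for v in range(n)}
        r = newman_assortativity(g, vals, weighted=True).r
        scaled = {v: 3.0 * x + 7.0 for v, x in vals.items()}
        flipped = {v: -2.0 * x + 1.0 for v, x in vals.items()}
        assert newman_assortativity(g, scaled, weighted=True).r == pytest.approx(r)
        assert newman_assortativity(g, flipped, weighted=True).r == pytest.approx(r)

    def test_zero_variance_flagged_undefined(self):
        g = nx.cycle_graph(5)
        nx.set_edge_attributes(g, 1.0, "strength")
        res = newman_assortativity(g, {v: 2.0 for v in g.nodes})
        assert res.undefined
        assert math.isnan(res.r)


class TestDegreeCorrelation:
    def test_regular_graph_undefined(self):
        g = nx.cycle_graph(6)  # 2-regular, all weighted degrees equal
        nx.set_edge_attributes(g, 1.0, "strength")
        res = pm.degree_correlation(g)
        assert res.undefined

    def test_star_graph_is_disassortative(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 1.0, "strength")
        assert pm.degree_correlation(g).r < 0

    def test_matches_direct_formula_on_random_weighted_graph(self):
        rng = np.random.default_rng(9)
        n, edges, strengths = random_connected_graph(rng)
        g = graph_with_strengths(n, edges, strengths)
        wdeg = {v: 0.0 for v in range(n)}
        for a, b in edges:
            s = strengths[tuple(sorted((a, b)))]
            wdeg[a] += s
            wdeg[b] += s
        pairs = [(wdeg[a], wdeg[b]) for a, b in edges]
        w = np.array([strengths[tuple(sorted(e))] for e in edges])
        assert pm.degree_correlation(g, weighted=True).r == pytest.approx(
            _edge_pearson(pairs, w)
        )
        # excess variant subtracts the focal edge from both endpoints
        pairs_x = [
            (
                wdeg[a] - strengths[tuple(sorted((a, b)))],
                wdeg[b] - strengths[tuple(sorted((a, b)))],
            )
            for a, b in edges
        ]
        assert pm.degree_correlation(g, weighted=True, excess=True).r == pytest.approx(
            _edge_pearson(pairs_x, w)
        )
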