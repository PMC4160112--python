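"""Shared fixtures and the independent brute-force shortest-path oracle.

The oracle enumerates *all* simple paths between every node pair by
depth-first search and derives betweenness, edge betweenness and
closeness from first principles; it shares no code path with the
package's centrality implementations.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
import pytest

import polydomy as pm


# ---------------------------------------------------------------------------
# brute-force centrality oracle


def _all_simple_paths(adj, s, t):
    """Yield every simple s->t path as a list of nodes (DFS)."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def brute_force_centralities(nodes, edges, dist):
    """Betweenness, edge betweenness and closeness by path enumeration.

    ``edges`` is a list of (a, b) tuples; ``dist`` maps each sorted edge
    tuple to a positive traversal cost.  Returns raw (unnormalised)
    betweenness with fractional credit for ties, edge betweenness keyed
    by sorted tuple, and closeness (n-1)/sum-of-distances.
    """
    adj = defaultdict(list)
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    node_bet = {v: 0.0 for v in nodes}
    edge_bet = {tuple(sorted(e)): 0.0 for e in edges}
    total_dist = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t))
        costs = [
            sum(dist[tuple(sorted((p[i], p[i + 1])))] for i in range(len(p) - 1))
            for p in paths
        ]
        best = min(costs)
        shortest = [p for p, c in zip(paths, costs) if abs(c - best) < 1e-12]
        total_dist[s] += best
        total_dist[t] += best
        k = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                node_bet[v] += 1.0 / k
            for i in range(len(p) - 1):
                edge_bet[tuple(sorted((p[i], p[i + 1])))] += 1.0 / k
    n = len(nodes)
    closeness = {v: (n - 1) / total_dist[v] for v in nodes}
    return node_bet, edge_bet, closeness


def random_connected_graph(rng, max_nodes=8):
    """A random connected simple graph with strength-attributed edges."""
    n = int(rng.integers(3, max_nodes + 1))
    while True:
        p = rng.uniform(0.3, 0.9)
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        # connectivity via union-find
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            parent[find(a)] = find(b)
        if len(edges) >= n - 1 and len({find(i) for i in range(n)}) == 1:
            break
    strengths = {tuple(sorted(e)): float(rng.uniform(0.2, 2.0)) for e in edges}
    return n, edges, strengths


def graph_with_strengths(n, edges, strengths):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a, b in edges:
        g.add_edge(a, b, strength=strengths[tuple(sorted((a, b)))])
    return g


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def demo_colony():
    """The 7-nest example colony with all derived quantities computed."""
    net = pm.example_colony()
    pm.compute_all(net)
    return net


@pytest.fixture(scope="session")
def small_study():
    """A generated 10-colony study with derived quantities computed."""
    networks, truth = pm.generate_study(pm.GeneratorConfig(seed=11))
    for net in networks:
        pm.compute_all(net)
    return networks, truth


@pytest.fixture(scope="session")
def study_arrays(small_study):
    networks, _ = small_study
    return [pm.colony_arrays(net) for net in networks]


def identity_perms(cols):
    return [np.arange(c.n) for c in cols]
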