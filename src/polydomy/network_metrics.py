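"""Connectedness, centrality and assortativity on colony networks.

All measures come in an unweighted variant (every trail counts as one
step) and a strength-weighted variant.  For the weighted shortest-path
measures an edge's traversal cost is a decreasing transform of its
strength — a stronger trail is a shorter channel.  Two transforms are
provided: ``"inverse"`` (cost = 1/S, the standard flow-network reading)
and ``"neglog"`` (cost = -ln S, additive over independent multiplicative
capacities; requires S < 1 so that costs stay positive).

Betweenness values are raw shortest-path counts with fractional credit
shared among tied shortest paths (set ``normalized=True`` for the
pair-count-normalised convention).  On a disconnected graph, betweenness
and closeness are computed per connected component and the result is
flagged, never silently mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .colony import ColonyNetwork, to_graph
from .errors import DomainError

__all__ = [
    "AssortativityResult",
    "strength_graph",
    "degree_and_weighted_degree",
    "node_betweenness",
    "trail_betweenness",
    "closeness",
    "newman_assortativity",
    "degree_correlation",
    "nest_metrics_table",
]

_DISTANCE_KEY = "_distance"


def strength_graph(
    network_or_graph: Union[ColonyNetwork, nx.Graph],
    transform: str = "inverse",
) -> nx.Graph:
    """Internest graph with a per-edge traversal cost derived from strength.

    The cost lands in the ``"_distance"`` edge attribute.  Every edge must
    carry a positive ``strength`` and the resulting cost must be positive
    (``neglog`` therefore requires strengths below 1).
    """
    g = network_or_graph if isinstance(network_or_graph, nx.Graph) else to_graph(
        network_or_graph
    )
    g = g.copy()
    for a, b, data in g.edges(data=True):
        s = data.get("strength")
        if s is None or s <= 0:
            raise DomainError(
                f"edge ({a}, {b}): positive strength required for weighted metrics"
            )
        if transform == "inverse":
            d = 1.0 / s
        elif transform == "neglog":
            d = -math.log(s)
        else:
            raise ValueError(f"unknown distance transform {transform!r}")
        if d <= 0:
            raise DomainError(
                f"edge ({a}, {b}): non-positive distance {d} under {transform!r}"
            )
        data[_DISTANCE_KEY] = d
    return g


def _as_graph(network_or_graph) -> nx.Graph:
    if isinstance(network_or_graph, nx.Graph):
        return network_or_graph
    return to_graph(network_or_graph)


def degree_and_weighted_degree(network_or_graph) -> dict[str, tuple[int, float]]:
    """Per nest: (number of connected nests, sum of incident trail strengths)."""
    g = _as_graph(network_or_graph)
    out: dict[str, tuple[int, float]] = {}
    for node in g.nodes:
        deg = g.degree(node)
        wdeg = 0.0
        for _, _, data in g.edges(node, data=True):
            s = data.get("strength")
            if s is None:
                raise DomainError(
                    f"node {node}: edge without strength in weighted degree"
                )
            wdeg += s
        out[node] = (int(deg), float(wdeg))
    return out


def _weighted_graph(network_or_graph, weighted: bool, transform: str) -> tuple[
    nx.Graph, Optional[str]
]:
    g = _as_graph(network_or_graph)
    if weighted:
        return strength_graph(g, transform), _DISTANCE_KEY
    return g, None


def node_betweenness(
    network_or_graph,
    weighted: bool = False,
    transform: str = "inverse",
    normalized: bool = False,
) -> dict[str, float]:
    """Shortest-path betweenness of each nest.

    For every unordered pair (s, t) the fraction of shortest s–t paths
    passing through the nest is accumulated; ties share credit.
    """
    g, key = _weighted_graph(network_or_graph, weighted, transform)
    return dict(nx.betweenness_centrality(g, weight=key, normalized=normalized))


def trail_betweenness(
    network_or_graph,
    weighted: bool = False,
    transform: str = "inverse",
    normalized: bool = False,
) -> dict[tuple, float]:
    """Shortest-path betweenness of each internest trail (edge)."""
    g, key = _weighted_graph(network_or_graph, weighted, transform)
    raw = nx.edge_betweenness_centrality(g, weight=key, normalized=normalized)
    return {tuple(sorted(e)): v for e, v in raw.items()}


def closeness(
    network_or_graph,
    weighted: bool = False,
    transform: str = "inverse",
) -> tuple[dict[str, float], bool]:
    """Closeness of each nest: (n_reachable - 1) / sum of distances.

    Returns ``(values, per_component)``; ``per_component`` is True when
    the graph is disconnected, in which case each value is relative to
    the nest's own component.  A singleton component has undefined
    closeness, reported as NaN.
    """
    g, key = _weighted_graph(network_or_graph, weighted, transform)
    per_component = g.number_of_nodes() > 0 and not nx.is_connected(g)
    vals = {}
    for node in g.nodes:
        lengths = nx.single_source_dijkstra_path_length(g, node, weight=key) if key \
            else nx.single_source_shortest_path_length(g, node)
        total = sum(d for t, d in lengths.items() if t != node)
        reachable = len(lengths) - 1
        vals[node] = reachable / total if reachable > 0 else float("nan")
    return vals, per_component


@dataclass(frozen=True)
class AssortativityResult:
    """Newman assortativity of a scalar nest attribute over the trails."""

    attribute_name: str
    r: float  # in [-1, 1]; NaN when undefined
    weighted: bool
    n_edges: int
    undefined: bool = False


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / math.sqrt(vx * vy))


def newman_assortativity(
    network_or_graph,
    attribute: Union[str, Mapping[str, float]],
    weighted: bool = False,
    attribute_name: Optional[str] = None,
) -> AssortativityResult:
    """Newman's assortativity coefficient r for a scalar nest attribute.

    r is the Pearson correlation of the attribute across the two ends of
    every trail, symmetrised so each undirected trail contributes both
    orderings.  The weighted variant weights each trail's contribution by
    its strength.  Zero attribute variance over edge endpoints makes r
    undefined (flagged, not NaN-propagated downstream).
    """
    g = _as_graph(network_or_graph)
    if isinstance(attribute, str):
        values = {n: g.nodes[n][attribute] for n in g.nodes}
        name = attribute_name or attribute
    else:
        values = dict(attribute)
        name = attribute_name or "attribute"
    missing = [n for n in g.nodes if n not in values or values[n] is None]
    if missing:
        raise DomainError(f"attribute {name!r} missing for nests {sorted(missing)}")

    xs, ys, ws = [], [], []
    for a, b, data in g.edges(data=True):
        w = 1.0
        if weighted:
            s = data.get("strength")
            if s is None or s < 0:
                raise DomainError(f"edge ({a}, {b}): strength required when weighted")
            w = float(s)
        xs.append(float(values[a]))
        ys.append(float(values[b]))
        ws.append(w)
    n_edges = len(xs)
    if n_edges < 2:
        return AssortativityResult(name, float("nan"), weighted, n_edges, True)
    # symmetrise: each undirected edge contributes both orderings
    x = np.array(xs + ys)
    y = np.array(ys + xs)
    w = np.array(ws + ws)
    if w.sum() <= 0:
        return AssortativityResult(name, float("nan"), weighted, n_edges, True)
    r = _weighted_pearson(x, y, w)
    undefined = math.isnan(r)
    return AssortativityResult(name, r, weighted, n_edges, undefined)


def degree_correlation(
    network_or_graph,
    weighted: bool = True,
    excess: bool = False,
) -> AssortativityResult:
    """Assortment by weighted degree (the "degree correlation").

    With ``excess=False`` (default, simplest reading) each endpoint's
    weighted degree includes the focal trail's own strength; with
    ``excess=True`` the focal trail is subtracted from both endpoints
    before correlating (the excess-degree convention).
    """
    g = _as_graph(network_or_graph)
    wdeg = {n: wd for n, (_, wd) in degree_and_weighted_degree(g).items()}
    if not excess:
        return newman_assortativity(
            g, wdeg, weighted=weighted, attribute_name="weighted_degree"
        )
    xs, ys, ws = [], [], []
    for a, b, data in g.edges(data=True):
        s = float(data.get("strength", 0.0))
        xs.append(wdeg[a] - s)
        ys.append(wdeg[b] - s)
        ws.append(s if weighted else 1.0)
    if len(xs) < 2:
        return AssortativityResult(
            "excess_weighted_degree", float("nan"), weighted, len(xs), True
        )
    x = np.array(xs + ys)
    y = np.array(ys + xs)
    w = np.array(ws + ws)
    if w.sum() <= 0:
        return AssortativityResult(
            "excess_weighted_degree", float("nan"), weighted, len(xs), True
        )
    r = _weighted_pearson(x, y, w)
    return AssortativityResult(
        "excess_weighted_degree", r, weighted, len(xs), math.isnan(r)
    )


def nest_metrics_table(
    network: ColonyNetwork, transform: str = "inverse"
) -> pd.DataFrame:
    """All per-nest metrics for one colony as a tidy frame."""
    g = to_graph(network)
    deg = degree_and_weighted_degree(g)
    bet = node_betweenness(g)
    wbet = node_betweenness(g, weighted=True, transform=transform)
    clo, per_comp = closeness(g)
    wclo, _ = closeness(g, weighted=True, transform=transform)
    rows = [
        {
            "colony_id": network.colony_id,
            "nest_id": n,
            "degree": deg[n][0],
            "weighted_degree": deg[n][1],
            "betweenness": bet[n],
            "weighted_betweenness": wbet[n],
            "closeness": clo[n],
            "weighted_closeness": wclo[n],
            "per_component": per_comp,
        }
        for n in g.nodes
    ]
    return pd.DataFrame(rows)
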