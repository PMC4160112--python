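"""Domain model for polydomous colonies and its tabular/GraphML serialization.

A polydomous wood ant colony occupies several spatially separated nest
mounds connected by persistent trails of workers.  The colony is modelled
as an attributed undirected graph: nests are nodes, internest trails are
weighted edges, and foraging trails connect nests to trees hosting aphid
herds.  Raw field measurements (trail length, the distance needed to count
10 ants, mound dimensions, canopy photographs) are stored alongside the
derived quantities (trail strength, population estimate, foraging status)
which are filled in by :mod:`polydomy.trail_metrics`.

Interchange formats
-------------------
Comma-separated UTF-8 text with a header row and ``.`` decimal separator:

* ``nests.csv`` — nest_id, colony_id, x_m, y_m, diameter1_m, diameter2_m,
  height_m, optional canopy_cover in [0, 1], optional population.
* ``trees.csv`` — tree_id, colony_id, x_m, y_m.
* ``internest_trails.csv`` — colony_id, nest_a, nest_b, length_m and one of
  dist_to_10_ants_m or ants_per_m.
* ``foraging_trails.csv`` — colony_id, nest_id, tree_id, length_m and one of
  dist_to_10_ants_m or ants_per_m.

Graphs are exported as GraphML (nests + internest trails only).
Coordinates are planar site metres; no geographic CRS is attached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .errors import DomainError, FormatError, IntegrityError

__all__ = [
    "Nest",
    "Tree",
    "InternestTrail",
    "ForagingTrail",
    "ColonyNetwork",
    "read_colony",
    "read_study",
    "write_graphml",
    "read_graphml",
    "to_graph",
]


@dataclass
class Nest:
    """One nest mound.  Derived fields stay ``None`` until computed."""

    nest_id: str
    colony_id: str
    x: float = float("nan")
    y: float = float("nan")
    diameter_1: Optional[float] = None  # two perpendicular mound diameters, m
    diameter_2: Optional[float] = None
    height: Optional[float] = None  # mound height, m
    canopy_cover: Optional[float] = None  # fraction of dark pixels, [0, 1]
    volume: Optional[float] = None  # half-ellipsoid mound volume, m^3
    population: Optional[float] = None  # worker count ("nest size")
    amount_of_foraging: Optional[float] = None  # sum of foraging-trail strengths
    is_foraging: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("diameter_1", "diameter_2", "height"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"nest {self.nest_id}: {name} must be > 0, got {v}")
        if self.canopy_cover is not None and not 0.0 <= self.canopy_cover <= 1.0:
            raise DomainError(
                f"nest {self.nest_id}: canopy_cover must lie in [0, 1], "
                f"got {self.canopy_cover}"
            )
        if self.population is not None and self.population < 0:
            raise DomainError(f"nest {self.nest_id}: population must be >= 0")


@dataclass
class Tree:
    """A tree that may host aphid herds (a foraging-trail endpoint)."""

    tree_id: str
    x: float = float("nan")
    y: float = float("nan")


@dataclass
class InternestTrail:
    """Undirected weighted edge between two nests of one colony.

    ``ants_per_metre`` (w) and ``length`` (l) are measured in the field;
    ``strength`` S = w*l / mean population of the endpoints and the
    foraging ``category`` (F-F / nF-F / nF-nF) are derived.
    """

    nest_a: str
    nest_b: str
    length: float
    ants_per_metre: float
    strength: Optional[float] = None
    category: Optional[str] = None
    foraging_differential: Optional[float] = None
    excluded: Optional[bool] = None  # nF-nF trails are excluded from
    # differential analyses (differential identically 0)

    def __post_init__(self) -> None:
        if self.nest_a == self.nest_b:
            raise IntegrityError(f"self-loop trail at nest {self.nest_a}")
        if self.length <= 0:
            raise DomainError(f"trail {self.key}: length must be > 0")
        if self.ants_per_metre < 0:
            raise DomainError(f"trail {self.key}: ants_per_metre must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        """Order-free edge identity: (a, b) and (b, a) are the same trail."""
        return (self.nest_a, self.nest_b) if self.nest_a <= self.nest_b else (
            self.nest_b,
            self.nest_a,
        )


@dataclass
class ForagingTrail:
    """A trail from a nest to a tree; qualifies only above the clear-trail
    activity threshold (more than 10 ants per 40 cm, i.e. w > 25 ants/m)."""

    nest_id: str
    tree_id: str
    length: float
    ants_per_metre: float
    strength: Optional[float] = None  # w*l / population of origin nest

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DomainError(
                f"foraging trail {self.nest_id}->{self.tree_id}: length must be > 0"
            )
        if self.ants_per_metre < 0:
            raise DomainError(
                f"foraging trail {self.nest_id}->{self.tree_id}: "
                "ants_per_metre must be >= 0"
            )


@dataclass
class ColonyNetwork:
    """One colony: nests, trees and both kinds of trails, cross-referenced."""

    colony_id: str
    nests: dict[str, Nest] = field(default_factory=dict)
    trees: dict[str, Tree] = field(default_factory=dict)
    internest_trails: list[InternestTrail] = field(default_factory=list)
    foraging_trails: list[ForagingTrail] = field(default_factory=list)

    @property
    def n_nests(self) -> int:
        return len(self.nests)

    @property
    def n_internest_trails(self) -> int:
        return len(self.internest_trails)

    def validate(self, warn_disconnected: bool = True) -> None:
        """Check referential integrity; warn (not fail) on disconnection.

        A polydomous colony is defined by communication between its nests,
        so a disconnected internest graph is suspicious — but a user may
        load partial data deliberately, hence a warning.
        """
        dangling: list[str] = []
        seen: set[tuple[str, str]] = set()
        for t in self.internest_trails:
            for nid in (t.nest_a, t.nest_b):
                if nid not in self.nests:
                    dangling.append(nid)
            if t.key in seen:
                raise IntegrityError(
                    f"colony {self.colony_id}: duplicate internest trail {t.key}"
                )
            seen.add(t.key)
        for ft in self.foraging_trails:
            if ft.nest_id not in self.nests:
                dangling.append(ft.nest_id)
            if ft.tree_id not in self.trees:
                dangling.append(ft.tree_id)
        if dangling:
            raise IntegrityError(
                f"colony {self.colony_id}: unresolved endpoint ids "
                f"{sorted(set(dangling))}"
            )
        if warn_disconnected and self.n_nests:
            g = to_graph(self)
            if not nx.is_connected(g):
                comps = [sorted(c) for c in nx.connected_components(g)]
                warnings.warn(
                    f"colony {self.colony_id}: internest graph is disconnected "
                    f"({len(comps)} components: {comps})",
                    stacklevel=2,
                )


def to_graph(network: ColonyNetwork) -> nx.Graph:
    """Internest graph as a networkx Graph; available attributes attached."""
    g = nx.Graph()
    for nid, nest in network.nests.items():
        attrs = {
            k: v
            for k, v in (
                ("population", nest.population),
                ("canopy_cover", nest.canopy_cover),
                ("is_foraging", nest.is_foraging),
                ("amount_of_foraging", nest.amount_of_foraging),
            )
            if v is not None
        }
        g.add_node(nid, **attrs)
    for t in network.internest_trails:
        attrs = {"length": t.length, "ants_per_metre": t.ants_per_metre}
        if t.strength is not None:
            attrs["strength"] = t.strength
        if t.category is not None:
            attrs["category"] = t.category
        g.add_edge(t.nest_a, t.nest_b, **attrs)
    return g


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _ants_per_m_column(df: pd.DataFrame, path) -> pd.Series:
    """Accept either a direct ants_per_m column or the field measure
    dist_to_10_ants_m (distance to count 10 ants; w = 10 / dist)."""
    if "ants_per_m" in df.columns:
        return df["ants_per_m"].astype(float)
    if "dist_to_10_ants_m" in df.columns:
        dist = df["dist_to_10_ants_m"].astype(float)
        if (dist <= 0).any():
            raise DomainError(f"{path}: dist_to_10_ants_m must be > 0")
        return 10.0 / dist
    raise FormatError(
        f"{path}: missing required column(s) "
        "['ants_per_m' or 'dist_to_10_ants_m']"
    )


def _opt(v) -> Optional[float]:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_study(
    nest_table_path,
    tree_table_path,
    internest_table_path,
    foraging_table_path,
) -> list[ColonyNetwork]:
    """Read every colony present in the four CSV tables.

    Returns one validated :class:`ColonyNetwork` per distinct ``colony_id``
    in the nest table, ordered by colony id.
    """
    nests = pd.read_csv(nest_table_path)
    trees = pd.read_csv(tree_table_path)
    internest = pd.read_csv(internest_table_path)
    foraging = pd.read_csv(foraging_table_path)

    _require_columns(nests, ["nest_id", "colony_id", "x_m", "y_m"], nest_table_path)
    _require_columns(trees, ["tree_id", "colony_id", "x_m", "y_m"], tree_table_path)
    if len(internest):
        _require_columns(
            internest,
            ["colony_id", "nest_a", "nest_b", "length_m"],
            internest_table_path,
        )
        internest = internest.assign(
            _w=_ants_per_m_column(internest, internest_table_path)
        )
    if len(foraging):
        _require_columns(
            foraging,
            ["colony_id", "nest_id", "tree_id", "length_m"],
            foraging_table_path,
        )
        foraging = foraging.assign(_w=_ants_per_m_column(foraging, foraging_table_path))

    networks: list[ColonyNetwork] = []
    for colony_id in sorted(nests["colony_id"].astype(str).unique()):
        net = ColonyNetwork(colony_id=colony_id)
        sub = nests[nests["colony_id"].astype(str) == colony_id]
        for _, row in sub.iterrows():
            nid = str(row["nest_id"])
            if nid in net.nests:
                raise IntegrityError(f"colony {colony_id}: duplicate nest id {nid}")
            net.nests[nid] = Nest(
                nest_id=nid,
                colony_id=colony_id,
                x=float(row["x_m"]),
                y=float(row["y_m"]),
                diameter_1=_opt(row.get("diameter1_m")),
                diameter_2=_opt(row.get("diameter2_m")),
                height=_opt(row.get("height_m")),
                canopy_cover=_opt(row.get("canopy_cover")),
                population=_opt(row.get("population")),
            )
        for _, row in trees[trees["colony_id"].astype(str) == colony_id].iterrows():
            tid = str(row["tree_id"])
            if tid in net.trees:
                raise IntegrityError(f"colony {colony_id}: duplicate tree id {tid}")
            net.trees[tid] = Tree(tree_id=tid, x=float(row["x_m"]), y=float(row["y_m"]))
        if len(internest):
            sub = internest[internest["colony_id"].astype(str) == colony_id]
            for _, row in sub.iterrows():
                net.internest_trails.append(
                    InternestTrail(
                        nest_a=str(row["nest_a"]),
                        nest_b=str(row["nest_b"]),
                        length=float(row["length_m"]),
                        ants_per_metre=float(row["_w"]),
                    )
                )
        if len(foraging):
            sub = foraging[foraging["colony_id"].astype(str) == colony_id]
            for _, row in sub.iterrows():
                net.foraging_trails.append(
                    ForagingTrail(
                        nest_id=str(row["nest_id"]),
                        tree_id=str(row["tree_id"]),
                        length=float(row["length_m"]),
                        ants_per_metre=float(row["_w"]),
                    )
                )
        net.validate()
        networks.append(net)
    return networks


def read_colony(
    nest_table_path,
    tree_table_path,
    internest_table_path,
    foraging_table_path,
    colony_id: Optional[str] = None,
) -> ColonyNetwork:
    """Read a single colony from the four CSV tables.

    If the tables span several colonies, ``colony_id`` selects one;
    omitting it with multi-colony tables is a format error.
    """
    networks = read_study(
        nest_table_path, tree_table_path, internest_table_path, foraging_table_path
    )
    if colony_id is not None:
        for net in networks:
            if net.colony_id == str(colony_id):
                return net
        raise IntegrityError(f"colony id {colony_id!r} not present in tables")
    if len(networks) != 1:
        raise FormatError(
            f"tables contain {len(networks)} colonies; pass colony_id to select one"
        )
    return networks[0]


def write_graphml(network: ColonyNetwork, path) -> None:
    """Write the internest nest graph as GraphML.

    Nodes carry population, canopy_cover, is_foraging and
    amount_of_foraging; edges carry length, ants_per_metre, strength and
    category.  Unset (None) attributes are omitted.  The export
    round-trips through :func:`read_graphml` without loss of the listed
    attributes.  Trees and foraging trails are not part of the GraphML
    schema; use the CSV tables for a full round trip.
    """
    g = to_graph(network)
    g.graph["colony_id"] = network.colony_id
    nx.write_graphml(g, path)


def read_graphml(path) -> ColonyNetwork:
    """Inverse of :func:`write_graphml` for the nest graph."""
    g = nx.read_graphml(path)
    net = ColonyNetwork(colony_id=str(g.graph.get("colony_id", Path(path).stem)))
    for nid, data in g.nodes(data=True):
        net.nests[str(nid)] = Nest(
            nest_id=str(nid),
            colony_id=net.colony_id,
            population=_opt(data.get("population")),
            canopy_cover=_opt(data.get("canopy_cover")),
            amount_of_foraging=_opt(data.get("amount_of_foraging")),
            is_foraging=(
                bool(data["is_foraging"]) if "is_foraging" in data else None
            ),
        )
    for a, b, data in g.edges(data=True):
        trail = InternestTrail(
            nest_a=str(a),
            nest_b=str(b),
            length=float(data["length"]),
            ants_per_metre=float(data.get("ants_per_metre", 0.0)),
        )
        trail.strength = _opt(data.get("strength"))
        trail.category = data.get("category")
        net.internest_trails.append(trail)
    return net
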