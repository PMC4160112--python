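"""Synthetic polydomous colony networks with known ground truth.

The real networks this package analyses exist only as field maps, so the
generator provides colonies with the same statistical shape for
calibration, power and parameter-recovery work:

* 10 colonies per study, 7–22 nests and at most 30 internest trails each,
  with trail counts barely above a spanning tree (edge/node ratio about
  1.0–1.4) — the topology is a Euclidean minimum spanning tree over
  randomly placed nests plus a few short extra edges, because the real
  networks are spatial and sparse;
* a foraging/nonforaging nest dichotomy (foraging fraction ≈ 0.54) with
  class-contrasted worker populations (right-skewed lognormal; foraging
  nests larger) and canopy cover (beta; foraging nests more shaded);
* category-conditional trail lengths (F-F trails longest);
* internest trail ant loads generated as ``A = A0 + β·differential·p̄``
  on nF-F trails (A0 an iid lognormal baseline load, p̄ the mean endpoint
  population), so trail strength A/p̄ is the baseline strength plus
  β·differential.  β is solved against the realised sample so the pooled
  nF-F differential–strength Pearson correlation equals ``rho_target``
  (default 0.36).  This linear mechanism is the minimal model producing
  the observed correlation, a modelling convenience rather than a claim
  about ant behaviour.

With ``rho_target = 0`` every measured quantity on the trails is drawn
independently of the nest attribute bundles, so the attribute bundles
are exchangeable over the nests of a colony given the trail structure —
exactly the null hypothesis of the QAP node-label permutation test.

Dispersion defaults are reconstructed from published class means and
standard errors (SD = SE·√n) and are therefore approximate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .colony import ColonyNetwork, ForagingTrail, InternestTrail, Nest, Tree
from .errors import GenerationError
from .trail_metrics import foraging_trail_strength

__all__ = [
    "GeneratorConfig",
    "generate_colony",
    "generate_study",
    "write_fixture",
    "example_colony",
]

#: Nominal packing density used to back out mound dimensions from a
#: generated worker population (workers per m^3 of mound).
WORKER_DENSITY = 50_000.0


@dataclass
class GeneratorConfig:
    """Study conditions for the generator.

    Class keys are "F"/"nF" for nests and "F-F"/"nF-F"/"nF-nF" for
    trails.  Means are in workers (sizes), fraction (canopy) and metres
    (lengths); SDs reconstructed from published standard errors.
    """

    n_colonies: int = 10
    nests_per_colony: tuple[int, int] = (7, 22)
    trees_per_colony: tuple[int, int] = (4, 38)
    foraging_fraction: float = 75.0 / 140.0
    size_mean: dict = field(
        default_factory=lambda: {"F": 72_630.0, "nF": 22_760.0}
    )
    size_sd: dict = field(
        default_factory=lambda: {"F": 206_983.0, "nF": 39_691.0}
    )
    canopy_mean: dict = field(default_factory=lambda: {"F": 0.30, "nF": 0.21})
    canopy_sd: dict = field(default_factory=lambda: {"F": 0.2252, "nF": 0.1935})
    trail_length_mean: dict = field(
        default_factory=lambda: {"F-F": 6.72, "nF-F": 3.18, "nF-nF": 2.61}
    )
    trail_length_sd: dict = field(
        default_factory=lambda: {"F-F": 8.82, "nF-F": 2.13, "nF-nF": 2.94}
    )
    edge_node_ratio: tuple[float, float] = (1.0, 1.4)
    max_trails_per_colony: int = 30
    rho_target: float = 0.36  # pooled nF-F differential-strength correlation
    ant_load_mean: float = 150.0  # baseline ants per internest trail
    ant_load_cv: float = 1.0
    foraging_ants_per_m: tuple[float, float] = (26.0, 120.0)
    foraging_trails_per_nest: tuple[int, int] = (1, 3)
    foraging_length_mean: float = 4.0  # metres
    foraging_length_cv: float = 0.6
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("nests_per_colony", "trees_per_colony", "foraging_trails_per_nest"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise GenerationError(f"{name}: empty or invalid range ({lo}, {hi})")
        if not 0.0 <= self.foraging_fraction <= 1.0:
            raise GenerationError("foraging_fraction must lie in [0, 1]")
        if not -1.0 < self.rho_target < 1.0:
            raise GenerationError("rho_target must lie in (-1, 1)")
        if self.ant_load_mean <= 0 or self.ant_load_cv <= 0:
            raise GenerationError("ant load mean and CV must be positive")
        if self.foraging_length_mean <= 0 or self.foraging_length_cv <= 0:
            raise GenerationError("foraging length mean and CV must be positive")
        if self.foraging_ants_per_m[0] <= 25.0:
            raise GenerationError(
                "foraging_ants_per_m must exceed the clear-trail threshold (25/m)"
            )
        if self.max_trails_per_colony < self.nests_per_colony[1] - 1:
            raise GenerationError(
                "max_trails_per_colony cannot accommodate a spanning tree"
            )


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Lognormal draws moment-matched to the given mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _beta(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Beta draws on [0, 1] moment-matched to the given mean and SD."""
    var = min(sd**2, 0.95 * mean * (1 - mean))
    k = mean * (1 - mean) / var - 1.0
    return rng.beta(mean * k, (1 - mean) * k, size)


@dataclass
class _Skeleton:
    """A colony before trail strengths are assigned."""

    network: ColonyNetwork
    nest_ids: list[str]
    is_foraging: np.ndarray
    amounts: np.ndarray
    edge_index: np.ndarray  # (m, 2) positions into nest_ids
    edge_category: list[str]
    edge_length: np.ndarray
    edge_mean_pop: np.ndarray
    edge_differential: np.ndarray
    edge_base_load: np.ndarray  # baseline ants per trail, iid of attributes


def _build_skeleton(
    config: GeneratorConfig, rng: np.random.Generator, colony_id: str
) -> _Skeleton:
    n = int(rng.integers(config.nests_per_colony[0], config.nests_per_colony[1] + 1))
    side = 6.0 * math.sqrt(n)
    pos = rng.uniform(0.0, side, size=(n, 2))

    status = rng.random(n) < config.foraging_fraction
    if config.foraging_fraction > 0 and not status.any():
        status[rng.integers(n)] = True

    sizes = np.empty(n)
    canopy = np.empty(n)
    for cls, mask in (("F", status), ("nF", ~status)):
        k = int(mask.sum())
        if k:
            sizes[mask] = _lognormal(rng, config.size_mean[cls], config.size_sd[cls], k)
            canopy[mask] = _beta(rng, config.canopy_mean[cls], config.canopy_sd[cls], k)

    # sparse spatial topology: Euclidean MST plus a few short extra edges
    dmat = squareform(pdist(pos))
    mst = minimum_spanning_tree(dmat).tocoo()
    edges = {tuple(sorted((int(i), int(j)))) for i, j in zip(mst.row, mst.col)}
    ratio = rng.uniform(*config.edge_node_ratio)
    target = int(np.clip(round(ratio * n), n - 1, config.max_trails_per_colony))
    candidates = sorted(
        (
            (dmat[i, j], (i, j))
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in edges
        ),
    )
    extra = target - len(edges)
    if extra > 0 and candidates:
        pool = candidates[: max(3 * extra, 10)]
        picks = rng.choice(len(pool), size=min(extra, len(pool)), replace=False)
        for k in picks:
            edges.add(pool[k][1])
    edge_index = np.array(sorted(edges), dtype=int)

    # trees, clustered around a handful of centres
    n_trees = int(rng.integers(config.trees_per_colony[0], config.trees_per_colony[1] + 1))
    n_centres = max(1, n_trees // 4)
    centres = rng.uniform(0.0, side, size=(n_centres, 2))
    tree_pos = centres[rng.integers(n_centres, size=n_trees)] + rng.normal(
        0.0, side / 8.0, size=(n_trees, 2)
    )
    tree_pos = np.clip(tree_pos, 0.0, side)

    net = ColonyNetwork(colony_id=colony_id)
    nest_ids = [f"{colony_id}-N{i + 1:02d}" for i in range(n)]
    for i, nid in enumerate(nest_ids):
        vol = sizes[i] / WORKER_DENSITY
        d = (18.0 * vol / math.pi) ** (1.0 / 3.0)
        net.nests[nid] = Nest(
            nest_id=nid,
            colony_id=colony_id,
            x=float(pos[i, 0]),
            y=float(pos[i, 1]),
            diameter_1=d,
            diameter_2=d,
            height=d / 3.0,
            canopy_cover=float(canopy[i]),
            population=float(sizes[i]),
        )
    tree_ids = [f"{colony_id}-T{i + 1:02d}" for i in range(n_trees)]
    for i, tid in enumerate(tree_ids):
        net.trees[tid] = Tree(tree_id=tid, x=float(tree_pos[i, 0]), y=float(tree_pos[i, 1]))

    # foraging trails: each foraging nest reaches its 1-3 nearest trees;
    # measured trail lengths are drawn, not geometric, so nest attribute
    # bundles stay independent of the spatial embedding
    amounts = np.zeros(n)
    lo_t, hi_t = config.foraging_trails_per_nest
    for i in np.flatnonzero(status):
        k = int(rng.integers(lo_t, min(hi_t, n_trees) + 1))
        dists = np.hypot(*(tree_pos - pos[i]).T)
        for j in np.argsort(dists)[:k]:
            w = float(rng.uniform(*config.foraging_ants_per_m))
            length = float(
                _lognormal(
                    rng,
                    config.foraging_length_mean,
                    config.foraging_length_cv * config.foraging_length_mean,
                    1,
                )[0]
            )
            net.foraging_trails.append(
                ForagingTrail(
                    nest_id=nest_ids[i],
                    tree_id=tree_ids[j],
                    length=length,
                    ants_per_metre=w,
                )
            )
            amounts[i] += foraging_trail_strength(w, length, sizes[i])

    m = len(edge_index)
    cats = []
    for a, b in edge_index:
        fa, fb = status[a], status[b]
        cats.append("F-F" if fa and fb else ("nF-nF" if not fa and not fb else "nF-F"))
    lengths = np.empty(m)
    for cat in ("F-F", "nF-F", "nF-nF"):
        mask = np.array([c == cat for c in cats])
        if mask.any():
            lengths[mask] = _lognormal(
                rng,
                config.trail_length_mean[cat],
                config.trail_length_sd[cat],
                int(mask.sum()),
            )
    mean_pop = sizes[edge_index].mean(axis=1)
    differential = np.abs(amounts[edge_index[:, 0]] - amounts[edge_index[:, 1]])
    base_load = _lognormal(
        rng, config.ant_load_mean, config.ant_load_cv * config.ant_load_mean, m
    )
    return _Skeleton(
        network=net,
        nest_ids=nest_ids,
        is_foraging=status,
        amounts=amounts,
        edge_index=edge_index,
        edge_category=cats,
        edge_length=lengths,
        edge_mean_pop=mean_pop,
        edge_differential=differential,
        edge_base_load=base_load,
    )


def _calibrate_beta(config: GeneratorConfig, skeletons: list[_Skeleton]) -> float:
    """β making the pooled nF-F differential-strength Pearson hit rho_target.

    With strength S = A0/p̄ + β·d (baseline strength u = A0/p̄ plus the
    coupling), the sample correlation corr(d, u + β·d) = ρ solves a
    quadratic in β whose admissible root is

        β = (-c + sign(ρ)·|ρ|·sqrt((v_d v_u - c²)/(1 - ρ²))) / v_d

    where c = cov(d, u) and v are sample variances.  The realised pooled
    correlation then equals rho_target exactly up to the rare clipping of
    negative loads.
    """
    rho = config.rho_target
    if rho == 0.0:
        return 0.0
    diffs, base = [], []
    for s in skeletons:
        mask = np.array([c == "nF-F" for c in s.edge_category], dtype=bool)
        diffs.append(s.edge_differential[mask])
        base.append(s.edge_base_load[mask] / s.edge_mean_pop[mask])
    d = np.concatenate(diffs or [np.empty(0)])
    u = np.concatenate(base or [np.empty(0)])
    if d.size < 3 or d.std() == 0:
        return 0.0
    vd, vu = d.var(), u.var()
    c = float(np.cov(d, u, bias=True)[0, 1])
    disc = vd * vu - c**2
    if disc <= 0:
        return 0.0
    beta = (-c + math.copysign(1.0, rho) * abs(rho) * math.sqrt(
        disc / (1.0 - rho**2)
    )) / vd
    return float(beta)


def _assign_strengths(
    config: GeneratorConfig,
    skeletons: list[_Skeleton],
    beta: float,
) -> None:
    """Fill internest trails with (w, l) realising the ant-load model."""
    for s in skeletons:
        for e in range(len(s.edge_index)):
            load = s.edge_base_load[e]
            if s.edge_category[e] == "nF-F":
                load = load + beta * s.edge_differential[e] * s.edge_mean_pop[e]
            load = max(1e-3, load)
            w = load / s.edge_length[e]
            a, b = s.edge_index[e]
            s.network.internest_trails.append(
                InternestTrail(
                    nest_a=s.nest_ids[a],
                    nest_b=s.nest_ids[b],
                    length=float(s.edge_length[e]),
                    ants_per_metre=float(w),
                )
            )


def _ground_truth(
    config: GeneratorConfig, skeletons: list[_Skeleton], beta: float
) -> dict:
    return {
        "seed": config.seed,
        "rho_target": config.rho_target,
        "beta": beta,
        "ant_load_mean": config.ant_load_mean,
        "ant_load_cv": config.ant_load_cv,
        "n_nff_trails": int(
            sum(c == "nF-F" for s in skeletons for c in s.edge_category)
        ),
        "colonies": {
            s.network.colony_id: {
                "n_nests": len(s.nest_ids),
                "n_trails": len(s.edge_index),
                "is_foraging": {
                    nid: bool(f) for nid, f in zip(s.nest_ids, s.is_foraging)
                },
            }
            for s in skeletons
        },
    }


def generate_colony(
    config: GeneratorConfig,
    rng: np.random.Generator,
    colony_id: str = "C01",
) -> tuple[ColonyNetwork, dict]:
    """One synthetic colony plus its ground-truth record.

    The strength-differential coupling β is calibrated from this colony's
    own nF-F trails; for a study-level pooled calibration use
    :func:`generate_study`.
    """
    config.validate()
    skeleton = _build_skeleton(config, rng, colony_id)
    beta = _calibrate_beta(config, [skeleton])
    _assign_strengths(config, [skeleton], beta)
    return skeleton.network, _ground_truth(config, [skeleton], beta)


def generate_study(
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ColonyNetwork], dict]:
    """A full study of independent colonies with pooled β calibration.

    With ``rng`` omitted, randomness flows from ``config.seed`` and the
    output is reproducible byte-for-byte.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    skeletons = [
        _build_skeleton(config, rng, f"C{i + 1:02d}")
        for i in range(config.n_colonies)
    ]
    beta = _calibrate_beta(config, skeletons)
    _assign_strengths(config, skeletons, beta)
    return [s.network for s in skeletons], _ground_truth(config, skeletons, beta)


_NEST_COLS = [
    "nest_id",
    "colony_id",
    "x_m",
    "y_m",
    "diameter1_m",
    "diameter2_m",
    "height_m",
    "canopy_cover",
    "population",
]


def write_fixture(
    networks: list[ColonyNetwork],
    directory,
    ground_truth: Optional[dict] = None,
    config: Optional[GeneratorConfig] = None,
) -> Path:
    """Write networks in the exact CSV layout the readers consume.

    Emits nests.csv, trees.csv, internest_trails.csv, foraging_trails.csv,
    a manifest.json, and optionally ground_truth.json / config.json.
    ``ants_per_m`` is stored directly so the round trip is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nests, trees, internest, foraging = [], [], [], []
    for net in networks:
        for n in net.nests.values():
            nests.append(
                {
                    "nest_id": n.nest_id,
                    "colony_id": net.colony_id,
                    "x_m": n.x,
                    "y_m": n.y,
                    "diameter1_m": n.diameter_1,
                    "diameter2_m": n.diameter_2,
                    "height_m": n.height,
                    "canopy_cover": n.canopy_cover,
                    "population": n.population,
                }
            )
        for t in net.trees.values():
            trees.append(
                {"tree_id": t.tree_id, "colony_id": net.colony_id, "x_m": t.x, "y_m": t.y}
            )
        for tr in net.internest_trails:
            internest.append(
                {
                    "colony_id": net.colony_id,
                    "nest_a": tr.nest_a,
                    "nest_b": tr.nest_b,
                    "length_m": tr.length,
                    "ants_per_m": tr.ants_per_metre,
                }
            )
        for ft in net.foraging_trails:
            foraging.append(
                {
                    "colony_id": net.colony_id,
                    "nest_id": ft.nest_id,
                    "tree_id": ft.tree_id,
                    "length_m": ft.length,
                    "ants_per_m": ft.ants_per_metre,
                }
            )
    pd.DataFrame(nests, columns=_NEST_COLS).to_csv(directory / "nests.csv", index=False)
    pd.DataFrame(trees, columns=["tree_id", "colony_id", "x_m", "y_m"]).to_csv(
        directory / "trees.csv", index=False
    )
    pd.DataFrame(
        internest, columns=["colony_id", "nest_a", "nest_b", "length_m", "ants_per_m"]
    ).to_csv(directory / "internest_trails.csv", index=False)
    pd.DataFrame(
        foraging, columns=["colony_id", "nest_id", "tree_id", "length_m", "ants_per_m"]
    ).to_csv(directory / "foraging_trails.csv", index=False)
    manifest = {
        "colonies": [net.colony_id for net in networks],
        "files": [
            "nests.csv",
            "trees.csv",
            "internest_trails.csv",
            "foraging_trails.csv",
        ],
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2, sort_keys=True) + "\n"
        )
    if config is not None:
        (directory / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
        )
    return directory


def example_colony() -> ColonyNetwork:
    """A small deterministic colony: 7 nests in a spanning tree of 6
    trails, 6 foraging nests each with a clear trail to its own tree, and
    1 nonforaging nest.  Handy for worked examples and table checks."""
    net = ColonyNetwork(colony_id="demo")
    pops = [60_000, 45_000, 80_000, 30_000, 55_000, 40_000, 12_000]
    canopy = [0.32, 0.28, 0.35, 0.25, 0.30, 0.27, 0.15]
    for i in range(7):
        nid = f"N{i + 1}"
        net.nests[nid] = Nest(
            nest_id=nid,
            colony_id="demo",
            x=float(3 * i),
            y=float((i % 2) * 2),
            canopy_cover=canopy[i],
            population=float(pops[i]),
        )
    # star-ish spanning tree around N3 and a short chain
    for a, b, length, w in [
        ("N1", "N3", 3.2, 40.0),
        ("N2", "N3", 2.8, 35.0),
        ("N3", "N4", 4.1, 30.0),
        ("N4", "N5", 2.5, 45.0),
        ("N5", "N6", 3.0, 38.0),
        ("N6", "N7", 2.2, 28.0),
    ]:
        net.internest_trails.append(
            InternestTrail(nest_a=a, nest_b=b, length=length, ants_per_metre=w)
        )
    for i in range(6):  # N7 forms no trail to any tree: nonforaging
        tid = f"T{i + 1}"
        net.trees[tid] = Tree(tree_id=tid, x=float(3 * i), y=-4.0)
        net.foraging_trails.append(
            ForagingTrail(
                nest_id=f"N{i + 1}",
                tree_id=tid,
                length=4.0 + 0.5 * i,
                ants_per_metre=30.0 + 5.0 * i,
            )
        )
    net.validate()
    return net
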