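"""End-to-end analysis of a set of polydomous colony networks.

:func:`run_analysis` takes field CSVs (or a generator configuration) and
reproduces the full battery of nest-network tests: trail strength by
trail type, foraging differential against strength by category, trail
length relationships, nest properties against network position, trail
strength against trail betweenness, per-colony assortativity with
Bonferroni correction, and the foraging/nonforaging nest contrasts.
Every network-based significance value comes from a QAP node-label
permutation test, blocked within colonies for pooled data.

To keep thousands of permutations cheap, each colony is lowered to a
:class:`ColonyArrays` view — flat numpy arrays of nest attributes plus a
fixed edge index — and every statistic recomputes its derived quantities
(trail strengths, categories, differentials, weighted degrees) from the
permuted attribute arrays on each draw.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .colony import ColonyNetwork, read_study, to_graph, write_graphml
from .errors import DomainError, UndefinedStatisticError
from .field_measures import PopulationCalibration
from .network_metrics import (
    closeness,
    degree_and_weighted_degree,
    node_betweenness,
    trail_betweenness,
)
from .qap import QAPResult, bonferroni, qap_test
from .synthetic import GeneratorConfig, generate_study
from .trail_metrics import (
    compute_all,
    nest_foraging_table,
    qualify_foraging_trail,
    trail_table,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "ColonyArrays",
    "colony_arrays",
    "run_analysis",
    "summarize_colony",
    "write_report",
]

logger = logging.getLogger("polydomy")

#: number of assortativity attributes tested per colony (nest size,
#: amount of foraging, weighted degree) — the Bonferroni family size
ASSORTATIVITY_ATTRIBUTES = ("population", "amount_of_foraging", "weighted_degree")


# ---------------------------------------------------------------------------
# fast per-colony views


@dataclass
class ColonyArrays:
    """Flat numeric view of one colony for permutation-heavy statistics.

    ``edges`` indexes into the nest arrays; ``degree``, ``betweenness``,
    ``closeness`` and ``edge_betweenness`` are the *unweighted* structural
    metrics, which are invariant under node-label permutation.
    """

    colony_id: str
    nest_ids: list[str]
    population: np.ndarray
    canopy: np.ndarray
    amount: np.ndarray
    is_foraging: np.ndarray
    edges: np.ndarray  # (m, 2)
    edge_w: np.ndarray  # ants per metre
    edge_l: np.ndarray  # metres
    degree: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    edge_betweenness: np.ndarray

    @property
    def n(self) -> int:
        return len(self.nest_ids)


def colony_arrays(network: ColonyNetwork) -> ColonyArrays:
    """Lower a fully derived colony to its array view."""
    nest_ids = list(network.nests)
    index = {nid: i for i, nid in enumerate(nest_ids)}
    nests = [network.nests[nid] for nid in nest_ids]
    for nest in nests:
        if nest.population is None or nest.amount_of_foraging is None:
            raise DomainError(
                f"nest {nest.nest_id}: derived fields missing; run compute_all first"
            )
    g = to_graph(network)
    bet = node_betweenness(g)
    clo, _ = closeness(g)
    ebet = trail_betweenness(g)
    edges = np.array(
        [[index[t.nest_a], index[t.nest_b]] for t in network.internest_trails],
        dtype=int,
    ).reshape(-1, 2)
    edge_keys = [
        tuple(sorted((t.nest_a, t.nest_b))) for t in network.internest_trails
    ]
    return ColonyArrays(
        colony_id=network.colony_id,
        nest_ids=nest_ids,
        population=np.array([n.population for n in nests], dtype=float),
        canopy=np.array(
            [math.nan if n.canopy_cover is None else n.canopy_cover for n in nests]
        ),
        amount=np.array([n.amount_of_foraging for n in nests], dtype=float),
        is_foraging=np.array([bool(n.is_foraging) for n in nests]),
        edge_w=np.array([t.ants_per_metre for t in network.internest_trails]),
        edge_l=np.array([t.length for t in network.internest_trails]),
        edges=edges,
        degree=np.array([g.degree(nid) for nid in nest_ids], dtype=float),
        betweenness=np.array([bet[nid] for nid in nest_ids]),
        closeness=np.array([clo[nid] for nid in nest_ids]),
        edge_betweenness=np.array([ebet[k] for k in edge_keys]),
    )


def _derived(col: ColonyArrays, perm: np.ndarray):
    """Recompute permutation-dependent derived quantities for one colony.

    Returns (strength, n_foraging_ends, differential) per edge, where
    n_foraging_ends is 0/1/2 encoding nF-nF / nF-F / F-F.
    """
    pop = col.population[perm]
    amount = col.amount[perm]
    forag = col.is_foraging[perm]
    a, b = col.edges[:, 0], col.edges[:, 1]
    strength = col.edge_w * col.edge_l / ((pop[a] + pop[b]) / 2.0)
    cat = forag[a].astype(int) + forag[b].astype(int)
    diff = np.abs(amount[a] - amount[b])
    return strength, cat, diff


_CAT_CODE = {"nF-nF": 0, "nF-F": 1, "F-F": 2}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise UndefinedStatisticError("fewer than 3 observations")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("zero variance")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3:
        raise UndefinedStatisticError("fewer than 3 observations")
    return _pearson(stats.rankdata(x), stats.rankdata(y))


def _fstat(values: np.ndarray, codes: np.ndarray) -> float:
    labels = np.unique(codes)
    if labels.size < 2 or values.size - labels.size < 1:
        raise UndefinedStatisticError("insufficient groups for F")
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in labels:
        v = values[codes == g]
        m = v.mean()
        ss_b += v.size * (m - grand) ** 2
        ss_w += float(((v - m) ** 2).sum())
    if ss_w == 0:
        raise UndefinedStatisticError("zero within-group variance")
    return float((ss_b / (labels.size - 1)) / (ss_w / (values.size - labels.size)))


# ---------------------------------------------------------------------------
# statistic factories (each closure recomputes derived values per permutation)


def _corr_diff_strength(cols, categories: Sequence[str], method="pearson"):
    wanted = {_CAT_CODE[c] for c in categories}
    corr = _pearson if method == "pearson" else _spearman

    def stat(perms):
        xs, ys = [], []
        for col, perm in zip(cols, perms):
            strength, cat, diff = _derived(col, perm)
            mask = np.isin(cat, list(wanted))
            xs.append(diff[mask])
            ys.append(strength[mask])
        return corr(np.concatenate(xs), np.concatenate(ys))

    return stat


def _f_by_category(cols, edge_values: Callable[[ColonyArrays, np.ndarray], np.ndarray]):
    def stat(perms):
        vals, codes = [], []
        for col, perm in zip(cols, perms):
            strength, cat, _ = _derived(col, perm)
            vals.append(edge_values(col, strength))
            codes.append(cat)
        return _fstat(np.concatenate(vals), np.concatenate(codes))

    return stat


def _corr_length_vs(cols, target: str, category: str):
    code = _CAT_CODE[category]

    def stat(perms):
        xs, ys = [], []
        for col, perm in zip(cols, perms):
            strength, cat, diff = _derived(col, perm)
            mask = cat == code
            xs.append(col.edge_l[mask])
            ys.append((strength if target == "strength" else diff)[mask])
        return _pearson(np.concatenate(xs), np.concatenate(ys))

    return stat


def _node_attr(col: ColonyArrays, perm: np.ndarray, name: str) -> np.ndarray:
    if name == "population":
        return col.population[perm]
    if name == "canopy_cover":
        return col.canopy[perm]
    if name == "amount_of_foraging":
        return col.amount[perm]
    raise KeyError(name)


def _weighted_degree(col: ColonyArrays, strength: np.ndarray) -> np.ndarray:
    wdeg = np.zeros(col.n)
    np.add.at(wdeg, col.edges[:, 0], strength)
    np.add.at(wdeg, col.edges[:, 1], strength)
    return wdeg


def _corr_metric_property(cols, metric: str, prop: str):
    def stat(perms):
        xs, ys = [], []
        for col, perm in zip(cols, perms):
            if metric == "weighted_degree":
                strength, _, _ = _derived(col, perm)
                x = _weighted_degree(col, strength)
            else:
                x = getattr(col, metric)
            xs.append(x)
            ys.append(_node_attr(col, perm, prop))
        return _pearson(np.concatenate(xs), np.concatenate(ys))

    return stat


def _f_attr_by_status(cols, prop: str):
    """Contrast of a nest attribute between foraging and nonforaging
    nests.  The attribute is permuted against the fixed status labels —
    permuting the whole bundle would leave the pairing intact."""
    codes = np.concatenate([c.is_foraging.astype(int) for c in cols])

    def stat(perms):
        vals = [
            _node_attr(col, perm, prop) for col, perm in zip(cols, perms)
        ]
        return _fstat(np.concatenate(vals), codes)

    return stat


def _corr_attr_attr(cols, prop_x: str, prop_y: str, foraging_only=False):
    """Association between two nest attributes: x stays fixed, y is
    permuted within colony (restricted to foraging nests on request)."""
    xs, ys = [], []
    for col in cols:
        mask = col.is_foraging if foraging_only else np.ones(col.n, bool)
        if mask.sum() == 0:
            continue
        xs.append(_node_attr(col, np.arange(col.n), prop_x)[mask])
        ys.append(_node_attr(col, np.arange(col.n), prop_y)[mask])
    x_fixed = np.concatenate(xs) if xs else np.empty(0)
    blocks = [len(y) for y in ys]

    def stat(perms):
        y = np.concatenate([arr[perm] for arr, perm in zip(ys, perms)])
        return _pearson(x_fixed, y)

    return stat, blocks, int(x_fixed.size)


def _corr_strength_edge_betweenness(cols):
    def stat(perms):
        xs, ys = [], []
        for col, perm in zip(cols, perms):
            strength, _, _ = _derived(col, perm)
            xs.append(strength)
            ys.append(col.edge_betweenness)
        return _pearson(np.concatenate(xs), np.concatenate(ys))

    return stat


def _corr_nf_size_relative_foraging(cols):
    """On nF-F trails: nF endpoint size vs relative foraging of the F
    endpoint (amount of foraging / population)."""

    def stat(perms):
        xs, ys = [], []
        for col, perm in zip(cols, perms):
            pop = col.population[perm]
            amount = col.amount[perm]
            forag = col.is_foraging[perm]
            a, b = col.edges[:, 0], col.edges[:, 1]
            mask = forag[a] != forag[b]
            fa = np.where(forag[a], a, b)[mask]  # foraging endpoint
            na = np.where(forag[a], b, a)[mask]  # nonforaging endpoint
            xs.append(pop[na])
            ys.append(amount[fa] / pop[fa])
        return _pearson(np.concatenate(xs), np.concatenate(ys))

    return stat


def _assortativity_stat(col: ColonyArrays, attribute: str, weighted: bool):
    a, b = col.edges[:, 0], col.edges[:, 1]

    def stat(perms):
        (perm,) = perms
        strength, _, _ = _derived(col, perm)
        if attribute == "weighted_degree":
            x = _weighted_degree(col, strength)
        else:
            x = _node_attr(col, perm, attribute)
        w = strength if weighted else np.ones(len(strength))
        xa = np.concatenate([x[a], x[b]])
        xb = np.concatenate([x[b], x[a]])
        ww = np.concatenate([w, w])
        tot = ww.sum()
        if tot <= 0 or xa.size < 4 or np.ptp(xa) == 0:
            raise UndefinedStatisticError("assortativity undefined")
        ww = ww / tot
        mx, my = ww @ xa, ww @ xb
        vx = ww @ ((xa - mx) ** 2)
        vy = ww @ ((xb - my) ** 2)
        if vx <= 0 or vy <= 0:
            raise UndefinedStatisticError("zero endpoint variance")
        return float((ww @ ((xa - mx) * (xb - my))) / math.sqrt(vx * vy))

    return stat


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisConfig:
    """Settings for one analysis run."""

    seed: int = 0
    n_permutations: int = 1000
    calibration: Optional[PopulationCalibration] = None
    distance_transform: str = "inverse"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise DomainError("n_permutations must be >= 1")


@dataclass
class AnalysisReport:
    """All tables produced by :func:`run_analysis`."""

    colony_summaries: pd.DataFrame
    nest_metrics: pd.DataFrame
    nests: pd.DataFrame
    trails: pd.DataFrame
    tests: pd.DataFrame
    assortativity: pd.DataFrame
    seed: int
    n_permutations: int
    qap_results: dict[str, QAPResult] = field(default_factory=dict, repr=False)


def summarize_colony(network: ColonyNetwork) -> tuple[int, int, int, int]:
    """(n nests, n internest trails, n foraged trees, n nonforaging nests).

    A tree counts as foraged when at least one qualifying (clear) foraging
    trail reaches it.  Foraging profiles must have been computed.
    """
    foraged_trees = {
        ft.tree_id
        for ft in network.foraging_trails
        if qualify_foraging_trail(ft.ants_per_metre)
    }
    n_nonforaging = sum(
        1 for nest in network.nests.values() if not nest.is_foraging
    )
    return (
        network.n_nests,
        network.n_internest_trails,
        len(foraged_trees),
        n_nonforaging,
    )


@dataclass
class _TestSpec:
    name: str
    scope: str
    stat: Callable[[list[np.ndarray]], float]
    blocks: list
    n: int
    alternative: str


def _battery(cols: list[ColonyArrays]) -> list[_TestSpec]:
    """The default test battery.

    Three permutation modes appear, all blocked within colony:

    * bundle permutation against fixed structure, with derived trail
      quantities recomputed (trail-level and metric-vs-property tests);
    * one attribute permuted against another fixed attribute
      (nest-variable contrasts and correlations);
    * bundle permutation within a single colony (trail betweenness and
      assortativity tests, appended in :func:`run_analysis`).
    """
    cats = np.concatenate(
        [_derived(c, np.arange(c.n))[1] for c in cols] or [np.empty(0, int)]
    )
    n_edges = int(cats.size)
    n_nests = int(sum(c.n for c in cols))
    n_by_code = {code: int((cats == code).sum()) for code in (0, 1, 2)}

    specs = [
        _TestSpec(
            "strength_by_trail_type",
            "pooled",
            _f_by_category(cols, lambda col, s: s),
            cols,
            n_edges,
            "greater",
        ),
        _TestSpec(
            "differential_vs_strength_nF-F",
            "pooled",
            _corr_diff_strength(cols, ["nF-F"]),
            cols,
            n_by_code[1],
            "two-sided",
        ),
        _TestSpec(
            "differential_vs_strength_nF-F_spearman",
            "pooled",
            _corr_diff_strength(cols, ["nF-F"], method="spearman"),
            cols,
            n_by_code[1],
            "two-sided",
        ),
        _TestSpec(
            "differential_vs_strength_F-F",
            "pooled",
            _corr_diff_strength(cols, ["F-F"]),
            cols,
            n_by_code[2],
            "two-sided",
        ),
        _TestSpec(
            "differential_vs_strength_combined",
            "pooled",
            _corr_diff_strength(cols, ["F-F", "nF-F"]),
            cols,
            n_by_code[1] + n_by_code[2],
            "two-sided",
        ),
        _TestSpec(
            "length_by_trail_type",
            "pooled",
            _f_by_category(cols, lambda col, s: col.edge_l),
            cols,
            n_edges,
            "greater",
        ),
        _TestSpec(
            "population_by_foraging_status",
            "pooled",
            _f_attr_by_status(cols, "population"),
            cols,
            n_nests,
            "greater",
        ),
        _TestSpec(
            "canopy_by_foraging_status",
            "pooled",
            _f_attr_by_status(cols, "canopy_cover"),
            cols,
            n_nests,
            "greater",
        ),
        _TestSpec(
            "nF_size_vs_relative_F_foraging",
            "pooled",
            _corr_nf_size_relative_foraging(cols),
            cols,
            n_by_code[1],
            "two-sided",
        ),
    ]
    for cat_name in ("nF-F", "F-F"):
        for target in ("strength", "differential"):
            specs.append(
                _TestSpec(
                    f"length_vs_{target}_{cat_name}",
                    "pooled",
                    _corr_length_vs(cols, target, cat_name),
                    cols,
                    n_by_code[_CAT_CODE[cat_name]],
                    "two-sided",
                )
            )
    for prop_x, prop_y, subset in (
        ("canopy_cover", "population", False),
        ("population", "amount_of_foraging", True),
        ("canopy_cover", "amount_of_foraging", True),
    ):
        stat, blocks, n = _corr_attr_attr(cols, prop_x, prop_y, foraging_only=subset)
        suffix = "_F_nests" if subset else ""
        specs.append(
            _TestSpec(
                f"{prop_y}_vs_{prop_x}{suffix}",
                "pooled",
                stat,
                blocks,
                n,
                "two-sided",
            )
        )
    for metric in ("degree", "weighted_degree", "betweenness", "closeness"):
        for prop in ("population", "canopy_cover", "amount_of_foraging"):
            specs.append(
                _TestSpec(
                    f"{metric}_vs_{prop}",
                    "pooled",
                    _corr_metric_property(cols, metric, prop),
                    cols,
                    n_nests,
                    "two-sided",
                )
            )
    return specs


def run_analysis(
    source: Union[str, Path, GeneratorConfig, Sequence[ColonyNetwork]],
    config: Optional[AnalysisConfig] = None,
) -> AnalysisReport:
    """Run the full nest-network analysis battery.

    ``source`` may be a directory of CSV tables, a
    :class:`GeneratorConfig` (synthetic study), or pre-built networks.
    Populations are taken from an explicit population column when
    present, otherwise predicted from mound dimensions through
    ``config.calibration``.  Identical (source, config) pairs produce
    identical reports.
    """
    config = config or AnalysisConfig()
    if isinstance(source, GeneratorConfig):
        networks, _ = generate_study(source)
    elif isinstance(source, (str, Path)):
        d = Path(source)
        networks = read_study(
            d / "nests.csv",
            d / "trees.csv",
            d / "internest_trails.csv",
            d / "foraging_trails.csv",
        )
    else:
        networks = list(source)

    for net in networks:
        compute_all(net, config.calibration)
    cols = [colony_arrays(net) for net in networks]

    colony_summaries = pd.DataFrame(
        [
            (net.colony_id, *summarize_colony(net))
            for net in networks
        ],
        columns=[
            "colony_id",
            "n_nests",
            "n_internest_trails",
            "n_foraged_trees",
            "n_nonforaging_nests",
        ],
    )
    from .network_metrics import nest_metrics_table

    nest_metrics = pd.concat(
        [nest_metrics_table(net, config.distance_transform) for net in networks],
        ignore_index=True,
    )
    nests = pd.concat([nest_foraging_table(net) for net in networks], ignore_index=True)
    trails = pd.concat([trail_table(net) for net in networks], ignore_index=True)

    seeds = np.random.SeedSequence(config.seed)
    entries = _battery(cols)
    n_assort = len(ASSORTATIVITY_ATTRIBUTES) * len(cols)
    children = seeds.spawn(len(entries) + n_assort)

    qap_results: dict[str, QAPResult] = {}
    rows = []
    for spec, child in zip(entries, children):
        row = {
            "test": spec.name,
            "scope": spec.scope,
            "observed": math.nan,
            "p_value": math.nan,
            "n": spec.n,
            "n_permutations": config.n_permutations,
            "alternative": spec.alternative,
            "seed": config.seed,
            "skipped": "",
        }
        if spec.n < 3 or not spec.blocks:
            row["skipped"] = f"only {spec.n} observations"
            logger.warning("test %s skipped: %s", spec.name, row["skipped"])
            rows.append(row)
            continue
        try:
            result = qap_test(
                spec.stat,
                spec.blocks,
                n_permutations=config.n_permutations,
                alternative=spec.alternative,
                rng=np.random.default_rng(child),
                statistic_name=spec.name,
            )
        except UndefinedStatisticError as exc:
            row["skipped"] = str(exc)
            logger.warning("test %s skipped: %s", spec.name, exc)
            rows.append(row)
            continue
        qap_results[spec.name] = result
        row["observed"] = result.observed
        row["p_value"] = result.p_value
        rows.append(row)
        logger.info(
            "test %s: observed=%.4g p=%.4g (n=%d, %d permutations)",
            spec.name,
            result.observed,
            result.p_value,
            spec.n,
            result.n_permutations,
        )

    # per-colony strength vs (unweighted) trail betweenness
    extra_children = seeds.spawn(len(cols))
    for col, child in zip(cols, extra_children):
        name = f"strength_vs_trail_betweenness_{col.colony_id}"
        try:
            result = qap_test(
                _corr_strength_edge_betweenness([col]),
                [col.n],
                n_permutations=config.n_permutations,
                alternative="two-sided",
                rng=np.random.default_rng(child),
                statistic_name=name,
            )
        except UndefinedStatisticError as exc:
            logger.warning("test %s skipped: %s", name, exc)
            rows.append(
                {
                    "test": name,
                    "scope": col.colony_id,
                    "observed": math.nan,
                    "p_value": math.nan,
                    "n": len(col.edge_l),
                    "n_permutations": config.n_permutations,
                    "alternative": "two-sided",
                    "seed": config.seed,
                    "skipped": str(exc),
                }
            )
            continue
        qap_results[name] = result
        rows.append(
            {
                "test": name,
                "scope": col.colony_id,
                "observed": result.observed,
                "p_value": result.p_value,
                "n": len(col.edge_l),
                "n_permutations": result.n_permutations,
                "alternative": "two-sided",
                "seed": config.seed,
                "skipped": "",
            }
        )

    tests = pd.DataFrame(rows)

    # per-colony assortativity with Bonferroni over the attribute family
    m = len(ASSORTATIVITY_ATTRIBUTES)
    assort_rows = []
    for col, chunk in zip(
        cols,
        [children[len(entries) + i * m : len(entries) + (i + 1) * m] for i in range(len(cols))],
    ):
        colony_results = []
        for attribute, child in zip(ASSORTATIVITY_ATTRIBUTES, chunk):
            name = f"assortativity_{attribute}_{col.colony_id}"
            try:
                result = qap_test(
                    _assortativity_stat(col, attribute, weighted=True),
                    [col.n],
                    n_permutations=config.n_permutations,
                    alternative="two-sided",
                    rng=np.random.default_rng(child),
                    statistic_name=name,
                )
                colony_results.append((attribute, result))
                qap_results[name] = result
            except UndefinedStatisticError as exc:
                logger.warning("assortativity %s skipped: %s", name, exc)
                colony_results.append((attribute, None))
        p_raw = [r.p_value for _, r in colony_results if r is not None]
        p_adj = iter(bonferroni(p_raw, m=m)) if p_raw else iter(())
        for attribute, result in colony_results:
            if result is None:
                assort_rows.append(
                    {
                        "colony_id": col.colony_id,
                        "attribute": attribute,
                        "weighted": True,
                        "r": math.nan,
                        "n_edges": len(col.edge_l),
                        "undefined": True,
                        "p_value": math.nan,
                        "p_adjusted": math.nan,
                        "m": m,
                        "significant_05": False,
                        "marginal_10": False,
                    }
                )
                continue
            adj = next(p_adj)
            assort_rows.append(
                {
                    "colony_id": col.colony_id,
                    "attribute": attribute,
                    "weighted": True,
                    "r": result.observed,
                    "n_edges": len(col.edge_l),
                    "undefined": False,
                    "p_value": result.p_value,
                    "p_adjusted": adj,
                    "m": m,
                    "significant_05": adj < 0.05,
                    "marginal_10": 0.05 <= adj < 0.1,
                }
            )
    assortativity = pd.DataFrame(assort_rows)

    return AnalysisReport(
        colony_summaries=colony_summaries,
        nest_metrics=nest_metrics,
        nests=nests,
        trails=trails,
        tests=tests,
        assortativity=assortativity,
        seed=config.seed,
        n_permutations=config.n_permutations,
        qap_results=qap_results,
    )


def write_report(
    report: AnalysisReport,
    out_dir,
    networks: Optional[Sequence[ColonyNetwork]] = None,
) -> Path:
    """Write all report tables as CSV plus a JSON run summary.

    Output bytes depend only on the report contents, so identical runs
    give identical files.  When ``networks`` is given, each colony is
    also exported as GraphML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    report.colony_summaries.to_csv(out / "colony_summaries.csv", index=False)
    report.nest_metrics.to_csv(out / "nest_metrics.csv", index=False, float_format=fmt)
    report.nests.to_csv(out / "nest_foraging.csv", index=False, float_format=fmt)
    report.trails.to_csv(out / "trail_metrics.csv", index=False, float_format=fmt)
    report.tests.to_csv(out / "qap_results.csv", index=False, float_format=fmt)
    report.assortativity.to_csv(
        out / "assortativity.csv", index=False, float_format=fmt
    )
    summary = {
        "seed": report.seed,
        "n_permutations": report.n_permutations,
        "n_colonies": int(len(report.colony_summaries)),
        "n_tests": int(len(report.tests)),
        "n_skipped": int((report.tests["skipped"] != "").sum()),
        "min_p_value": float(np.nanmin(report.tests["p_value"]))
        if len(report.tests)
        else None,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    if networks is not None:
        for net in networks:
            write_graphml(net, out / f"{net.colony_id}.graphml")
    return out
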