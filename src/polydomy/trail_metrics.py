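"""Trail-level statistics of the polydomous network.

The central quantity is the strength of an internest trail,

    S_ab = w * l / mean(p_a, p_b),

the estimated number of ants on the trail (ants-per-metre w times length
l) divided by the mean worker population of the two nests it connects.
Dividing by population expresses the trail as a per-capita investment, so
a thin trail between two small nests can be as "strong" as a busy trail
between large ones.

Foraging trails from a nest to an aphid-bearing tree are scored the same
way but normalised by the origin nest's population alone; a nest's
*amount of foraging* is the sum of its qualifying foraging-trail
strengths, and a nest with no qualifying trail to any tree is classed
nonforaging.  Internest trails then fall into three categories — F-F,
nF-F and nF-nF — and the *foraging differential* of a trail is the
absolute difference in amount of foraging between its endpoints (nF-nF
trails are excluded: their differential is identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Mapping, Optional

import pandas as pd

from .colony import ColonyNetwork, InternestTrail
from .errors import DomainError, IntegrityError
from .field_measures import (
    PopulationCalibration,
    estimate_population,
    mound_volume,
)

__all__ = [
    "CLEAR_TRAIL_THRESHOLD",
    "NestForagingProfile",
    "internest_trail_strength",
    "foraging_trail_strength",
    "qualify_foraging_trail",
    "amount_of_foraging",
    "classify_trail",
    "foraging_differential",
    "compute_populations",
    "compute_all",
    "trail_table",
    "nest_foraging_table",
]

#: Minimum activity for a "clear" foraging trail: more than 10 ants in
#: 40 cm, i.e. strictly more than 25 ants per metre.
CLEAR_TRAIL_THRESHOLD = 25.0


@dataclass(frozen=True)
class NestForagingProfile:
    nest_id: str
    amount_of_foraging: float
    is_foraging: bool


def internest_trail_strength(
    ants_per_metre: float, length: float, pop_a: float, pop_b: float
) -> float:
    """Strength of an internest trail: S = w*l / mean(p_a, p_b)."""
    if length <= 0:
        raise DomainError(f"length must be > 0, got {length}")
    mean_pop = fmean((pop_a, pop_b))
    if mean_pop <= 0:
        raise DomainError("strength undefined for non-positive mean population")
    return ants_per_metre * length / mean_pop


def foraging_trail_strength(
    ants_per_metre: float, length: float, origin_population: float
) -> float:
    """Strength of a nest→tree trail: w*l over the origin nest population."""
    if length <= 0:
        raise DomainError(f"length must be > 0, got {length}")
    if origin_population <= 0:
        raise DomainError("strength undefined for non-positive origin population")
    return ants_per_metre * length / origin_population


def qualify_foraging_trail(ants_per_metre: float) -> bool:
    """True iff the trail is "clear": strictly more than 25 ants per metre."""
    if ants_per_metre < 0:
        raise DomainError("ants_per_metre must be >= 0")
    return ants_per_metre > CLEAR_TRAIL_THRESHOLD


def amount_of_foraging(network: ColonyNetwork) -> dict[str, NestForagingProfile]:
    """Per-nest foraging profile: summed qualifying trail strengths.

    Requires populations to have been computed.  Nests with no qualifying
    foraging trail are flagged nonforaging with amount 0.
    """
    totals: dict[str, float] = {nid: 0.0 for nid in network.nests}
    counts: dict[str, int] = {nid: 0 for nid in network.nests}
    for ft in network.foraging_trails:
        if ft.nest_id not in network.nests:
            raise IntegrityError(f"foraging trail references unknown nest {ft.nest_id}")
        if not qualify_foraging_trail(ft.ants_per_metre):
            continue
        pop = network.nests[ft.nest_id].population
        if pop is None:
            raise DomainError(
                f"nest {ft.nest_id}: population must be computed before foraging"
            )
        s = foraging_trail_strength(ft.ants_per_metre, ft.length, pop)
        ft.strength = s
        totals[ft.nest_id] += s
        counts[ft.nest_id] += 1
    return {
        nid: NestForagingProfile(nid, totals[nid], counts[nid] > 0)
        for nid in network.nests
    }


def classify_trail(
    trail: InternestTrail, profiles: Mapping[str, NestForagingProfile]
) -> str:
    """Trail category from endpoint foraging status: F-F, nF-F or nF-nF."""
    try:
        a, b = profiles[trail.nest_a], profiles[trail.nest_b]
    except KeyError as exc:
        raise IntegrityError(f"no foraging profile for nest {exc.args[0]}") from exc
    if a.is_foraging and b.is_foraging:
        return "F-F"
    if not a.is_foraging and not b.is_foraging:
        return "nF-nF"
    return "nF-F"


def foraging_differential(
    trail: InternestTrail, profiles: Mapping[str, NestForagingProfile]
) -> tuple[float, bool]:
    """(|amount_a - amount_b|, excluded) for an internest trail.

    The differential of an nF-nF trail is identically zero, so those
    trails are marked excluded from differential analyses.
    """
    try:
        a, b = profiles[trail.nest_a], profiles[trail.nest_b]
    except KeyError as exc:
        raise IntegrityError(f"no foraging profile for nest {exc.args[0]}") from exc
    diff = abs(a.amount_of_foraging - b.amount_of_foraging)
    excluded = not a.is_foraging and not b.is_foraging
    return diff, excluded


def compute_populations(
    network: ColonyNetwork, calibration: Optional[PopulationCalibration] = None
) -> None:
    """Fill nest volume and population in place.

    An explicitly supplied population column takes precedence; otherwise
    the population is predicted from mound dimensions through the
    volume→population calibration.
    """
    for nest in network.nests.values():
        if (
            nest.diameter_1 is not None
            and nest.diameter_2 is not None
            and nest.height is not None
        ):
            nest.volume = mound_volume(nest.diameter_1, nest.diameter_2, nest.height)
        if nest.population is not None:
            continue
        if nest.volume is None:
            raise DomainError(
                f"nest {nest.nest_id}: no population and no mound dimensions"
            )
        if calibration is None:
            raise DomainError(
                f"nest {nest.nest_id}: population requires a calibration"
            )
        nest.population = estimate_population(nest.volume, calibration)


def compute_all(
    network: ColonyNetwork, calibration: Optional[PopulationCalibration] = None
) -> dict[str, NestForagingProfile]:
    """Derive every trail- and nest-level quantity for one colony in place.

    Order matters: populations first (strengths divide by them), then
    foraging profiles (status feeds trail categories), then internest
    strengths, categories and differentials.  Returns the foraging
    profiles keyed by nest id.
    """
    compute_populations(network, calibration)
    profiles = amount_of_foraging(network)
    for nid, prof in profiles.items():
        network.nests[nid].amount_of_foraging = prof.amount_of_foraging
        network.nests[nid].is_foraging = prof.is_foraging
    for trail in network.internest_trails:
        pa = network.nests[trail.nest_a].population
        pb = network.nests[trail.nest_b].population
        trail.strength = internest_trail_strength(
            trail.ants_per_metre, trail.length, pa, pb
        )
        trail.category = classify_trail(trail, profiles)
        trail.foraging_differential, trail.excluded = foraging_differential(
            trail, profiles
        )
    return profiles


def trail_table(network: ColonyNetwork) -> pd.DataFrame:
    """Internest trails as a tidy frame (one row per trail)."""
    rows = [
        {
            "colony_id": network.colony_id,
            "nest_a": t.nest_a,
            "nest_b": t.nest_b,
            "length_m": t.length,
            "ants_per_m": t.ants_per_metre,
            "strength": t.strength,
            "category": t.category,
            "foraging_differential": t.foraging_differential,
            "excluded": t.excluded,
        }
        for t in network.internest_trails
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "colony_id",
            "nest_a",
            "nest_b",
            "length_m",
            "ants_per_m",
            "strength",
            "category",
            "foraging_differential",
            "excluded",
        ],
    )


def nest_foraging_table(network: ColonyNetwork) -> pd.DataFrame:
    """Per-nest foraging summary (one row per nest)."""
    rows = [
        {
            "colony_id": network.colony_id,
            "nest_id": n.nest_id,
            "population": n.population,
            "canopy_cover": n.canopy_cover,
            "amount_of_foraging": n.amount_of_foraging,
            "is_foraging": n.is_foraging,
        }
        for n in network.nests.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "colony_id",
            "nest_id",
            "population",
            "canopy_cover",
            "amount_of_foraging",
            "is_foraging",
        ],
    )
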