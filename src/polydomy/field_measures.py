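"""Estimators turning raw field measurements into nest-level quantities.

Four measurements feed the nest-network analysis:

* trail activity — the distance along a central portion of a trail needed
  to count 10 ants, converted to ants per metre;
* mound volume — half the volume of an ellipsoid fitted from two
  perpendicular diameters and the mound height;
* worker population — predicted from mound volume via a site-specific
  linear calibration against mark–release–recapture counts;
* canopy cover — the fraction of dark pixels in an 8-bit vertical
  photograph taken above the nest (a proxy for reduced insolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "ants_per_metre",
    "mound_volume",
    "PopulationCalibration",
    "fit_population_calibration",
    "estimate_population",
    "canopy_cover",
    "load_canopy_image",
]


def ants_per_metre(dist_to_10_ants: float) -> float:
    """Convert the 10-ant count distance (m) to ants per metre: w = 10/d.

    The count-distance measure is insensitive to walking speed, unlike
    rate-based activity measures, and converts directly to a density.
    """
    if dist_to_10_ants <= 0:
        raise DomainError(f"dist_to_10_ants must be > 0, got {dist_to_10_ants}")
    return 10.0 / dist_to_10_ants


def mound_volume(diameter_1: float, diameter_2: float, height: float) -> float:
    """Nest-mound volume as half an ellipsoid (m^3).

    The mound is the upper half of an ellipsoid whose horizontal axes are
    the two perpendicular diameters and whose vertical semi-axis is the
    mound height: V = (1/2)(4/3)π (d1/2)(d2/2) h = π d1 d2 h / 6.
    """
    if diameter_1 <= 0 or diameter_2 <= 0 or height <= 0:
        raise DomainError(
            "mound dimensions must be > 0, got "
            f"({diameter_1}, {diameter_2}, {height})"
        )
    return math.pi * diameter_1 * diameter_2 * height / 6.0


@dataclass(frozen=True)
class PopulationCalibration:
    """Linear volume→population calibration (population = intercept + slope·V)."""

    slope: float  # workers per m^3
    intercept: float  # workers
    r_squared: float  # fraction in [0, 1]
    n: int
    p_value: float  # two-sided p for the slope

    @property
    def r_squared_percent(self) -> float:
        return 100.0 * self.r_squared


def fit_population_calibration(
    volumes: Sequence[float], mrr_populations: Sequence[float]
) -> PopulationCalibration:
    """OLS fit of mark–release–recapture population counts on mound volume.

    Requires at least 3 paired observations and a non-degenerate
    predictor.  Reports R² both as a fraction (``r_squared``) and percent
    (``r_squared_percent``).
    """
    v = np.asarray(volumes, dtype=float)
    p = np.asarray(mrr_populations, dtype=float)
    if v.shape != p.shape or v.ndim != 1:
        raise DomainError("volumes and populations must be equal-length 1-D")
    if v.size < 3:
        raise DomainError(f"calibration needs n >= 3 pairs, got {v.size}")
    if np.ptp(v) == 0:
        raise DomainError("all volumes identical: calibration slope undefined")
    fit = stats.linregress(v, p)
    return PopulationCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(v.size),
        p_value=float(fit.pvalue),
    )


def estimate_population(volume: float, calib: PopulationCalibration) -> float:
    """Predicted worker population for a mound volume, floored at 0.

    The regression line can dip below zero for tiny mounds; a mound that
    exists cannot house a negative population.
    """
    if volume <= 0:
        raise DomainError(f"volume must be > 0, got {volume}")
    return max(0.0, calib.intercept + calib.slope * volume)


def canopy_cover(image: np.ndarray, dark_threshold: int = 255) -> float:
    """Fraction of dark pixels in an 8-bit grayscale image.

    A pixel counts as canopy when its intensity is strictly below
    ``dark_threshold``.  The default threshold of 255 counts every
    non-pure-white pixel as canopy, matching the standard thresholding
    workflow on binarised canopy photographs.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise DomainError("empty canopy image")
    if not 0 <= dark_threshold <= 255:
        raise DomainError(f"dark_threshold must lie in [0, 255], got {dark_threshold}")
    return float(np.count_nonzero(arr < dark_threshold) / arr.size)


def load_canopy_image(path) -> np.ndarray:
    """Load an image file as an 8-bit grayscale intensity matrix."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
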