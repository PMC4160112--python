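"""Turning raw field measurements into nest-level quantities.

Builds the chain: 10-ant count distance -> ants per metre, mound
dimensions -> half-ellipsoid volume, a volume/population calibration
regression, and pixel-counted canopy cover.
"""

import numpy as np

import polydomy as pm

# trail activity: 10 ants counted over 0.4 m means 25 ants per metre
w = pm.ants_per_metre(0.4)
print(f"ants per metre for a 0.4 m count distance: {w:.1f}")

# a mound with perpendicular diameters 1.8 m x 1.6 m and height 0.6 m
v = pm.mound_volume(1.8, 1.6, 0.6)
print(f"mound volume (half ellipsoid): {v:.3f} m^3")

# calibrate volume -> population against mark-release-recapture counts
rng = np.random.default_rng(0)
volumes = rng.uniform(0.1, 2.5, 26)
mrr = 55_000 * volumes + rng.normal(0, 18_000, 26)
calib = pm.fit_population_calibration(volumes, mrr)
print(
    f"calibration: slope={calib.slope:.0f} workers/m^3, "
    f"intercept={calib.intercept:.0f}, R^2={calib.r_squared_percent:.1f}% "
    f"(n={calib.n}, p={calib.p_value:.2g})"
)
print(f"predicted population for the mound above: "
      f"{pm.estimate_population(v, calib):.0f} workers")

# canopy cover: fraction of dark pixels in an 8-bit vertical photograph
img = np.full((100, 100), 255, dtype=np.uint8)
img[:40] = 10  # canopy shades the top 40% of the frame
print(f"canopy cover: {pm.canopy_cover(img):.2f}")

# The printed numbers trace one nest through the field protocol: trail
# activity becomes a density, mound size becomes a worker population via
# the site calibration, and the photograph becomes a shading fraction.
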