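"""Micelle shape descriptors and aggregate detection.

Computes the radius of gyration, principal moments of inertia and
asphericity alpha = (2 I1 - I2 - I3)/(I1 + I2 + I3) for a sphere and a
stretched ellipsoid (alpha = 0 means perfectly spherical), then clusters a
dumbbell with the 10 A maximum-distance criterion to recover its two
aggregates.
"""
import numpy as np

from sansmi.shape_analysis import find_aggregates, shape_params, size_histogram
from sansmi.toy_sim import make_dumbbell, make_uniform_sphere

rng = np.random.default_rng(4)

ball = make_uniform_sphere(17.0, 1500, 1.0, rng, mass=72.0)
stretched = ball.copy()
stretched.positions = ball.positions * np.array([1.6, 1.0, 0.9])

for name, sites in (("sphere", ball), ("ellipsoid", stretched)):
    sp = shape_params(sites)
    i1, i2, i3 = sp.moments_table_units
    print(f"{name:10s} Rg={sp.rg:6.2f} A   "
          f"I=({i1:.2f}, {i2:.2f}, {i3:.2f}) x1e-4 Da nm^2   "
          f"alpha={sp.alpha:.2f}")

dumbbell = make_dumbbell(6.0, 40, 40.0, 1.0, rng)
agg = find_aggregates(dumbbell, cutoff=10.0)
print(f"\ndumbbell: {agg.n_clusters} aggregates, "
      f"size histogram {size_histogram(agg)}")
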