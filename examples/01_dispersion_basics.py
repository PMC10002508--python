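"""The Iδ dispersion index for three canonical 1-D point patterns.

Positions of particles along a 200 μm axon are generated by a jittered
lattice (even spacing), a homogeneous Poisson process (random), and a
Neyman–Scott process (clustered); the Iδ index is swept over compartment
widths and each curve is reduced to a pattern call.
"""

import numpy as np

from mitospread import classify_pattern, id_curve, sample_positions
from mitospread.dispersion import DEFAULT_WIDTHS_UM

L = 200.0
patterns = {
    "uniform": dict(density_per_um=1.2, jitter_sd_um=0.15),
    "random": dict(density_per_um=1.2),
    "clustered": dict(cluster_rate_per_um=0.05, cluster_size_mean=8.0,
                      cluster_sd_um=1.0),
}

for name, params in patterns.items():
    pos = sample_positions(name, L, **params, seed=42)
    curve = id_curve(pos, L, DEFAULT_WIDTHS_UM)
    call = classify_pattern(curve)
    small = curve.id_values[curve.defined][:3]
    print(f"{name:9s} n={len(pos):3d}  "
          f"Iδ at 2/4/6 μm = {np.round(small, 2)}  ->  {call.label}")

print("\nIδ near 0 at small widths flags even spacing, ≈1 flags spatial "
      "randomness,\nand values above 1 flag clustering at that scale.")
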