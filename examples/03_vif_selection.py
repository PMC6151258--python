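"""Screen collinear environmental variables with VIF backward elimination.

Elevation-driven climate layers are strongly correlated with elevation and
with each other; variance inflation factors (1 / (1 - R^2)) above 10 flag
the redundancy, and backward elimination keeps a stable subset.
"""

import numpy as np

from gapstack import (default_virtual_species, generate_landscape,
                      generate_zones_and_roads, sample_occurrences,
                      seasonal_subset, select_variables_vif)
from gapstack.background import buffer_roads, sample_background

land = generate_landscape(seed=7)
_, roads = generate_zones_and_roads(land, seed=7)
env = seasonal_subset(land.env_stack(), "resident")

vs = default_virtual_species(land, seed=7)[0]
occ = sample_occurrences(vs, land, n=150, seed=1)
pool = sample_background(buffer_roads(roads, land.grid), land.grid, seed=2)
pts = np.vstack([occ[["x", "y"]].to_numpy(), pool.points])

diag = select_variables_vif(env, pts, threshold=10.0)
print("candidate layers:", env.names)
for name, rnd in diag.dropped:
    print(f"  dropped round {rnd}: {name}")
print("selected:", diag.selected)
print("final VIFs:", {k: round(v, 2) for k, v in diag.vif.items()})
# Survivors all have VIF < 10: each remaining predictor carries information
# the others cannot reproduce by linear combination.
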