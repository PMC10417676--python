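"""Mechanistic plate simulator: biased run-and-tumble chemotaxis.

Worms start at the center of a 9 cm assay plate, alternate noisy
reorientations with runs, drift along the odor gradient of the two urine
spots in proportion to the attraction parameter, and freeze when they
reach a sodium azide spot.  The chemotaxis index emerges from the final
half-plane counts.
"""

import numpy as np

from nnose import WalkParams, simulate_plate_walk
from nnose.chemotaxis import chemotaxis_index

params = WalkParams()
print(f"plate radius {params.plate_radius} cm, urine spots "
      f"{params.urine_spot_positions}, {params.n_steps} steps of "
      f"{params.step_length} cm\n")

print("attraction   mean CI over 50 plates of 100 worms")
for attraction in (-1.0, -0.5, 0.0, 0.25, 0.5, 1.0):
    cis = [
        chemotaxis_index(
            simulate_plate_walk(attraction, params, 100, seed=1000 + k)
        )
        for k in range(50)
    ]
    print(f"  {attraction:+5.2f}      {np.mean(cis):+.3f}  (sd {np.std(cis):.3f})")

print("\nMean CI rises monotonically with attraction, is ~0 for an")
print("indifferent odor, and saturates near +-1 when the gradient pull")
print("dominates the turning noise.")
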