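"""Curvature of a closed repeat ring (TIM-barrel-like topology).

A ring of N identical units closing on itself constrains each pair's
curvature to 2*pi/N: for 8 units that is ~0.785 rad, comfortably above the
0.5 rad floor that separates closed topologies from elongated solenoids.
"""

import numpy as np

from repeatgeom import compute_region_geometry
from repeatgeom.synthetic import SolenoidParams, generate_solenoid

result = generate_solenoid(SolenoidParams(n_units=8, closed=True,
                                          radius=20.0, seed=1))
table = compute_region_geometry(result.structure, result.region)

mean_curv = table.summary.loc["mean", "curvature"]
print(table.pairs[["pair_index", "curvature", "radius"]]
      .to_string(index=False))
print(f"\nmean curvature = {mean_curv:.6f} rad "
      f"(2*pi/8 = {2 * np.pi / 8:.6f})")
print("Closed topologies always sit above 0.5 rad; open solenoids can go")
print("arbitrarily low.")
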