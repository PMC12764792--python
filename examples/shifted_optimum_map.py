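"""Where do successful polyploids establish when their optimum is shifted?

Neotetraploids whose environmental optimum is moved 20 patches away from
the diploid founder area establish at the margin of the diploid range, in
the direction of the shift — here accumulated into a first-SPE density map
over a few replicates.
"""

import numpy as np

from polyestab import SimulationConfig, run_experiment
from polyestab.experiments import ExperimentDesign, diploid_range_boundary, spe_density_map

base = SimulationConfig()
design = ExperimentDesign(
    family="shifted_optimum", levels=(20.0,), replicates=4,
    base_config=base, root_seed=3,
)
table = run_experiment(design)
print(table[["replicate", "spe", "final_4x", "gpip", "first_spe_x", "first_spe_y"]]
      .to_string(index=False))

dmap = spe_density_map(table, (100, 100))
mask = diploid_range_boundary(base)
print(f"\nfirst-SPE founders located: {dmap.sum()} (one per replicate with an SPE)")
locs = np.argwhere(dmap > 0)
for y, x in locs:
    d = np.hypot(x - 49.5, y - 49.5)
    inside = "inside" if mask[y, x] else "outside"
    print(f"  SPE founder at (x={x}, y={y}): {d:.1f} patches from the founder "
          f"centroid, {inside} the maximum diploid range")
print("\ndistances cluster near the 20-patch shift: establishment tracks the new optimum.")
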