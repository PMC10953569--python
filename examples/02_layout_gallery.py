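"""Generate the four MEA layout families and verify their geometry.

Rectangular grids (59/128/256/512 electrodes), a curved variant bent to
0.35 mm^-1 (the gross curvature of mouse cortex), a perturbed variant with
displacements bounded by 50 µm, and a 4-well arrangement.
"""

import numpy as np

import meakit as mk
from meakit.layouts import row_curvature

for cap in (59, 128, 256, 512):
    lay = mk.make_rect(cap)
    span = np.ptp(lay.positions, axis=0)
    print(f"rect {cap:3d}: {lay.n_electrodes} electrodes, "
          f"footprint {span[0]:.0f} x {span[1]:.0f} µm")

curved = mk.make_curved(128, curvature_per_mm=0.35)
print(f"curved 128: fitted row curvature {row_curvature(curved):.6f} mm^-1")

base = mk.make_rect(128).positions
pert = mk.make_perturbed(128, max_disp_um=50, seed=42)
disp = np.hypot(*(pert.positions - base).T)
print(f"perturbed 128: max displacement {disp.max():.1f} µm (bound 50 µm)")

wells = mk.make_multiwell(n_wells=4, per_well_capacity=32)
print(f"multiwell: {wells.n_electrodes} electrodes in "
      f"{len(wells.wells())} wells of 32")

# Each printed check restates a design constraint: exact capacity, the
# commercial 1400 µm footprint for the 59-site grid, row curvature equal to
# the parameter, and displacements inside the collision-safe bound.
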