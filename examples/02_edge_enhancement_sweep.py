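"""Energy / distance sweep of propagation-based edge enhancement.

A 54-um ethanol-filled vessel in liver tissue is imaged at three beam
energies and four object-to-detector distances; the vessel-wall edge
contrast C = (Imax - Imin)/(Imax + Imin) is read off a line profile
crossing the wall.  Contrast grows with distance in the near field and is
larger at softer energies — at contact (0.05 m) the vessel is nearly
invisible, which is why propagation distance is what makes unstained
microvasculature visible at all.
"""

import numpy as np

import phasevasc as pv
from phasevasc.phantom import cylinder_battery

vol, masks = cylinder_battery(grid=256, n_slices=4, diameters_um=(54.0,))
x0 = float(np.nonzero(masks[54.0][0].any(axis=0))[0].mean())
segment = ((1.0, x0 - 15.0), (1.0, x0 + 15.0))

print("edge contrast C across the vessel wall")
print("energy   " + "".join(f"{d:>8} m" for d in (0.05, 1.0, 3.0)))
for energy in (12.0, 15.0, 20.0):
    row = f"{energy:4.0f} keV"
    for distance in (0.05, 1.0, 3.0):
        geom = pv.BeamGeometry(energy_kev=energy,
                               object_detector_distance_m=distance,
                               n_angles=1, photons=None)
        phase, att = pv.complex_transmission(vol, 0.0, geom)
        img = pv.fresnel_propagate(phase, att, distance, geom).intensity
        c = pv.roi_edge_contrast(img, [segment])[0].contrast
        row += f"{c:10.4f}"
    print(row)
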