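"""Simulate a CT scan, reconstruct it, and show the ring-artifact confound.

A cylinder phantom is scanned (400 noisy projections, 15 keV, 1 m), one
detector column is given a +2% gain error, and both sinograms are
FBP-reconstructed.  The gain error back-projects into a ring at exactly
the column's distance from the rotation center; its gray values sit in
the same range as real vessels, which is why global-threshold vessel
extraction over-counts on ring-contaminated data.
"""

import numpy as np

import phasevasc as pv
from phasevasc.phantom import cylinder_battery
from phasevasc.vesselquant import segment_vessels

vol, masks = cylinder_battery(grid=128, n_slices=8, diameters_um=(36.0, 54.0))
geom = pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                       n_angles=400, photons=1e4)
sino = pv.acquire_sinogram(vol, geom, seed=1)
ring_col = 90
ring_sino = pv.inject_ring_artifact(sino, [ring_col], [0.02])

rec_clean = pv.reconstruct_volume(sino).gray
rec_ring = pv.reconstruct_volume(ring_sino).gray

n = rec_clean.shape[1]
center = (n - 1) / 2
diff = (rec_ring - rec_clean)[4]
yy, xx = np.mgrid[0:n, 0:n]
radius = np.hypot(yy - center, xx - center)
profile = [np.abs(diff[(radius >= k) & (radius < k + 1)]).mean()
           for k in range(int(center))]
print(f"ring expected at radius {abs(ring_col - center):.1f} px, "
      f"observed at {int(np.argmax(profile))} px")

for name, rec in (("clean", rec_clean), ("with ring", rec_ring)):
    seg = segment_vessels(rec, vol.tumor_region_mask, method="robust")
    dens = pv.compute_density(seg.vessel_mask, vol.tumor_region_mask, 9.0)
    print(f"{name:10s} global-threshold density: "
          f"{dens['vascular_density_pct']:.3f} %")
print(f"ground truth density:                {vol.ground_truth.vascular_density_pct:.3f} %")
# The ring adds misclassified voxels on top of the fringe-driven
# over-segmentation — the threshold-setting difficulty of phase-contrast CT.
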