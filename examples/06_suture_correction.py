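"""Transmittance-threshold correction of the suture shadow.

Surgical suture inside the specimen is nearly opaque and shadows the
projection; pixels below a transmittance cutoff are masked and inpainted
from their surroundings before projection-based contrast analysis, so
the suture does not dominate the local-contrast statistics.
"""

import numpy as np

import phasevasc as pv

spec = pv.PhantomSpec(week_stage=2, domain_size_mm=(0.576,) * 3,
                      voxel_size_um=9.0, seed=4,
                      suture_absorption_multiplier=60.0)
spec.suture = spec.default_suture()
phantom = pv.rasterize_phantom(spec)
geom = pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                       n_angles=1, photons=None)
phase, att = pv.complex_transmission(phantom, 0.0, geom)
projection = pv.fresnel_propagate(phase, att, 1.0, geom).intensity

mask, corrected = pv.mask_low_transmittance(projection, cutoff=0.35,
                                            dilate_px=2)
print(f"projection transmittance range: "
      f"{projection.min():.3f} .. {projection.max():.3f}")
print(f"masked suture-shadow pixels: {mask.sum()} "
      f"({100 * mask.mean():.2f} % of the image)")

before = pv.local_contrast_map(projection, window=15).c_map
after = pv.local_contrast_map(corrected, window=15).c_map
print(f"mean local contrast before correction: {before.mean():.4f}")
print(f"mean local contrast after correction:  {after.mean():.4f}")
# The drop is confined to the shadow region: the suture no longer counts
# as (spurious) high-contrast structure in the projection statistics.
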