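"""Shared fixtures: small phantoms and reconstructions reused across tests.

Everything is generated at test time from seeds; session scope keeps the
expensive simulate/reconstruct artifacts to one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

import phasevasc as pv
from phasevasc.phantom import cylinder_battery


@pytest.fixture(scope="session")
def small_spec():
    """A 64^3 week-2 specimen spec (0.576 mm cube at 9 um)."""
    return pv.PhantomSpec(week_stage=2, domain_size_mm=(0.576,) * 3,
                          voxel_size_um=9.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return pv.rasterize_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_geometry():
    return pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                           n_angles=200, photons=None)


@pytest.fixture(scope="session")
def battery():
    """Cylinder battery phantom (two calibers) with ground-truth masks."""
    return cylinder_battery(grid=128, n_slices=8, diameters_um=(36, 54))


@pytest.fixture(scope="session")
def battery_recon(battery):
    """Noisy scan + FBP of the small battery phantom, plus the clean and
    ring-perturbed variants used by the ring-artifact tests."""
    vol, masks = battery
    geom = pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                           n_angles=400, photons=1e4)
    sino = pv.acquire_sinogram(vol, geom, seed=1)
    ring_col = 90
    ring_sino = pv.inject_ring_artifact(sino, [ring_col], [0.02])
    rec_clean = pv.reconstruct_volume(sino).gray
    rec_ring = pv.reconstruct_volume(ring_sino).gray
    return {"volume": vol, "masks": masks, "geometry": geom,
            "rec_clean": rec_clean, "rec_ring": rec_ring,
            "ring_col": ring_col}


def disk_image(n: int, radius: float, value: float = 1.0) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    return np.where((yy - c) ** 2 + (xx - c) ** 2 <= radius**2, value, 0.0)


def disk_chords(n: int, radius: float, value: float = 1.0) -> np.ndarray:
    """Analytic parallel-beam line integrals of a centered disk."""
    s = np.arange(n) - (n - 1) / 2.0
    return value * 2.0 * np.sqrt(np.maximum(radius**2 - s**2, 0.0))


@pytest.fixture(scope="session")
def disk():
    n, radius, mu = 129, 40.0, 0.003
    image = disk_image(n, radius, mu)
    return {"n": n, "radius": radius, "mu": mu, "image": image,
            "chords": disk_chords(n, radius, mu)}
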