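"""Numba kernels for parallel-beam forward and back projection.

Geometry convention shared by both kernels: rays live in the (y, x) plane
of a (z, y, x) volume, the rotation center sits at pixel ((n-1)/2) of both
the image and the detector, and a projection angle of 0 integrates along
+y so that the detector coordinate coincides with +x.  Path lengths are in
voxel units; callers convert to physical units.

These are deliberately simple bilinear-interpolation kernels: the inner
loop runs over z so that one trigonometric setup per (angle, t, s) serves
every slice of the volume, which is what makes full-volume projection and
reconstruction tractable on a single core.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange


@njit(parallel=True, fastmath=True, cache=True)
def _forward_kernel(vol_t, cos_a, sin_a, out):  # pragma: no cover - jit
    # vol_t: (ny, nx, nz) contiguous; out: (na, nz, ns)
    ny, nx, nz = vol_t.shape
    na = cos_a.shape[0]
    ns = out.shape[2]
    cx = (nx - 1) * 0.5
    cy = (ny - 1) * 0.5
    cs = (ns - 1) * 0.5
    for a in prange(na):
        c = cos_a[a]
        s = sin_a[a]
        for it in range(ny):
            t = it - cy
            for isd in range(ns):
                sd = isd - cs
                x = cx + sd * c - t * s
                y = cy + sd * s + t * c
                if x < 0.0 or x > nx - 1.0 or y < 0.0 or y > ny - 1.0:
                    continue
                x0 = int(np.floor(x))
                y0 = int(np.floor(y))
                x1 = min(x0 + 1, nx - 1)
                y1 = min(y0 + 1, ny - 1)
                fx = x - x0
                fy = y - y0
                w00 = (1.0 - fx) * (1.0 - fy)
                w01 = fx * (1.0 - fy)
                w10 = (1.0 - fx) * fy
                w11 = fx * fy
                for z in range(nz):
                    out[a, z, isd] += (w00 * vol_t[y0, x0, z]
                                       + w01 * vol_t[y0, x1, z]
                                       + w10 * vol_t[y1, x0, z]
                                       + w11 * vol_t[y1, x1, z])


@njit(parallel=True, fastmath=True, cache=True)
def _back_kernel(filt_t, cos_a, sin_a, center_offset, out_t):  # pragma: no cover
    # filt_t: (na, ns, nz); out_t: (ny, nx, nz)
    na, ns, nz = filt_t.shape
    ny = out_t.shape[0]
    nx = out_t.shape[1]
    cx = (nx - 1) * 0.5
    cy = (ny - 1) * 0.5
    cs = (ns - 1) * 0.5 + center_offset
    for iy in prange(ny):
        y = iy - cy
        for ix in range(nx):
            x = ix - cx
            for a in range(na):
                sd = cs + x * cos_a[a] + y * sin_a[a]
                if sd < 0.0 or sd > ns - 1.0:
                    continue
                s0 = int(np.floor(sd))
                s1 = min(s0 + 1, ns - 1)
                f = sd - s0
                for z in range(nz):
                    out_t[iy, ix, z] += ((1.0 - f) * filt_t[a, s0, z]
                                         + f * filt_t[a, s1, z])


def forward_project(volume: np.ndarray, angles_deg: np.ndarray,
                    dtype=np.float32) -> np.ndarray:
    """Line integrals of ``volume`` (z, y, x) at each angle.

    Returns (n_angles, nz, ns) with ns = nx, in voxel-length units.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    vol_t = np.ascontiguousarray(np.transpose(volume, (1, 2, 0)).astype(dtype))
    ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    out = np.zeros((len(ang), volume.shape[0], volume.shape[2]), dtype)
    _forward_kernel(vol_t, np.cos(ang), np.sin(ang), out)
    return out


def back_project(filtered: np.ndarray, angles_deg: np.ndarray,
                 center_offset: float = 0.0, dtype=np.float32) -> np.ndarray:
    """Back-project a filtered sinogram stack (na, nz, ns) onto (nz, ns, ns)."""
    filtered = np.asarray(filtered)
    na, nz, ns = filtered.shape
    filt_t = np.ascontiguousarray(np.transpose(filtered, (0, 2, 1)).astype(dtype))
    out_t = np.zeros((ns, ns, nz), dtype)
    ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    _back_kernel(filt_t, np.cos(ang), np.sin(ang), float(center_offset), out_t)
    return np.transpose(out_t, (2, 0, 1))
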