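"""Filtered back projection reconstruction of edge-enhanced sinograms.

The intensity data are log-normalized into line integrals and
reconstructed slice-by-slice with standard parallel-beam FBP (ramp filter
by default, Shepp-Logan and Hann windows available).  The edge-enhanced
intensity is reconstructed directly, without phase retrieval, exactly as
beamline "fast slice reconstruction" software does; the bright/dark
fringes at interfaces therefore survive into the reconstructed gray
values — a deliberate property the downstream contrast and segmentation
analyses rely on (and a known source of fringe artifacts around vessels).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from ._projection import back_project
from .optics import BeamGeometry, Sinogram

__all__ = ["ReconVolume", "preprocess_sinogram", "fbp_reconstruct",
           "reconstruct_volume", "FILTERS"]

log = logging.getLogger(__name__)

FILTERS = ("ramlak", "shepp-logan", "hann")


@dataclass
class ReconVolume:
    """Reconstructed grayscale volume (z = rotation axis) with provenance."""

    gray: np.ndarray
    voxel_size_um: float
    geometry: BeamGeometry | None = None
    filter_name: str = "ramlak"

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray)
        if not np.all(np.isfinite(self.gray)):
            raise ValueError("reconstruction contains non-finite values")


def preprocess_sinogram(sinogram: Sinogram | np.ndarray, i0: float = 1.0,
                        floor: float = 1e-6) -> np.ndarray:
    """Convert intensity to line integrals: -log(I / I0).

    ``i0`` is the flat (air) intensity; with the simulator's unit
    normalization it is 1.  Nonpositive ratios are clipped at ``floor``
    (and logged), so opaque pixels saturate instead of producing infs.
    """
    intensity = sinogram.intensity if isinstance(sinogram, Sinogram) else sinogram
    ratio = np.asarray(intensity, dtype=np.float64) / i0
    n_clipped = int(np.count_nonzero(ratio < floor))
    if n_clipped:
        log.info("preprocess_sinogram: clipped %d nonpositive/undersized "
                 "intensity values at floor %g", n_clipped, floor)
    return -np.log(np.clip(ratio, floor, None))


def _ramp_filter_response(n_pad: int, filter_name: str) -> np.ndarray:
    """Frequency response of the windowed ramp filter.

    Built from the exact band-limited real-space ramp kernel
    (h[0] = 1/4, h[k] = -1/(pi k)^2 for odd k, else 0) so the DC bias of a
    naive |f| ramp is avoided.
    """
    h = np.zeros(n_pad)
    h[0] = 0.25
    for i in range(1, n_pad):
        m = min(i, n_pad - i)  # symmetric (circular) kernel
        if m % 2 == 1:
            h[i] = -1.0 / (np.pi * m) ** 2
    H = 2.0 * np.real(np.fft.fft(h))
    freq = np.fft.fftfreq(n_pad)
    if filter_name == "ramlak":
        pass
    elif filter_name == "shepp-logan":
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.sinc(freq)  # sin(pi f)/(pi f)
        H *= w
    elif filter_name == "hann":
        H *= 0.5 * (1 + np.cos(2 * np.pi * freq))
    else:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    return H


def _filter_sinogram(sino: np.ndarray, filter_name: str) -> np.ndarray:
    na, nz, ns = sino.shape
    n_pad = int(2 ** np.ceil(np.log2(max(64, 2 * ns))))
    H = _ramp_filter_response(n_pad, filter_name)
    padded = np.zeros((na, nz, n_pad))
    padded[:, :, :ns] = sino
    filt = np.real(np.fft.ifft(np.fft.fft(padded, axis=2) * H, axis=2))[:, :, :ns]
    filt *= np.pi / (2.0 * na)
    return filt


def fbp_reconstruct(sinogram: np.ndarray, angles_deg: np.ndarray,
                    filter_name: str = "ramlak", center_offset: float = 0.0,
                    dtype=np.float32) -> np.ndarray:
    """Reconstruct one slice from a (n_angles, n_detector) line-integral
    sinogram.

    Standard FBP: ramp-filter each projection in Fourier space, then
    back-project with linear interpolation.  The rotation center defaults
    to the detector midpoint, shifted by ``center_offset`` pixels.  The
    transform is linear in its input and the output is in inverse
    voxel-length units (multiply by 1/voxel size for absolute attenuation
    coefficients).
    """
    sinogram = np.asarray(sinogram, dtype=np.float64)
    if sinogram.ndim != 2:
        raise ValueError("slice sinogram must be 2D (angles, detector)")
    if sinogram.shape[0] < 2:
        raise ValueError("FBP needs at least 2 projection angles")
    angles_deg = np.asarray(angles_deg, dtype=float)
    if len(angles_deg) != sinogram.shape[0]:
        raise ValueError("angle count mismatch")
    span = angles_deg.max() - angles_deg.min()
    if span > 180.0 + 1e-9:
        raise ValueError("angles must span at most 180 degrees")
    filt = _filter_sinogram(sinogram[:, None, :], filter_name)
    rec = back_project(filt, angles_deg, center_offset, dtype=dtype)
    return rec[0]


def reconstruct_volume(sinogram: Sinogram, filter_name: str = "ramlak",
                       center_offset: float = 0.0, i0: float = 1.0,
                       dtype=np.float32) -> ReconVolume:
    """Log-normalize and FBP-reconstruct every slice of a sinogram stack."""
    t0 = time.perf_counter()
    line = preprocess_sinogram(sinogram, i0=i0)
    if line.shape[0] < 2:
        raise ValueError("FBP needs at least 2 projection angles")
    filt = _filter_sinogram(line, filter_name)
    gray = back_project(filt, sinogram.angles_deg, center_offset, dtype=dtype)
    dt = time.perf_counter() - t0
    log.info("reconstruct_volume: %d slices x %d angles in %.2f s "
             "(%.1f ms/slice)", gray.shape[0], sinogram.n_angles, dt,
             1e3 * dt / gray.shape[0])
    voxel_um = sinogram.geometry.pixel_size_um if sinogram.geometry else 1.0
    return ReconVolume(gray, voxel_um, sinogram.geometry, filter_name)
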