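"""Forward imaging model: projection, Fresnel propagation, noise, rings.

The model is the standard near-field description of propagation-based
(in-line) phase contrast with a synchrotron source: a monochromatic plane
wave (the source sits tens of meters upstream, so magnification is ~1 and
the illumination is treated as parallel) traverses the object under the
projection approximation, picking up a phase shift from the refractive
index decrement delta and attenuation from the absorption index beta; the
exit wave then propagates freely over the object-to-detector distance,
where Fresnel diffraction converts phase gradients into the bright/dark
edge fringes that make unstained soft-tissue interfaces visible.  At zero
distance the model reduces exactly to conventional absorption imaging.

Propagation is carried out in Fourier space with the paraxial Fresnel
transfer function H(f) = exp(-i pi lambda z |f|^2), applied to the full
2D exit wave of each projection so edge enhancement acts along both
detector axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import default_rng

from ._projection import forward_project
from .phantom import PhantomVolume

__all__ = ["BeamGeometry", "ProjectionImage", "Sinogram", "HC_KEV_ANGSTROM",
           "complex_transmission", "fresnel_propagate", "acquire_sinogram",
           "inject_ring_artifact"]

#: hc in keV * Angstrom; wavelength[A] = HC_KEV_ANGSTROM / energy[keV].
HC_KEV_ANGSTROM = 12.39842


@dataclass(frozen=True)
class BeamGeometry:
    """Acquisition parameters of the imaging beamline.

    Defaults mirror a hard-X-ray imaging beamline: tunable energy within
    8-72.5 keV, object ~34 m from the storage ring, detector 0-8 m behind
    the object with 9 um effective pixels, and 1200 projections over 180
    degrees.  ``photons`` is the expected photon count per detector pixel
    in air (the exposure proxy); ``None`` disables noise.
    """

    energy_kev: float = 15.0
    object_detector_distance_m: float = 1.0
    source_object_distance_m: float = 34.0
    pixel_size_um: float = 9.0
    n_angles: int = 1200
    arc_deg: float = 180.0
    photons: float | None = 1e4

    def __post_init__(self) -> None:
        if not 8.0 <= self.energy_kev <= 72.5:
            raise ValueError("energy must lie within the 8-72.5 keV beamline range")
        if self.object_detector_distance_m < 0 or self.source_object_distance_m < 0:
            raise ValueError("distances must be nonnegative")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if not 0 < self.arc_deg <= 180:
            raise ValueError("arc must lie in (0, 180] degrees")
        if self.photons is not None and not np.isinf(self.photons) and self.photons <= 0:
            raise ValueError("photon level must be positive (or None for noiseless)")

    @property
    def wavelength_angstrom(self) -> float:
        return HC_KEV_ANGSTROM / self.energy_kev

    @property
    def wavelength_m(self) -> float:
        return self.wavelength_angstrom * 1e-10

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.arc_deg / self.n_angles

    @property
    def angle_step_deg(self) -> float:
        return self.arc_deg / self.n_angles


@dataclass
class ProjectionImage:
    """One edge-enhanced intensity projection (rows = z, columns = x)."""

    intensity: np.ndarray
    angle_deg: float
    geometry: BeamGeometry

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("projection intensity must be 2D")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class Sinogram:
    """Stack of projections: intensity[angle, detector_row, detector_col].

    ``gain_profile`` is the per-detector-column response multiplier (all
    ones for an ideal flat field); injected ring perturbations are
    recorded there.
    """

    intensity: np.ndarray
    angles_deg: np.ndarray
    geometry: BeamGeometry
    gain_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("sinogram intensity must be (angles, rows, columns)")
        if len(self.angles_deg) != self.intensity.shape[0]:
            raise ValueError("angle count must match the projection count")
        if len(self.angles_deg) > 1:
            steps = np.diff(self.angles_deg)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8):
                raise ValueError("angles must be strictly increasing and uniform")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.gain_profile is None:
            self.gain_profile = np.ones(self.intensity.shape[2])

    @property
    def n_angles(self) -> int:
        return self.intensity.shape[0]

    def slice_sinogram(self, row: int) -> np.ndarray:
        """(angles, detector) sinogram of one slice row."""
        return self.intensity[:, row, :]


def _rescaled_grids(volume: PhantomVolume, energy_kev: float):
    """delta/beta grids rescaled from the phantom's reference energy."""
    r = volume.reference_energy_kev / energy_kev
    return volume.delta_grid * r**2, volume.beta_grid * r**4


def complex_transmission(volume: PhantomVolume, angle_deg: float,
                         geometry: BeamGeometry):
    """Projection-approximation phase and attenuation maps at one angle.

    phase = -(2 pi / lambda) * integral of delta along the ray;
    attenuation = (4 pi / lambda) * integral of beta (so the transmitted
    intensity is exp(-attenuation)).  Both maps are (nz, nx).
    """
    maps = complex_transmission_stack(volume, np.asarray([angle_deg]), geometry)
    return maps[0][0], maps[1][0]


def complex_transmission_stack(volume: PhantomVolume, angles_deg: np.ndarray,
                               geometry: BeamGeometry):
    """Vectorized ``complex_transmission`` over many angles.

    Returns (phase, attenuation) arrays of shape (n_angles, nz, nx).
    """
    if volume.voxel_size_um <= 0:
        raise ValueError("voxel size must be positive")
    delta, beta = _rescaled_grids(volume, geometry.energy_kev)
    # stack delta and beta along z so one kernel pass projects both
    nz = delta.shape[0]
    stacked = np.concatenate([delta, beta], axis=0)
    proj = forward_project(stacked, np.asarray(angles_deg, dtype=float))
    path_m = volume.voxel_size_um * 1e-6
    lam = geometry.wavelength_m
    phase = -(2 * np.pi / lam) * proj[:, :nz, :] * path_m
    attenuation = (4 * np.pi / lam) * proj[:, nz:, :] * path_m
    return phase, attenuation


def fresnel_transfer(shape: tuple[int, int], distance_m: float,
                     geometry: BeamGeometry) -> np.ndarray:
    """Paraxial Fresnel transfer function on the detector frequency grid."""
    px_m = geometry.pixel_size_um * 1e-6
    fz = np.fft.fftfreq(shape[0], d=px_m)
    fx = np.fft.fftfreq(shape[1], d=px_m)
    f2 = fz[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-1j * np.pi * geometry.wavelength_m * distance_m * f2)


def fresnel_propagate(phase_map: np.ndarray, attenuation_map: np.ndarray,
                      distance_m: float, geometry: BeamGeometry,
                      angle_deg: float = 0.0) -> ProjectionImage:
    """Free-space propagation of the exit wave to the detector plane.

    intensity = |F^-1[ F[exp(i phase - attenuation/2)] H ]|^2.  At zero
    distance this returns exp(-attenuation) exactly (contact regime,
    i.e. conventional absorption imaging).
    """
    if distance_m < 0:
        raise ValueError("propagation distance must be nonnegative")
    phase_map = np.asarray(phase_map, dtype=np.float64)
    attenuation_map = np.asarray(attenuation_map, dtype=np.float64)
    if phase_map.shape != attenuation_map.shape:
        raise ValueError("phase and attenuation maps must share a shape")
    if distance_m == 0:
        return ProjectionImage(np.exp(-attenuation_map), angle_deg, geometry)
    px_m = geometry.pixel_size_um * 1e-6
    n = min(phase_map.shape)
    z_crit = n * px_m**2 / geometry.wavelength_m
    if distance_m > z_crit:
        warnings.warn(
            f"propagation distance {distance_m:.3g} m exceeds the aliasing "
            f"limit ~{z_crit:.3g} m of the Fresnel transfer function at this "
            "sampling; fringes may wrap")
    exit_wave = np.exp(1j * phase_map - attenuation_map / 2.0)
    det_wave = propagate_field(exit_wave, distance_m, geometry)
    return ProjectionImage(np.abs(det_wave) ** 2, angle_deg, geometry)


def propagate_field(wave: np.ndarray, distance_m: float,
                    geometry: BeamGeometry) -> np.ndarray:
    """Propagate a complex field by ``distance_m`` of free space.

    Exposed separately from :func:`fresnel_propagate` so that the
    semigroup property (propagating d1 then d2 equals d1 + d2) can be
    exercised on fields, where it holds exactly up to FFT round-off.
    """
    if distance_m < 0:
        raise ValueError("propagation distance must be nonnegative")
    if distance_m == 0:
        return np.asarray(wave, dtype=complex).copy()
    H = fresnel_transfer(wave.shape, distance_m, geometry)
    return np.fft.ifft2(np.fft.fft2(wave) * H)


def acquire_sinogram(volume: PhantomVolume, geometry: BeamGeometry,
                     seed: int | None = 0) -> Sinogram:
    """Simulate a full CT scan: one propagated, noisy projection per angle.

    Photon (Poisson) noise is applied per pixel with mean photons *
    normalized intensity; ``geometry.photons`` of None or infinity gives
    the noiseless sinogram.  Identical volume, geometry and seed produce
    identical data.
    """
    if geometry.photons is not None and not np.isinf(geometry.photons) \
            and geometry.photons <= 0:
        raise ValueError("photon level must be positive")
    angles = geometry.angles_deg
    phase, attenuation = complex_transmission_stack(volume, angles, geometry)
    d = geometry.object_detector_distance_m
    nz, nx = phase.shape[1], phase.shape[2]
    out = np.empty((len(angles), nz, nx), dtype=np.float64)
    for i in range(len(angles)):
        out[i] = fresnel_propagate(phase[i], attenuation[i], d, geometry,
                                   angles[i]).intensity
    noiseless = geometry.photons is None or np.isinf(geometry.photons)
    if not noiseless:
        rng = default_rng(None if seed is None else int(seed) % (2**31))
        out = rng.poisson(np.clip(out, 0, None) * geometry.photons) \
            .astype(np.float64) / geometry.photons
    return Sinogram(out.astype(np.float32), angles, geometry)


def inject_ring_artifact(sinogram: Sinogram, column_offsets,
                         gain_errors) -> Sinogram:
    """Miscalibrate detector columns: multiply them by (1 + gain_error).

    A constant per-column gain error is what back-projects into a
    concentric ring at radius |column - rotation center| pixels.  The
    perturbation is recorded in the returned sinogram's gain profile.
    """
    column_offsets = np.atleast_1d(np.asarray(column_offsets, dtype=int))
    gain_errors = np.broadcast_to(np.atleast_1d(np.asarray(gain_errors,
                                                           dtype=float)),
                                  column_offsets.shape)
    ns = sinogram.intensity.shape[2]
    if np.any((column_offsets < 0) | (column_offsets >= ns)):
        raise ValueError("column offsets must lie within the detector width")
    if np.any(np.abs(gain_errors) >= 1):
        raise ValueError("|gain_error| must be < 1 (nonphysical otherwise)")
    intensity = sinogram.intensity.copy()
    gain = np.asarray(sinogram.gain_profile).copy()
    for col, g in zip(column_offsets, gain_errors):
        intensity[:, :, col] *= (1.0 + g)
        gain[col] *= (1.0 + g)
    return Sinogram(intensity, sinogram.angles_deg.copy(), sinogram.geometry,
                    gain)
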