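"""X-ray optical constants for the phantom materials.

The complex refractive index is n = 1 - delta + i*beta.  delta drives the
phase shift accumulated along a ray, beta the absorption.  Values below are
order-of-magnitude realistic for soft tissue and ethanol around 15 keV
(delta ~ 1e-6, beta ~ 1e-9), derived from electron density for delta and
tabulated attenuation coefficients for beta.  They are a built-in default
table, not a measurement: every entry is configurable.

Energy scaling: delta scales with E^-2 (Thomson scattering off electron
density); beta scales with E^-4 in the photoelectric-dominated regime that
holds for soft tissue below ~30 keV.  The scaling is applied relative to
the reference energy the table is defined at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reference energy (keV) at which the default table values are defined.
REFERENCE_ENERGY_KEV = 15.0

#: Integer labels of the voxelized phantom.
BACKGROUND, LIVER, TUMOR, VESSEL, SUTURE = 0, 1, 2, 3, 4

LABEL_NAMES = {
    BACKGROUND: "background",
    LIVER: "liver",
    TUMOR: "tumor",
    VESSEL: "vessel",
    SUTURE: "suture",
}


@dataclass(frozen=True)
class Material:
    """Optical constants of one phantom material at the reference energy."""

    name: str
    delta: float  # refractive index decrement, dimensionless
    beta: float   # absorption index, dimensionless

    def at_energy(self, energy_kev: float,
                  reference_kev: float = REFERENCE_ENERGY_KEV) -> "Material":
        """Rescale (delta, beta) from the reference energy to ``energy_kev``."""
        r = reference_kev / energy_kev
        return Material(self.name, self.delta * r**2, self.beta * r**4)


def default_materials(suture_absorption_multiplier: float = 30.0) -> dict[int, Material]:
    """Default material table at 15 keV, keyed by phantom label.

    Liver and tumor are water-like soft tissue (the tumor slightly denser
    and more absorbing); the vessel lumen is ethanol, reflecting
    ethanol-dehydrated fixed specimens, which is what gives vessels their
    negative contrast against tissue without any contrast agent.  The
    suture is a dense polymer whose absorption is boosted by
    ``suture_absorption_multiplier`` so that it casts the characteristic
    low-transmittance shadow in projections.
    """
    return {
        BACKGROUND: Material("air", 0.0, 0.0),
        LIVER: Material("liver tissue", 1.05e-6, 1.15e-9),
        TUMOR: Material("tumor tissue", 1.12e-6, 1.30e-9),
        VESSEL: Material("ethanol lumen", 0.80e-6, 0.66e-9),
        SUTURE: Material("polymer suture", 1.40e-6,
                         1.15e-9 * suture_absorption_multiplier),
    }


def delta_beta_grids(label_grid: np.ndarray,
                     materials: dict[int, Material]) -> tuple[np.ndarray, np.ndarray]:
    """Map a label grid to per-voxel (delta, beta) grids via the table."""
    delta = np.zeros(label_grid.shape, dtype=np.float32)
    beta = np.zeros(label_grid.shape, dtype=np.float32)
    for lbl, mat in materials.items():
        sel = label_grid == lbl
        delta[sel] = mat.delta
        beta[sel] = mat.beta
    return delta, beta
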