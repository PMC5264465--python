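"""Shared result containers for 3D vessel quantification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class QuantReport:
    """Per-specimen quantification of tumor neovascularization.

    One row of the week-series summary: tumor volume, vascular volume,
    vascular density (vascular volume / tumor volume, percent), the
    smallest vessel diameter and the vessel-diameter histogram.

    ``min_diameter_um`` is the per-segment statistic (median local
    thickness of the thinnest connected component); the per-voxel minimum
    is kept alongside in ``min_voxel_diameter_um``.  Diameters at or below
    two voxels are at the resolution floor of the thickness estimator and
    are flagged via ``sub_resolution``.
    """

    tumor_volume_mm3: float
    vascular_volume_mm3: float
    vascular_density_pct: float
    min_diameter_um: float
    diameter_bin_edges_um: np.ndarray
    diameter_counts: np.ndarray
    week: int | None = None
    min_voxel_diameter_um: float | None = None
    sub_resolution: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameter_bin_edges_um = np.asarray(self.diameter_bin_edges_um, dtype=float)
        self.diameter_counts = np.asarray(self.diameter_counts, dtype=int)
        if self.tumor_volume_mm3 > 0:
            expected = 100.0 * self.vascular_volume_mm3 / self.tumor_volume_mm3
            if not np.isclose(expected, self.vascular_density_pct, rtol=1e-9, atol=1e-12):
                raise ValueError(
                    "vascular_density_pct inconsistent with volume ratio: "
                    f"{self.vascular_density_pct} vs {expected}")

    def as_dict(self) -> dict:
        return {
            "week": self.week,
            "tumor_volume_mm3": self.tumor_volume_mm3,
            "vascular_volume_mm3": self.vascular_volume_mm3,
            "vascular_density_pct": self.vascular_density_pct,
            "min_diameter_um": self.min_diameter_um,
            "min_voxel_diameter_um": self.min_voxel_diameter_um,
            "sub_resolution": self.sub_resolution,
            "diameter_bin_edges_um": self.diameter_bin_edges_um.tolist(),
            "diameter_counts": self.diameter_counts.tolist(),
        }
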