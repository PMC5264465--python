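"""TIFF-stack and config I/O.

Volumes travel as 32-bit float grayscale TIFF stacks with a JSON sidecar
(`<name>.json`) holding voxel size and provenance; phantoms are written
as three stacks (delta, beta, label) plus a ground-truth sidecar.
Configs are flat key/value YAML mappings mirroring the dataclass fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .materials import REFERENCE_ENERGY_KEV
from .phantom import PhantomVolume
from .quant_types import QuantReport

__all__ = ["save_volume", "load_volume", "save_phantom", "load_phantom",
           "load_config", "save_config"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(path, volume: np.ndarray, voxel_size_um: float,
                meta: dict | None = None) -> None:
    path = Path(path)
    arr = np.asarray(volume)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    side = {"voxel_size_um": voxel_size_um, "shape": list(arr.shape),
            "dtype": str(arr.dtype)}
    side.update(meta or {})
    _sidecar(path).write_text(json.dumps(side, indent=2))


def load_volume(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return arr, meta


def save_phantom(directory, phantom: PhantomVolume, stem: str = "phantom") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size_um
    save_volume(directory / f"{stem}_delta.tiff", phantom.delta_grid, vs)
    save_volume(directory / f"{stem}_beta.tiff", phantom.beta_grid, vs)
    tifffile.imwrite(directory / f"{stem}_label.tiff",
                     phantom.label_grid.astype(np.uint8),
                     photometric="minisblack")
    tifffile.imwrite(directory / f"{stem}_tumor_mask.tiff",
                     phantom.tumor_region_mask.astype(np.uint8),
                     photometric="minisblack")
    gt = phantom.ground_truth.as_dict()
    gt.update({"voxel_size_um": vs,
               "reference_energy_kev": phantom.reference_energy_kev,
               "density_tol_pct": phantom.density_tol_pct,
               "discretization_rel_err": phantom.discretization_rel_err})
    (directory / f"{stem}_ground_truth.json").write_text(json.dumps(gt, indent=2))


def load_phantom(directory, stem: str = "phantom") -> PhantomVolume:
    directory = Path(directory)
    delta, meta = load_volume(directory / f"{stem}_delta.tiff")
    beta, _ = load_volume(directory / f"{stem}_beta.tiff")
    label = tifffile.imread(directory / f"{stem}_label.tiff")
    tumor = tifffile.imread(directory / f"{stem}_tumor_mask.tiff").astype(bool)
    gt = json.loads((directory / f"{stem}_ground_truth.json").read_text())
    report = QuantReport(
        tumor_volume_mm3=gt["tumor_volume_mm3"],
        vascular_volume_mm3=gt["vascular_volume_mm3"],
        vascular_density_pct=gt["vascular_density_pct"],
        min_diameter_um=gt["min_diameter_um"],
        diameter_bin_edges_um=np.asarray(gt["diameter_bin_edges_um"]),
        diameter_counts=np.asarray(gt["diameter_counts"]),
        week=gt.get("week"),
        min_voxel_diameter_um=gt.get("min_voxel_diameter_um"),
        sub_resolution=gt.get("sub_resolution", False),
    )
    return PhantomVolume(delta, beta, label, gt["voxel_size_um"], report, tumor,
                         gt.get("reference_energy_kev", REFERENCE_ENERGY_KEV),
                         gt.get("density_tol_pct", 0.0),
                         gt.get("discretization_rel_err", 0.0))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key/value mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
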