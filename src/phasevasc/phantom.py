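"""Synthetic liver/tumor specimens with known vascular ground truth.

The generator replaces animal specimens: it builds a voxelized liver lobe
containing an embedded tumor, populates both with branching vessel trees
(regular dichotomous branching in normal liver; tortuous, cluster-forming,
partly avascular trees in the tumor), threads a low-transmittance suture
through the tumor, and reports exact ground-truth volumes so every
downstream stage of the imaging chain can be validated.

Axis convention: grids are indexed (z, y, x) with z the tomographic
rotation axis; voxels are isotropic (9 um by default).  Physical
coordinates are in mm, radii in um.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import default_rng

from .materials import (BACKGROUND, LIVER, REFERENCE_ENERGY_KEV, SUTURE,
                        TUMOR, VESSEL, Material, default_materials,
                        delta_beta_grids)
from .quant_types import QuantReport

__all__ = [
    "TreeConfig", "SutureSpec", "PhantomSpec", "VesselTree", "PhantomVolume",
    "build_vessel_tree", "rasterize_phantom", "stage_series",
    "TABLE_TUMOR_VOLUME_MM3", "TABLE_VASCULAR_DENSITY_PCT",
]

#: Printed week-series means the staged generator emulates (weeks 1-4):
#: tumor volume in mm^3 at full specimen scale, and vascular density in %.
TABLE_TUMOR_VOLUME_MM3 = {1: 3.78, 2: 27.97, 3: 129.27, 4: 409.10}
TABLE_VASCULAR_DENSITY_PCT = {1: 3.51, 2: 4.29, 3: 2.62, 4: 1.52}

#: Default avascular (necrotic) tumor-volume fraction per week; avascular
#: regions appear and then grow at the late stages.
DEFAULT_AVASCULAR_FRACTION = {1: 0.0, 2: 0.03, 3: 0.15, 4: 0.30}


class EmptyRegionError(ValueError):
    """Raised when a vessel tree is requested for a region with no volume."""


@dataclass
class TreeConfig:
    """Parameters of the stochastic recursive-bifurcation vessel model.

    Radii follow a deterministic geometric rule: every child carries
    ``radius_ratio`` times its parent's radius, so a tree of *g*
    generations spans root_radius * radius_ratio**g at the leaves.
    Segment lengths scale with the local radius.  ``tortuosity`` is the
    amplitude of a per-segment sinusoidal centerline perturbation,
    expressed as a fraction of segment length (0 = straight segments).
    ``cluster_probability`` controls glomeruloid cluster motifs: bursts of
    short curled twigs sprouting from a single node, as seen in tumor
    neovasculature.
    """

    root_radius_um: float = 90.0
    radius_ratio: float = 0.8
    min_radius_um: float = 9.0
    max_generations: int = 8
    length_to_radius: float = 6.0
    branch_angle_deg: tuple[float, float] = (25.0, 55.0)
    direction_jitter_deg: float = 8.0
    tortuosity: float = 0.08
    cluster_probability: float = 0.0
    cluster_size: int = 5
    n_roots: int = 2
    volume_overshoot: float = 1.7

    def validate(self) -> None:
        if self.root_radius_um <= 0 or self.min_radius_um <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.radius_ratio <= 1:
            raise ValueError("radius_ratio must be in (0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")


def liver_tree_config() -> TreeConfig:
    """Regular dichotomous branching of a normal hepatic tree."""
    return TreeConfig(root_radius_um=90.0, radius_ratio=0.8, tortuosity=0.05,
                      cluster_probability=0.0, n_roots=2)


def tumor_tree_config() -> TreeConfig:
    """Disorganized tumor neovasculature: strongly tortuous, with
    cluster motifs and many tiny twigs branching off a few thick feeders."""
    return TreeConfig(root_radius_um=36.0, radius_ratio=0.70,
                      length_to_radius=5.0, max_generations=10,
                      branch_angle_deg=(20.0, 80.0), direction_jitter_deg=25.0,
                      tortuosity=0.22, cluster_probability=0.25,
                      cluster_size=5, n_roots=2, volume_overshoot=10.0)


@dataclass
class SutureSpec:
    """A surgical-suture inclusion: a straight absorbing cylinder."""

    center_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (z, y, x) direction
    radius_um: float = 40.0
    length_mm: float = 0.8
    absorption_multiplier: float = 30.0


@dataclass
class PhantomSpec:
    """Complete description of one synthetic specimen.

    ``domain_size_mm`` is (z, y, x); the object (liver lobe) is kept inside
    the cylinder inscribed in the (y, x) cross-section so that parallel-beam
    tomography over 180 degrees sees it fully at every angle.
    """

    week_stage: int = 2
    domain_size_mm: tuple[float, float, float] = (1.152, 1.152, 1.152)
    voxel_size_um: float = 9.0
    tumor_volume_mm3: float | None = None  # default: 15% of the domain volume
    vascular_density_pct: float = 4.29
    liver_vascular_density_pct: float = 6.0
    avascular_fraction: float = 0.03
    suture: SutureSpec | None = None
    seed: int = 0
    liver_tree: TreeConfig = field(default_factory=liver_tree_config)
    tumor_tree: TreeConfig = field(default_factory=tumor_tree_config)
    liver_axis_fractions: tuple[float, float, float] = (0.90, 0.95, 0.95)
    tumor_center_offset_mm: tuple[float, float, float] = (0.0, 0.018, 0.018)
    reference_energy_kev: float = REFERENCE_ENERGY_KEV
    suture_absorption_multiplier: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.week_stage not in (1, 2, 3, 4):
            raise ValueError("week_stage must be one of 1..4")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if not 0 <= self.avascular_fraction < 1:
            raise ValueError("avascular_fraction must be in [0, 1)")
        if self.vascular_density_pct <= 0:
            raise ValueError("target vascular density must be positive")
        if any(s <= 0 for s in self.domain_size_mm):
            raise ValueError("domain size must be positive")
        self.liver_tree.validate()
        self.tumor_tree.validate()

    # ---- derived geometry -------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        vs = self.voxel_size_um * 1e-3
        return tuple(int(round(s / vs)) for s in self.domain_size_mm)

    @property
    def domain_center_mm(self) -> np.ndarray:
        return np.asarray(self.domain_size_mm) / 2.0

    def liver_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        """(center_mm, semi_axes_mm) of the liver-lobe ellipsoid."""
        half = np.asarray(self.domain_size_mm) / 2.0
        return self.domain_center_mm, half * np.asarray(self.liver_axis_fractions)

    def tumor_geometry(self) -> tuple[np.ndarray, float]:
        """(center_mm, radius_mm) of the spherical tumor, clamped inside
        the liver lobe."""
        vol = (0.15 * float(np.prod(self.domain_size_mm))
               if self.tumor_volume_mm3 is None else self.tumor_volume_mm3)
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        lc, lax = self.liver_geometry()
        offset = np.asarray(self.tumor_center_offset_mm, dtype=float)
        # shrink the offset until the tumor sits fully inside the lobe
        for _ in range(32):
            if np.all(np.abs(offset) + r <= lax - 2e-3 * self.voxel_size_um):
                break
            offset *= 0.5
        if r > lax.min():
            raise ValueError(
                f"tumor radius {r:.3f} mm does not fit inside the liver lobe "
                f"(smallest semi-axis {lax.min():.3f} mm)")
        return lc + offset, r

    def avascular_spheres(self) -> list[tuple[np.ndarray, float]]:
        """Necrotic exclusion spheres inside the tumor, deterministic in
        the spec seed.  Total volume ~= avascular_fraction * tumor volume."""
        if self.avascular_fraction <= 0:
            return []
        tc, tr = self.tumor_geometry()
        rng = default_rng([int(self.seed) % (2**31), 7])
        n = 1 + int(self.avascular_fraction > 0.1) + int(self.avascular_fraction > 0.25)
        vol_each = self.avascular_fraction * (4 / 3) * np.pi * tr**3 / n
        r_each = (3 * vol_each / (4 * np.pi)) ** (1 / 3)
        out = []
        for _ in range(n):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            d = rng.uniform(0, max(tr - r_each, 0) * 0.8)
            out.append((tc + u * d, r_each))
        return out

    def default_suture(self) -> SutureSpec:
        """Implantation-site suture: a fixed-caliber rod lying tangentially
        at the tumor margin (where the graft was tied in), deterministic in
        the spec seed."""
        tc, tr = self.tumor_geometry()
        rng = default_rng([int(self.seed) % (2**31), 11])
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        axis = np.cross(u, rng.normal(size=3))
        axis /= np.linalg.norm(axis)
        center = tc + u * tr  # centered on the tumor surface
        return SutureSpec(center_mm=tuple(center), axis=tuple(axis),
                          radius_um=40.0,
                          length_mm=min(2.0 * tr + 0.2,
                                        0.7 * min(self.domain_size_mm)),
                          absorption_multiplier=self.suture_absorption_multiplier)


class _Region:
    """Ellipsoidal region with spherical exclusions, in mm coordinates."""

    def __init__(self, center, semi_axes, exclude=()):
        self.center = np.asarray(center, dtype=float)
        self.semi_axes = np.asarray(semi_axes, dtype=float)
        self.exclude = [(np.asarray(c, dtype=float), float(r)) for c, r in exclude]

    def contains(self, p: np.ndarray) -> bool:
        q = (p - self.center) / self.semi_axes
        if q @ q > 1.0:
            return False
        for c, r in self.exclude:
            if np.sum((p - c) ** 2) < r * r:
                return False
        return True

    @property
    def volume_mm3(self) -> float:
        v = (4 / 3) * np.pi * float(np.prod(self.semi_axes))
        for _, r in self.exclude:
            v -= (4 / 3) * np.pi * r**3
        return max(v, 0.0)

    def surface_point(self, rng) -> tuple[np.ndarray, np.ndarray]:
        """A point on the ellipsoid surface and the inward direction."""
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = self.center + u * self.semi_axes
        inward = self.center - p
        return p, inward / np.linalg.norm(inward)


@dataclass
class VesselTree:
    """A forest of tapering vessel segments.

    ``positions`` are node coordinates in mm (N, 3); ``radii_um`` per-node
    segment radii; ``edges`` (M, 2) parent->child node indices in growth
    (breadth-first) order, so rasterizing edges in order lays thick
    proximal vessels before distal twigs.  Roots are nodes that appear as
    no edge's child.  ``tortuosity`` is the sinusoidal centerline
    perturbation amplitude shared by all segments (0 = straight).
    """

    positions: np.ndarray
    radii_um: np.ndarray
    edges: np.ndarray
    tortuosity: float
    seed: int
    region: str = "tumor"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.validate()

    def validate(self) -> None:
        if np.any(self.radii_um <= 0):
            raise ValueError("all radii must be positive")
        if self.edges.size:
            if np.any(self.edges[:, 1] <= self.edges[:, 0]):
                raise ValueError("edges must point parent -> later child (acyclic)")
            child_counts = np.bincount(self.edges[:, 1], minlength=len(self.radii_um))
            if child_counts.max(initial=0) > 1:
                raise ValueError("edge set is not a forest (node has two parents)")
            if np.any(self.radii_um[self.edges[:, 1]] >
                      self.radii_um[self.edges[:, 0]] + 1e-9):
                raise ValueError("child radius exceeds parent radius")

    @property
    def n_segments(self) -> int:
        return len(self.edges)

    def segment_length_mm(self, i: int) -> float:
        a, b = self.edges[i]
        return float(np.linalg.norm(self.positions[b] - self.positions[a]))

    def analytic_volume_mm3(self) -> float:
        """Sum of cylinder volumes pi r^2 L over segments (overlap ignored)."""
        v = 0.0
        for i, (a, b) in enumerate(self.edges):
            r = self.radii_um[b] * 1e-3
            v += np.pi * r * r * self.segment_length_mm(i)
        return v


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))


def _perpendicular(v: np.ndarray, rng) -> np.ndarray:
    while True:
        u = rng.normal(size=3)
        u -= (u @ v) * v / (v @ v)
        n = np.linalg.norm(u)
        if n > 1e-8:
            return u / n


def build_vessel_tree(spec: PhantomSpec, region: str = "tumor",
                      seed: int | None = None) -> VesselTree:
    """Grow a stochastic bifurcating vessel tree filling ``region``.

    Growth is breadth-first from one or more root segments entering
    through the region surface.  A child inherits radius_ratio times its
    parent's radius (deterministically), and growth stops when the
    cumulative analytic segment volume exceeds the region's target vessel
    volume by the configured overshoot, when radii fall below the minimum,
    or when the generation cap is reached.  Identical spec + seed yields
    identical trees.
    """
    if region not in ("liver", "tumor"):
        raise ValueError("region must be 'liver' or 'tumor'")
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = default_rng([int(seed) % (2**31), 1 if region == "liver" else 2])

    tc, tr = spec.tumor_geometry()
    if region == "tumor":
        cfg = spec.tumor_tree
        geom = _Region(tc, (tr, tr, tr), exclude=spec.avascular_spheres())
        density = spec.vascular_density_pct
        # keep feeder vessels slender relative to a small tumor, but never
        # below the caliber of co-opted host feeders (~36 um diameter)
        root_radius = min(cfg.root_radius_um, max(0.15 * tr * 1e3, 18.0))
    else:
        cfg = spec.liver_tree
        lc, lax = spec.liver_geometry()
        geom = _Region(lc, lax, exclude=[(tc, tr)])
        density = spec.liver_vascular_density_pct
        # keep the root slender relative to a small lobe
        root_radius = min(cfg.root_radius_um, 0.12 * lax.min() * 1e3)
    root_radius = max(root_radius, cfg.min_radius_um)
    region_scale_mm = float(np.min(geom.semi_axes))

    if geom.volume_mm3 <= 0:
        raise EmptyRegionError(f"region '{region}' has zero volume")
    target_mm3 = density / 100.0 * geom.volume_mm3

    positions: list[np.ndarray] = []
    radii: list[float] = []
    edges: list[tuple[int, int]] = []
    queue: deque = deque()

    for _ in range(cfg.n_roots):
        p, d = geom.surface_point(rng)
        positions.append(p)
        radii.append(root_radius)
        queue.append((len(positions) - 1, d, root_radius, 0, False))

    analytic = 0.0
    n_roots = cfg.n_roots
    vox_mm = spec.voxel_size_um * 1e-3
    while True:
        if not queue:
            # region not yet filled to target: admit another feeder root
            if analytic >= cfg.volume_overshoot * target_mm3 or n_roots >= 64:
                break
            p, d = geom.surface_point(rng)
            positions.append(p)
            radii.append(root_radius)
            queue.append((len(positions) - 1, d, root_radius, 0, False))
            n_roots += 1
        if analytic >= cfg.volume_overshoot * target_mm3:
            break
        idx, direction, radius, gen, is_cluster = queue.popleft()
        if radius < cfg.min_radius_um or gen > cfg.max_generations:
            continue
        length = cfg.length_to_radius * radius * 1e-3
        if is_cluster:
            length *= 0.5
        length = min(max(length, 3 * vox_mm), 0.6 * region_scale_mm)
        length *= rng.uniform(0.8, 1.2)

        jitter = np.deg2rad(cfg.direction_jitter_deg)
        placed = False
        for attempt in range(14):
            d = _rotate_about(direction, _perpendicular(direction, rng),
                              rng.uniform(0, jitter) if attempt == 0
                              else rng.uniform(0, jitter + attempt * 0.15))
            end = positions[idx] + d * length
            if geom.contains(end) and geom.contains(positions[idx] + d * length / 2):
                placed = True
                break
            if attempt in (5, 8, 11):
                length = max(length / 2, 2 * vox_mm)
        if not placed:
            continue

        positions.append(end)
        radii.append(radius)
        new_idx = len(positions) - 1
        edges.append((idx, new_idx))
        analytic += np.pi * (radius * 1e-3) ** 2 * length

        if is_cluster or gen >= cfg.max_generations:
            continue
        # dichotomous bifurcation with deterministic radius taper
        child_r = radius * cfg.radius_ratio
        lo, hi = np.deg2rad(cfg.branch_angle_deg)
        axis = _perpendicular(d, rng)
        for sign in (+1, -1):
            cd = _rotate_about(d, axis, sign * rng.uniform(lo, hi))
            queue.append((new_idx, cd, child_r, gen + 1, False))
        # glomeruloid cluster motif: burst of short curled twigs
        if cfg.cluster_probability > 0 and rng.random() < cfg.cluster_probability:
            twig_r = max(child_r * 0.55, cfg.min_radius_um)
            for _ in range(cfg.cluster_size):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                queue.append((new_idx, u, twig_r, cfg.max_generations, True))

    if not edges:
        raise EmptyRegionError(
            f"no vessel segments could be placed in region '{region}'")
    return VesselTree(np.array(positions), np.array(radii),
                      np.array(edges), cfg.tortuosity, int(seed), region)


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class PhantomVolume:
    """Voxelized specimen: optical-constant grids, labels and ground truth.

    ``delta_grid``/``beta_grid`` hold the refractive-index decrement and
    absorption index at ``reference_energy_kev``; ``label_grid`` the
    material enum; ``tumor_region_mask`` the full tumor support (tissue +
    embedded vessels + necrosis + suture), which is what a manual tumor
    outline would capture and is the density denominator.
    """

    delta_grid: np.ndarray
    beta_grid: np.ndarray
    label_grid: np.ndarray
    voxel_size_um: float
    ground_truth: QuantReport
    tumor_region_mask: np.ndarray
    reference_energy_kev: float = REFERENCE_ENERGY_KEV
    density_tol_pct: float = 0.0
    discretization_rel_err: float = 0.0
    subresolution_segments: int = 0
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        shapes = {self.delta_grid.shape, self.beta_grid.shape,
                  self.label_grid.shape, self.tumor_region_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all grids must share one shape")
        if np.any(self.delta_grid < 0) or np.any(self.beta_grid < 0):
            raise ValueError("delta and beta must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def vessel_mask(self) -> np.ndarray:
        return self.label_grid == VESSEL

    def suture_mask(self) -> np.ndarray:
        return self.label_grid == SUTURE


def _mm_to_vox(p_mm: np.ndarray, voxel_size_um: float) -> np.ndarray:
    """mm coordinates -> fractional voxel indices (voxel centers at i + 0.5)."""
    return p_mm / (voxel_size_um * 1e-3) - 0.5


def _segment_centerline(tree: VesselTree, i: int, voxel_size_um: float,
                        n_min: int = 6) -> np.ndarray:
    """Sample the (possibly sinusoidally perturbed) centerline of segment i
    at ~0.4-voxel spacing, in mm.  Deterministic in (tree.seed, i)."""
    a, b = tree.edges[i]
    p0, p1 = tree.positions[a], tree.positions[b]
    length = np.linalg.norm(p1 - p0)
    vox_mm = voxel_size_um * 1e-3
    n = max(n_min, int(np.ceil(length / (0.4 * vox_mm))) + 1)
    t = np.linspace(0.0, 1.0, n)
    line = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    if tree.tortuosity > 0 and length > 0:
        rng = default_rng([int(tree.seed) % (2**31), 104729 + i])
        d = (p1 - p0) / length
        u = _perpendicular(d, rng)
        v = np.cross(d, u)
        amp = tree.tortuosity * length
        freq = rng.integers(1, 3)
        phase = rng.uniform(0, 2 * np.pi)
        sweep = np.sin(np.pi * t) * np.sin(2 * np.pi * freq * t + phase)
        sweep -= sweep[0]  # endpoints stay fixed via the sin(pi t) envelope
        angle = rng.uniform(0, 2 * np.pi)
        perp = np.cos(angle) * u + np.sin(angle) * v
        line = line + amp * sweep[:, None] * perp[None, :]
    return line


def _paint_segment(mask: np.ndarray, centerline_mm: np.ndarray,
                   radius_um: float, voxel_size_um: float,
                   allowed: np.ndarray,
                   budget: int | None = None) -> tuple[int, bool]:
    """Mark voxels within radius of the centerline (restricted to
    ``allowed``).

    When ``budget`` is given and the full segment would paint more new
    voxels, only the proximal part of the segment is painted (voxels are
    assigned to their nearest centerline chord and painted in arc-length
    order), leaving a truncated terminal vessel; this is what lets the
    rasterizer hit a target vessel-voxel count to within one chord disk.
    Returns (# newly painted voxels, sub_resolution flag).
    """
    shape = mask.shape
    r_vox = radius_um / voxel_size_um
    sub = r_vox < 0.5
    pts = _mm_to_vox(centerline_mm, voxel_size_um)  # (n, 3) fractional idx
    eff_r = max(r_vox, 0.5)
    lo = np.maximum(np.floor(pts.min(axis=0) - eff_r - 1).astype(int), 0)
    hi = np.minimum(np.ceil(pts.max(axis=0) + eff_r + 1).astype(int) + 1,
                    np.asarray(shape))
    if np.any(hi <= lo):
        return 0, sub
    zz, yy, xx = np.meshgrid(*(np.arange(lo[k], hi[k]) for k in range(3)),
                             indexing="ij")
    box = np.stack([zz, yy, xx], axis=-1).astype(float)  # voxel indices
    d2min = np.full(box.shape[:3], np.inf)
    kmin = np.zeros(box.shape[:3], dtype=np.int32)  # nearest chord index
    for k in range(len(pts) - 1):
        # distance to the chord between consecutive samples
        p, q = pts[k], pts[k + 1]
        pq = q - p
        denom = pq @ pq
        w = box - p
        if denom > 1e-12:
            t = np.clip(np.einsum("zyxc,c->zyx", w, pq) / denom, 0.0, 1.0)
        else:
            t = np.zeros(box.shape[:3])
        diff = w - t[..., None] * pq
        d2 = np.einsum("zyxc,zyxc->zyx", diff, diff)
        closer = d2 < d2min
        kmin[closer] = k
        d2min[closer] = d2[closer]
    inside = d2min <= eff_r * eff_r
    sub_mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_allowed = allowed[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    new = inside & sub_allowed & ~sub_mask
    n_new = int(new.sum())
    if budget is not None and n_new > budget:
        # truncate: keep only voxels near the proximal chords
        order = np.sort(kmin[new])
        k_cut = int(order[budget - 1]) if budget > 0 else -1
        new &= kmin <= k_cut
        inside = new  # only paint the truncated part
        n_new = int(new.sum())
        sub_mask |= new
        return n_new, sub
    sub_mask |= inside & sub_allowed
    return n_new, sub


def _ellipsoid_mask(shape, center_mm, semi_axes_mm, voxel_size_um) -> np.ndarray:
    idx = np.indices(shape).astype(np.float32)
    vox_mm = voxel_size_um * 1e-3
    out = np.zeros(shape, dtype=bool)
    q = np.zeros(shape, dtype=np.float32)
    for k in range(3):
        coord = (idx[k] + 0.5) * vox_mm
        q += ((coord - center_mm[k]) / semi_axes_mm[k]) ** 2
    out = q <= 1.0
    return out


def rasterize_phantom(spec: PhantomSpec,
                      trees: list[VesselTree] | None = None,
                      materials: dict[int, Material] | None = None) -> PhantomVolume:
    """Voxelize a specimen: liver lobe, tumor, vessel trees and suture.

    Vessel segments are painted in growth order; painting of a region's
    tree stops once the vessel voxel count inside that region reaches the
    region's target (density * region voxels), so the achieved
    ground-truth density matches the target up to one terminal segment.
    The residual |analytic - voxelized| / analytic volume discrepancy of
    the painted tumor segments is reported as ``discretization_rel_err``
    and folded into ``density_tol_pct``.

    Label priority at overlaps: suture > vessel > tumor > liver > background.
    """
    spec.validate()
    shape = spec.grid_shape
    vs = spec.voxel_size_um
    if trees is None:
        trees = [build_vessel_tree(spec, "liver"), build_vessel_tree(spec, "tumor")]
    if materials is None:
        materials = default_materials(spec.suture_absorption_multiplier)

    label = np.zeros(shape, dtype=np.uint8)
    lc, lax = spec.liver_geometry()
    liver_mask = _ellipsoid_mask(shape, lc, lax, vs)
    tc, tr = spec.tumor_geometry()
    tumor_mask = _ellipsoid_mask(shape, tc, (tr, tr, tr), vs) & liver_mask
    label[liver_mask] = LIVER
    label[tumor_mask] = TUMOR

    tumor_voxels = int(tumor_mask.sum())
    liver_only = liver_mask & ~tumor_mask
    liver_voxels = int(liver_only.sum())
    if tumor_voxels == 0:
        raise EmptyRegionError("tumor region rasterized to zero voxels")

    # the suture is laid down first and excluded from the vessel-painting
    # domain, so the density target is met in the remaining tumor space and
    # the suture > vessel label priority costs no vessel voxels
    suture = spec.suture
    smask = np.zeros(shape, dtype=bool)
    if suture is not None:
        c = np.asarray(suture.center_mm)
        ax = np.asarray(suture.axis, dtype=float)
        ax /= np.linalg.norm(ax)
        half = suture.length_mm / 2.0
        ends = np.stack([c - ax * half, c + ax * half])
        # densify so the painter's chord distance is exact for a straight rod
        t = np.linspace(0, 1, 9)[:, None]
        line = ends[0][None, :] * (1 - t) + ends[1][None, :] * t
        _paint_segment(smask, line, suture.radius_um, vs,
                       np.ones(shape, dtype=bool))

    vessel_mask = np.zeros(shape, dtype=bool)
    n_subres = 0
    tumor_segments_painted: list[tuple[float, int]] = []  # (radius_um, voxels)
    analytic_painted_mm3 = 0.0
    last_increment = 0

    for tree in trees:
        if tree.region == "tumor":
            allowed = tumor_mask & ~smask
            target_vox = int(round(spec.vascular_density_pct / 100.0 * tumor_voxels))
        else:
            allowed = liver_only & ~smask
            target_vox = int(round(spec.liver_vascular_density_pct / 100.0
                                   * liver_voxels))
        painted = 0
        for i in range(tree.n_segments):
            if painted >= target_vox:
                break
            cl = _segment_centerline(tree, i, vs)
            radius = tree.radii_um[tree.edges[i, 1]]
            if tree.region == "tumor":
                # analytic volume of the paintable part of the segment:
                # centerline samples outside the region or inside an
                # already-painted vessel (junction overlap) do not add volume
                idx = np.clip(np.round(_mm_to_vox(cl, vs)).astype(int), 0,
                              np.asarray(shape) - 1)
                ok = allowed[idx[:, 0], idx[:, 1], idx[:, 2]] \
                    & ~vessel_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
                seg_len = np.linalg.norm(np.diff(cl, axis=0), axis=1)
                frac = float(ok[:-1].mean()) if len(ok) > 1 else 0.0
                seg_analytic = np.pi * (radius * 1e-3) ** 2 * seg_len.sum() * frac
            n_new, sub = _paint_segment(vessel_mask, cl, radius, vs, allowed,
                                        budget=target_vox - painted)
            painted += n_new
            n_subres += int(sub)
            if tree.region == "tumor" and n_new > 0:
                tumor_segments_painted.append((radius, n_new))
                if painted >= target_vox:  # segment was truncated at target
                    seg_analytic = min(seg_analytic,
                                       n_new * (vs * 1e-3) ** 3)
                analytic_painted_mm3 += seg_analytic
                last_increment = n_new
        if painted < 0.5 * target_vox:
            warnings.warn(
                f"{tree.region} tree reached only {painted}/{target_vox} "
                "target vessel voxels; consider more generations or roots")

    label[vessel_mask] = VESSEL

    if suture is not None:
        label[smask] = SUTURE

    delta, beta = delta_beta_grids(label, materials)

    vessel_in_tumor = int(((label == VESSEL) & tumor_mask).sum())
    voxvol = (vs * 1e-3) ** 3
    density = 100.0 * vessel_in_tumor / tumor_voxels

    painted_vox_mm3 = sum(n for _, n in tumor_segments_painted) * voxvol
    disc_rel = (abs(analytic_painted_mm3 - painted_vox_mm3) / analytic_painted_mm3
                if analytic_painted_mm3 > 0 else 0.0)
    granularity_pct = 100.0 * last_increment / tumor_voxels
    density_tol_pct = spec.vascular_density_pct * disc_rel + granularity_pct

    diam = np.array([2 * r for r, _ in tumor_segments_painted]) \
        if tumor_segments_painted else np.array([2 * spec.tumor_tree.min_radius_um])
    bin_w = vs
    edges = np.arange(0.0, diam.max() + 2 * bin_w, bin_w)
    counts, _ = np.histogram(diam, bins=edges)
    gt = QuantReport(
        tumor_volume_mm3=tumor_voxels * voxvol,
        vascular_volume_mm3=vessel_in_tumor * voxvol,
        vascular_density_pct=density,
        min_diameter_um=float(diam.min()),
        diameter_bin_edges_um=edges,
        diameter_counts=counts,
        week=spec.week_stage,
        min_voxel_diameter_um=float(diam.min()),
        sub_resolution=bool(diam.min() < 2 * vs),
        meta={"target_density_pct": spec.vascular_density_pct,
              "density_tol_pct": density_tol_pct},
    )
    return PhantomVolume(delta, beta, label, vs, gt, tumor_mask,
                         spec.reference_energy_kev, density_tol_pct,
                         disc_rel, n_subres, spec)


def stage_series(base_spec: PhantomSpec, seed: int | None = None,
                 week4_volume_mm3: float | None = None,
                 densities: dict[int, float] | None = None,
                 avascular: dict[int, float] | None = None,
                 include_suture: bool = True) -> list[PhantomVolume]:
    """Generate the four-week tumor-growth series.

    Tumor volumes follow the printed week-series ratios (roughly
    1 : 7.4 : 34 : 108), scaled so the week-4 tumor occupies
    ``week4_volume_mm3`` (default: the largest sphere that fits the
    lobe with margin).  Densities rise to week 2 and then fall; the
    avascular fraction grows at weeks 3-4.
    """
    seed = base_spec.seed if seed is None else int(seed)
    densities = dict(TABLE_VASCULAR_DENSITY_PCT if densities is None else densities)
    avascular = dict(DEFAULT_AVASCULAR_FRACTION if avascular is None else avascular)
    if week4_volume_mm3 is None:
        # keep a parenchyma margin around even the largest tumor: its
        # boundary must stay clear of the specimen/air interface fringes
        domain_vol = float(np.prod(base_spec.domain_size_mm))
        week4_volume_mm3 = 0.14 * domain_vol
    ratios = {w: TABLE_TUMOR_VOLUME_MM3[w] / TABLE_TUMOR_VOLUME_MM3[4]
              for w in (1, 2, 3, 4)}
    volumes = []
    for week in (1, 2, 3, 4):
        spec = replace(base_spec,
                       week_stage=week,
                       tumor_volume_mm3=week4_volume_mm3 * ratios[week],
                       vascular_density_pct=densities[week],
                       avascular_fraction=avascular[week],
                       seed=(seed * 10 + week) % (2**31))
        if include_suture and spec.suture is None:
            spec.suture = spec.default_suture()
        volumes.append(rasterize_phantom(spec))
    return volumes


def cylinder_battery(diameters_um=(9, 18, 27, 36, 45, 54, 63, 72, 81, 90),
                     grid: int = 128, n_slices: int | None = None,
                     voxel_size_um: float = 9.0,
                     materials: dict[int, Material] | None = None,
                     tissue_radius_fraction: float = 0.44,
                     ) -> tuple[PhantomVolume, dict[float, np.ndarray]]:
    """Detection-limit test object: straight vessels of graded caliber.

    Ethanol-filled cylinders of the given diameters run along the rotation
    axis through a liver-tissue cylinder, placed on a ring so neighbouring
    fringes do not interact.  Returns the voxelized phantom and a map
    diameter -> ground-truth cylinder mask, from which per-caliber voxel
    recall of a segmentation can be scored.
    """
    diameters_um = tuple(float(d) for d in diameters_um)
    if n_slices is None:
        n_slices = max(grid // 4, 8)
    shape = (n_slices, grid, grid)
    if materials is None:
        materials = default_materials()
    c = (grid - 1) / 2.0
    yy, xx = np.mgrid[0:grid, 0:grid].astype(float)
    tissue_r = tissue_radius_fraction * grid
    tissue = (yy - c) ** 2 + (xx - c) ** 2 <= tissue_r**2

    label2d = np.zeros((grid, grid), dtype=np.uint8)
    label2d[tissue] = LIVER
    masks2d: dict[float, np.ndarray] = {}
    ring_r = 0.62 * tissue_r
    for k, d_um in enumerate(diameters_um):
        ang = 2 * np.pi * k / len(diameters_um)
        # snap to voxel centers so sub-resolution cylinders keep >= 1 voxel
        cy = round(c + ring_r * np.sin(ang))
        cx = round(c + ring_r * np.cos(ang))
        r_vox = max(d_um / voxel_size_um / 2.0, 0.5)
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_vox**2
        m &= tissue
        label2d[m] = VESSEL
        masks2d[d_um] = m
    label = np.broadcast_to(label2d, shape).copy()
    delta, beta = delta_beta_grids(label, materials)
    tumor_region = np.broadcast_to(tissue, shape).copy()

    n_vessel = int((label == VESSEL).sum())
    n_region = int(tumor_region.sum())
    voxvol = (voxel_size_um * 1e-3) ** 3
    edges = np.arange(0.0, max(diameters_um) + 2 * voxel_size_um,
                      voxel_size_um)
    counts, _ = np.histogram(diameters_um, bins=edges)
    gt = QuantReport(
        tumor_volume_mm3=n_region * voxvol,
        vascular_volume_mm3=n_vessel * voxvol,
        vascular_density_pct=100.0 * n_vessel / n_region,
        min_diameter_um=min(diameters_um),
        diameter_bin_edges_um=edges, diameter_counts=counts,
        week=None, min_voxel_diameter_um=min(diameters_um),
        sub_resolution=min(diameters_um) < 2 * voxel_size_um,
    )
    vol = PhantomVolume(delta, beta, label, voxel_size_um, gt, tumor_region)
    masks3d = {d: np.broadcast_to(m, shape).copy() for d, m in masks2d.items()}
    return vol, masks3d
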