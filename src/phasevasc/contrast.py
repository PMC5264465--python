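"""The two image-contrast statistics used for edge-enhancement analysis.

1. Vessel-wall edge contrast from a line profile crossing the vessel
   boundary: C = (Imax - Imin) / (Imax + Imin), where Imax and Imin are
   the gray values on either side of the wall.  Operationally the two
   values are the extrema of the profile within a half-width around its
   steepest gradient, which captures the bright/dark fringe pair of
   propagation-based edge enhancement.

2. A map of overlapping local contrasts: per pixel, the coefficient of
   variation over a WxW window,
   C(x, y) = sqrt(<I^2>_W - <I>_W^2) / <I>_W,
   which quantifies the intensity fluctuation texture that dense,
   edge-enhanced vasculature produces.  The map is invariant under global
   intensity scaling and identically zero on constant images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["RoiContrast", "LocalContrastMap", "edge_contrast",
           "roi_edge_contrast", "local_contrast_map",
           "tumor_vs_liver_contrast", "sample_profile"]


@dataclass
class RoiContrast:
    """Edge contrast of one measured vessel crossing."""

    roi_id: int | str
    i_max: float
    i_min: float
    contrast: float
    degenerate: bool = False
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined:
            if self.i_max < self.i_min or self.i_min < 0:
                raise ValueError("requires i_max >= i_min >= 0")
            if not -1e-12 <= self.contrast <= 1 + 1e-12:
                raise ValueError("contrast must lie in [0, 1]")


@dataclass
class LocalContrastMap:
    """Windowed coefficient-of-variation map."""

    c_map: np.ndarray
    window: int
    boundary: str = "reflect"
    invalid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.c_map = np.asarray(self.c_map)
        if np.any(self.c_map < 0):
            raise ValueError("local contrast map must be nonnegative")


def edge_contrast(profile: np.ndarray, half_width: int = 10,
                  roi_id: int | str = 0, quantize_256: bool = False) -> RoiContrast:
    """Edge contrast C = (Imax - Imin)/(Imax + Imin) from a line profile.

    The profile is assumed to cross one vessel wall.  Imax/Imin are the
    extreme values within ``half_width`` samples of the steepest-gradient
    point, i.e. the gray levels on either side of the wall (including any
    edge-enhancement overshoot).  ``quantize_256`` first maps the profile
    onto 256 gray levels, replicating analysis on 8-bit exports.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 5:
        raise ValueError("profile must be 1D with at least 5 samples")
    if quantize_256:
        lo, hi = profile.min(), profile.max()
        if hi > lo:
            profile = np.round((profile - lo) / (hi - lo) * 255.0)
    grad = np.diff(profile)
    if np.allclose(grad, 0):
        return RoiContrast(roi_id, float(profile[0]), float(profile[0]), 0.0,
                           degenerate=True)
    g = int(np.argmax(np.abs(grad)))
    lo = max(0, g - half_width)
    hi = min(profile.size, g + 1 + half_width + 1)
    window = profile[lo:hi]
    i_max = float(window.max())
    i_min = float(window.min())
    if i_max + i_min == 0:
        return RoiContrast(roi_id, i_max, i_min, 0.0, undefined=True)
    c = (i_max - i_min) / (i_max + i_min)
    return RoiContrast(roi_id, i_max, i_min, c)


def sample_profile(image: np.ndarray, p0, p1, spacing: float = 1.0) -> np.ndarray:
    """Bilinear line profile between points p0 -> p1, given as (row, col)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / spacing)) + 1, 5)
    t = np.linspace(0.0, 1.0, n)
    coords = p0[:, None] * (1 - t) + p1[:, None] * t
    return ndi.map_coordinates(np.asarray(image, dtype=float), coords, order=1)


def roi_edge_contrast(image: np.ndarray, segments,
                      roi_boxes=None, half_width: int = 10,
                      quantize_256: bool = False) -> list[RoiContrast]:
    """Edge contrast for each marked vessel crossing.

    ``segments`` is a sequence of ((row0, col0), (row1, col1)) lines, each
    crossing a vessel boundary; ``roi_boxes`` optionally carries
    (row, col, height, width) boxes that must contain their segment.
    Returns one RoiContrast per segment; summarize with mean +/- SD over
    segments.
    """
    image = np.asarray(image, dtype=float)
    out = []
    for k, (p0, p1) in enumerate(segments):
        for p in (p0, p1):
            if not (0 <= p[0] <= image.shape[0] - 1
                    and 0 <= p[1] <= image.shape[1] - 1):
                raise ValueError(f"segment {k} endpoint {p} outside image")
        if roi_boxes is not None:
            r, c, h, w = roi_boxes[k]
            for p in (p0, p1):
                if not (r <= p[0] <= r + h and c <= p[1] <= c + w):
                    raise ValueError(f"segment {k} leaves its ROI box")
        profile = sample_profile(image, p0, p1)
        out.append(edge_contrast(profile, half_width, roi_id=k,
                                 quantize_256=quantize_256))
    return out


def contrast_summary(records: list[RoiContrast]) -> tuple[float, float]:
    """Mean and SD of contrast over measured segments."""
    c = np.array([r.contrast for r in records])
    return float(c.mean()), float(c.std(ddof=1)) if c.size > 1 else 0.0


def local_contrast_map(image: np.ndarray, window: int = 15,
                       exclude_mask: np.ndarray | None = None) -> LocalContrastMap:
    """Overlapping local-contrast (windowed coefficient of variation) map.

    Window moments use reflective boundary handling.  Pixels under
    ``exclude_mask`` (e.g. the suture shadow) are left out of the window
    averages; pixels whose window mean vanishes get map value 0 and are
    flagged in ``invalid_mask``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("image must be nonnegative")
    if exclude_mask is None:
        m1 = ndi.uniform_filter(image, window, mode="reflect")
        m2 = ndi.uniform_filter(image * image, window, mode="reflect")
    else:
        valid = (~np.asarray(exclude_mask, dtype=bool)).astype(np.float64)
        wsum = ndi.uniform_filter(valid, window, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = ndi.uniform_filter(image * valid, window, mode="reflect") / wsum
            m2 = ndi.uniform_filter(image**2 * valid, window, mode="reflect") / wsum
        m1 = np.nan_to_num(m1)
        m2 = np.nan_to_num(m2)
    var = np.clip(m2 - m1 * m1, 0.0, None)
    invalid = m1 <= 0
    c = np.zeros_like(image)
    np.divide(np.sqrt(var), m1, out=c, where=~invalid)
    return LocalContrastMap(c, window, invalid_mask=invalid)


def tumor_vs_liver_contrast(projection: np.ndarray, tumor_mask: np.ndarray,
                            liver_mask: np.ndarray, window: int = 15,
                            exclude_mask: np.ndarray | None = None
                            ) -> tuple[float, float]:
    """Mean local contrast inside the tumor and liver masks of a projection.

    On tumor-bearing specimens the normal liver shows the higher mean
    (dense regular vasculature with strong boundary enhancement) and the
    tumor the lower one.  Masks must be disjoint and nonempty.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if np.any(tumor_mask & liver_mask):
        raise ValueError("tumor and liver masks must be disjoint")
    if not tumor_mask.any() or not liver_mask.any():
        raise ValueError("masks must be nonempty")
    cmap = local_contrast_map(projection, window, exclude_mask).c_map
    return float(cmap[tumor_mask].mean()), float(cmap[liver_mask].mean())
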