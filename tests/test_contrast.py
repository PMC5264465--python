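"""Edge contrast (line-profile statistic) and local-contrast maps."""

import numpy as np
import pytest

import phasevasc as pv
from phasevasc.contrast import contrast_summary


def brute_force_cv_map(image: np.ndarray, window: int,
                       exclude: np.ndarray | None = None) -> np.ndarray:
    """Double-loop windowed coefficient of variation with reflective
    (edge-duplicating) boundaries — independent oracle for the map."""
    h = window // 2
    pad = np.pad(image, h, mode="symmetric")
    if exclude is None:
        valid = np.ones_like(pad, dtype=bool)
    else:
        valid = ~np.pad(exclude, h, mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    for y in range(image.shape[0]):
        for x in range(image.shape[1]):
            win = pad[y:y + window, x:x + window]
            ok = valid[y:y + window, x:x + window]
            vals = win[ok]
            if vals.size == 0 or vals.mean() <= 0:
                out[y, x] = 0.0
                continue
            m1 = vals.mean()
            m2 = (vals**2).mean()
            out[y, x] = np.sqrt(max(m2 - m1 * m1, 0.0)) / m1
    return out


class TestEdgeContrast:
    def test_direct_arithmetic(self):
        """Two gray levels 200 and 100 across an edge give C = 1/3."""
        profile = np.r_[np.full(10, 200.0), np.full(10, 100.0)]
        rc = pv.edge_contrast(profile)
        assert rc.i_max == 200 and rc.i_min == 100
        assert rc.contrast == pytest.approx(1.0 / 3.0)

    def test_ideal_step_full_range(self):
        profile = np.r_[np.zeros(8), np.full(8, 255.0)]
        assert pv.edge_contrast(profile).contrast == pytest.approx(1.0)

    def test_flat_profile_degenerate(self):
        rc = pv.edge_contrast(np.full(11, 37.0))
        assert rc.contrast == 0.0 and rc.degenerate

    def test_all_zero_profile_undefined(self):
        rc = pv.edge_contrast(np.r_[np.zeros(10), np.zeros(10)])
        assert rc.degenerate  # gradient-free, flagged before the 0/0 case

    def test_output_range_random_profiles(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            profile = rng.uniform(0, 255, size=rng.integers(5, 60))
            rc = pv.edge_contrast(profile)
            assert 0.0 <= rc.contrast <= 1.0
            assert rc.i_max >= rc.i_min >= 0

    def test_order_free_under_reversal(self):
        rng = np.random.default_rng(6)
        profile = np.cumsum(rng.uniform(-1, 2, 30)) + 10
        a = pv.edge_contrast(profile)
        b = pv.edge_contrast(profile[::-1])
        assert a.contrast == pytest.approx(b.contrast)

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            pv.edge_contrast(np.array([1.0, 2.0, 3.0]))


class TestRoiEdgeContrast:
    def test_dark_band_analytic_value(self):
        """A dark band on a bright background: C = (b - d)/(b + d)."""
        img = np.full((40, 40), 180.0)
        img[:, 18:23] = 60.0
        segs = [((20.0, 8.0), (20.0, 32.0))]
        rc = pv.roi_edge_contrast(img, segs)[0]
        assert rc.contrast == pytest.approx((180 - 60) / (180 + 60))

    def test_identical_segments_identical_contrast(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(50, 200, (30, 30))
        seg = ((5.0, 3.0), (25.0, 27.0))
        a, b = pv.roi_edge_contrast(img, [seg, seg])
        assert a.contrast == b.contrast

    def test_segment_outside_image_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError, match="outside"):
            pv.roi_edge_contrast(img, [((0.0, 0.0), (25.0, 5.0))])

    def test_roi_box_containment_enforced(self):
        img = np.ones((30, 30))
        segs = [((5.0, 5.0), (5.0, 25.0))]
        with pytest.raises(ValueError, match="ROI"):
            pv.roi_edge_contrast(img, segs, roi_boxes=[(0, 0, 10, 10)])

    def test_summary_mean_sd(self):
        img = np.full((40, 40), 100.0)
        img[:, 15:25] = 50.0
        segs = [((10.0, 5.0), (10.0, 35.0)), ((30.0, 5.0), (30.0, 35.0))]
        records = pv.roi_edge_contrast(img, segs)
        mean, sd = contrast_summary(records)
        assert mean == pytest.approx(records[0].contrast)
        assert sd == pytest.approx(0.0)


class TestLocalContrastMap:
    def test_constant_image_zero_map(self):
        out = pv.local_contrast_map(np.full((20, 20), 7.0), window=5)
        assert not out.c_map.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        img = rng.uniform(1.0, 10.0, (32, 32))
        out = pv.local_contrast_map(img, window=7)
        oracle = brute_force_cv_map(img, 7)
        np.testing.assert_allclose(out.c_map, oracle, atol=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        img = rng.uniform(1.0, 5.0, (24, 24))
        a = pv.local_contrast_map(img, window=5).c_map
        b = pv.local_contrast_map(3.0 * img, window=5).c_map
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_equal_count_two_level_window_gives_unit_cv(self):
        """Values {0, 2} in equal numbers: mean 1, second moment 2,
        so C = sqrt(2 - 1)/1 = 1 — the hand evaluation of the statistic."""
        vals = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0])
        m1, m2 = vals.mean(), (vals**2).mean()
        assert np.sqrt(m2 - m1**2) / m1 == pytest.approx(1.0)

    def test_masked_pixels_excluded_from_averages(self):
        rng = np.random.default_rng(13)
        img = rng.uniform(1.0, 4.0, (32, 32))
        mask = np.zeros((32, 32), bool)
        mask[10:15, 12:20] = True
        out = pv.local_contrast_map(img, window=7, exclude_mask=mask)
        oracle = brute_force_cv_map(img, 7, exclude=mask)
        np.testing.assert_allclose(out.c_map, oracle, atol=1e-10)

    def test_even_or_tiny_window_rejected(self):
        img = np.ones((10, 10))
        for w in (2, 4, 1):
            with pytest.raises(ValueError):
                pv.local_contrast_map(img, window=w)

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            pv.local_contrast_map(-np.ones((8, 8)), window=3)


class TestTumorVsLiver:
    def test_identical_texture_equal_means(self):
        rng = np.random.default_rng(21)
        img = rng.uniform(1, 2, (60, 60))
        tumor = np.zeros((60, 60), bool)
        liver = np.zeros((60, 60), bool)
        tumor[10:25, 10:50] = True
        liver[35:50, 10:50] = True
        t, l = pv.tumor_vs_liver_contrast(img, tumor, liver, window=7)
        assert abs(t - l) / l < 0.05

    def test_overlapping_masks_rejected(self):
        img = np.ones((20, 20))
        m = np.ones((20, 20), bool)
        with pytest.raises(ValueError, match="disjoint"):
            pv.tumor_vs_liver_contrast(img, m, m, window=5)

    def test_empty_mask_rejected(self):
        img = np.ones((20, 20))
        m = np.zeros((20, 20), bool)
        m2 = np.zeros((20, 20), bool)
        m2[3:6, 3:6] = True
        with pytest.raises(ValueError, match="nonempty"):
            pv.tumor_vs_liver_contrast(img, m, m2, window=5)


@pytest.fixture(scope="module")
def projection():
    # week-1 specimen: small tumor with sparse thin vessels embedded in
    # normally vascularized liver
    dom = 0.576
    spec = pv.PhantomSpec(week_stage=1, domain_size_mm=(dom,) * 3,
                          voxel_size_um=9.0, seed=7,
                          tumor_volume_mm3=0.14 * dom**3 * 3.78 / 409.10,
                          vascular_density_pct=3.51,
                          avascular_fraction=0.0)
    vol = pv.rasterize_phantom(spec)
    g = pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                        n_angles=1, photons=None)
    phase, att = pv.complex_transmission(vol, 0.0, g)
    img = pv.fresnel_propagate(phase, att, 1.0, g).intensity
    return vol, img


class TestProjectionContrastDirections:
    """Directional findings on a simulated tumor-bearing projection."""

    def test_liver_contrast_exceeds_tumor_contrast(self, projection):
        """Denser, more boundary-enhanced normal liver shows the higher
        mean local contrast in projections; the tumor reads lower."""
        vol, img = projection
        # project the masks along the beam direction (y) at angle 0
        tp = vol.tumor_region_mask.sum(axis=1)
        tumor2d = tp > 0.5 * tp.max()
        liver2d = ((vol.label_grid != 0).sum(axis=1) > 10) & (tp == 0)
        t, l = pv.tumor_vs_liver_contrast(img, tumor2d, liver2d, window=15)
        assert l > t

    def test_thin_liver_edge_has_lower_contrast_than_thick_center(self, projection):
        """The thin peripheral liver edge produces weaker boundary
        enhancement than thick central liver tissue."""
        vol, img = projection
        thickness = (vol.label_grid != 0).sum(axis=1)
        tumor2d = vol.tumor_region_mask.sum(axis=1) > 0
        thin = (thickness > 2) & (thickness < 0.25 * thickness.max()) & ~tumor2d
        thick = (thickness > 0.7 * thickness.max()) & ~tumor2d
        cmap = pv.local_contrast_map(img, window=15).c_map
        assert cmap[thin].mean() < cmap[thick].mean()
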