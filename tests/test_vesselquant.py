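"""3D quantification: masking, segmentation, density, local thickness."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import phasevasc as pv
from phasevasc.vesselquant import (correct_sinogram_transmittance,
                                   enhance_vessels, local_thickness,
                                   vessel_diameters)


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Maximal-inscribed-sphere local thickness, exhaustively.

    For every voxel c of the mask with EDT radius r, every voxel within
    distance r of c is covered by a sphere of diameter 2r; the local
    thickness is the largest such diameter.  O(N * ball volume) — fine
    for <= 64^3 test masks.
    """
    mask = np.asarray(mask, dtype=bool)
    edt = ndi.distance_transform_edt(np.pad(mask, 1))[
        tuple(slice(1, -1) for _ in mask.shape)]
    out = np.zeros(mask.shape)
    centers = np.argwhere(mask)
    for c in centers:
        r = edt[tuple(c)]
        ri = int(np.ceil(r))
        lo = np.maximum(c - ri, 0)
        hi = np.minimum(c + ri + 1, mask.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        zz, yy, xx = np.mgrid[sl]
        inside = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) \
            <= r * r
        region = out[sl]
        np.maximum(region, np.where(inside & mask[sl], 2 * r, 0), out=region)
    return out


def digital_cylinder(radius_vox: float, length: int = 40,
                     pad: int = 6) -> np.ndarray:
    n = 2 * int(radius_vox + pad) + 1
    c = n // 2  # voxel-centered axis
    yy, xx = np.mgrid[0:n, 0:n]
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    out = np.zeros((length + 6, n, n), bool)
    out[3:3 + length] = disk
    return out


class TestMaskLowTransmittance:
    def test_cutoff_below_minimum_no_change(self):
        img = np.full((20, 20), 0.8)
        mask, out = pv.mask_low_transmittance(img, cutoff=0.1)
        assert not mask.any()
        np.testing.assert_array_equal(out, img)

    def test_suture_disk_masked_exactly(self):
        """A 10%-transmittance disk under a 20% cutoff is masked exactly
        and inpainted to the background level."""
        img = np.full((64, 64), 0.85)
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (yy - 30) ** 2 + (xx - 34) ** 2 <= 8**2
        img[disk] = 0.10
        mask, out = pv.mask_low_transmittance(img, cutoff=0.20)
        np.testing.assert_array_equal(mask, disk)
        np.testing.assert_allclose(out[disk], 0.85)

    def test_overmasking_refused(self):
        img = np.full((10, 10), 0.5)
        with pytest.raises(ValueError, match="plausible"):
            pv.mask_low_transmittance(img, cutoff=0.9)

    def test_sinogram_stack_correction(self):
        intensity = np.full((6, 4, 32), 0.9)
        intensity[:, :, 10:13] = 0.05
        g = pv.BeamGeometry(n_angles=6, photons=None)
        sino = pv.Sinogram(intensity, np.arange(6) * 30.0, g)
        masks, corrected = correct_sinogram_transmittance(sino, cutoff=0.2,
                                                          dilate_px=0)
        assert masks[:, :, 10:13].all()
        np.testing.assert_allclose(corrected.intensity[:, :, 10:13], 0.9)


class TestSegmentTumor:
    def test_provided_mask_volume_arithmetic(self):
        """10^6 voxels at 9 um isotropic = 0.729 mm^3."""
        mask = np.ones((100, 100, 100), bool)
        gray = np.zeros_like(mask, dtype=float)
        tumor, n = pv.segment_tumor(gray, mask=mask)
        from phasevasc.vesselquant import tumor_volume_mm3
        assert n == 10**6
        assert tumor_volume_mm3(tumor, 9.0) == pytest.approx(0.729)

    def test_ground_truth_passthrough_exact(self, small_phantom):
        tumor, n = pv.segment_tumor(small_phantom.delta_grid,
                                    mask=small_phantom.tumor_region_mask)
        assert n == small_phantom.tumor_region_mask.sum()

    def test_seeded_growth_recovers_separable_tumor(self):
        """Seeded fallback on a 2-sigma-separated synthetic tumor reaches
        Dice >= 0.9 against ground truth."""
        rng = np.random.default_rng(3)
        shape = (48, 48, 48)
        zz, yy, xx = np.mgrid[0:48, 0:48, 0:48]
        truth = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 14**2
        gray = np.where(truth, 1.0, 0.0) + rng.normal(0, 0.2, shape)
        tumor, _ = pv.segment_tumor(gray, seed_point=(24, 24, 24),
                                    intensity_band=0.5)
        dice = 2 * (tumor & truth).sum() / (tumor.sum() + truth.sum())
        assert dice >= 0.9

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            pv.segment_tumor(np.zeros((4, 4, 4)),
                             mask=np.zeros((4, 4, 4), bool))


class TestSegmentVessels:
    def test_otsu_exact_on_bimodal_volume(self):
        gray = np.ones((20, 20, 20))
        truth = np.zeros_like(gray, dtype=bool)
        truth[5:15, 8:12, 8:12] = True
        gray[truth] = 0.0
        masks = pv.segment_vessels(gray, None, method="otsu")
        np.testing.assert_array_equal(masks.vessel_mask, truth)

    def test_fixed_threshold_at_data_minimum_empty(self):
        gray = np.ones((10, 10, 10))
        gray[5, 5, 5] = 0.0
        masks = pv.segment_vessels(gray, None, method="fixed", threshold=0.0)
        assert not masks.vessel_mask.any()

    def test_fixed_threshold_outside_range_rejected(self):
        gray = np.ones((6, 6, 6))
        with pytest.raises(ValueError):
            pv.segment_vessels(gray, None, method="fixed", threshold=5.0)

    def test_threshold_monotonicity(self):
        """Lowering the dark-vessel threshold never grows the mask."""
        rng = np.random.default_rng(8)
        gray = rng.normal(1.0, 0.2, (24, 24, 24))
        sizes = []
        for thr in (1.2, 0.9, 0.6, 0.3):
            m = pv.segment_vessels(gray, None, method="fixed", threshold=thr,
                                   min_component_voxels=1)
            sizes.append(m.vessel_mask.sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_small_components_cleaned(self):
        gray = np.ones((20, 20, 20))
        gray[2, 2, 2] = 0.0          # single-voxel speck
        gray[10:14, 10:14, 10:14] = 0.0  # 64-voxel block
        masks = pv.segment_vessels(gray, None, method="fixed", threshold=0.5,
                                   min_component_voxels=8)
        assert not masks.vessel_mask[2, 2, 2]
        assert masks.vessel_mask[11, 11, 11]

    def test_suture_voxels_excluded(self):
        rng = np.random.default_rng(17)
        gray = rng.uniform(0.0, 1.0, (10, 10, 10))
        suture = np.zeros(gray.shape, dtype=bool)
        suture[:, :5] = True
        masks = pv.segment_vessels(gray, None, method="fixed",
                                   threshold=0.5, suture_mask=suture,
                                   min_component_voxels=1)
        assert not (masks.vessel_mask & suture).any()
        assert masks.vessel_mask.any()


class TestComputeDensity:
    def test_simple_ratio(self):
        tumor = np.zeros((30, 30, 30), bool)
        tumor[:10, :10, :10] = True  # 1000... adjust to 10000 voxels
        tumor = np.zeros((30, 30, 30), bool)
        tumor.flat[:10000] = True
        vessel = np.zeros_like(tumor)
        vessel.flat[:100] = True
        out = pv.compute_density(vessel, tumor, 9.0)
        assert out["vascular_density_pct"] == pytest.approx(1.0)

    def test_full_overlap_hundred_percent(self):
        m = np.ones((8, 8, 8), bool)
        assert pv.compute_density(m, m, 9.0)["vascular_density_pct"] == 100.0

    def test_phantom_passthrough_identity(self, small_phantom):
        out = pv.compute_density(small_phantom.vessel_mask(),
                                 small_phantom.tumor_region_mask,
                                 small_phantom.voxel_size_um)
        gt = small_phantom.ground_truth
        assert out["vascular_density_pct"] == pytest.approx(
            gt.vascular_density_pct, rel=1e-12)
        assert out["tumor_volume_mm3"] == pytest.approx(gt.tumor_volume_mm3)

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError):
            pv.compute_density(np.zeros((4, 4, 4), bool),
                               np.zeros((4, 4, 4), bool), 9.0)


class TestVesselDiameters:
    def test_cylinder_median_diameter(self):
        """Radius-2 digital cylinder: median thickness 4 voxels = 36 um."""
        mask = digital_cylinder(2.0)
        out = vessel_diameters(mask, 9.0)
        assert out["min_diameter_um"] == pytest.approx(36.0, abs=9.0)

    def test_single_voxel_line_flagged_subresolution(self):
        mask = np.zeros((30, 9, 9), bool)
        mask[:, 4, 4] = True
        out = vessel_diameters(mask, 9.0)
        assert out["min_diameter_um"] <= 2 * 9.0
        assert out["sub_resolution"]

    def test_histogram_counts_components(self):
        cyl = digital_cylinder(3.0, length=30)
        mask = np.zeros((cyl.shape[0], 40, 40), bool)
        mask[5:30, 5, 5] = True
        mask[:, 20:20 + cyl.shape[1], 20:20 + cyl.shape[2]] |= cyl
        out = vessel_diameters(mask, 9.0)
        assert out["diameter_counts"].sum() == 2

    def test_min_diameter_within_one_voxel_of_truth(self):
        """Thinnest cylinder 27 um (1.5 voxel radius) reported within
        +/- 1 voxel."""
        mask = digital_cylinder(1.5)
        out = vessel_diameters(mask, 9.0)
        assert 27.0 - 9.0 <= out["min_diameter_um"] <= 27.0 + 9.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vessel_diameters(np.zeros((5, 5, 5), bool), 9.0)


class TestLocalThickness:
    @pytest.mark.parametrize("builder,name", [
        (lambda: digital_cylinder(2.0, length=30), "cylinder_r2"),
        (lambda: digital_cylinder(4.0, length=24), "cylinder_r4"),
    ])
    def test_matches_inscribed_sphere_oracle(self, builder, name):
        """2 x EDT on the skeleton agrees with the exhaustive
        maximal-inscribed-sphere thickness within 1 voxel."""
        mask = builder()
        skel, thickness = local_thickness(mask)
        oracle = brute_force_local_thickness(mask)
        assert np.abs(thickness[skel] - oracle[skel]).max() <= 1.0
        assert np.abs(thickness[mask] - oracle[mask]).max() <= 1.0

    def test_sphere_center_thickness(self):
        zz, yy, xx = np.mgrid[0:21, 0:21, 0:21]
        sphere = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 6**2
        skel, thickness = local_thickness(sphere)
        oracle = brute_force_local_thickness(sphere)
        assert np.abs(thickness[skel] - oracle[skel]).max() <= 1.0
        assert thickness.max() == pytest.approx(oracle.max(), abs=1.0)


class TestRingGrayProfile:
    def test_identical_regions_zero_difference(self):
        img = np.full((40, 40), 3.0)
        prof = pv.ring_gray_profile(img, ((5.0, 5.0), (5.0, 20.0)),
                                    ((30.0, 5.0), (30.0, 20.0)))
        assert prof.mean_difference == 0.0
        assert prof.overlap == 1.0

    def test_summary_recomputable_from_samples(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0, 1, (30, 30))
        prof = pv.ring_gray_profile(img, ((2.0, 2.0), (2.0, 25.0)),
                                    ((20.0, 2.0), (20.0, 25.0)))
        md, _ = prof.summary_recomputed()
        assert md == pytest.approx(prof.mean_difference)

    def test_segment_outside_slice_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError):
            pv.ring_gray_profile(img, ((0.0, 0.0), (25.0, 0.0)),
                                 ((1.0, 1.0), (2.0, 2.0)))

    def test_injected_ring_is_localized_at_predicted_radius(self, battery_recon):
        """A +2% single-column gain error back-projects into a ring whose
        radius equals the column's offset from the rotation center."""
        rec_c = battery_recon["rec_clean"]
        rec_r = battery_recon["rec_ring"]
        col = battery_recon["ring_col"]
        n = rec_c.shape[1]
        c = (n - 1) / 2
        diff = (rec_r - rec_c)[4]
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - c, xx - c)
        prof = np.array([np.abs(diff[(r >= k) & (r < k + 1)]).mean()
                         for k in range(int(c))])
        assert abs(np.argmax(prof) - abs(col - c)) <= 1.0
        assert prof.max() > 0

    def test_ring_confusable_with_vessel_when_amplitudes_match(self, battery):
        """With the gain error scaled so the ring amplitude approaches the
        vessel contrast, the gray-level overlap statistic flags the ring
        as confusable and a global threshold over-counts vessels."""
        vol, masks = battery
        geom = pv.BeamGeometry(energy_kev=15.0, object_detector_distance_m=1.0,
                               n_angles=400, photons=1e4)
        sino = pv.acquire_sinogram(vol, geom, seed=3)
        ring_sino = pv.inject_ring_artifact(sino, [78], [0.25])
        rec = pv.reconstruct_volume(ring_sino).gray
        sl = rec[4]
        n = sl.shape[0]
        c = (n - 1) / 2
        m = masks[54.0][4]
        ys, xs = np.nonzero(m)
        vseg = ((ys.mean() - 4.0, xs.mean()), (ys.mean() + 4.0, xs.mean()))
        ring_r = abs(78 - c)
        rseg = ((c, c + ring_r - 3), (c, c + ring_r + 3))
        prof = pv.ring_gray_profile(sl, vseg, rseg)
        assert prof.overlap > 0.3  # distributions substantially overlap
        # global threshold over-counts density relative to ground truth
        masks_seg = pv.segment_vessels(rec, vol.tumor_region_mask,
                                       method="robust")
        dens = pv.compute_density(masks_seg.vessel_mask,
                                  vol.tumor_region_mask, 9.0)
        assert dens["vascular_density_pct"] > \
            vol.ground_truth.vascular_density_pct


class TestEnhanceVessels:
    def test_removes_low_frequency_background(self):
        rng = np.random.default_rng(9)
        zz = np.linspace(0, 1, 32)
        background = zz[:, None, None] * np.ones((32, 32, 32))
        out = enhance_vessels(background, smooth_sigma=1.0, background_sigma=6.0)
        assert np.abs(out[8:-8, 8:-8, 8:-8]).max() < 0.05
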