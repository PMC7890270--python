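"""Densitometry: segmentation, weight estimate, slice metrics, biopsy,
spleen normalization — all validated against phantom ground truth and
closed-form mixing values."""

import numpy as np
import pytest

from myoct.densitometry import (
    EmptyROIError,
    PlacementError,
    SliceROI,
    body_weight_from_volumes,
    classify_tissues,
    dorsal_muscle_metrics,
    estimate_body_weight,
    normalize_densities,
    spleen_density,
    virtual_liver_biopsy,
    visceral_fat_area,
)
from myoct.volume_io import CalibratedVolume, Calibration

from conftest import make_phantom


def _uniform_volume(value_hu, shape=(8, 10, 10), voxel=0.2, slope=1.0, intercept=0.0):
    grey = np.full(shape, (value_hu - intercept) / slope, dtype=np.float32)
    return CalibratedVolume(grey, voxel, Calibration(slope, intercept))


class TestClassifyTissues:
    def test_zero_noise_phantom_recovers_truth_masks(self, tiny_phantom):
        labels = classify_tissues(tiny_phantom.calibrated())
        lab = labels.labels
        assert np.array_equal(lab == 1, tiny_phantom.masks["fat"])
        assert np.array_equal(lab == 2, tiny_phantom.masks["lean"])
        assert np.array_equal(lab == 3, tiny_phantom.masks["bone"])

    def test_all_air_volume_has_zero_compartments(self):
        labels = classify_tissues(_uniform_volume(-1000.0))
        assert labels.v_fat == labels.v_lean == labels.v_bone == 0.0

    def test_noisy_phantom_volumes_within_2_percent(self, noisy_phantom):
        labels = classify_tissues(noisy_phantom.calibrated())
        truth = noisy_phantom.truth.volumes
        for name in ("fat", "lean", "bone"):
            assert labels.volume_of(name) == pytest.approx(truth[name], rel=0.02)

    def test_overlapping_windows_rejected(self, tiny_phantom):
        with pytest.raises(ValueError, match="non-overlapping"):
            classify_tissues(
                tiny_phantom.calibrated(), fat_window=(-300, 0), lean_window=(-30, 300)
            )


class TestBodyWeight:
    @pytest.mark.parametrize(
        "v_fat,v_lean,v_bone,expected",
        [
            (0.0, 0.0, 0.0, 0.0),
            (0.0, 10.0, 0.0, 10.5),
            (15.0, 30.0, 2.0, 49.59),  # 15*0.95 + 30*1.05 + 2*1.92
        ],
    )
    def test_printed_density_formula(self, v_fat, v_lean, v_bone, expected):
        assert body_weight_from_volumes(v_fat, v_lean, v_bone) == pytest.approx(expected)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            body_weight_from_volumes(-1.0, 0.0, 0.0)

    def test_estimate_matches_truth_on_zero_noise_phantom(self, tiny_phantom):
        labels = classify_tissues(tiny_phantom.calibrated())
        assert estimate_body_weight(labels) == pytest.approx(tiny_phantom.truth.mass, rel=1e-6)


class TestSliceMetrics:
    def test_uniform_lean_slice_area_and_density(self):
        vol = _uniform_volume(50.0, shape=(4, 20, 20), voxel=0.2)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 100 pixels, 0.04 mm2 each
        m = dorsal_muscle_metrics(vol, SliceROI(1, mask), SliceROI(2, mask), (-250, 300))
        assert m.dorsal_muscle_area_mean == pytest.approx(4.0)
        assert m.dorsal_muscle_hu_mean == pytest.approx(50.0)
        assert m.flags == []

    def test_bone_pixels_excluded_without_changing_density(self):
        vol = _uniform_volume(50.0, shape=(4, 20, 20), voxel=0.2)
        hu = vol.calibration.hu_of(vol.grey_volume).copy()
        hu[1, 5:15, 5:10] = 800.0  # half of the ROI becomes bone
        vol.grey_volume = vol.calibration.grey_of(hu).astype(np.float32)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        m = dorsal_muscle_metrics(vol, SliceROI(1, mask), SliceROI(2, mask), (-250, 300))
        assert m.dorsal_muscle_area_l4 == pytest.approx(2.0)  # halved
        assert m.dorsal_muscle_hu_l4 == pytest.approx(50.0)  # unchanged

    def test_mixing_value_on_phantom(self):
        # f_m = 0.3 between lean 50 and fat -100 gives 5 HU
        p = make_phantom(muscle_lipid_fraction=0.3)
        m = dorsal_muscle_metrics(
            p.calibrated(),
            SliceROI(p.slice_index_l4, p.masks["dorsal_muscle_l4"]),
            SliceROI(p.slice_index_l5, p.masks["dorsal_muscle_l5"]),
        )
        assert m.dorsal_muscle_hu_mean == pytest.approx(5.0, abs=1e-4)

    def test_empty_roi_flagged_not_silent(self):
        vol = _uniform_volume(-1000.0, shape=(4, 8, 8))
        mask = np.ones((8, 8), dtype=bool)
        m = dorsal_muscle_metrics(vol, SliceROI(1, mask), SliceROI(2, mask), (-250, 300))
        assert "empty_roi_l4" in m.flags and "empty_roi_l5" in m.flags
        assert np.isnan(m.dorsal_muscle_hu_mean)

    def test_mean_fields_are_arithmetic_means(self, noisy_phantom):
        p = noisy_phantom
        m = dorsal_muscle_metrics(
            p.calibrated(),
            SliceROI(p.slice_index_l4, p.masks["dorsal_muscle_l4"]),
            SliceROI(p.slice_index_l5, p.masks["dorsal_muscle_l5"]),
        )
        assert m.dorsal_muscle_area_mean == pytest.approx(
            (m.dorsal_muscle_area_l4 + m.dorsal_muscle_area_l5) / 2
        )
        assert m.dorsal_muscle_hu_mean == pytest.approx(
            (m.dorsal_muscle_hu_l4 + m.dorsal_muscle_hu_l5) / 2
        )


class TestVisceralFat:
    def test_roi_without_fat_gives_zero(self):
        vol = _uniform_volume(50.0, shape=(4, 8, 8))
        assert visceral_fat_area(vol, SliceROI(1, np.ones((8, 8), bool))) == 0.0

    def test_recovers_truth_mask_area(self, tiny_phantom):
        p = tiny_phantom
        whole = np.ones(p.grey_volume.shape[1:], dtype=bool)
        area = visceral_fat_area(p.calibrated(), SliceROI(p.slice_index_l4, whole))
        # whole-slice fat at L4 = visceral deposit + subcutaneous rim
        fat_slice = p.masks["fat"][p.slice_index_l4]
        assert area == pytest.approx(fat_slice.sum() * p.voxel_size**2)
        visc_area = p.masks["visceral_fat_l4"].sum() * p.voxel_size**2
        roi_area = visceral_fat_area(
            p.calibrated(), SliceROI(p.slice_index_l4, p.masks["visceral_fat_l4"])
        )
        assert roi_area == pytest.approx(visc_area)

    def test_area_scales_with_pixel_size(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        a1 = visceral_fat_area(_uniform_volume(-100.0, (4, 8, 8), voxel=0.2), SliceROI(1, mask))
        a2 = visceral_fat_area(_uniform_volume(-100.0, (4, 8, 8), voxel=0.4), SliceROI(1, mask))
        assert a2 == pytest.approx(4.0 * a1)


class TestVirtualBiopsy:
    def test_homogeneous_liver_mean_is_liver_hu(self):
        vol = _uniform_volume(30.0, shape=(40, 40, 40), voxel=0.2)
        liver = np.zeros(vol.grey_volume.shape, dtype=bool)
        liver[5:35, 5:35, 5:35] = True
        res = virtual_liver_biopsy(vol, liver, np.zeros_like(liver), target_volume=0.05)
        assert res.mean_hu == pytest.approx(30.0)
        assert res.n_voxels > 0

    def test_mixing_value_on_phantom(self):
        # f_l = 0.4 between lean 50 and fat -100 gives -10 HU
        p = make_phantom(liver_lipid_fraction=0.4)
        res = virtual_liver_biopsy(
            p.calibrated(), p.masks["liver"], p.masks["liver_vessels"], seed=0
        )
        assert res.mean_hu == pytest.approx(-10.0, abs=1e-4)

    def test_cylinder_avoids_vessels(self, tiny_phantom):
        p = tiny_phantom
        res = virtual_liver_biopsy(p.calibrated(), p.masks["liver"], p.masks["liver_vessels"])
        assert res.vessel_margin_mm > res.radius_mm  # centre clears the vessels
        assert res.volume_cm3 <= 0.25 * p.masks["liver"].sum() * p.voxel_size**3 / 1000.0 * 1.5

    def test_deterministic_placement(self, noisy_phantom):
        p = noisy_phantom
        a = virtual_liver_biopsy(p.calibrated(), p.masks["liver"], p.masks["liver_vessels"])
        b = virtual_liver_biopsy(p.calibrated(), p.masks["liver"], p.masks["liver_vessels"])
        assert a == b

    def test_no_room_raises_placement_error(self):
        vol = _uniform_volume(30.0, shape=(10, 10, 10), voxel=0.2)
        liver = np.zeros(vol.grey_volume.shape, dtype=bool)
        liver[4:6, 4:6, 4:6] = True
        vessels = liver.copy()  # completely vascularized: nothing allowed
        with pytest.raises(PlacementError):
            virtual_liver_biopsy(vol, liver, vessels, target_volume=1.3)

    def test_empty_liver_mask_rejected(self):
        vol = _uniform_volume(30.0)
        empty = np.zeros(vol.grey_volume.shape, dtype=bool)
        with pytest.raises(PlacementError):
            virtual_liver_biopsy(vol, empty, empty)


class TestSpleenNormalization:
    def test_uniform_spleen_density(self):
        vol = _uniform_volume(50.0)
        mask = np.ones(vol.grey_volume.shape, dtype=bool)
        assert spleen_density(vol, mask) == pytest.approx(50.0)

    def test_noisy_mean_within_clt_bound(self):
        rng = np.random.default_rng(0)
        shape = (25, 20, 20)  # 10^4 voxels
        grey = (50.0 + rng.normal(0, 15.0, shape)).astype(np.float32)
        vol = CalibratedVolume(grey, 0.2, Calibration(1.0, 0.0))
        mask = np.ones(shape, dtype=bool)
        assert spleen_density(vol, mask) == pytest.approx(50.0, abs=1.0)

    def test_empty_mask_rejected(self):
        vol = _uniform_volume(50.0)
        with pytest.raises(EmptyROIError):
            spleen_density(vol, np.zeros(vol.grey_volume.shape, dtype=bool))

    def test_ratio_identities(self):
        r = normalize_densities(50.0, 50.0, 50.0, area_mean=5.0, body_weight=50.0)
        assert r.muscle_density_ratio == pytest.approx(1.0)
        assert r.relative_muscle_area == pytest.approx(0.1)
        # raw positive working scale: muscle 40 / spleen 50 = 0.8
        raw = normalize_densities(40.0, 45.0, 50.0, 5.0, 50.0, offset=0.0)
        assert raw.muscle_density_ratio == pytest.approx(0.8)

    def test_nonpositive_spleen_rejected_with_offset_hint(self):
        with pytest.raises(ValueError, match="offset"):
            normalize_densities(-500.0, -500.0, -1000.0, 5.0, 50.0)

    def test_ratio_strictly_decreasing_in_muscle_lipid(self):
        ratios = []
        for f in (0.0, 0.2, 0.4):
            p = make_phantom(muscle_lipid_fraction=f)
            m = dorsal_muscle_metrics(
                p.calibrated(),
                SliceROI(p.slice_index_l4, p.masks["dorsal_muscle_l4"]),
                SliceROI(p.slice_index_l5, p.masks["dorsal_muscle_l5"]),
            )
            sp = spleen_density(p.calibrated(), p.masks["spleen"])
            r = normalize_densities(m.dorsal_muscle_hu_mean, 0.0, sp, 1.0, 1.0)
            ratios.append(r.muscle_density_ratio)
        assert ratios[0] > ratios[1] > ratios[2]


class TestCalibrationInvariance:
    def test_segmentation_and_ratios_invariant_under_recalibration(self):
        import dataclasses

        from conftest import TINY

        base = dataclasses.replace(
            TINY, noise_sd=10.0, muscle_lipid_fraction=0.2, liver_lipid_fraction=0.2, seed=6
        )
        alt = dataclasses.replace(base, calibration=(0.5, -1200.0))
        results = []
        for spec in (base, alt):
            from myoct.phantom import generate_phantom

            p = generate_phantom(spec)
            labels = classify_tissues(p.calibrated())
            m = dorsal_muscle_metrics(
                p.calibrated(),
                SliceROI(p.slice_index_l4, p.masks["dorsal_muscle_l4"]),
                SliceROI(p.slice_index_l5, p.masks["dorsal_muscle_l5"]),
            )
            sp = spleen_density(p.calibrated(), p.masks["spleen"])
            r = normalize_densities(m.dorsal_muscle_hu_mean, 0.0, sp, 1.0, 1.0)
            results.append((labels, r.muscle_density_ratio))
        (lab_a, ratio_a), (lab_b, ratio_b) = results
        assert np.array_equal(lab_a.labels, lab_b.labels)
        assert ratio_a == pytest.approx(ratio_b, rel=1e-4)
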