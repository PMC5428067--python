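"""Phantom generator: protocol, geometry, enhancement and noise model."""

import numpy as np
import pytest

from wmgm4d.phantom import (
    LABEL_CODES,
    AcquisitionProtocol,
    EnhancementCurve,
    PhantomSpec,
    apply_rigid_motion,
    build_phantom,
    stroke_protocol,
    temporal_contrast_only_spec,
)
from wmgm4d.registration import RigidTransform


class TestStrokeProtocol:
    @pytest.mark.parametrize("late_phase,n", [(True, 24), (False, 19)])
    def test_acquisition_count(self, late_phase, n):
        assert len(stroke_protocol(late_phase)) == n

    def test_total_exposure_late_phase(self):
        assert stroke_protocol(True).total_exposure_mAs == 2250.0

    def test_structure(self):
        p = stroke_protocol(True)
        times = np.asarray(p.times_s)
        exposures = np.asarray(p.exposures_mAs)
        assert times[0] == 0.0 and exposures[0] == 200.0
        assert times[1] == 4.0
        assert np.all(np.diff(times[1:14]) == 2.0) and np.all(exposures[1:14] == 100.0)
        assert np.all(np.diff(times[14:]) == 5.0) and np.all(exposures[14:] == 75.0)

    @pytest.mark.parametrize(
        "times,exposures",
        [((1.0, 2.0), (100.0, 100.0)),      # first time not 0
         ((0.0, 2.0, 2.0), (1.0, 1.0, 1.0)),  # not strictly increasing
         ((0.0, 2.0), (100.0, -5.0)),       # negative exposure
         ((0.0, 2.0), (100.0,))],           # length mismatch
    )
    def test_invalid_protocols_rejected(self, times, exposures):
        with pytest.raises(ValueError):
            AcquisitionProtocol(times, exposures)


class TestSpecValidation:
    def test_skull_must_be_bone_bright(self):
        hu = {"air": -1000, "skull": 500, "csf": 4, "wm": 35, "gm": 45, "vessel": 50}
        with pytest.raises(ValueError, match="skull"):
            PhantomSpec(tissue_hu=hu)

    def test_gm_must_enhance_more_than_wm(self):
        spec = PhantomSpec()
        enh = dict(spec.enhancement)
        enh["gm"] = EnhancementCurve(3.0, 14.0, 8.0)  # below WM amplitude
        with pytest.raises(ValueError, match="perfused"):
            PhantomSpec(enhancement=enh)

    def test_degenerate_skull_rejected(self):
        with pytest.raises(ValueError, match="thinner"):
            PhantomSpec(skull_thickness_mm=0.2)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_phantom(PhantomSpec(grid_shape=(16, 16, 16)))


class TestBuildPhantom:
    def test_zero_noise_equals_clean(self):
        series, truth = build_phantom(
            PhantomSpec(grid_shape=(48, 48, 48), noise_constant=0.0)
        )
        for noisy, clean in zip(series.volumes, truth.clean_series.volumes):
            np.testing.assert_array_equal(noisy.data, clean.data)

    def test_labels_partition_grid(self, default_phantom):
        _, truth = default_phantom
        total = np.zeros(truth.labels.shape, dtype=int)
        for mask in truth.masks.values():
            total += mask.data
        assert np.all(total == 1)

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), rng_seed=3)
        s1, _ = build_phantom(spec)
        s2, _ = build_phantom(PhantomSpec(grid_shape=(48, 48, 48), rng_seed=3))
        for a, b in zip(s1.volumes, s2.volumes):
            np.testing.assert_array_equal(a.data, b.data)

    def test_noise_std_follows_exposure_model(self, default_phantom):
        """Measured per-volume noise std ≈ k/√E within 5% on ≥10⁴ voxels."""
        series, truth = default_phantom
        spec = PhantomSpec()
        region = np.zeros(series.shape, dtype=bool)
        region[4:28, 4:28, 4:28] = True  # uniform air corner, 13824 voxels
        region &= truth.masks["air"].data
        assert region.sum() >= 10_000
        for i in (0, 1, len(series) - 1):
            resid = series.volumes[i].data[region] - truth.clean_series.volumes[i].data[region]
            expected = spec.noise_constant / np.sqrt(series.exposures_mAs[i])
            assert resid.std() == pytest.approx(expected, rel=0.05)

    def test_noise_ratio_between_exposures(self, default_phantom):
        """std(75 mAs) / std(200 mAs) ≈ √(200/75) within 10%."""
        series, truth = default_phantom
        region = truth.masks["air"].data.copy()
        region[:, :, :2] = False
        resid0 = series.volumes[0].data[region] - truth.clean_series.volumes[0].data[region]
        late = len(series) - 1
        residL = series.volumes[late].data[region] - truth.clean_series.volumes[late].data[region]
        assert series.exposures_mAs[0] == 200.0 and series.exposures_mAs[late] == 75.0
        assert residL.std() / resid0.std() == pytest.approx(np.sqrt(200 / 75), rel=0.10)

    def test_gm_curve_peaks_above_wm(self, default_phantom):
        series, truth = default_phantom
        clean = truth.clean_series
        gm_curve = np.array([v.data[truth.masks["gm"].data].mean() for v in clean.volumes])
        wm_curve = np.array([v.data[truth.masks["wm"].data].mean() for v in clean.volumes])
        assert gm_curve.max() > wm_curve.max()


class TestRigidMotion:
    def test_identity_transforms_leave_series_unchanged(self, small_phantom):
        series, _ = small_phantom
        transforms = [RigidTransform.identity() for _ in range(len(series))]
        moved = apply_rigid_motion(series, transforms)
        for a, b in zip(moved.volumes, series.volumes):
            np.testing.assert_array_equal(a.data, b.data)

    def test_first_transform_must_be_identity(self, small_phantom):
        series, _ = small_phantom
        transforms = [RigidTransform(translation_mm=(2, 0, 0))] * len(series)
        with pytest.raises(ValueError, match="identity"):
            apply_rigid_motion(series, transforms)

    def test_skull_leaving_grid_rejected(self, small_phantom):
        series, _ = small_phantom
        transforms = [RigidTransform.identity()] + [
            RigidTransform(translation_mm=(40.0, 0, 0)) for _ in range(len(series) - 1)
        ]
        with pytest.raises(ValueError, match="skull"):
            apply_rigid_motion(series, transforms)


class TestTemporalOnlySpec:
    def test_wta_contrast_removed_but_dynamics_differ(self):
        spec = temporal_contrast_only_spec()
        assert spec.tissue_hu["gm"] == pytest.approx(spec.tissue_hu["wm"], abs=1e-6)
        w = np.asarray(spec.protocol.exposures_mAs)
        w = w / w.sum()
        t = np.asarray(spec.protocol.times_s)
        wm_mean = float(np.sum(w * spec.enhancement["wm"](t)))
        gm_mean = float(np.sum(w * spec.enhancement["gm"](t)))
        assert gm_mean == pytest.approx(wm_mean, rel=1e-6)
        assert spec.enhancement["gm"].amplitude_hu > spec.enhancement["wm"].amplitude_hu
        # curve shapes still differ at individual time points
        diff = spec.enhancement["gm"](t) - spec.enhancement["wm"](t)
        assert np.abs(diff).max() > 1.0
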