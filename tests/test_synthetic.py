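import numpy as np
import pytest

from pedimpact.corridors import ResponseCurve
from pedimpact.kinematics import ContactPlane
from pedimpact.signals import resultant
from pedimpact.synthetic import (PulseSpec, StrainFieldSpec, TrajectorySpec,
                                 default_segments, gen_angular_velocity,
                                 gen_body_surface, gen_brain_strain_field,
                                 gen_cadaver_curves, gen_crash_pulse,
                                 gen_pedestrian_trajectory,
                                 gen_skull_stress_field)


class TestCrashPulse:
    def test_zero_peak_gives_zero_channels(self):
        for ch in gen_crash_pulse(PulseSpec(peak=0.0, duration=20.0)):
            assert not ch.values.any()

    def test_constant_shape_resultant(self):
        chans = gen_crash_pulse(PulseSpec(peak=100.0, duration=20.0,
                                          shape="constant"))
        res = resultant(*chans)
        np.testing.assert_allclose(res.values, 100.0, rtol=1e-12)
        assert res.times[0] == 0.0 and res.times[-1] == pytest.approx(20.0)

    @pytest.mark.parametrize("shape", ["haversine", "triangular"])
    def test_resultant_attains_peak(self, shape):
        chans = gen_crash_pulse(PulseSpec(peak=150.0, duration=18.0, shape=shape,
                                          seed=9))
        res = resultant(*chans)
        assert res.values.max() == pytest.approx(150.0, rel=5e-3)
        assert res.values[0] == pytest.approx(0.0, abs=1e-9)
        assert res.values[-1] == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self):
        spec = PulseSpec(peak=80.0, duration=25.0, seed=42)
        a = gen_crash_pulse(spec)
        b = gen_crash_pulse(spec)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.values, cb.values)

    @pytest.mark.parametrize("bad", [
        dict(peak=-1.0, duration=10.0), dict(peak=1.0, duration=0.0),
        dict(peak=1.0, duration=10.0, sample_rate=0.0),
        dict(peak=1.0, duration=10.0, shape="square")])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            PulseSpec(**bad)


class TestAngularVelocity:
    def test_zero_peaks(self):
        for ch in gen_angular_velocity((0.0, 0.0, 0.0), 40.0):
            assert not ch.values.any()

    def test_single_axis_peak(self):
        wx, wy, wz = gen_angular_velocity((10.0, 0.0, 0.0), 40.0, seed=1)
        assert np.abs(wx.values).max() == pytest.approx(10.0, rel=1e-12)
        assert not wy.values.any() and not wz.values.any()

    def test_seed_changes_waveform_not_maxima(self):
        peaks = (25.0, 40.0, 15.0)
        a = gen_angular_velocity(peaks, 40.0, seed=1)
        b = gen_angular_velocity(peaks, 40.0, seed=2)
        assert any(not np.array_equal(ca.values, cb.values) for ca, cb in zip(a, b))
        for chans in (a, b):
            scanned = [max(abs(v) for v in ch.values) for ch in chans]
            np.testing.assert_allclose(scanned, peaks, rtol=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            gen_angular_velocity((1.0, 1.0, 1.0), -5.0)


class TestBrainStrainField:
    def test_no_exceedance_when_fraction_zero(self):
        f, truth = gen_brain_strain_field(
            StrainFieldSpec(n_elements=50, exceed_fraction=0.0, seed=3))
        assert not f.exceedance_mask(0.25).any()
        assert truth.exceeding_ids.size == 0

    def test_all_exceed_when_fraction_one(self):
        f, _ = gen_brain_strain_field(
            StrainFieldSpec(n_elements=50, exceed_fraction=1.0, seed=3))
        assert f.exceedance_mask(0.25).all()

    def test_exact_crossing_count_equal_volumes(self):
        f, truth = gen_brain_strain_field(
            StrainFieldSpec(n_elements=1000, exceed_fraction=0.49, seed=7))
        mask = f.exceedance_mask(0.25)
        assert mask.sum() == 490
        np.testing.assert_array_equal(np.nonzero(mask)[0], truth.exceeding_ids)

    def test_field_maximum_precedes_contact_by_lead(self):
        spec = StrainFieldSpec(n_elements=200, exceed_fraction=0.3,
                               contact_time=94.0, peak_lead=4.0, seed=11)
        f, truth = gen_brain_strain_field(spec)
        ei, ti = np.unravel_index(np.argmax(f.traces), f.traces.shape)
        assert f.times[ti] == truth.peak_time
        assert spec.contact_time - f.times[ti] == pytest.approx(4.0, abs=f.times[1])

    def test_lead_outside_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            gen_brain_strain_field(StrainFieldSpec(
                n_elements=10, exceed_fraction=0.5, peak_lead=7.0))

    def test_level_above_peak_rejected(self):
        with pytest.raises(ValueError, match="level"):
            gen_brain_strain_field(StrainFieldSpec(
                n_elements=10, exceed_fraction=0.5, peak_strain=0.4), level=0.5)


class TestSkullStressField:
    def test_empty_subset_stays_below_threshold(self):
        f = gen_skull_stress_field(np.full(30, 100.0), np.array([], dtype=int),
                                   seed=5)
        assert not f.exceedance_mask(65.0).any()

    def test_subset_recovered_by_direct_scan(self, rng):
        for seed in range(5):
            n = 40
            ids = rng.choice(n, size=7, replace=False)
            f = gen_skull_stress_field(np.full(n, 120.0), ids, seed=seed)
            np.testing.assert_array_equal(np.nonzero(f.exceedance_mask(65.0))[0],
                                          np.sort(ids))

    def test_out_of_range_ids_rejected(self):
        with pytest.raises(ValueError, match="range"):
            gen_skull_stress_field(np.full(5, 100.0), np.array([7]))


class TestBodySurface:
    @pytest.mark.parametrize("stature", [1690.0, 1786.0])
    def test_vertical_extent_matches_stature(self, stature):
        mesh, _ = gen_body_surface(stature, 70.0, seed=0)
        assert mesh.vertical_extent() == pytest.approx(stature, abs=1.0)

    def test_landmark_names_cover_required_set(self):
        _, lm = gen_body_surface(1690.0, 67.6)
        for name in ("vertex", "eye", "shoulder_l", "shoulder_r", "perineum",
                     "tibia", "thorax_front", "thorax_back"):
            assert name in lm

    def test_seeds_share_global_dimensions(self):
        m1, lm1 = gen_body_surface(1690.0, 67.6, seed=1)
        m2, lm2 = gen_body_surface(1690.0, 67.6, seed=2)
        assert not np.array_equal(m1.vertices, m2.vertices)  # local jitter
        assert m1.vertical_extent() == m2.vertical_extent()
        np.testing.assert_array_equal(lm1.coordinates, lm2.coordinates)

    def test_degenerate_stature_rejected(self):
        with pytest.raises(ValueError):
            gen_body_surface(0.0, 70.0)


class TestCadaverCurves:
    @pytest.fixture
    def base(self):
        x = np.linspace(0, 50, 60)
        return ResponseCurve(x, 0.1 * x, subject_mass=68.0)

    def test_zero_sd_reproduces_base(self, base):
        out = gen_cadaver_curves(4, 68.0, 0.0, base, seed=0, noise_sd=0.0)
        for mass, curve in out:
            assert mass == 68.0
            np.testing.assert_array_equal(curve.ordinate, base.ordinate)

    def test_counts_and_masses(self, base):
        out = gen_cadaver_curves(3, 68.0, 5.0, base, seed=1, noise_sd=0.1)
        assert len(out) == 3
        masses = [m for m, _ in out]
        assert len(set(masses)) == 3 and all(m > 0 for m in masses)

    def test_noise_is_bounded(self, base):
        out = gen_cadaver_curves(20, 68.0, 0.0, base, seed=2, noise_sd=0.05)
        for _, curve in out:
            assert np.abs(curve.ordinate - base.ordinate).max() <= 4 * 0.05 + 1e-12

    def test_rejects_invalid_subject_count(self, base):
        with pytest.raises(ValueError):
            gen_cadaver_curves(0, 68.0, 1.0, base)


class TestPedestrianTrajectory:
    @pytest.fixture
    def plane(self):
        return ContactPlane((2500.0, 0.0, 1200.0), (0.0, 0.0, 1.0))

    def test_vertical_impact_when_angle_90(self, plane):
        spec = TrajectorySpec(default_segments(), 40.0, plane, 100.0, 90.0, seed=0)
        traj = gen_pedestrian_trajectory(spec)
        v = traj.truth.velocity_mm_ms
        assert abs(v[0]) < 1e-9 and v[2] < 0

    def test_ground_truth_carries_targets(self, plane):
        spec = TrajectorySpec(default_segments(), 40.4, plane, 118.0, 81.0, seed=4)
        traj = gen_pedestrian_trajectory(spec)
        assert traj.truth.time_ms == 118.0
        assert traj.truth.intrusion_angle_deg == 81.0
        assert traj.truth.speed_km_h == pytest.approx(40.4, rel=1e-12)
        np.testing.assert_allclose(traj.truth.location_mm, plane.point)

    def test_head_meets_plane_at_target_time(self, plane):
        spec = TrajectorySpec(default_segments(), 35.0, plane, 95.0, 70.0, seed=2)
        traj = gen_pedestrian_trajectory(spec)
        d = plane.signed_distance(traj.head)
        i = np.argmin(np.abs(traj.times - 95.0))
        assert abs(d[i]) < 1.0  # within a sample step of the plane

    def test_unreachable_angle_rejected(self, plane):
        # a shallow angle reached very late needs a decelerating-to-negative
        # angular rate, infeasible for the chain profile
        with pytest.raises(ValueError, match="[Uu]nreachable"):
            gen_pedestrian_trajectory(TrajectorySpec(
                default_segments(), 45.0, plane, 400.0, 5.0, seed=0))

    def test_zero_angle_rejected(self, plane):
        with pytest.raises(ValueError, match="unreachable|chain"):
            gen_pedestrian_trajectory(TrajectorySpec(
                default_segments(), 40.0, plane, 100.0, 0.0, seed=0))

    def test_spec_validation(self, plane):
        with pytest.raises(ValueError):
            TrajectorySpec((-100.0,), 40.0, plane, 100.0, 45.0)
        with pytest.raises(ValueError):
            TrajectorySpec(default_segments(), 40.0, plane, 100.0, 95.0)
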