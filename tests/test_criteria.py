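import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedimpact.criteria import (InjuryReport, Thresholds, apply_flags, bric,
                                build_report, csdm, fracture_area, hic, mps)
from pedimpact.fields import ElementFieldHistory
from pedimpact.report import PUBLISHED_PEAKS, published_report
from pedimpact.signals import resultant
from pedimpact.synthetic import (PulseSpec, StrainFieldSpec,
                                 gen_angular_velocity, gen_brain_strain_field,
                                 gen_crash_pulse, gen_skull_stress_field)
from conftest import hic_brute_force


def strain_field(traces, volumes=None, dt=1.0):
    traces = np.atleast_2d(np.asarray(traces, float))
    n, m = traces.shape
    return ElementFieldHistory(
        element_ids=np.arange(n),
        element_measure=np.full(n, 1.0) if volumes is None else np.asarray(volumes, float),
        times=np.arange(m) * dt, traces=traces,
        quantity="principal_strain", measure_kind="volume_mm3")


def stress_field(traces, areas, dt=1.0):
    traces = np.atleast_2d(np.asarray(traces, float))
    return ElementFieldHistory(
        element_ids=np.arange(traces.shape[0]),
        element_measure=np.asarray(areas, float),
        times=np.arange(traces.shape[1]) * dt, traces=traces,
        quantity="von_mises_stress_MPa", measure_kind="area_mm2")


class TestHic:
    def test_zero_signal(self, channel_factory):
        value, t1, t2 = hic(channel_factory(np.zeros(100)))
        assert value == 0.0

    def test_constant_pulse_closed_form(self, channel_factory):
        # 15 ms window of constant 100 g: 0.015 * 100**2.5 = 1500
        value, t1, t2 = hic(channel_factory(np.full(300, 100.0), dt=0.1))
        assert value == pytest.approx(1500.0, rel=1e-9)
        assert t2 - t1 == pytest.approx(15.0, rel=1e-9)

    def test_matches_brute_force_on_haversine(self, channel_factory):
        chans = gen_crash_pulse(PulseSpec(peak=160.0, duration=25.0, seed=5,
                                          sample_rate=8.0))
        res = resultant(*chans)
        assert hic(res) == hic_brute_force(res)

    def test_rejects_negative_samples(self, channel_factory):
        with pytest.raises(ValueError, match="non-negative"):
            hic(channel_factory([1.0, -0.5, 1.0]))

    def test_rejects_wrong_units(self, channel_factory):
        with pytest.raises(ValueError, match="units"):
            hic(channel_factory([1.0, 1.0], units="m/s^2"))

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_property(self, scale):
        rng = np.random.default_rng(77)
        vals = rng.uniform(0, 80, size=200)
        times = np.arange(200) * 0.2
        from pedimpact.signals import TimeSeriesChannel
        base = TimeSeriesChannel(times, vals, "g")
        scaled = TimeSeriesChannel(times, vals * scale, "g")
        v0, *_ = hic(base)
        v1, *_ = hic(scaled)
        assert v1 == pytest.approx(v0 * scale**2.5, rel=1e-6)


class TestBric:
    def test_zero_omega(self):
        chans = gen_angular_velocity((0.0, 0.0, 0.0), 30.0)
        assert bric(*chans) == 0.0

    def test_normalization_to_one(self):
        chans = gen_angular_velocity((66.25, 0.0, 0.0), 30.0, seed=3)
        assert bric(*chans) == pytest.approx(1.0, rel=1e-9)

    def test_half_criticals_closed_form(self):
        chans = gen_angular_velocity((66.25 / 2, 56.45 / 2, 42.87 / 2), 30.0,
                                     seed=4)
        assert bric(*chans) == pytest.approx(np.sqrt(3 * 0.25), rel=1e-9)

    def test_invariant_to_sign_flip_and_time_reversal(self, channel_factory):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 20, size=(3, 80))
        chans = [channel_factory(v, units="rad/s") for v in vals]
        flipped = [channel_factory(-v, units="rad/s") for v in vals]
        reversed_ = [channel_factory(v[::-1], units="rad/s") for v in vals]
        assert bric(*chans) == bric(*flipped) == bric(*reversed_)

    def test_zero_critical_rejected(self, channel_factory):
        chans = [channel_factory(np.ones(5), units="rad/s")] * 3
        with pytest.raises(ValueError, match="positive"):
            bric(*chans, critical=(1.0, 0.0, 1.0))


class TestMps:
    def test_all_zeros(self):
        value, _, _ = mps(strain_field(np.zeros((4, 10))))
        assert value == 0.0

    def test_single_element_peak(self):
        traces = np.zeros((3, 5))
        traces[1, 3] = 0.86
        value, element, time = mps(strain_field(traces))
        assert (value, element, time) == (0.86, 1, 3.0)

    def test_matches_exhaustive_scan(self, rng):
        traces = rng.uniform(0, 1, size=(30, 40))
        value, element, time = mps(strain_field(traces))
        assert value == traces.max()
        assert traces[element, int(time)] == value


class TestCsdm:
    def test_no_exceedance(self):
        assert csdm(strain_field(np.full((5, 4), 0.1))) == 0.0

    def test_all_exceed(self):
        assert csdm(strain_field(np.full((5, 4), 0.4))) == 1.0

    def test_cumulative_rise_then_fall_counts(self):
        # 490 of 1000 equal-volume elements exceed 0.25 transiently
        traces = np.full((1000, 6), 0.1)
        traces[:490, 2] = 0.3   # exceed then drop back
        assert csdm(strain_field(traces)) == pytest.approx(0.490)

    def test_volume_weighting(self):
        traces = np.array([[0.4, 0.0], [0.1, 0.1]])
        f = strain_field(traces, volumes=[3.0, 1.0])
        assert csdm(f) == pytest.approx(0.75)

    def test_permutation_invariance(self, rng):
        traces = rng.uniform(0, 0.5, size=(50, 20))
        vols = rng.uniform(0.5, 2.0, size=50)
        perm = rng.permutation(50)
        a = csdm(strain_field(traces, vols))
        b = csdm(strain_field(traces[perm], vols[perm]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_nondecreasing_on_growing_prefixes(self, rng):
        f, _ = gen_brain_strain_field(StrainFieldSpec(
            n_elements=100, exceed_fraction=0.4, seed=6))
        values = []
        for stop in range(2, len(f.times), 25):
            prefix = dataclasses.replace(f, times=f.times[:stop],
                                         traces=f.traces[:, :stop])
            values.append(csdm(prefix))
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_mps_at_least_threshold_when_csdm_positive(self, rng):
        for seed in range(5):
            f, _ = gen_brain_strain_field(StrainFieldSpec(
                n_elements=60, exceed_fraction=0.3, seed=seed))
            if csdm(f) > 0:
                assert mps(f)[0] > 0.25


class TestFractureArea:
    def test_no_exceedance(self):
        f = stress_field(np.full((4, 5), 30.0), areas=np.full(4, 100.0))
        assert fracture_area(f) == 0.0

    def test_additivity_across_times(self):
        traces = np.array([[70.0, 0.0, 0.0], [0.0, 0.0, 80.0], [10.0, 10.0, 10.0]])
        f = stress_field(traces, areas=[300.0, 200.0, 999.0])
        assert fracture_area(f) == 500.0

    def test_element_counted_once(self):
        traces = np.array([[70.0, 90.0, 75.0]])
        f = stress_field(traces, areas=[300.0])
        assert fracture_area(f) == 300.0

    def test_generator_ground_truth(self, rng):
        areas = rng.uniform(50, 200, size=60)
        ids = rng.choice(60, size=12, replace=False)
        f = gen_skull_stress_field(areas, ids, seed=2)
        assert fracture_area(f) == pytest.approx(areas[np.sort(ids)].sum())

    def test_permutation_invariance(self, rng):
        traces = rng.uniform(0, 120, size=(40, 10))
        areas = rng.uniform(10, 50, size=40)
        perm = rng.permutation(40)
        a = fracture_area(stress_field(traces, areas))
        b = fracture_area(stress_field(traces[perm], areas[perm]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_rejects_volume_measures(self):
        f = strain_field(np.full((2, 3), 0.1))
        with pytest.raises(ValueError, match="von Mises"):
            fracture_area(f)


class TestBuildReport:
    def test_empty_inputs_give_empty_report(self):
        report = build_report()
        assert report.metrics() == {}
        assert report.flags == {}

    def test_composition_equals_standalone_metrics(self):
        thresholds = Thresholds(cfc_class=None)
        linear = gen_crash_pulse(PulseSpec(peak=140.0, duration=20.0, seed=1))
        angular = gen_angular_velocity((30.0, 45.0, 20.0), 30.0, seed=2)
        brain, _ = gen_brain_strain_field(StrainFieldSpec(
            n_elements=80, exceed_fraction=0.5, seed=3))
        rng = np.random.default_rng(4)
        skull = gen_skull_stress_field(rng.uniform(50, 150, 40),
                                       np.arange(5), seed=4)
        report = build_report({"linear": linear, "angular": angular},
                              skull, brain, thresholds)
        assert report.hic15 == hic(resultant(*linear))[0]
        assert report.bric == bric(*angular)
        assert report.mps == mps(brain)[0]
        assert report.csdm == csdm(brain)
        assert report.fracture_area_mm2 == fracture_area(skull)

    def test_published_peaks_all_exceed_hic_reference(self):
        thresholds = Thresholds()
        for scenario in PUBLISHED_PEAKS:
            for model in ("chinese", "thums"):
                report = apply_flags(published_report(scenario, model),
                                     thresholds)
                assert report.flags["hic_above_reference"], (scenario, model)

    def test_flags_on_thresholds(self):
        report = InjuryReport(hic15=800.0, mps=0.35, csdm=0.49,
                              fracture_area_mm2=0.0)
        report = apply_flags(report, Thresholds())
        assert report.flags == {"hic_above_reference": True,
                                "skull_fracture": False,
                                "brain_tissue_damage": True,
                                "dai": True}
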