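"""Cycle segmentation, per-cycle metrics and the seven RPI outcome measures."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoquant import rpi, synthetic
from osteoquant.exceptions import (
    InsufficientCyclesError,
    NoContactError,
    ParameterError,
    SegmentationError,
)


def _parallelogram_cycle(n=200):
    """Loading along x = F, flat top from (10, 10N) to (15, 10N),
    unloading along x = F + 5.  Enclosed area is the parallelogram's
    base x height = 5 x 10 = 50 N*um (shoelace-verified in the test)."""
    f_up = np.linspace(0.0, 10.0, n, endpoint=False)
    x_up = f_up.copy()
    f_top = np.full(12, 10.0)
    x_top = np.linspace(10.0, 15.0, 12)
    f_dn = np.linspace(10.0, 0.0, n)[1:]
    x_dn = f_dn + 5.0
    force = np.concatenate([f_up, f_top, f_dn])
    x = np.concatenate([x_up, x_top, x_dn])
    t = np.arange(force.size, dtype=float)
    return t, force, x


class TestLoopArea:
    def test_parallelogram_energy_is_shoelace_area(self):
        t, f, x = _parallelogram_cycle()
        # independent oracle: shoelace over the polygon vertices
        vx = np.array([0.0, 10.0, 15.0, 5.0])
        vf = np.array([0.0, 10.0, 10.0, 0.0])
        oracle = rpi.polygon_area(vx, vf)
        assert oracle == pytest.approx(50.0, abs=1e-12)
        m = rpi.analyze_cycle(t, f, x, origin=0.0)
        assert m.energy_dissipated == pytest.approx(50.0, rel=1e-3)
        assert m.depth_at_peak == pytest.approx(10.0, rel=1e-6)
        assert m.creep_distance == pytest.approx(5.0, rel=1e-6)
        assert m.indentation_distance == pytest.approx(15.0, rel=1e-6)
        assert m.unloading_slope == pytest.approx(1.0, rel=1e-6)

    def test_identical_load_unload_path_dissipates_nothing(self):
        f_up = np.linspace(0.0, 10.0, 300, endpoint=False)
        f_top = np.full(12, 10.0)
        f_dn = np.linspace(10.0, 0.0, 300)[1:]
        force = np.concatenate([f_up, f_top, f_dn])
        x = force * 2.0  # same path both ways, constant during the flat top
        t = np.arange(force.size, dtype=float)
        m = rpi.analyze_cycle(t, force, x, origin=0.0)
        assert m.energy_dissipated == pytest.approx(0.0, abs=1e-9)
        assert m.creep_distance == pytest.approx(0.0, abs=1e-9)

    @given(
        base=st.floats(1.0, 30.0),
        height=st.floats(1.0, 20.0),
        shear=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_shoelace_matches_parallelogram_closed_form(self, base, height, shear):
        vx = np.array([0.0, shear, shear + base, base])
        vy = np.array([0.0, height, height, 0.0])
        assert rpi.polygon_area(vx, vy) == pytest.approx(
            base * height, rel=1e-9
        )


class TestTouchdown:
    def test_origin_at_first_threshold_crossing(self, default_trace):
        trace, truth = default_trace
        origin = rpi.detect_touchdown(trace)
        # generator contact is at displacement 0; the threshold crossing
        # sits on the steep initial contact rise
        assert abs(origin) < 0.05

    def test_threshold_above_peak_force_is_no_contact(self, default_trace):
        trace, _ = default_trace
        with pytest.raises(NoContactError):
            rpi.detect_touchdown(trace, force_threshold=99.0)

    def test_trace_must_start_below_threshold(self):
        t = np.arange(200.0)
        f = np.linspace(5.0, 10.0, 200)
        with pytest.raises(ParameterError):
            rpi.detect_touchdown(
                rpi.IndentationTrace(t, f, np.linspace(0, 1, 200))
            )


class TestSegmentation:
    def test_ten_cycle_trace_gives_ten_ranges(self, default_trace):
        trace, truth = default_trace
        ranges = rpi.segment_cycles(trace, 10)
        assert len(ranges) == 10
        # contiguous, non-overlapping cover
        for (a0, b0), (a1, b1) in zip(ranges[:-1], ranges[1:]):
            assert b0 == a1
        # boundaries within 2 samples of the generator-recorded starts
        for (a, _b), start in zip(ranges[1:], truth.cycle_starts[1:]):
            assert abs(a - start) <= 2

    def test_truncated_trace_reports_found_count(self, default_trace):
        trace, truth = default_trace
        cut = truth.cycle_starts[7]
        short = rpi.IndentationTrace(
            trace.time[:cut], trace.force[:cut], trace.displacement[:cut]
        )
        with pytest.raises(SegmentationError) as exc:
            rpi.segment_cycles(short, 10)
        assert exc.value.found == 7


class TestSummary:
    def test_round_trip_recovers_all_seven_metrics(self, default_trace, default_summary):
        _trace, truth = default_trace
        for f in dataclasses.fields(rpi.RPISummary):
            got = getattr(default_summary, f.name)
            want = getattr(truth, f.name)
            assert got == pytest.approx(want, rel=5e-3), f.name

    def test_cyplus_settings_round_trip(self):
        params = synthetic.RPITraceParams(
            first_depth=88.24, idi_true=12.71, creep_true=7.17,
            hysteresis_energy_true=297.94, unloading_slope_true=0.45,
        )
        trace, truth = synthetic.generate_rpi_trace(params)
        s = rpi.analyze_trace(trace)
        assert s.indentation_distance_increase == pytest.approx(12.71, rel=5e-3)
        assert s.first_cycle_energy_dissipation == pytest.approx(297.94, rel=5e-3)
        assert s.first_cycle_unloading_slope == pytest.approx(0.45, rel=5e-3)

    def test_identical_cycles_give_zero_idi(self):
        trace, _ = synthetic.generate_rpi_trace(
            synthetic.RPITraceParams(idi_true=0.0)
        )
        s = rpi.analyze_trace(trace)
        assert s.indentation_distance_increase == pytest.approx(0.0, abs=1e-6)

    def test_total_energy_is_sum_of_cycle_loop_areas(self, default_trace):
        trace, truth = default_trace
        origin = rpi.detect_touchdown(trace)
        ranges = rpi.segment_cycles(trace, 10)
        areas = [
            rpi.polygon_area(trace.displacement[a:b], trace.force[a:b])
            for a, b in ranges
        ]
        s = rpi.analyze_trace(trace)
        assert s.total_energy_dissipation == pytest.approx(sum(areas), rel=1e-9)
        assert s.total_energy_dissipation == pytest.approx(
            truth.total_energy_dissipation, rel=1e-3
        )

    def test_fewer_than_two_cycles_is_an_error(self):
        with pytest.raises(InsufficientCyclesError):
            rpi.summarize_test([])

    def test_summary_invariants(self, default_summary):
        s = default_summary
        assert s.total_energy_dissipation >= s.first_cycle_energy_dissipation
        assert (
            s.total_indentation_distance >= s.first_cycle_indentation_distance
        )
        assert s.indentation_distance_increase >= 0


class TestScaling:
    def test_force_scaling_scales_energy_and_slope_only(self, default_trace):
        trace, _ = default_trace
        k = 2.0
        scaled = rpi.IndentationTrace(
            trace.time, trace.force * k, trace.displacement
        )
        s0 = rpi.analyze_trace(trace, force_threshold=0.1)
        s1 = rpi.analyze_trace(scaled, force_threshold=0.1 * k)
        assert s1.first_cycle_energy_dissipation == pytest.approx(
            k * s0.first_cycle_energy_dissipation, rel=1e-9
        )
        assert s1.first_cycle_unloading_slope == pytest.approx(
            k * s0.first_cycle_unloading_slope, rel=1e-9
        )
        assert s1.first_cycle_indentation_distance == pytest.approx(
            s0.first_cycle_indentation_distance, rel=1e-6
        )
        assert s1.indentation_distance_increase == pytest.approx(
            s0.indentation_distance_increase, rel=1e-6
        )


class TestAggregation:
    def test_single_site_is_identity(self, default_summary):
        agg = rpi.aggregate_animal([default_summary])
        assert agg == default_summary

    def test_five_identical_sites_keep_values(self, default_summary):
        agg = rpi.aggregate_animal([default_summary] * 5)
        for f in dataclasses.fields(rpi.RPISummary):
            assert getattr(agg, f.name) == pytest.approx(
                getattr(default_summary, f.name)
            )

    def test_mean_is_hand_computed(self):
        mk = lambda v: rpi.RPISummary(*([v] * 7))
        agg = rpi.aggregate_animal([mk(1.0), mk(2.0), mk(6.0)])
        assert agg.first_cycle_indentation_distance == pytest.approx(3.0)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ParameterError):
            rpi.aggregate_animal([])
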