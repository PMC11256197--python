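import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashtox import (
    EvalGrid,
    build_field_plan,
    calibration_for_dose,
    cumulative_timeline,
    dose_at_point,
    doserate_report,
    dr_pbs95,
    field_dose_rate,
    schedule_conv,
    schedule_flash,
)
from flashtox.delivery import DeliverySchedule, FieldPlan, Spot, SpotDelivery


def single_spot_schedule(weight=1.0, sigma=8.0, dose=10.0, duration=1.0):
    plan = FieldPlan(spots=(Spot(0.0, 0.0, weight, sigma),), rows=1, cols=1,
                     spacing=6.0, rim_factor=1.0)
    ev = (SpotDelivery(0, 0.0, duration, 1.0, 0),)
    return DeliverySchedule(plan, ev, prescribed_dose=dose, n_repaints=1, mean_pause=0.0)


def two_pulse_schedule():
    """Two 0.1 s pulses of 5 Gy each at one spot, separated by a 0.8 s pause."""
    plan = FieldPlan(spots=(Spot(0.0, 0.0, 1.0, 8.0),), rows=1, cols=1,
                     spacing=6.0, rim_factor=1.0)
    ev = (SpotDelivery(0, 0.0, 0.1, 0.5, 0), SpotDelivery(0, 0.9, 0.1, 0.5, 1))
    return DeliverySchedule(plan, ev, prescribed_dose=10.0, n_repaints=2, mean_pause=0.8)


class TestDoseAtPoint:
    def test_kernel_center(self):
        s = single_spot_schedule()
        assert dose_at_point(s, (0, 0), 10.0) == pytest.approx(10.0)

    def test_one_sigma_offset_closed_form(self):
        s = single_spot_schedule(sigma=8.0)
        assert dose_at_point(s, (8, 0), 10.0) == pytest.approx(10.0 * np.exp(-0.5))

    def test_superposition_of_symmetric_spots(self):
        plan = FieldPlan(
            spots=(Spot(-5.0, 0.0, 1.0, 8.0), Spot(5.0, 0.0, 1.0, 8.0)),
            rows=1, cols=2, spacing=10.0, rim_factor=1.0,
        )
        ev = (SpotDelivery(0, 0.0, 0.5, 0.5, 0), SpotDelivery(1, 0.5, 0.5, 0.5, 0))
        s = DeliverySchedule(plan, ev, 10.0, 1, 0.0)
        single = single_spot_schedule()
        assert dose_at_point(s, (0, 0), 10.0) == pytest.approx(
            dose_at_point(single, (5, 0), 10.0)
        )

    def test_paint_invariance(self, plan):
        flash = schedule_flash(plan, 30.0, 60.0)
        conv = schedule_conv(plan, 30.0, 0.35, n_repaints=144)
        for pt in [(0.0, 0.0), (7.3, -4.1), (18.0, 12.0)]:
            assert dose_at_point(conv, pt, 1.0) == pytest.approx(
                dose_at_point(flash, pt, 1.0), abs=1e-9
            )


class TestCumulativeTimeline:
    def test_single_event_linear(self):
        tl = cumulative_timeline(single_spot_schedule(), (0, 0), 10.0)
        assert np.allclose(tl.times, [0.0, 1.0])
        assert np.allclose(tl.cumdose, [0.0, 10.0])

    def test_two_pulse_breakpoints(self):
        tl = cumulative_timeline(two_pulse_schedule(), (0, 0), 10.0)
        assert np.allclose(tl.times, [0.0, 0.1, 0.9, 1.0])
        assert np.allclose(tl.cumdose, [0.0, 5.0, 5.0, 10.0])

    def test_repainted_final_dose_matches_single_paint(self, plan):
        flash = schedule_flash(plan, 30.0, 60.0)
        conv = schedule_conv(plan, 30.0, 0.35, n_repaints=200)
        pt = (3.0, 2.0)
        a = cumulative_timeline(flash, pt, 1.0).total_dose
        b = cumulative_timeline(conv, pt, 1.0).total_dose
        assert a == pytest.approx(b, abs=1e-9)


class TestDrPbs95:
    def test_constant_rate_equals_field_rate(self):
        # D Gy over T s at constant rate: 0.95 D / 0.95 T = D / T exactly
        s = single_spot_schedule(dose=40.0, duration=2.0)
        tl = cumulative_timeline(s, (0, 0), 40.0)
        assert dr_pbs95(tl) == pytest.approx(40.0 / 2.0, abs=1e-12)

    def test_two_pulse_closed_form(self):
        tl = cumulative_timeline(two_pulse_schedule(), (0, 0), 10.0)
        # t2.5 = 0.005 s, t97.5 = 0.995 s -> 9.5 / 0.99 Gy/s
        assert dr_pbs95(tl) == pytest.approx(9.5 / 0.99)

    def test_heavy_repainting_approaches_field_rate(self, conv_schedule):
        cal = calibration_for_dose(conv_schedule)
        tl = cumulative_timeline(conv_schedule, (0.0, 0.0), cal)
        rate = field_dose_rate(conv_schedule)
        assert dr_pbs95(tl) == pytest.approx(rate, rel=0.05)

    def test_zero_dose_undefined(self):
        s = single_spot_schedule()
        tl = cumulative_timeline(s, (1e4, 1e4), 10.0)
        tl = type(tl)(point=tl.point, times=tl.times, cumdose=np.zeros_like(tl.cumdose))
        with pytest.raises(ValueError):
            dr_pbs95(tl)


class TestDoseRateReport:
    def test_single_spot_mask_and_mean(self):
        s = single_spot_schedule()
        grid = EvalGrid(np.array([[0.0, 0.0]]))
        rep = doserate_report(s, grid, 10.0, reference_dose=10.0)
        assert rep.high_region_mask.tolist() == [True]
        tl = cumulative_timeline(s, (0, 0), 10.0)
        assert rep.high_region_mean_dr == pytest.approx(dr_pbs95(tl))

    def test_flash_field_lower_bound_everywhere(self, flash_schedule):
        """DR_PBS95% >= 0.95 x dose / total duration at every lattice point."""
        cal = calibration_for_dose(flash_schedule)
        grid = EvalGrid.for_plan(flash_schedule.plan, pitch=1.0)
        rep = doserate_report(flash_schedule, grid, cal, reference_dose=60.0)
        T = flash_schedule.total_duration
        pos = rep.dose > 0
        assert np.all(rep.dr_pbs95[pos] >= 0.95 * rep.dose[pos] / T - 1e-9)

    def test_flash_high_region_exceeds_field_rate(self, flash_schedule):
        """Single-paint delivery concentrates each point's dose in time."""
        cal = calibration_for_dose(flash_schedule)
        grid = EvalGrid.for_plan(flash_schedule.plan, pitch=1.0)
        rep = doserate_report(flash_schedule, grid, cal, reference_dose=60.0)
        assert rep.high_region_mask.sum() > 0
        assert rep.high_region_mean_dr > rep.field_dose_rate
        lo, hi = rep.high_region_range
        assert lo > rep.field_dose_rate

    def test_empty_high_region_flagged(self):
        s = single_spot_schedule()
        grid = EvalGrid(np.array([[100.0, 100.0]]))
        rep = doserate_report(s, grid, 10.0, reference_dose=10.0)
        assert rep.empty_high_region
        assert rep.high_region_mean_dr is None


@settings(deadline=None, max_examples=25)
@given(
    dx=st.floats(-50, 50),
    dy=st.floats(-50, 50),
    px=st.floats(-20, 20),
    py=st.floats(-20, 20),
)
def test_translation_equivariance(dx, dy, px, py):
    """Translating spots and evaluation point together changes nothing."""
    base = build_field_plan(2, 3, 6.0, 1.4, 8.0)
    shifted = FieldPlan(
        spots=tuple(Spot(s.x + dx, s.y + dy, s.weight, s.sigma) for s in base.spots),
        rows=base.rows, cols=base.cols, spacing=base.spacing, rim_factor=base.rim_factor,
    )
    s0 = schedule_flash(base, 20.0, 40.0)
    s1 = DeliverySchedule(shifted, s0.events, s0.prescribed_dose, 1, 0.0)
    d0 = dose_at_point(s0, (px, py), 5.0)
    d1 = dose_at_point(s1, (px + dx, py + dy), 5.0)
    assert d1 == pytest.approx(d0, rel=1e-12, abs=1e-300)
    if d0 > 1e-9:
        t0 = cumulative_timeline(s0, (px, py), 5.0)
        t1 = cumulative_timeline(s1, (px + dx, py + dy), 5.0)
        assert dr_pbs95(t1) == pytest.approx(dr_pbs95(t0), rel=1e-9)
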