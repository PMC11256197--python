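"""Time-resolved dose accumulation and the DR_PBS95% local dose-rate metric.

Each spot deposits dose laterally as an isotropic 2D Gaussian normalized to
1 at its center; a single scalar calibration maps relative weight to Gy at
a spot center, keeping absolute dosimetry out of the geometry model. Dose
at a point accrues linearly during each spot event and is flat during beam
pauses, giving a piecewise-linear cumulative dose timeline.

The local PBS dose rate at a point, DR_PBS95%, is 95% of the point's total
dose divided by the time between the 2.5% and 97.5% cumulative-dose
crossings. For a single constant-rate delivery it reduces exactly to the
field dose rate; with heavy repainting it converges to the point's mean
dose rate; for a single-paint FLASH field it exceeds the field rate because
most of a point's dose arrives while nearby spots are being painted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .delivery import DeliverySchedule, FieldPlan, field_dose_rate

__all__ = [
    "EvalGrid",
    "PointTimeline",
    "DoseRateReport",
    "dose_at_point",
    "cumulative_timeline",
    "dr_pbs95",
    "doserate_report",
    "calibration_for_dose",
]


@dataclass(frozen=True)
class EvalGrid:
    """Evaluation points in the treatment plane (mm)."""

    points: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
            raise ValueError("points must be a non-empty (N, 2) array")
        object.__setattr__(self, "points", pts)

    @classmethod
    def lattice(cls, origin: tuple[float, float], pitch: float, nx: int, ny: int) -> "EvalGrid":
        """Regular lattice with the given origin (lower-left corner) and pitch."""
        xs = origin[0] + pitch * np.arange(nx)
        ys = origin[1] + pitch * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys)
        return cls(np.column_stack([gx.ravel(), gy.ravel()]))

    @classmethod
    def for_plan(cls, plan: FieldPlan, pitch: float = 1.0, margin: float | None = None) -> "EvalGrid":
        """Lattice covering the field extents plus a margin (default 2 sigma)."""
        pos = plan.positions()
        if margin is None:
            margin = 2.0 * plan.spots[0].sigma
        x0, x1 = pos[:, 0].min() - margin, pos[:, 0].max() + margin
        y0, y1 = pos[:, 1].min() - margin, pos[:, 1].max() + margin
        nx = int(np.floor((x1 - x0) / pitch)) + 1
        ny = int(np.floor((y1 - y0) / pitch)) + 1
        return cls.lattice((x0, y0), pitch, nx, ny)


@dataclass(frozen=True)
class PointTimeline:
    """Piecewise-linear cumulative dose versus time at one point."""

    point: tuple[float, float]
    times: np.ndarray
    cumdose: np.ndarray

    @property
    def total_dose(self) -> float:
        return float(self.cumdose[-1])

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumdose) < -1e-12):
            raise ValueError("cumulative dose must be non-decreasing")


@dataclass
class DoseRateReport:
    """Per-point dose and DR_PBS95% with high-dose-region summaries.

    The high-dose region is the set of points receiving at least 95% of
    ``reference_dose``; its summaries are the mean and (min, max) of
    DR_PBS95% over that region.
    """

    points: np.ndarray
    dose: np.ndarray
    t025: np.ndarray
    t975: np.ndarray
    dr_pbs95: np.ndarray
    field_dose_rate: float
    reference_dose: float
    high_region_mask: np.ndarray
    high_region_mean_dr: float | None = None
    high_region_range: tuple[float, float] | None = None
    empty_high_region: bool = field(default=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "dose_Gy": self.dose,
                "t025_s": self.t025,
                "t975_s": self.t975,
                "dr_pbs95_Gy_s": self.dr_pbs95,
                "in_high_region": self.high_region_mask,
            }
        )

    def summary(self) -> dict:
        return {
            "field_dose_rate_Gy_s": self.field_dose_rate,
            "reference_dose_Gy": self.reference_dose,
            "n_points": int(len(self.dose)),
            "n_high_region": int(self.high_region_mask.sum()),
            "empty_high_region": bool(self.empty_high_region),
            "high_region_mean_dr_Gy_s": self.high_region_mean_dr,
            "high_region_range_Gy_s": self.high_region_range,
        }


def _event_arrays(schedule: DeliverySchedule):
    """Stack event timing/geometry into arrays (starts, durations, positions, weights, sigmas)."""
    ev = schedule.events
    starts = np.array([e.start for e in ev])
    durations = np.array([e.duration for e in ev])
    weights = np.array([e.dose_weight for e in ev])
    pos = schedule.plan.positions()[[e.spot_index for e in ev]]
    sigmas = np.array([schedule.plan.spots[e.spot_index].sigma for e in ev])
    return starts, durations, weights, pos, sigmas


def _per_event_dose(schedule: DeliverySchedule, points: np.ndarray, calibration: float) -> np.ndarray:
    """(n_events, n_points) dose contribution matrix."""
    _, _, weights, pos, sigmas = _event_arrays(schedule)
    d2 = ((points[None, :, :] - pos[:, None, :]) ** 2).sum(axis=2)
    g = np.exp(-0.5 * d2 / sigmas[:, None] ** 2)
    return calibration * weights[:, None] * g


def dose_at_point(
    schedule: DeliverySchedule, point: tuple[float, float], calibration: float
) -> float:
    """Total dose (Gy) at a point: sum of Gaussian spot contributions.

    ``calibration`` maps a unit dose-weight to Gy at a spot center
    (kernel normalized to G(0) = 1).
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    pts = np.asarray(point, dtype=float).reshape(1, 2)
    return float(_per_event_dose(schedule, pts, calibration).sum())


def cumulative_timeline(
    schedule: DeliverySchedule, point: tuple[float, float], calibration: float
) -> PointTimeline:
    """Piecewise-linear cumulative dose at a point over the delivery.

    Dose accrues linearly within each spot event and is flat during pauses.
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    pts = np.asarray(point, dtype=float).reshape(1, 2)
    inc = _per_event_dose(schedule, pts, calibration)[:, 0]
    starts, durations, _, _, _ = _event_arrays(schedule)

    times = [starts[0]]
    cum = [0.0]
    acc = 0.0
    for s, d, dd in zip(starts, durations, inc):
        if s > times[-1] + 1e-15:  # pause: flat segment
            times.append(s)
            cum.append(acc)
        acc += dd
        times.append(s + d)
        cum.append(acc)
    return PointTimeline(
        point=(float(pts[0, 0]), float(pts[0, 1])),
        times=np.asarray(times),
        cumdose=np.asarray(cum),
    )


def _first_crossing(times: np.ndarray, cum: np.ndarray, threshold: float) -> float:
    """Earliest time the non-decreasing cumulative curve reaches threshold."""
    i = int(np.searchsorted(cum, threshold, side="left"))
    if i == 0:
        return float(times[0])
    if i >= len(cum):
        return float(times[-1])
    rise = cum[i] - cum[i - 1]
    if rise <= 0:
        return float(times[i - 1])
    frac = (threshold - cum[i - 1]) / rise
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def dr_pbs95(timeline: PointTimeline) -> float:
    """DR_PBS95% (Gy/s): 95% of the total dose over the 2.5%-97.5% time window."""
    d = timeline.total_dose
    if d <= 0:
        raise ValueError("DR_PBS95% is undefined at a point with zero dose")
    t_lo = _first_crossing(timeline.times, timeline.cumdose, 0.025 * d)
    t_hi = _first_crossing(timeline.times, timeline.cumdose, 0.975 * d)
    return 0.95 * d / (t_hi - t_lo)


def calibration_for_dose(
    schedule: DeliverySchedule,
    dose: float | None = None,
    point: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Calibration (Gy per unit weight) putting ``dose`` at ``point``.

    Defaults to the schedule's prescribed dose at the field center, mirroring
    an absolute ionization-chamber calibration at the reference point.
    """
    if dose is None:
        dose = schedule.prescribed_dose
    unit = dose_at_point(schedule, point, calibration=1.0)
    return dose / unit


def doserate_report(
    schedule: DeliverySchedule,
    grid: EvalGrid,
    calibration: float,
    reference_dose: float,
) -> DoseRateReport:
    """Per-point dose and DR_PBS95% over a grid, with high-region summaries.

    The high-dose region contains the points with dose >= 0.95 x
    ``reference_dose`` (the prescribed dose by default convention).
    """
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    pts = grid.points
    starts, durations, _, _, _ = _event_arrays(schedule)
    inc = _per_event_dose(schedule, pts, calibration)  # (E, N)
    cum_end = np.cumsum(inc, axis=0)
    dose = cum_end[-1]

    n = pts.shape[0]
    t025 = np.empty(n)
    t975 = np.empty(n)
    cum_start = cum_end - inc
    for thr_frac, out in ((0.025, t025), (0.975, t975)):
        thr = thr_frac * dose
        # first event index at which the cumulative dose reaches the threshold
        idx = np.argmax(cum_end >= thr[None, :] - 1e-300, axis=0)
        lo = cum_start[idx, np.arange(n)]
        rise = inc[idx, np.arange(n)]
        frac = np.where(rise > 0, (thr - lo) / np.where(rise > 0, rise, 1.0), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        out[:] = starts[idx] + frac * durations[idx]

    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.where(dose > 0, 0.95 * dose / (t975 - t025), np.nan)

    mask = dose >= 0.95 * reference_dose
    report = DoseRateReport(
        points=pts,
        dose=dose,
        t025=t025,
        t975=t975,
        dr_pbs95=dr,
        field_dose_rate=field_dose_rate(schedule),
        reference_dose=reference_dose,
        high_region_mask=mask,
    )
    if mask.any():
        sel = dr[mask]
        report.high_region_mean_dr = float(sel.mean())
        report.high_region_range = (float(sel.min()), float(sel.max()))
    else:
        report.empty_high_region = True
    return report
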