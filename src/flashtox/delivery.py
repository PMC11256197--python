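"""Spot maps and timed pencil-beam-scanning (PBS) delivery schedules.

A field is a rectangular grid of proton spots; the spots on the grid rim
carry extra weight to flatten the lateral dose profile. A delivery is a
time-ordered sequence of spot events. Two delivery styles are modelled:

* FLASH — the spot pattern is painted once, back to back, at a high field
  dose rate (prescribed dose / total field duration).
* CONV — the pattern is repainted many times with a fixed beam pause after
  every spot delivery, stretching the same dose over minutes.

Per-spot beam-on time is proportional to spot weight (constant beam
current); pauses are modelled at their mean value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import datasets

__all__ = [
    "Spot",
    "FieldPlan",
    "SpotDelivery",
    "DeliverySchedule",
    "InfeasibleScheduleError",
    "build_field_plan",
    "schedule_flash",
    "schedule_conv",
    "field_dose_rate",
    "repaints_for_dose",
]


class InfeasibleScheduleError(ValueError):
    """Requested timing cannot be met (pause time alone exceeds the field duration)."""


@dataclass(frozen=True)
class Spot:
    """A single PBS spot: position in the treatment plane and relative weight.

    ``sigma`` is the lateral Gaussian spread (mm) of the spot's dose
    footprint at the treatment depth.
    """

    x: float
    y: float
    weight: float
    sigma: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"spot weight must be >= 0, got {self.weight}")
        if self.sigma <= 0:
            raise ValueError(f"spot sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class FieldPlan:
    """An ordered spot map on a regular grid, centered on the origin."""

    spots: tuple[Spot, ...]
    rows: int
    cols: int
    spacing: float
    rim_factor: float

    @property
    def total_weight(self) -> float:
        return float(sum(s.weight for s in self.spots))

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def positions(self) -> np.ndarray:
        """(n_spots, 2) array of spot (x, y) positions in mm."""
        return np.array([(s.x, s.y) for s in self.spots], dtype=float)

    def extents(self) -> tuple[float, float]:
        """Grid extents (y span, x span) in mm: (rows-1, cols-1) x spacing."""
        return ((self.rows - 1) * self.spacing, (self.cols - 1) * self.spacing)


@dataclass(frozen=True)
class SpotDelivery:
    """One timed spot event: a fraction of the field's dose at one spot."""

    spot_index: int
    start: float
    duration: float
    dose_weight: float
    painting: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if self.start < 0:
            raise ValueError("event start must be >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DeliverySchedule:
    """A complete timed field delivery: plan + time-ordered spot events.

    Invariants: events are non-overlapping and time-ordered, and the event
    dose weights sum to 1 (each is the fraction of the prescribed field
    weight delivered in that event).
    """

    plan: FieldPlan
    events: tuple[SpotDelivery, ...]
    prescribed_dose: float
    n_repaints: int
    mean_pause: float

    @property
    def total_duration(self) -> float:
        """Total field duration (s): last event end minus first event start."""
        if not self.events:
            raise ValueError("schedule has no events")
        return self.events[-1].end - self.events[0].start


def build_field_plan(
    rows: int,
    cols: int,
    spacing: float = datasets.SPOT_SPACING_MM,
    rim_factor: float = datasets.RIM_FACTOR,
    sigma: float = datasets.SPOT_SIGMA_MM,
) -> FieldPlan:
    """Build a rows x cols spot grid centered on the origin.

    Perimeter spots carry weight ``rim_factor``; interior spots weight 1.
    Spots are ordered row-major (row index increases downward in y).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if rim_factor < 1:
        raise ValueError("rim_factor must be >= 1")

    spots = []
    for r in range(rows):
        for c in range(cols):
            x = (c - (cols - 1) / 2.0) * spacing
            y = ((rows - 1) / 2.0 - r) * spacing
            on_rim = r in (0, rows - 1) or c in (0, cols - 1)
            w = rim_factor if on_rim else 1.0
            spots.append(Spot(x=x, y=y, weight=w, sigma=sigma))
    return FieldPlan(
        spots=tuple(spots), rows=rows, cols=cols, spacing=spacing, rim_factor=rim_factor
    )


def _scan_indices(plan: FieldPlan, scan_order: str) -> list[int]:
    """Spot visiting order for one painting.

    ``serpentine`` (default) alternates scan direction on successive rows,
    as is typical for PBS; ``raster`` always scans left to right.
    """
    if scan_order not in ("serpentine", "raster"):
        raise ValueError(f"unknown scan_order {scan_order!r}")
    order: list[int] = []
    for r in range(plan.rows):
        row = list(range(r * plan.cols, (r + 1) * plan.cols))
        if scan_order == "serpentine" and r % 2 == 1:
            row.reverse()
        order.extend(row)
    return order


def schedule_flash(
    plan: FieldPlan,
    prescribed_dose: float,
    field_dose_rate: float = datasets.FLASH_FIELD_DOSE_RATE,
    scan_order: str = "serpentine",
) -> DeliverySchedule:
    """Single-paint delivery: one contiguous event per spot, zero pauses.

    Per-event duration is proportional to spot weight; the total duration is
    ``prescribed_dose / field_dose_rate``.
    """
    if prescribed_dose <= 0 or field_dose_rate <= 0:
        raise ValueError("prescribed_dose and field_dose_rate must be > 0")
    total_t = prescribed_dose / field_dose_rate
    total_w = plan.total_weight
    events = []
    t = 0.0
    for idx in _scan_indices(plan, scan_order):
        frac = plan.spots[idx].weight / total_w
        dur = total_t * frac
        events.append(
            SpotDelivery(spot_index=idx, start=t, duration=dur, dose_weight=frac, painting=0)
        )
        t += dur
    return DeliverySchedule(
        plan=plan,
        events=tuple(events),
        prescribed_dose=prescribed_dose,
        n_repaints=1,
        mean_pause=0.0,
    )


def schedule_conv(
    plan: FieldPlan,
    prescribed_dose: float,
    field_dose_rate: float = datasets.CONV_FIELD_DOSE_RATE,
    n_repaints: int | None = None,
    mean_pause: float = datasets.CONV_MEAN_PAUSE_S,
    scan_order: str = "serpentine",
) -> DeliverySchedule:
    """Repainted delivery: ``n_repaints`` passes with a pause after every spot.

    Each spot's weight is split evenly across paintings. Beam-on durations
    are scaled so that prescribed_dose / total duration equals the requested
    field dose rate; the pause after the final spot is not delivered.

    If ``n_repaints`` is None it is chosen from the dose via
    :func:`repaints_for_dose`.
    """
    if prescribed_dose <= 0 or field_dose_rate <= 0:
        raise ValueError("prescribed_dose and field_dose_rate must be > 0")
    if n_repaints is None:
        n_repaints = repaints_for_dose(prescribed_dose)
    if n_repaints < 1:
        raise ValueError("n_repaints must be >= 1")
    if mean_pause < 0:
        raise ValueError("mean_pause must be >= 0")

    total_t = prescribed_dose / field_dose_rate
    n_events = plan.n_spots * n_repaints
    total_pause = (n_events - 1) * mean_pause
    beam_on = total_t - total_pause
    if beam_on <= 0:
        raise InfeasibleScheduleError(
            f"pause time {total_pause:.4g} s alone exceeds the field duration "
            f"{total_t:.4g} s at {field_dose_rate} Gy/s"
        )

    total_w = plan.total_weight
    scan = _scan_indices(plan, scan_order)
    events = []
    t = 0.0
    for p in range(n_repaints):
        for idx in scan:
            frac = plan.spots[idx].weight / (total_w * n_repaints)
            dur = beam_on * frac
            events.append(
                SpotDelivery(spot_index=idx, start=t, duration=dur, dose_weight=frac, painting=p)
            )
            t += dur + mean_pause
    # drop the trailing pause so the schedule ends at the last beam-off
    return DeliverySchedule(
        plan=plan,
        events=tuple(events),
        prescribed_dose=prescribed_dose,
        n_repaints=n_repaints,
        mean_pause=mean_pause,
    )


def field_dose_rate(schedule: DeliverySchedule) -> float:
    """Field dose rate (Gy/s): prescribed dose over total field duration."""
    if not schedule.events:
        raise ValueError("schedule has no events")
    return schedule.prescribed_dose / schedule.total_duration


def repaints_for_dose(dose: float) -> int:
    """Repaint count for a CONV delivery, linear in dose.

    Interpolates between the endpoints of the observed regime (144 repaints
    at 19.9 Gy up to 360 at 49.7 Gy) and clips outside it.
    """
    d_lo, d_hi = datasets.CONV_REPAINT_DOSE_RANGE
    n_lo, n_hi = datasets.CONV_REPAINT_RANGE
    n = n_lo + (dose - d_lo) * (n_hi - n_lo) / (d_hi - d_lo)
    return int(round(min(max(n, n_lo), n_hi)))
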