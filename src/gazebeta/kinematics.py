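"""Parabolic target kinematics and screen-coordinate conversions.

The stimulus is a target launched from the lower-left of the display on a
ballistic (drag-free) parabola under a nominal gravitational acceleration of
9.81 cm/s², landing at the same height it was launched from after 4.6 s.
Three conditions (CLOSE / MID / DISTANT) differ in launch speed and angle,
shifting the landing point horizontally by ~1 cm steps.  The target is
visible for the first half of the flight and occluded for the second half.

Everything here is closed form: position, flight time, apex, occlusion
state, and the linear conversions between centimetres on the screen,
pixels, and degrees of visual angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

GRAVITY_CM_S2 = 9.81
FLIGHT_DURATION_S = 4.6
OCCLUSION_ONSET_S = 2.3
LAUNCH_HEIGHT_CM = 0.12


class Condition(str, Enum):
    CLOSE = "CLOSE"
    MID = "MID"
    DISTANT = "DISTANT"


@dataclass(frozen=True)
class TrajectoryParams:
    """One condition's parabola: launch speed (cm/s), angle (deg above
    horizontal), gravity (cm/s²), nominal duration and occlusion onset (s),
    and the launch position (cm, physical y up)."""

    condition_label: Condition
    initial_speed: float
    launch_angle: float
    gravity: float = GRAVITY_CM_S2
    duration: float = FLIGHT_DURATION_S
    occlusion_onset: float = OCCLUSION_ONSET_S
    launch_position: Tuple[float, float] = (0.0, LAUNCH_HEIGHT_CM)

    def __post_init__(self) -> None:
        if not self.initial_speed > 0:
            raise ValueError("initial_speed must be positive")
        if not 0 < self.launch_angle < 90:
            raise ValueError("launch_angle must be in (0, 90) degrees")
        if not self.gravity > 0:
            raise ValueError("gravity must be positive")
        if not 0 <= self.occlusion_onset <= self.duration:
            raise ValueError("occlusion_onset must lie within [0, duration]")

    @property
    def _angle_rad(self) -> float:
        return math.radians(self.launch_angle)

    @property
    def vx(self) -> float:
        return self.initial_speed * math.cos(self._angle_rad)

    @property
    def vy(self) -> float:
        return self.initial_speed * math.sin(self._angle_rad)


#: Launch speed (cm/s) and angle (deg) for the three trajectory conditions.
CONDITION_TABLE = {
    Condition.CLOSE: (23.28, 75.96),
    Condition.MID: (23.33, 75.45),
    Condition.DISTANT: (23.39, 74.93),
}


def default_params(condition: Condition | str) -> TrajectoryParams:
    """TrajectoryParams for one of the three standard conditions."""
    condition = Condition(condition)
    speed, angle = CONDITION_TABLE[condition]
    return TrajectoryParams(condition, speed, angle)


def target_position(params: TrajectoryParams, t: float) -> Tuple[float, float]:
    """Target position (x, y) in cm at time t since motion onset.

    x = x0 + v·cosθ·t,  y = y0 + v·sinθ·t − ½·g·t².  Raises for t outside
    [0, duration].
    """
    if not 0 <= t <= params.duration:
        raise ValueError(f"t={t} outside flight window [0, {params.duration}]")
    x0, y0 = params.launch_position
    x = x0 + params.vx * t
    y = y0 + params.vy * t - 0.5 * params.gravity * t * t
    return (x, y)


def flight_time(params: TrajectoryParams) -> float:
    """Time (s) for the target to return to launch height: 2·v·sinθ/g."""
    return 2.0 * params.vy / params.gravity


def apex_time(params: TrajectoryParams) -> float:
    """Time of the trajectory's highest point: v·sinθ/g."""
    return params.vy / params.gravity


def landing_position(params: TrajectoryParams) -> Tuple[float, float]:
    """Landing point (cm) at the ballistic flight time.

    Computed closed-form (the ballistic flight time may exceed the nominal
    duration by a few ms of rounding); the height is the launch height by
    symmetry.
    """
    x0, y0 = params.launch_position
    return (x0 + params.vx * flight_time(params), y0)


def is_occluded(params: TrajectoryParams, t: float) -> bool:
    """True iff the target is hidden at time t.

    The boundary sample t == occlusion_onset belongs to the visible phase,
    so the visible analysis window [0, occlusion_onset] is closed.
    """
    if not 0 <= t <= params.duration:
        raise ValueError(f"t={t} outside flight window [0, {params.duration}]")
    return t > params.occlusion_onset


@dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry: a 19-inch 1280×1024 monitor at 60 cm viewing
    distance subtending 35.66° × 28.86°."""

    width_px: int = 1280
    height_px: int = 1024
    horizontal_extent_deg: float = 35.66
    vertical_extent_deg: float = 28.86
    viewing_distance_cm: float = 60.0
    diagonal_inch: float = 19.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "horizontal_extent_deg",
            "vertical_extent_deg",
            "viewing_distance_cm",
            "diagonal_inch",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    # Degrees of visual angle per pixel, per axis. These differ slightly
    # (0.02786 vs 0.02818 deg/px), so conversions are always per-axis.
    @property
    def deg_per_px_x(self) -> float:
        return self.horizontal_extent_deg / self.width_px

    @property
    def deg_per_px_y(self) -> float:
        return self.vertical_extent_deg / self.height_px

    # Physical screen size from viewing distance and angular extent:
    # extent_cm = 2·d·tan(extent/2).
    @property
    def width_cm(self) -> float:
        half = math.radians(self.horizontal_extent_deg / 2.0)
        return 2.0 * self.viewing_distance_cm * math.tan(half)

    @property
    def height_cm(self) -> float:
        half = math.radians(self.vertical_extent_deg / 2.0)
        return 2.0 * self.viewing_distance_cm * math.tan(half)

    @property
    def px_per_cm_x(self) -> float:
        return self.width_px / self.width_cm

    @property
    def px_per_cm_y(self) -> float:
        return self.height_px / self.height_cm


#: Default pixel location of the physical origin (the launch point).
#: Places the launch in the lower-left screen region so that the
#: occlusion-onset crossing falls in the low-600s pixel range.
DEFAULT_ANCHOR_PX = (165.0, 900.0)


def px_to_deg(geometry: ScreenGeometry, dx_px, dy_px):
    """Convert pixel offsets to degrees of visual angle, per axis.

    Linear scaling by the full-screen angular extents; accepts scalars or
    arrays.
    """
    dx_deg = np.asarray(dx_px, dtype=float) * geometry.deg_per_px_x
    dy_deg = np.asarray(dy_px, dtype=float) * geometry.deg_per_px_y
    if np.ndim(dx_px) == 0 and np.ndim(dy_px) == 0:
        return (float(dx_deg), float(dy_deg))
    return (dx_deg, dy_deg)


def deg_to_px(geometry: ScreenGeometry, dx_deg, dy_deg):
    """Inverse of :func:`px_to_deg`."""
    dx_px = np.asarray(dx_deg, dtype=float) / geometry.deg_per_px_x
    dy_px = np.asarray(dy_deg, dtype=float) / geometry.deg_per_px_y
    if np.ndim(dx_deg) == 0 and np.ndim(dy_deg) == 0:
        return (float(dx_px), float(dy_px))
    return (dx_px, dy_px)


def cm_to_px(
    geometry: ScreenGeometry,
    x_cm,
    y_cm,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
):
    """Map physical coordinates (cm, y up) into the display pixel frame.

    ``anchor`` is the pixel location of the physical origin (the launch
    point).  The display y-axis points downward, so physical +y maps to
    decreasing pixel y.
    """
    ax, ay = anchor
    x_px = ax + np.asarray(x_cm, dtype=float) * geometry.px_per_cm_x
    y_px = ay - np.asarray(y_cm, dtype=float) * geometry.px_per_cm_y
    if np.ndim(x_cm) == 0 and np.ndim(y_cm) == 0:
        return (float(x_px), float(y_px))
    return (x_px, y_px)


def px_to_cm(
    geometry: ScreenGeometry,
    x_px,
    y_px,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
):
    """Inverse of :func:`cm_to_px`."""
    ax, ay = anchor
    x_cm = (np.asarray(x_px, dtype=float) - ax) / geometry.px_per_cm_x
    y_cm = (ay - np.asarray(y_px, dtype=float)) / geometry.px_per_cm_y
    if np.ndim(x_px) == 0 and np.ndim(y_px) == 0:
        return (float(x_cm), float(y_cm))
    return (x_cm, y_cm)


def landing_position_px(
    params: TrajectoryParams,
    geometry: ScreenGeometry,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
) -> Tuple[float, float]:
    """Landing point rendered into the gaze pixel frame."""
    x_cm, y_cm = landing_position(params)
    return cm_to_px(geometry, x_cm, y_cm, anchor)


def target_position_px(
    params: TrajectoryParams,
    geometry: ScreenGeometry,
    t,
    anchor: Tuple[float, float] = DEFAULT_ANCHOR_PX,
):
    """Target position in pixels at time(s) t (vectorized over t)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > params.duration):
        raise ValueError("t outside flight window")
    x0, y0 = params.launch_position
    x_cm = x0 + params.vx * t_arr
    y_cm = y0 + params.vy * t_arr - 0.5 * params.gravity * t_arr**2
    return cm_to_px(geometry, x_cm, y_cm, anchor)
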