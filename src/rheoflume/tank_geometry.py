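"""Geometry of the annular (circular-flow) test tank.

The tank is a ring between an inner island wall and an outer chamber wall.
Water circulates around the ring, so "upstream" at any point is the tangent
direction opposing the circulation. Positions are planar coordinates in cm
with the tank center at the origin; all angles are radians measured
counterclockwise from the positive x-axis.

The ring is partitioned into concentric flow zones, each with a nominal
water speed. Zone score 0 is the slowest zone; scores increase with speed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: default radial slack (cm) tolerated outside the annulus before a hard error
DEFAULT_CLAMP_TOL = 0.5


class GeometryError(ValueError):
    """Invalid geometric configuration or coordinates."""


class DegenerateCoordinateError(GeometryError):
    """A coordinate that has no polar representation (the tank center)."""


class OutOfTankError(GeometryError):
    """A radius outside the annulus beyond the clamping tolerance."""


def wrap_angle(angle: float) -> float:
    """Wrap an angle into [0, 2*pi)."""
    return angle % TWO_PI


def wrap_signed(angle: float) -> float:
    """Wrap an angular difference into (-pi, pi]."""
    a = (angle + math.pi) % TWO_PI - math.pi
    if a == -math.pi:
        a = math.pi
    return a


def wrap_signed_array(angles: np.ndarray) -> np.ndarray:
    """Vectorized :func:`wrap_signed`."""
    a = (np.asarray(angles, dtype=float) + np.pi) % TWO_PI - np.pi
    return np.where(a == -np.pi, np.pi, a)


@dataclass(frozen=True)
class TankGeometry:
    """The annular flume: inner island, outer wall, and flow direction.

    Parameters
    ----------
    inner_radius, outer_radius
        Radii of the island wall and the chamber wall, cm.
    water_depth
        Water depth, cm (informational; the analysis is planar).
    flow_sense
        +1 if the water circulates counterclockwise, -1 if clockwise.
    center
        Tank center in the coordinate frame of the input tracks, cm.
    """

    inner_radius: float = 12.5
    outer_radius: float = 32.5
    water_depth: float = 16.0
    flow_sense: int = 1
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_radius < self.outer_radius:
            raise GeometryError(
                f"need 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius} and {self.outer_radius}"
            )
        if self.flow_sense not in (1, -1):
            raise GeometryError(f"flow_sense must be +1 or -1, got {self.flow_sense}")

    @property
    def channel_width(self) -> float:
        return self.outer_radius - self.inner_radius


@dataclass(frozen=True)
class FlowZoneMap:
    """Radial partition of the annulus into flow zones with nominal speeds.

    ``zone_boundaries`` are ``n_zones + 1`` radii spanning exactly the
    annulus; zone *i* occupies ``[boundaries[i], boundaries[i+1])`` with the
    outermost band closed at the outer wall. Speeds are strictly increasing
    with zone score.
    """

    zone_speeds: tuple[float, ...] = (4.2, 6.9, 8.8, 17.1)
    zone_boundaries: tuple[float, ...] = (12.5, 17.5, 22.5, 27.5, 32.5)

    def __post_init__(self) -> None:
        speeds = np.asarray(self.zone_speeds, dtype=float)
        bounds = np.asarray(self.zone_boundaries, dtype=float)
        if speeds.size < 1:
            raise GeometryError("need at least one flow zone")
        if np.any(np.diff(speeds) <= 0):
            raise GeometryError(f"zone speeds must be strictly increasing: {speeds}")
        if bounds.size != speeds.size + 1:
            raise GeometryError(
                f"{speeds.size} zones need {speeds.size + 1} boundaries, "
                f"got {bounds.size}"
            )
        if np.any(np.diff(bounds) <= 0):
            raise GeometryError(f"zone boundaries must be strictly increasing: {bounds}")

    @classmethod
    def equal_width(
        cls,
        geom: TankGeometry,
        zone_speeds: Sequence[float] = (4.2, 6.9, 8.8, 17.1),
    ) -> "FlowZoneMap":
        """Equal-width concentric bands spanning the annulus of ``geom``."""
        n = len(zone_speeds)
        bounds = np.linspace(geom.inner_radius, geom.outer_radius, n + 1)
        return cls(tuple(float(s) for s in zone_speeds), tuple(bounds.tolist()))

    @property
    def n_zones(self) -> int:
        return len(self.zone_speeds)

    def validate_span(self, geom: TankGeometry, atol: float = 1e-9) -> None:
        """Raise unless the boundaries span exactly the annulus of ``geom``."""
        b = self.zone_boundaries
        if abs(b[0] - geom.inner_radius) > atol or abs(b[-1] - geom.outer_radius) > atol:
            raise GeometryError(
                f"zone boundaries {b[0]}..{b[-1]} do not span the annulus "
                f"{geom.inner_radius}..{geom.outer_radius}"
            )

    def mid_radius(self, zone: float) -> float:
        """Mid-band radius for an (optionally fractional) zone score.

        Fractional scores interpolate linearly between adjacent band centers,
        which gives the simulator a continuous target radius for strategies
        like "hold score 1.5".
        """
        b = np.asarray(self.zone_boundaries)
        centers = 0.5 * (b[:-1] + b[1:])
        return float(np.interp(zone, np.arange(self.n_zones), centers))


@dataclass(frozen=True)
class PolarPoint:
    """A point in the tank's polar frame: radius cm, angle in [0, 2*pi)."""

    radius: float
    angle: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DegenerateCoordinateError(f"radius must be positive, got {self.radius}")
        object.__setattr__(self, "angle", wrap_angle(self.angle))


def to_polar(point: Sequence[float], geom: TankGeometry) -> PolarPoint:
    """Convert a planar xy point (cm) to the tank's polar frame.

    Raises
    ------
    DegenerateCoordinateError
        If the point coincides with the tank center.
    """
    x = float(point[0]) - geom.center[0]
    y = float(point[1]) - geom.center[1]
    r = math.hypot(x, y)
    if r == 0.0:
        raise DegenerateCoordinateError("point coincides with the tank center")
    return PolarPoint(r, math.atan2(y, x))


def _clamp_radius(
    r: float, geom: TankGeometry, clamp_tol: float, frame: int | None
) -> float:
    if r < geom.inner_radius:
        if geom.inner_radius - r > clamp_tol:
            raise OutOfTankError(
                f"radius {r:.3f} cm inside the island wall "
                f"({geom.inner_radius} cm) beyond tolerance"
                + (f" at frame {frame}" if frame is not None else "")
            )
        logger.warning("clamping radius %.3f to inner wall %.1f", r, geom.inner_radius)
        return geom.inner_radius
    if r > geom.outer_radius:
        if r - geom.outer_radius > clamp_tol:
            raise OutOfTankError(
                f"radius {r:.3f} cm outside the outer wall "
                f"({geom.outer_radius} cm) beyond tolerance"
                + (f" at frame {frame}" if frame is not None else "")
            )
        logger.warning("clamping radius %.3f to outer wall %.1f", r, geom.outer_radius)
        return geom.outer_radius
    return r


def zone_index(
    p: PolarPoint,
    geom: TankGeometry,
    zones: FlowZoneMap,
    clamp_tol: float = DEFAULT_CLAMP_TOL,
    frame: int | None = None,
) -> int:
    """Flow-zone score (0-based, innermost band first) of a polar point.

    Bands are half-open ``[low, high)``; the outermost band is closed at the
    outer wall. Radii within ``clamp_tol`` cm outside the annulus (tracking
    jitter) are clamped with a warning; beyond that an :class:`OutOfTankError`
    names the frame.
    """
    r = _clamp_radius(p.radius, geom, clamp_tol, frame)
    bounds = np.asarray(zones.zone_boundaries)
    idx = int(np.searchsorted(bounds, r, side="right")) - 1
    return min(max(idx, 0), zones.n_zones - 1)


def zone_index_array(
    radii: np.ndarray,
    geom: TankGeometry,
    zones: FlowZoneMap,
    clamp_tol: float = DEFAULT_CLAMP_TOL,
) -> np.ndarray:
    """Vectorized :func:`zone_index` over an array of radii (frame-indexed)."""
    r = np.asarray(radii, dtype=float)
    low = r < geom.inner_radius - clamp_tol
    high = r > geom.outer_radius + clamp_tol
    if np.any(low | high):
        bad = int(np.flatnonzero(low | high)[0])
        raise OutOfTankError(
            f"radius {r[bad]:.3f} cm outside the annulus "
            f"[{geom.inner_radius}, {geom.outer_radius}] beyond tolerance "
            f"at frame {bad}"
        )
    n_clamped = int(np.sum((r < geom.inner_radius) | (r > geom.outer_radius)))
    if n_clamped:
        logger.warning("clamped %d radii onto the annulus walls", n_clamped)
    r = np.clip(r, geom.inner_radius, geom.outer_radius)
    bounds = np.asarray(zones.zone_boundaries)
    idx = np.searchsorted(bounds, r, side="right") - 1
    return np.clip(idx, 0, zones.n_zones - 1)


def flow_speed(zone: int, zones: FlowZoneMap) -> float:
    """Nominal water speed (cm/s) of a zone score."""
    if not 0 <= zone < zones.n_zones:
        raise IndexError(f"zone {zone} out of range 0..{zones.n_zones - 1}")
    return float(zones.zone_speeds[zone])


def upstream_tangent_angle(p: PolarPoint, geom: TankGeometry) -> float:
    """Direction (radians, [0, 2*pi)) of the tangent pointing against the flow.

    For counterclockwise circulation (``flow_sense = +1``) the local flow
    direction at angular position theta is ``theta + pi/2``, so the upstream
    tangent is ``theta - pi/2``; the clockwise case mirrors this.
    """
    return wrap_angle(p.angle - geom.flow_sense * math.pi / 2.0)


def signed_arc_step(p1: PolarPoint, p2: PolarPoint, geom: TankGeometry) -> float:
    """Along-channel arc length (cm) between two points, signed upstream-positive.

    The angular difference is wrapped to (-pi, pi] (a fish cannot be assumed
    to lap the tank between frames); the arc radius is the mean of the two
    endpoint radii. Motion opposing the circulation is positive (upstream).
    The measure-zero half-lap tie |dtheta| = pi resolves to upstream.
    """
    dtheta = wrap_signed(p2.angle - p1.angle)
    mean_r = 0.5 * (p1.radius + p2.radius)
    if dtheta == math.pi:
        return math.pi * mean_r
    return -geom.flow_sense * dtheta * mean_r


def signed_arc_steps(
    radii: np.ndarray, angles: np.ndarray, geom: TankGeometry
) -> np.ndarray:
    """Vectorized consecutive-frame :func:`signed_arc_step` along a track."""
    r = np.asarray(radii, dtype=float)
    th = np.asarray(angles, dtype=float)
    dtheta = wrap_signed_array(np.diff(th))
    mean_r = 0.5 * (r[:-1] + r[1:])
    steps = -geom.flow_sense * dtheta * mean_r
    tie = dtheta == np.pi
    if np.any(tie):
        steps[tie] = np.pi * mean_r[tie]
    return steps
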