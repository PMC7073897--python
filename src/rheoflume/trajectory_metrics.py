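"""Per-trial rheotaxis performance metrics from tracked body coordinates.

A trial is a fixed-rate sequence of frames; in each frame the anterior and
posterior ends of the fish were tracked. Four performance metrics summarize
one trial:

* **net displacement** — along-channel arc distance, upstream steps summed
  and downstream steps subtracted (cm; positive = net upstream progress);
* **cumulative upstream movement** — sum of only the upstream-directed step
  lengths (cm);
* **mean flow regime** — the ordinal flow-zone score (0 = slowest band)
  averaged over all frames;
* **upstream orientation** — the proportion of frames with the body axis
  within a +/-45 deg window of the local upstream tangent.

A passive, non-swimming object drifts downstream at the water speed of the
zone it occupies; :func:`passive_baseline` gives that closed-form drift as
the no-rheotaxis reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .tank_geometry import (
    DegenerateCoordinateError,
    FlowZoneMap,
    TankGeometry,
    flow_speed,
    signed_arc_steps,
    wrap_angle,
    wrap_signed_array,
    zone_index_array,
)

DEFAULT_FRAME_RATE = 1.5  # Hz
DEFAULT_DURATION = 300.0  # s
DEFAULT_ALIGNMENT_WINDOW_DEG = 45.0


class TrackError(ValueError):
    """Malformed track data (frame gaps, degenerate poses, ...)."""


@dataclass(frozen=True)
class FrameObservation:
    """One tracked frame: anterior and posterior body points in cm."""

    frame: int
    time: float
    anterior: tuple[float, float]
    posterior: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.anterior) == tuple(self.posterior):
            raise TrackError(f"degenerate pose (anterior == posterior) at frame {self.frame}")

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            0.5 * (self.anterior[0] + self.posterior[0]),
            0.5 * (self.anterior[1] + self.posterior[1]),
        )


@dataclass
class Track:
    """Ordered frame-wise anterior/posterior coordinates for one trial.

    Coordinates are stored as (n, 2) arrays in cm; frame indices are 0-based,
    strictly increasing and gap-free. The default trial is 450 frames:
    300 s filmed at 1.5 frames/s.
    """

    trial_id: str
    anterior: np.ndarray
    posterior: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if self.anterior.shape != self.posterior.shape or self.anterior.ndim != 2:
            raise TrackError("anterior and posterior must be matching (n, 2) arrays")
        n = len(self.anterior)
        if self.frame_index is None:
            self.frame_index = np.arange(n)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if len(self.frame_index) != n:
                raise TrackError("frame_index length mismatch")
            diffs = np.diff(self.frame_index)
            if np.any(diffs != 1):
                bad = int(np.flatnonzero(diffs != 1)[0])
                raise TrackError(
                    f"frame indices must be gap-free and strictly increasing; "
                    f"offence after frame {self.frame_index[bad]}"
                )
        same = np.all(self.anterior == self.posterior, axis=1)
        if np.any(same):
            raise TrackError(
                f"degenerate pose (anterior == posterior) at frame "
                f"{int(self.frame_index[np.flatnonzero(same)[0]])}"
            )
        if not self.frame_rate > 0:
            raise TrackError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.anterior)

    @property
    def times(self) -> np.ndarray:
        """Seconds from flow onset, frame_index / frame_rate."""
        return self.frame_index / self.frame_rate

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.anterior + self.posterior)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def observations(self) -> list[FrameObservation]:
        return [
            FrameObservation(
                int(f), float(t), tuple(a.tolist()), tuple(p.tolist())
            )
            for f, t, a, p in zip(self.frame_index, self.times, self.anterior, self.posterior)
        ]

    @classmethod
    def from_observations(
        cls, trial_id: str, obs: Iterable[FrameObservation], frame_rate: float = DEFAULT_FRAME_RATE
    ) -> "Track":
        obs = list(obs)
        return cls(
            trial_id,
            np.array([o.anterior for o in obs], dtype=float),
            np.array([o.posterior for o in obs], dtype=float),
            frame_rate=frame_rate,
            frame_index=np.array([o.frame for o in obs], dtype=int),
        )


@dataclass(frozen=True)
class TrialMetrics:
    """The four per-trial rheotaxis performance numbers."""

    trial_id: str
    net_displacement: float
    cumulative_upstream: float
    mean_flow_regime: float
    upstream_orientation: float

    def __post_init__(self) -> None:
        assert self.cumulative_upstream >= -1e-9
        assert -1e-9 <= self.upstream_orientation <= 1 + 1e-9
        assert self.cumulative_upstream >= self.net_displacement - 1e-6


@dataclass(frozen=True)
class TemporalProfile:
    """Per-frame group means of zone score and upstream alignment."""

    group: str
    mean_zone: np.ndarray
    mean_alignment: np.ndarray
    n_tracks: int


def body_axis_angle(obs: FrameObservation) -> float:
    """Direction (radians, [0, 2*pi)) of the posterior-to-anterior body axis."""
    dx = obs.anterior[0] - obs.posterior[0]
    dy = obs.anterior[1] - obs.posterior[1]
    if dx == 0.0 and dy == 0.0:
        raise TrackError(f"degenerate pose at frame {obs.frame}")
    return wrap_angle(math.atan2(dy, dx))


def _polar_arrays(points: np.ndarray, geom: TankGeometry) -> tuple[np.ndarray, np.ndarray]:
    xy = points - np.asarray(geom.center)
    r = np.hypot(xy[:, 0], xy[:, 1])
    if np.any(r == 0):
        raise DegenerateCoordinateError(
            f"point at the tank center at frame {int(np.flatnonzero(r == 0)[0])}"
        )
    return r, np.arctan2(xy[:, 1], xy[:, 0])


def _alignment_series(
    track: Track,
    geom: TankGeometry,
    window_deg: float = DEFAULT_ALIGNMENT_WINDOW_DEG,
) -> np.ndarray:
    """Boolean per-frame series: body axis within the upstream window."""
    body = track.anterior - track.posterior
    body_angle = np.arctan2(body[:, 1], body[:, 0])
    r, theta = _polar_arrays(track.midpoints, geom)
    upstream = theta - geom.flow_sense * np.pi / 2.0
    dev = np.abs(wrap_signed_array(body_angle - upstream))
    return dev <= math.radians(window_deg) + 1e-12  # inclusive at the window edge


def alignment_flag(
    obs: FrameObservation,
    geom: TankGeometry,
    zones: FlowZoneMap | None = None,
    window: float = DEFAULT_ALIGNMENT_WINDOW_DEG,
) -> bool:
    """True iff the body axis is within ``window`` degrees (inclusive) of the
    upstream tangent at the fish midpoint."""
    track = Track("_single", np.array([obs.anterior]), np.array([obs.posterior]))
    return bool(_alignment_series(track, geom, window)[0])


def zone_series(
    track: Track,
    geom: TankGeometry,
    zones: FlowZoneMap,
) -> np.ndarray:
    """Per-frame flow-zone score at the fish midpoint."""
    r, _ = _polar_arrays(track.midpoints, geom)
    return zone_index_array(r, geom, zones)


def compute_metrics(
    track: Track,
    geom: TankGeometry,
    zones: FlowZoneMap,
    window_deg: float = DEFAULT_ALIGNMENT_WINDOW_DEG,
    position: str = "midpoint",
) -> TrialMetrics:
    """Reduce one track to the four rheotaxis performance metrics.

    ``position`` selects the point that defines fish location for
    displacement and zone assignment: ``"midpoint"`` (default) of the two
    tracked ends, or ``"anterior"``.
    """
    if len(track) < 2:
        raise TrackError(f"track {track.trial_id!r} has fewer than 2 frames")
    if position == "midpoint":
        pts = track.midpoints
    elif position == "anterior":
        pts = track.anterior
    else:
        raise ValueError(f"unknown position {position!r}")
    r, theta = _polar_arrays(pts, geom)
    zs = zone_index_array(r, geom, zones)
    steps = signed_arc_steps(r, theta, geom)
    net = float(np.sum(steps))
    cumulative = float(np.sum(np.maximum(steps, 0.0)))
    align = _alignment_series(track, geom, window_deg)
    return TrialMetrics(
        trial_id=track.trial_id,
        net_displacement=net,
        cumulative_upstream=cumulative,
        mean_flow_regime=float(np.mean(zs)),
        upstream_orientation=float(np.mean(align)),
    )


def temporal_profiles(
    tracks: Sequence[Track],
    groups: Sequence[str],
    geom: TankGeometry,
    zones: FlowZoneMap,
    window_deg: float = DEFAULT_ALIGNMENT_WINDOW_DEG,
) -> list[TemporalProfile]:
    """Per-frame group means of zone score and alignment across tracks.

    All tracks must share length and frame rate; one profile is returned per
    distinct group label, in order of first appearance.
    """
    if len(tracks) != len(groups):
        raise ValueError("one group label per track required")
    if not tracks:
        raise ValueError("no tracks given")
    n = len(tracks[0])
    rate = tracks[0].frame_rate
    for t in tracks:
        if len(t) != n or t.frame_rate != rate:
            raise TrackError(
                f"track {t.trial_id!r} length/frame-rate differs from the first track"
            )
    order: list[str] = []
    by_group: dict[str, list[Track]] = {}
    for t, g in zip(tracks, groups):
        if g not in by_group:
            by_group[g] = []
            order.append(g)
        by_group[g].append(t)
    profiles = []
    for g in order:
        zs = np.stack([zone_series(t, geom, zones) for t in by_group[g]])
        al = np.stack([_alignment_series(t, geom, window_deg) for t in by_group[g]])
        profiles.append(
            TemporalProfile(
                group=g,
                mean_zone=zs.mean(axis=0),
                mean_alignment=al.astype(float).mean(axis=0),
                n_tracks=len(by_group[g]),
            )
        )
    return profiles


def passive_baseline(zone: int, duration: float, zones: FlowZoneMap) -> float:
    """Expected drift (cm, negative = downstream) of a non-swimmer held in a zone.

    The closed form ``-speed * duration`` is the single-zone advection
    baseline against which fish net displacement is judged.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    return -flow_speed(zone, zones) * duration
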