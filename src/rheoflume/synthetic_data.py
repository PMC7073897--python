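"""Synthetic trials: trajectory simulation, study designs, and video stand-ins.

No tracked videos accompany the study this package models, so every
downstream stage is exercised on simulated data with the same statistical
shape: a biased correlated random walk in the annulus (headings von-Mises
distributed around the local upstream tangent, advection downstream at the
occupied zone's water speed, radial relaxation toward a target flow zone),
a factorial river x pool x generation sampling design with realistic mass
and temperature distributions, and a renderer/detector pair that round-trips
tracks through marker images the way a webcam-plus-ImageJ workflow would.

Two flow-zone occupancy strategies are built in, mirroring the two observed
behavioral solutions: holding an intermediate zone for the whole trial
("Aripo-like") versus starting in the slowest zone and switching to the
fastest ("Turure-like").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .tank_geometry import FlowZoneMap, TankGeometry
from .trajectory_metrics import DEFAULT_FRAME_RATE, Track

DEFAULT_N_FRAMES = 450
DEFAULT_BODY_LENGTH = 2.0  # cm, anterior/posterior markers sit +/- 1 cm

RIVERS = ("Aripo", "Turure")
POOLS = ("Above", "Between", "Below")
GENERATIONS = ("F0", "F1")

#: fish analyzed per river x pool x generation cell (the study's design)
DEFAULT_COUNTS: dict[tuple[str, str, str], int] = {
    ("Aripo", "Above", "F0"): 11, ("Aripo", "Above", "F1"): 2,
    ("Aripo", "Between", "F0"): 5, ("Aripo", "Between", "F1"): 5,
    ("Aripo", "Below", "F0"): 6, ("Aripo", "Below", "F1"): 0,
    ("Turure", "Above", "F0"): 14, ("Turure", "Above", "F1"): 2,
    ("Turure", "Between", "F0"): 6, ("Turure", "Between", "F1"): 3,
    ("Turure", "Below", "F0"): 5, ("Turure", "Below", "F1"): 2,
}


class SimulationConfigError(ValueError):
    """Behavior or design parameters violating their invariants."""


class RenderError(ValueError):
    """Track cannot be rendered into the requested image geometry."""


class DetectionError(ValueError):
    """A frame without exactly one anterior and one posterior marker."""


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the biased correlated random walk.

    swim_speed
        Sustained swimming speed, cm/s, applied along the drawn heading.
    heading_concentration
        von Mises concentration (kappa) of the heading around the local
        upstream tangent; 0 gives uniform headings, ``inf`` locks the fish
        exactly upstream.
    zone_strategy
        Piecewise-constant target-zone schedule: ((start_s, zone), ...),
        sorted by start time; zone values may be fractional.
    radial_relaxation
        Rate (1/s) at which the radial position relaxes toward the target
        zone's mid-band radius.
    radial_noise_sd
        Gaussian radial jitter, cm per frame step.
    seed
        Default RNG seed when no generator is passed to the simulator.
    """

    swim_speed: float = 8.0
    heading_concentration: float = 2.0
    zone_strategy: tuple[tuple[float, float], ...] = ((0.0, 1.5),)
    radial_relaxation: float = 0.5
    radial_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swim_speed < 0 or self.radial_relaxation < 0 or self.radial_noise_sd < 0:
            raise SimulationConfigError("rates, speeds and noise SDs must be >= 0")
        if not (self.heading_concentration >= 0):
            raise SimulationConfigError("heading_concentration must be >= 0")
        if not self.zone_strategy:
            raise SimulationConfigError("zone_strategy needs at least one segment")
        starts = [s for s, _ in self.zone_strategy]
        if starts != sorted(starts) or starts[0] > 0:
            raise SimulationConfigError("zone_strategy must start at t<=0 and be sorted")

    def target_zone(self, t: float) -> float:
        z = self.zone_strategy[0][1]
        for start, zone in self.zone_strategy:
            if t >= start:
                z = zone
        return z

    def validate_zones(self, zones: FlowZoneMap) -> None:
        for _, z in self.zone_strategy:
            if not 0 <= z <= zones.n_zones - 1:
                raise SimulationConfigError(
                    f"zone_strategy value {z} outside 0..{zones.n_zones - 1}"
                )


def aripo_like(**overrides) -> BehaviorParams:
    """Constant-intermediate strategy: hold zone score 1.5 throughout."""
    return replace(BehaviorParams(zone_strategy=((0.0, 1.5),)), **overrides)


def turure_like(switch_time: float = 120.0, **overrides) -> BehaviorParams:
    """Low-then-high strategy: slowest zone first, fastest after the switch."""
    return replace(
        BehaviorParams(zone_strategy=((0.0, 0.0), (switch_time, 3.0))), **overrides
    )


@dataclass(frozen=True)
class OutlierSpec:
    """Inject extreme swimmers: ``count`` trials get swim_speed x multiplier."""

    count: int = 0
    multiplier: float = 5.0


@dataclass(frozen=True)
class StudyDesign:
    """Counts and trait distributions of a factorial river x pool x generation study.

    Defaults match the assayed sample (61 females; wild-caught F0 heavier than
    lab-reared F1) and the trial temperature record.
    """

    counts: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    mass_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"F0": (0.34, 0.08), "F1": (0.15, 0.07)}
    )
    temperature_mean_sd: tuple[float, float] = (23.0, 1.0)
    outliers: OutlierSpec = OutlierSpec()

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise SimulationConfigError("cell counts must be >= 0")
        if any(sd < 0 for _, sd in self.mass_mean_sd.values()) or self.temperature_mean_sd[1] < 0:
            raise SimulationConfigError("SDs must be >= 0")

    @property
    def n_trials(self) -> int:
        return sum(self.counts.values())


@dataclass
class TrialRecord:
    """Metadata for one simulated trial; metrics are attached downstream."""

    trial_id: str
    river: str
    pool: str
    generation: str
    mass_g: float
    mean_temp_c: float


def simulate_track(
    params: BehaviorParams,
    geom: TankGeometry,
    zones: FlowZoneMap,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate: float = DEFAULT_FRAME_RATE,
    rng: np.random.Generator | None = None,
    trial_id: str = "sim",
    body_length: float = DEFAULT_BODY_LENGTH,
) -> Track:
    """Simulate one trial as a biased correlated random walk in the annulus.

    Per frame step: a heading is drawn von-Mises around the local upstream
    tangent; the along-channel (arc) displacement is the heading's upstream
    component of thrust minus advection at the occupied zone's water speed;
    the radius takes the heading's radial thrust component, relaxes toward
    the strategy's target mid-band radius, receives Gaussian jitter, and is
    reflected at both walls. Anterior/posterior markers sit half a body
    length along the heading from the midpoint. Fully reproducible from the
    seed/generator.
    """
    if n_frames < 2:
        raise SimulationConfigError("n_frames must be >= 2")
    params.validate_zones(zones)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dt = 1.0 / frame_rate
    kappa = params.heading_concentration
    if math.isinf(kappa):
        devs = np.zeros(n_frames)
    else:
        # kappa=0 is the circular-uniform limit of the von Mises draw
        devs = rng.vonmises(0.0, kappa, size=n_frames)
    radial_noise = rng.normal(0.0, params.radial_noise_sd, size=n_frames)

    r = zones.mid_radius(params.target_zone(0.0))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    half = 0.5 * body_length
    mids = np.empty((n_frames, 2))
    headings = np.empty(n_frames)
    lo, hi = geom.inner_radius, geom.outer_radius
    bounds = np.asarray(zones.zone_boundaries)
    speeds = np.asarray(zones.zone_speeds)

    for i in range(n_frames):
        upstream = theta - geom.flow_sense * np.pi / 2.0
        h = upstream + devs[i]
        mids[i] = (r * math.cos(theta), r * math.sin(theta))
        headings[i] = h
        if i == n_frames - 1:
            break
        zone = min(max(int(np.searchsorted(bounds, r, side="right")) - 1, 0), len(speeds) - 1)
        # upstream arc displacement: thrust component along upstream minus advection
        arc = (params.swim_speed * math.cos(devs[i]) - speeds[zone]) * dt
        dtheta = -geom.flow_sense * arc / r
        # radial thrust component plus relaxation toward the target band, plus
        # jitter; exact exponential discretization keeps any relaxation rate stable
        relax = 1.0 - math.exp(-params.radial_relaxation * dt)
        dr = (
            params.swim_speed * math.cos(h - theta) * dt
            + relax * (zones.mid_radius(params.target_zone(i * dt)) - r)
            + radial_noise[i]
        )
        r_new = r + dr
        while r_new < lo or r_new > hi:  # reflect at both walls
            if r_new < lo:
                r_new = 2 * lo - r_new
            if r_new > hi:
                r_new = 2 * hi - r_new
        r = r_new
        theta = (theta + dtheta) % (2.0 * np.pi)

    offset = np.column_stack([np.cos(headings), np.sin(headings)]) * half
    center = np.asarray(geom.center)
    return Track(
        trial_id,
        anterior=mids + offset + center,
        posterior=mids - offset + center,
        frame_rate=frame_rate,
    )


def generate_study(
    design: StudyDesign,
    behavior_by_river: Mapping[str, BehaviorParams],
    geom: TankGeometry,
    zones: FlowZoneMap,
    seed: int = 0,
    n_frames: int = DEFAULT_N_FRAMES,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> tuple[list[TrialRecord], list[Track]]:
    """Simulate one full study: a record and a track per designed fish.

    Masses are drawn per generation (truncated at 0.02 g), temperatures per
    trial; per-trial RNG streams are spawned deterministically from ``seed``,
    so two runs with the same seed give identical tables and tracks.
    """
    if design.n_trials == 0:
        raise SimulationConfigError("study design has no fish")
    for river in {k[0] for k in design.counts if design.counts[k] > 0}:
        if river not in behavior_by_river:
            raise SimulationConfigError(f"no behavior parameters for river {river!r}")
    root = np.random.SeedSequence(seed)
    cells = sorted(design.counts.items())
    children = root.spawn(sum(c for _, c in cells) + 1)
    meta_rng = np.random.default_rng(children[0])

    records: list[TrialRecord] = []
    tracks: list[Track] = []
    child_iter = iter(children[1:])
    for (river, pool, gen), count in cells:
        mu, sd = design.mass_mean_sd[gen]
        t_mu, t_sd = design.temperature_mean_sd
        for i in range(count):
            trial_id = f"{river.lower()}-{pool.lower()}-{gen.lower()}-{i:02d}"
            mass = max(float(meta_rng.normal(mu, sd)), 0.02)
            temp = float(meta_rng.normal(t_mu, t_sd))
            records.append(TrialRecord(trial_id, river, pool, gen, mass, temp))
            rng = np.random.default_rng(next(child_iter))
            tracks.append(
                simulate_track(
                    behavior_by_river[river], geom, zones,
                    n_frames=n_frames, frame_rate=frame_rate, rng=rng, trial_id=trial_id,
                )
            )
    if design.outliers.count > 0:
        idx = meta_rng.choice(len(records), size=design.outliers.count, replace=False)
        for j in sorted(int(k) for k in idx):
            boosted = replace(
                behavior_by_river[records[j].river],
                swim_speed=behavior_by_river[records[j].river].swim_speed
                * design.outliers.multiplier,
                heading_concentration=50.0,
            )
            rng = np.random.default_rng(np.random.SeedSequence([seed, 9000 + j]))
            tracks[j] = simulate_track(
                boosted, geom, zones, n_frames=n_frames, frame_rate=frame_rate,
                rng=rng, trial_id=records[j].trial_id,
            )
    return records, tracks


# ---------------------------------------------------------------------------
# synthetic video frames: render tracks to marker images and detect them back
# ---------------------------------------------------------------------------

WALL_INTENSITY = 0.25
ANTERIOR_PEAK = 1.0
POSTERIOR_PEAK = 0.6
MARKER_SIGMA_PX = 1.0
DETECT_THRESHOLD = 0.25


def _to_pixel(points: np.ndarray, geom: TankGeometry, image_size: int, calibration: float):
    """cm -> (row, col) pixel coordinates; image row axis points down."""
    c = (image_size - 1) / 2.0
    xy = np.atleast_2d(points) - np.asarray(geom.center)
    col = c + xy[:, 0] / calibration
    row = c - xy[:, 1] / calibration
    return row, col


def _from_pixel(row, col, geom: TankGeometry, image_size: int, calibration: float):
    c = (image_size - 1) / 2.0
    x = (np.asarray(col) - c) * calibration + geom.center[0]
    y = (c - np.asarray(row)) * calibration + geom.center[1]
    return x, y


def render_background(geom: TankGeometry, image_size: int, calibration: float) -> np.ndarray:
    """Walls-only image: the two tank walls drawn as thin bright rings."""
    c = (image_size - 1) / 2.0
    rr, cc = np.mgrid[0:image_size, 0:image_size]
    dist = np.hypot(rr - c, cc - c) * calibration
    bg = np.zeros((image_size, image_size), dtype=float)
    for wall in (geom.inner_radius, geom.outer_radius):
        bg[np.abs(dist - wall) < calibration] = WALL_INTENSITY
    return bg


def render_frames(
    track: Track,
    geom: TankGeometry,
    image_size: int = 200,
    calibration: float = 0.35,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a track as a stack of grayscale marker images.

    Each frame shows the tank walls plus two Gaussian blobs: a bright
    anterior marker and a dimmer posterior marker, at calibrated pixel
    positions (``calibration`` cm per pixel). Optional Gaussian pixel noise
    is reproducible from ``rng``.
    """
    if calibration <= 0:
        raise RenderError("calibration must be positive (cm per pixel)")
    if len(track) == 0:
        raise RenderError("cannot render an empty track (no fish)")
    if 2.0 * geom.outer_radius / calibration > image_size:
        raise RenderError(
            f"tank (diameter {2 * geom.outer_radius} cm) does not fit in "
            f"{image_size} px at {calibration} cm/px"
        )
    bg = render_background(geom, image_size, calibration)
    stack = np.empty((len(track), image_size, image_size), dtype=float)
    grid = np.arange(image_size, dtype=float)
    for peak_check, pts in (("anterior", track.anterior), ("posterior", track.posterior)):
        row, col = _to_pixel(pts, geom, image_size, calibration)
        if np.any((row < 0) | (row > image_size - 1) | (col < 0) | (col > image_size - 1)):
            raise RenderError(f"{peak_check} marker outside the image after calibration")
    for i in range(len(track)):
        img = bg.copy()
        for pts, peak in ((track.anterior[i], ANTERIOR_PEAK), (track.posterior[i], POSTERIOR_PEAK)):
            row, col = _to_pixel(pts, geom, image_size, calibration)
            gr = np.exp(-0.5 * ((grid - row[0]) / MARKER_SIGMA_PX) ** 2)
            gc = np.exp(-0.5 * ((grid - col[0]) / MARKER_SIGMA_PX) ** 2)
            img += peak * np.outer(gr, gc)
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            img += rng.normal(0.0, noise_sd, img.shape)
        stack[i] = img
    return stack


def detect_markers(
    stack: np.ndarray,
    calibration: float,
    geom: TankGeometry,
    frame_rate: float = DEFAULT_FRAME_RATE,
    trial_id: str = "detected",
    threshold: float = DETECT_THRESHOLD,
) -> Track:
    """Recover anterior/posterior coordinates from a rendered image stack.

    The known walls-only background is subtracted, the residual thresholded
    and labelled; each frame must yield exactly two blobs. Blob positions are
    intensity-weighted centroids (sub-pixel); the brighter blob is the
    anterior marker.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise DetectionError("expected a (n_frames, h, w) image stack")
    n, h, w = stack.shape
    if h != w:
        raise DetectionError("expected square frames")
    bg = render_background(geom, h, calibration)
    anterior = np.empty((n, 2))
    posterior = np.empty((n, 2))
    for i in range(n):
        residual = np.clip(stack[i] - bg, 0.0, None)
        mask = residual > threshold
        labels, n_comp = ndimage.label(mask)
        if n_comp != 2:
            raise DetectionError(
                f"frame {i}: expected 2 markers, found {n_comp} blobs"
            )
        centroids = ndimage.center_of_mass(residual, labels, index=[1, 2])
        peaks = ndimage.maximum(residual, labels, index=[1, 2])
        order = np.argsort(peaks)[::-1]  # brighter blob first -> anterior
        for dest, k in zip((anterior, posterior), order):
            x, y = _from_pixel(centroids[k][0], centroids[k][1], geom, h, calibration)
            dest[i] = (float(x), float(y))
    return Track(trial_id, anterior=anterior, posterior=posterior, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# group-mean temporal profiles with autocorrelated noise (for smooth fitting)
# ---------------------------------------------------------------------------

def ar1_noise(
    n: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if not -1 < rho < 1:
        raise ValueError("AR(1) coefficient must be in (-1, 1)")
    e = np.empty(n)
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + shocks[t]
    return e


def step_trend(
    n_frames: int,
    frame_rate: float,
    low: float,
    high: float,
    switch_time: float,
    ramp_s: float = 10.0,
) -> np.ndarray:
    """Low-then-high trend through a smooth logistic ramp at ``switch_time``."""
    t = np.arange(n_frames) / frame_rate
    return low + (high - low) / (1.0 + np.exp(-(t - switch_time) / ramp_s))


def simulate_mean_profile(
    trend: np.ndarray,
    rho: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A group-mean temporal series: deterministic trend plus AR(1) noise."""
    trend = np.asarray(trend, dtype=float)
    return trend + ar1_noise(len(trend), rho, sd, rng)
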