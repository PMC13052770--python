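"""Seeded generators for ground-truth test data.

Track generators produce 2D trajectories whose ensemble MSDs converge to the
closed forms used by the fitter:

- brownian: independent Gaussian increments, variance 2*D*dt per component;
- prw: velocity follows a per-component Ornstein-Uhlenbeck process with
  correlation time P and stationary mean-square speed v^2; positions are the
  exact integral of the velocity (jointly Gaussian discrete update, no Euler
  error), so the ensemble MSD is exactly 2 v^2 P^2 (t/P - (1 - e^(-t/P)));
- confined: Brownian steps radially reflected inside a disc of radius b,
  initialized from the uniform stationary distribution; the long-lag MSD
  plateau is b^2.

Also provides synthetic calcium transients and disc-pair mask movies with
analytic ground truth.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .synapse_metrics import IntensityTrace, MaskMovie
from .track_io import (
    FLAG_GAPPED,
    FLAG_NOISY,
    Track,
    TrackCollection,
)

logger = logging.getLogger(__name__)

WALK_MODELS = ("brownian", "prw", "confined")

_PARAM_NAMES = {
    "brownian": ("D",),
    "prw": ("v", "P"),
    "confined": ("D", "disc_radius"),
}


@dataclass(frozen=True)
class WalkSimConfig:
    """Configuration for one simulated track ensemble.

    ``params`` is model-specific: brownian {D}, prw {v, P},
    confined {D, disc_radius}.  Units: µm, minutes.
    """

    model: str
    params: dict
    n_tracks: int
    n_frames: int
    frame_interval: float = 2.0
    localization_sigma: float = 0.0
    gap_rate: float = 0.0
    seed: int = 0
    condition: str = "sim"

    def __post_init__(self):
        if self.model not in WALK_MODELS:
            raise ConfigError(f"unknown walk model {self.model!r}")
        expected = _PARAM_NAMES[self.model]
        missing = [p for p in expected if p not in self.params]
        if missing:
            raise ConfigError(f"model {self.model}: missing params {missing}")
        if any(self.params[p] < 0 for p in expected):
            raise ConfigError("physical parameters must be non-negative")
        if self.n_tracks < 1 or self.n_frames < 2:
            raise ConfigError("need n_tracks >= 1 and n_frames >= 2")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.localization_sigma < 0:
            raise ConfigError("localization_sigma must be >= 0")
        if not 0.0 <= self.gap_rate <= 0.2:
            raise ConfigError("gap_rate must be in [0, 0.2]")


def simulate_tracks(config: WalkSimConfig) -> TrackCollection:
    """Dispatch to the model-specific generator."""
    return {
        "brownian": simulate_brownian,
        "prw": simulate_prw,
        "confined": simulate_confined,
    }[config.model](config)


def _package(config: WalkSimConfig, positions: np.ndarray, prefix: str) -> TrackCollection:
    """Wrap an (n_tracks, n_frames, 2) array as a TrackCollection, applying
    imaging artifacts if configured."""
    dt = config.frame_interval
    times = np.arange(config.n_frames) * dt
    tracks = [
        Track(
            track_id=f"{prefix}-{i:04d}",
            times=times.copy(),
            positions=positions[i],
            frame_interval=dt,
            condition=config.condition,
            source=f"simulate_{config.model}(seed={config.seed})",
        )
        for i in range(config.n_tracks)
    ]
    collection = TrackCollection(
        tracks=tracks,
        metadata={
            "frame_interval": dt,
            "model": config.model,
            "params": dict(config.params),
            "seed": config.seed,
        },
    )
    if config.localization_sigma > 0 or config.gap_rate > 0:
        collection = add_imaging_artifacts(
            collection,
            localization_sigma=config.localization_sigma,
            gap_rate=config.gap_rate,
            seed=config.seed + 1_000_003,
        )
    return collection


def simulate_brownian(config: WalkSimConfig) -> TrackCollection:
    """Isotropic Brownian tracks: increment variance 2*D*dt per component."""
    if config.model != "brownian":
        raise ConfigError("config.model must be 'brownian'")
    rng = np.random.default_rng(config.seed)
    D = config.params["D"]
    sigma = math.sqrt(2.0 * D * config.frame_interval)
    steps = rng.normal(0.0, sigma, size=(config.n_tracks, config.n_frames - 1, 2))
    positions = np.concatenate(
        [np.zeros((config.n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    return _package(config, positions, "brw")


def simulate_prw(config: WalkSimConfig) -> TrackCollection:
    """Persistent random walk via the exactly-discretized integrated
    Ornstein-Uhlenbeck velocity process (stationary initial velocity)."""
    if config.model != "prw":
        raise ConfigError("config.model must be 'prw'")
    v, P = config.params["v"], config.params["P"]
    if v <= 0 or P <= 0:
        raise ConfigError("prw requires v > 0 and P > 0")
    dt = config.frame_interval
    if dt >= 5.0 * P:
        logger.warning(
            "frame interval %.3g >= 5P (P=%.3g); persistence is barely sampled",
            dt, P,
        )
    rng = np.random.default_rng(config.seed)
    theta = 1.0 / P
    mu = math.exp(-theta * dt)
    sv2 = v**2 / 2.0  # stationary per-component velocity variance
    Svv = sv2 * (1.0 - mu**2)
    Sxv = sv2 * (1.0 - mu) ** 2 / theta
    Sxx = (2.0 * sv2 / theta) * (
        dt - 2.0 * (1.0 - mu) / theta + (1.0 - mu**2) / (2.0 * theta)
    )
    a = math.sqrt(Svv)
    c = Sxv / a
    d = math.sqrt(max(Sxx - c**2, 0.0))

    n, m = config.n_tracks, config.n_frames
    vel = rng.normal(0.0, math.sqrt(sv2), size=(n, 2))
    positions = np.zeros((n, m, 2))
    for j in range(1, m):
        xi1 = rng.normal(size=(n, 2))
        xi2 = rng.normal(size=(n, 2))
        dx = vel * (1.0 - mu) / theta + c * xi1 + d * xi2
        positions[:, j] = positions[:, j - 1] + dx
        vel = vel * mu + a * xi1
    return _package(config, positions, "prw")


def simulate_confined(config: WalkSimConfig) -> TrackCollection:
    """Brownian steps radially reflected inside a disc of radius
    ``disc_radius``, started from the uniform (stationary) in-disc law."""
    if config.model != "confined":
        raise ConfigError("config.model must be 'confined'")
    D, b = config.params["D"], config.params["disc_radius"]
    if b <= 0:
        raise ConfigError("disc_radius must be positive")
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    sigma = math.sqrt(2.0 * D * dt)
    n, m = config.n_tracks, config.n_frames

    # Stationary start: uniform in the disc.
    r0 = b * np.sqrt(rng.uniform(size=n))
    phi0 = rng.uniform(0.0, 2.0 * math.pi, size=n)
    pos = np.column_stack([r0 * np.cos(phi0), r0 * np.sin(phi0)])

    positions = np.zeros((n, m, 2))
    positions[:, 0] = pos
    for j in range(1, m):
        pos = pos + rng.normal(0.0, sigma, size=(n, 2))
        pos = _reflect_into_disc(pos, b)
        positions[:, j] = pos
    return _package(config, positions, "cnf")


def _reflect_into_disc(pos: np.ndarray, b: float) -> np.ndarray:
    """Radial mirror reflection about the circle |r| = b (repeated until
    every point is inside; exact for steps << b)."""
    pos = pos.copy()
    for _ in range(64):
        r = np.linalg.norm(pos, axis=1)
        outside = r > b
        if not outside.any():
            return pos
        r_out = r[outside]
        r_new = np.abs(2.0 * b - r_out)
        scale = np.where(r_out > 0, r_new / r_out, 1.0)
        pos[outside] *= scale[:, None]
    raise ConfigError("reflection failed to converge; step size >> disc radius?")


def add_imaging_artifacts(
    collection: TrackCollection,
    localization_sigma: float = 0.0,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> TrackCollection:
    """Add i.i.d. Gaussian localization noise and 1-2 frame gaps.

    Noise is per-component with standard deviation ``localization_sigma``
    (static error: shifts the MSD of a stationary track by 4 sigma^2 in 2D).
    Interior frames start a gap with probability ``gap_rate``; gap length is
    1 or 2 frames, never longer.  Affected tracks are flagged.
    """
    if localization_sigma < 0 or not 0.0 <= gap_rate <= 0.2:
        raise ConfigError("invalid artifact parameters")
    rng = np.random.default_rng(seed)
    out = []
    for track in collection:
        times = track.times.copy()
        positions = track.positions.copy()
        flags = set(track.flags)
        if localization_sigma > 0:
            positions = positions + rng.normal(
                0.0, localization_sigma, size=positions.shape
            )
            flags.add(FLAG_NOISY)
        if gap_rate > 0:
            keep = np.ones(len(times), dtype=bool)
            i = 1
            while i < len(times) - 2:
                if rng.uniform() < gap_rate:
                    length = int(rng.integers(1, 3))
                    length = min(length, len(times) - 2 - i + 1)
                    keep[i : i + length] = False
                    i += length + 1  # never merge two gaps into a longer run
                else:
                    i += 1
            if not keep.all():
                flags.add(FLAG_GAPPED)
                times = times[keep]
                positions = positions[keep]
        out.append(
            Track(
                track_id=track.track_id,
                times=times,
                positions=positions,
                frame_interval=track.frame_interval,
                condition=track.condition,
                flags=frozenset(flags),
                source=track.source,
            )
        )
    return TrackCollection(tracks=out, metadata=dict(collection.metadata))


# ---------------------------------------------------------------------------
# Calcium transients
# ---------------------------------------------------------------------------

@dataclass
class CalciumGroundTruth:
    """Closed-form description of a simulated calcium transient."""

    baseline: float
    peak_amplitude: float
    peak_time: float
    decay_time: float

    @property
    def normalized_peak(self) -> float:
        return 1.0 + self.peak_amplitude / self.baseline

    def analytic_auc(self, t0: float, t1: float) -> float:
        """Integral of the normalized (value/baseline) trace over [t0, t1]."""
        if t1 <= t0:
            return 0.0
        auc = t1 - t0  # the baseline contributes 1.0 per minute
        lo = max(t0, self.peak_time)
        if t1 > lo:
            ratio = self.peak_amplitude / self.baseline
            tau = self.decay_time
            auc += ratio * tau * (
                math.exp(-(lo - self.peak_time) / tau)
                - math.exp(-(t1 - self.peak_time) / tau)
            )
        return auc


def simulate_calcium_trace(
    baseline: float,
    peak_amplitude: float,
    peak_time: float,
    decay_time: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    duration: float = 40.0,
    dt: float = 0.5,
    cell_id: str = "sim-ca",
) -> tuple:
    """Baseline, instantaneous rise at ``peak_time``, exponential decay.

    Returns ``(IntensityTrace, CalciumGroundTruth)``; ``t_zero`` is set to 0.
    """
    if baseline <= 0 or peak_amplitude < 0 or decay_time <= 0 or dt <= 0:
        raise ConfigError("invalid calcium simulation parameters")
    if not 0 <= peak_time < duration:
        raise ConfigError("peak_time must lie inside the trace duration")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + dt / 2, dt)
    values = np.full_like(times, baseline)
    after = times >= peak_time
    values[after] += peak_amplitude * np.exp(-(times[after] - peak_time) / decay_time)
    if noise_sigma > 0:
        values = np.maximum(values + rng.normal(0.0, noise_sigma, size=values.shape), 0)
    trace = IntensityTrace(
        cell_id=cell_id, channel="calcium", times=times, values=values, t_zero=0.0
    )
    truth = CalciumGroundTruth(
        baseline=baseline,
        peak_amplitude=peak_amplitude,
        peak_time=peak_time,
        decay_time=decay_time,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Mask movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskMovieConfig:
    """Two discs translating at constant velocity inside a pixel grid.

    Positions and radii in µm; velocities in µm/min.  Both discs must stay
    inside the field of view on every frame.
    """

    shape_px: tuple = (128, 128)
    pixel_size: float = 0.5
    n_frames: int = 10
    frame_interval: float = 1.0
    radius_a: float = 8.0
    radius_b: float = 8.0
    center_a: tuple = (20.0, 20.0)
    center_b: tuple = (20.0, 44.0)
    velocity_a: tuple = (0.0, 0.0)
    velocity_b: tuple = (0.0, -2.0)

    def __post_init__(self):
        if self.pixel_size <= 0 or self.n_frames < 1 or self.frame_interval <= 0:
            raise ConfigError("invalid mask movie geometry")
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ConfigError("disc radii must be positive")


@dataclass
class MaskMoviePair:
    """Two synthetic mask movies plus their analytic per-frame overlap."""

    movie_a: MaskMovie
    movie_b: MaskMovie
    analytic_overlap: np.ndarray
    config: MaskMovieConfig = field(default=None)


def circle_overlap_area(r1: float, r2: float, d: float) -> float:
    """Exact lens area of two discs with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    a1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * math.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    return a1 + a2 - tri


def simulate_mask_movie(config: MaskMovieConfig, seed: int = 0) -> MaskMoviePair:
    """Rasterize the two-disc geometry and record the analytic overlap."""
    h, w = config.shape_px
    ps = config.pixel_size
    # pixel-center coordinates in µm
    yy, xx = np.mgrid[0:h, 0:w]
    cy = (yy + 0.5) * ps
    cx = (xx + 0.5) * ps
    times = np.arange(config.n_frames) * config.frame_interval

    frames_a = np.zeros((config.n_frames, h, w), dtype=bool)
    frames_b = np.zeros_like(frames_a)
    analytic = np.zeros(config.n_frames)
    fov = (h * ps, w * ps)
    for j, t in enumerate(times):
        ca = np.asarray(config.center_a) + np.asarray(config.velocity_a) * t
        cb = np.asarray(config.center_b) + np.asarray(config.velocity_b) * t
        for center, radius in ((ca, config.radius_a), (cb, config.radius_b)):
            if (
                center[0] - radius < 0
                or center[1] - radius < 0
                or center[0] + radius > fov[0]
                or center[1] + radius > fov[1]
            ):
                raise ConfigError(
                    f"disc leaves the field of view at frame {j} (center={center})"
                )
        frames_a[j] = (cy - ca[0]) ** 2 + (cx - ca[1]) ** 2 <= config.radius_a**2
        frames_b[j] = (cy - cb[0]) ** 2 + (cx - cb[1]) ** 2 <= config.radius_b**2
        analytic[j] = circle_overlap_area(
            config.radius_a, config.radius_b, float(np.linalg.norm(ca - cb))
        )
    movie_a = MaskMovie(cell_id="sim-tcell", frames=frames_a, pixel_size=ps, times=times)
    movie_b = MaskMovie(cell_id="sim-tumor", frames=frames_b, pixel_size=ps, times=times)
    return MaskMoviePair(
        movie_a=movie_a, movie_b=movie_b, analytic_overlap=analytic, config=config
    )
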