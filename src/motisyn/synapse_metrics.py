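"""Immune-synapse quantification on intensity traces and binary mask movies.

Implements calcium F/F0 normalization and area-under-curve, synapse area as
the per-frame intersection of independently segmented T-cell and tumor-cell
masks, response speed (first-minute regression slope), MTOC docking time
(first peak of the smoothed derivative), and center-of-mass distance to the
synapse interface.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, DegenerateInputError

logger = logging.getLogger(__name__)

CHANNELS = ("calcium", "car", "f_actin", "mtoc", "other")


@dataclass(frozen=True)
class IntensityTrace:
    """Time-stamped fluorescence values for one cell and channel.

    ``t_zero`` marks the declared interaction/activation onset (same time
    unit as ``times``, minutes by convention).
    """

    cell_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    t_zero: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or len(times) != len(values):
            raise ConfigError("times and values must be 1D of equal length")
        if np.any(np.diff(times) <= 0):
            raise ConfigError("times must be strictly increasing")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ConfigError("values must be finite and non-negative")


@dataclass(frozen=True)
class MaskMovie:
    """Per-frame binary masks with physical pixel size (µm/pixel)."""

    cell_id: str
    frames: np.ndarray  # (T, H, W) boolean
    pixel_size: float
    times: np.ndarray

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=bool)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)
        if frames.ndim != 3:
            raise ConfigError("frames must be a (T, H, W) stack")
        if len(times) != frames.shape[0]:
            raise ConfigError("times length must match frame count")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")


@dataclass
class SynapseMetrics:
    """Bundle of per-cell synapse read-outs."""

    cell_id: str
    normalized_peak: float | None = None
    calcium_auc_30min: float | None = None
    synapse_area_series: np.ndarray | None = None
    response_speed: float | None = None
    docking_time: float | None = None
    com_distance: float | None = None
    flags: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Calcium
# ---------------------------------------------------------------------------

@dataclass
class CalciumNormalization:
    """Normalized trace plus the F0 used and QC flags."""

    trace: IntensityTrace
    f0: float
    peak_index: int | None
    onset_index: int | None
    flags: frozenset

    @property
    def normalized_peak(self) -> float:
        return float(np.max(self.trace.values))


def normalize_calcium(
    trace: IntensityTrace, peak_prominence: float = 0.2
) -> CalciumNormalization:
    """Divide a calcium trace by its baseline before the first influx peak.

    The first local maximum after ``t_zero`` with prominence >=
    ``peak_prominence`` x the trace range is taken as the influx peak; its
    onset is found by backtracking to the last non-increasing frame, and F0
    is the mean of all samples before the onset.  Traces with no qualifying
    peak are normalized by the pre-``t_zero`` mean and flagged ``no_peak``.
    """
    if len(trace.values) < 5:
        raise DegenerateInputError("need >= 5 samples to normalize calcium")
    if not np.any(trace.times > trace.t_zero):
        raise DegenerateInputError("no samples after t_zero")
    values = trace.values
    flags: set[str] = set()
    rng = float(np.ptp(values))
    peak_index: int | None = None
    onset_index: int | None = None
    if rng > 0:
        peaks, _ = find_peaks(values, prominence=peak_prominence * rng)
        after = [int(p) for p in peaks if trace.times[p] >= trace.t_zero]
        if after:
            peak_index = after[0]
    if peak_index is None:
        flags.add("no_peak")
        pre = values[trace.times < trace.t_zero]
        f0 = float(np.mean(pre)) if len(pre) else float(np.mean(values))
    else:
        i = peak_index
        while i > 0 and values[i - 1] < values[i]:
            i -= 1
        onset_index = i
        f0 = float(np.mean(values[: max(onset_index, 1)]))
    if f0 <= 0:
        raise DegenerateInputError("baseline F0 is zero; cannot normalize")
    normalized = replace(trace, values=values / f0)
    return CalciumNormalization(
        trace=normalized,
        f0=f0,
        peak_index=peak_index,
        onset_index=onset_index,
        flags=frozenset(flags),
    )


def calcium_auc(trace: IntensityTrace, t_max: float = 30.0) -> float:
    """Trapezoidal integral of a normalized trace over [t_zero, t_zero+t_max].

    Window endpoints falling between samples are linearly interpolated.
    Traces ending early integrate to their last sample (logged as truncated).
    """
    t0 = trace.t_zero
    t1 = t0 + t_max
    times, values = trace.times, trace.values
    if times[-1] <= t0 or times[0] >= t1:
        raise DegenerateInputError("no samples inside the integration window")
    if times[-1] < t1:
        logger.info(
            "trace %s ends at %.3g min < window end %.3g; AUC truncated",
            trace.cell_id, times[-1], t1,
        )
        t1 = times[-1]
    t0 = max(t0, times[0])
    inside = (times > t0) & (times < t1)
    grid = np.concatenate(([t0], times[inside], [t1]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def mask_intersection_area(mask_a, mask_b, pixel_size: float) -> float:
    """Area (µm^2) of pixels true in both masks; symmetric in its arguments."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be positive")
    return float(np.count_nonzero(a & b)) * pixel_size**2


def synapse_area_series(movie_t_cell: MaskMovie, movie_tumor: MaskMovie) -> np.ndarray:
    """Per-frame intersection area of two frame-aligned mask movies (µm^2)."""
    a, b = movie_t_cell, movie_tumor
    if a.frames.shape != b.frames.shape:
        raise ConfigError("mask movies differ in shape or frame count")
    if not np.isclose(a.pixel_size, b.pixel_size, rtol=1e-9):
        raise ConfigError("mask movies differ in pixel size")
    if len(a.times) > 1:
        half_frame = 0.5 * float(np.median(np.diff(a.times)))
    else:
        half_frame = np.inf
    if np.any(np.abs(a.times - b.times) > half_frame):
        raise ConfigError("mask movies misaligned in time by more than half a frame")
    return np.array(
        [
            mask_intersection_area(fa, fb, a.pixel_size)
            for fa, fb in zip(a.frames, b.frames)
        ]
    )


def mask_area_series(movie: MaskMovie) -> np.ndarray:
    """Per-frame area of a single mask movie (TIRF actin-footprint variant)."""
    return movie.frames.reshape(movie.frames.shape[0], -1).sum(axis=1) * (
        movie.pixel_size**2
    )


# ---------------------------------------------------------------------------
# Response speed and docking
# ---------------------------------------------------------------------------

def response_speed(trace: IntensityTrace, window: float = 60.0) -> float:
    """OLS slope (units/min) over the first ``window`` seconds after t_zero."""
    if window <= 0:
        raise ConfigError("window must be positive")
    t0, t1 = trace.t_zero, trace.t_zero + window / 60.0
    sel = (trace.times >= t0) & (trace.times <= t1)
    if np.count_nonzero(sel) < 3:
        raise DegenerateInputError(
            f"need >= 3 samples within the first {window:g} s window"
        )
    slope = np.polyfit(trace.times[sel], trace.values[sel], 1)[0]
    return float(slope)


def docking_time(trace: IntensityTrace, smooth_window: int = 3) -> float:
    """Time (min) of the first peak of the smoothed trace's first derivative.

    The trace is moving-average smoothed (``smooth_window`` frames), a
    central-difference derivative taken, and the first local maximum with
    prominence >= 10% of the derivative range is reported.  Returns NaN if
    no peak qualifies (e.g. a monotone-linear recruitment trace).
    """
    if smooth_window < 1:
        raise ConfigError("smooth_window must be >= 1")
    if len(trace.values) < smooth_window + 3:
        raise DegenerateInputError(
            f"need >= smooth_window+3 = {smooth_window + 3} samples"
        )
    kernel = np.ones(smooth_window) / smooth_window
    padded = np.pad(trace.values, smooth_window, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")[
        smooth_window:-smooth_window
    ]
    deriv = np.gradient(smoothed, trace.times)
    # edge-padded smoothing flattens the ends; search the interior only
    lo = smooth_window
    hi = max(len(deriv) - smooth_window, lo + 1)
    interior = deriv[lo:hi]
    rng = float(np.ptp(interior))
    # flat up to rounding error counts as "no event"
    if rng <= 1e-8 * max(float(np.max(np.abs(interior))), 1e-30):
        logger.info("trace %s: flat derivative, no docking event", trace.cell_id)
        return float("nan")
    peaks, _ = find_peaks(interior, prominence=0.1 * rng)
    if len(peaks) == 0:
        logger.info("trace %s: no qualifying derivative peak", trace.cell_id)
        return float("nan")
    return float(trace.times[lo + peaks[0]])


# ---------------------------------------------------------------------------
# Center-of-mass distance
# ---------------------------------------------------------------------------

class Interface(NamedTuple):
    """A line (2D) or plane (3D) in physical µm coordinates: a point on the
    interface and its normal vector (need not be unit length)."""

    point: tuple
    normal: tuple


def com_distance(label_image, interface: Interface, pixel_size: float) -> float:
    """Distance (µm) from the intensity-weighted centroid to the interface.

    Image coordinates follow array axes scaled by ``pixel_size`` (pixel i of
    axis a sits at ``i * pixel_size``).  Smaller values mean the label is
    more accumulated at the synapse.
    """
    img = np.asarray(label_image, dtype=float)
    if img.ndim not in (2, 3):
        raise ConfigError("label_image must be 2D or 3D")
    if pixel_size <= 0:
        raise ConfigError("pixel_size must be positive")
    total = img.sum()
    if total <= 0:
        raise DegenerateInputError("label image has zero total intensity")
    point = np.asarray(interface.point, dtype=float)
    normal = np.asarray(interface.normal, dtype=float)
    if point.shape != (img.ndim,) or normal.shape != (img.ndim,):
        raise ConfigError("interface point/normal must match image dimensionality")
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ConfigError("interface normal must be non-zero")
    grids = np.indices(img.shape, dtype=float)
    com = np.array([float((g * img).sum()) for g in grids]) / total * pixel_size
    return float(abs(np.dot(com - point, normal / norm)))


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_intensity_traces_csv(path, t_zero: float = 0.0) -> list:
    """Load long-format traces (cell_id, channel, t_min, value)."""
    df = pd.read_csv(path)
    required = ("cell_id", "channel", "t_min", "value")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s) {missing}")
    traces = []
    for (cell_id, channel), grp in df.groupby(["cell_id", "channel"], sort=True):
        grp = grp.sort_values("t_min")
        traces.append(
            IntensityTrace(
                cell_id=str(cell_id),
                channel=str(channel),
                times=grp["t_min"].to_numpy(dtype=float),
                values=grp["value"].to_numpy(dtype=float),
                t_zero=t_zero,
            )
        )
    return traces


def read_mask_movie_tiff(
    path, pixel_size: float, frame_interval: float, cell_id: str = ""
) -> MaskMovie:
    """Load a multi-page TIFF of binary masks as a MaskMovie."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    times = np.arange(stack.shape[0]) * frame_interval
    return MaskMovie(
        cell_id=cell_id or str(path),
        frames=stack > 0,
        pixel_size=pixel_size,
        times=times,
    )
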