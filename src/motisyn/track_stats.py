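"""Per-track one-lag and directionality statistics.

Definitions follow the TrackMate conventions: confinement ratio is net
displacement over total path length; linearity of forward progression is the
mean straight-line speed divided by the mean instantaneous speed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .track_io import Track, TrackCollection


@dataclass(frozen=True)
class StepStats:
    """One-lag and directionality summary for a single track."""

    track_id: str
    median_step_size: float  # µm
    median_speed: float  # µm/min
    linearity_forward_progression: float
    confinement_ratio: float
    n_steps: int
    degenerate: bool = False


def step_displacements(track: Track) -> np.ndarray:
    """Euclidean frame-to-frame step lengths (µm); length n-1."""
    if track.n_points < 2:
        raise DegenerateInputError(
            f"track {track.track_id!r}: need >= 2 points for steps"
        )
    return np.linalg.norm(np.diff(track.positions, axis=0), axis=1)


def summarize_track(track: Track) -> StepStats:
    """Median step/speed, confinement ratio, and linearity for one track.

    A zero-path (stationary) track is flagged degenerate with both
    directionality statistics defined as 0.
    """
    if track.n_points < 3:
        raise DegenerateInputError(
            f"track {track.track_id!r}: need >= 3 points to summarize"
        )
    steps = step_displacements(track)
    path_length = float(steps.sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    duration = float(track.times[-1] - track.times[0])
    median_step = float(np.median(steps))
    if path_length == 0.0:
        return StepStats(
            track_id=track.track_id,
            median_step_size=0.0,
            median_speed=0.0,
            linearity_forward_progression=0.0,
            confinement_ratio=0.0,
            n_steps=len(steps),
            degenerate=True,
        )
    confinement = net / path_length
    mean_instant_speed = float(np.mean(steps / np.diff(track.times)))
    linearity = (net / duration) / mean_instant_speed
    return StepStats(
        track_id=track.track_id,
        median_step_size=median_step,
        median_speed=median_step / track.frame_interval,
        linearity_forward_progression=linearity,
        confinement_ratio=confinement,
        n_steps=len(steps),
    )


def stats_table(collection: TrackCollection) -> pd.DataFrame:
    """StepStats for every track as a tidy DataFrame."""
    rows = [summarize_track(t).__dict__ for t in collection]
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "median_step_size",
            "median_speed",
            "linearity_forward_progression",
            "confinement_ratio",
            "n_steps",
            "degenerate",
        ],
    )
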