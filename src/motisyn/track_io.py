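"""Read, validate, filter, and write 2D cell-track data.

Tracks are time-ordered 2D positions in micrometres sampled on a fixed frame
grid (times in minutes).  Two input formats are supported: a subset of the
TrackMate results XML (Model/AllSpots + Model/AllTracks) and a tidy CSV with
columns ``track_id, frame, t_min, x_um, y_um``.
"""
from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ParseError, SchemaError

logger = logging.getLogger(__name__)

FLAG_EDGE = "edge_of_slice"
FLAG_GLASS = "near_glass"
FLAG_INTERPOLATED = "interpolated_frames"
FLAG_GAPPED = "gapped"
FLAG_NOISY = "noisy"

#: Allowed QC marker vocabulary for :attr:`Track.flags`.
FLAG_VOCABULARY = frozenset(
    {FLAG_EDGE, FLAG_GLASS, FLAG_INTERPOLATED, FLAG_GAPPED, FLAG_NOISY}
)

CSV_REQUIRED_COLUMNS = ("track_id", "frame", "t_min", "x_um", "y_um")
_FLAG_COLUMNS = (FLAG_EDGE, FLAG_GLASS, FLAG_INTERPOLATED, FLAG_GAPPED, FLAG_NOISY)

_FRAME_TOL = 1e-6


@dataclass(frozen=True)
class Track:
    """One cell's time-ordered 2D trajectory.

    Parameters
    ----------
    track_id : str
        Unique identifier within a collection.
    times : ndarray
        Strictly increasing sample times in minutes; spacing must be an
        integer multiple of ``frame_interval`` (gaps are allowed until
        filtering interpolates or splits them).
    positions : ndarray, shape (n, 2)
        x/y positions in micrometres.
    frame_interval : float
        Acquisition frame interval in minutes.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float
    condition: str = ""
    flags: frozenset = frozenset()
    source: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "flags", frozenset(self.flags))
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise FormatError(
                f"track {self.track_id!r}: positions must be 2D (n, 2); "
                f"got shape {positions.shape} (3D input is not supported)"
            )
        if len(times) != len(positions):
            raise FormatError(
                f"track {self.track_id!r}: {len(times)} times vs "
                f"{len(positions)} positions"
            )
        if len(times) < 2:
            raise FormatError(f"track {self.track_id!r}: needs >= 2 points")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise FormatError(f"track {self.track_id!r}: non-finite times/positions")
        if self.frame_interval <= 0:
            raise FormatError(f"track {self.track_id!r}: frame_interval must be > 0")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise FormatError(f"track {self.track_id!r}: times not strictly increasing")
        mult = dts / self.frame_interval
        if np.any(np.abs(mult - np.round(mult)) > _FRAME_TOL) or np.any(
            np.round(mult) < 1
        ):
            raise FormatError(
                f"track {self.track_id!r}: time spacing is not an integer "
                f"multiple of frame_interval={self.frame_interval}"
            )
        extra = self.flags - FLAG_VOCABULARY
        if extra:
            raise FormatError(
                f"track {self.track_id!r}: unknown flags {sorted(extra)}"
            )

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def frames(self) -> np.ndarray:
        """Integer frame indices relative to the first sample."""
        return np.round((self.times - self.times[0]) / self.frame_interval).astype(int)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))

    @property
    def is_uniform(self) -> bool:
        return not self.has_gaps

    def with_flags(self, *new_flags: str) -> "Track":
        return replace(self, flags=self.flags | frozenset(new_flags))


@dataclass
class TrackCollection:
    """A set of tracks plus acquisition metadata."""

    tracks: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate track ids: {dupes}")
        if self.tracks and not self.metadata.get("mixed_acquisition", False):
            intervals = {t.frame_interval for t in self.tracks}
            if len(intervals) > 1:
                raise FormatError(
                    "tracks have mixed frame intervals "
                    f"{sorted(intervals)}; set metadata['mixed_acquisition']=True "
                    "if intentional"
                )

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, idx) -> Track:
        return self.tracks[idx]

    @property
    def frame_interval(self) -> float:
        if not self.tracks:
            return float(self.metadata.get("frame_interval", np.nan))
        return self.tracks[0].frame_interval


@dataclass(frozen=True)
class TrackFilterConfig:
    """Thresholds for track-level quality filtering.

    Defaults: minimum 20 frames, maximum plausible speed 25 µm/min, gaps of
    up to 2 frames interpolated (longer gaps split the track), and exclusion
    of tracks flagged at the slice edge or near the glass bottom.
    """

    min_frames: int = 20
    max_speed: float = 25.0
    max_gap_frames: int = 2
    exclude_flags: frozenset = frozenset({FLAG_EDGE, FLAG_GLASS})

    def __post_init__(self):
        if self.min_frames <= 0:
            raise FormatError("min_frames must be positive")
        if self.max_speed <= 0:
            raise FormatError("max_speed must be positive")
        if self.max_gap_frames < 0:
            raise FormatError("max_gap_frames must be >= 0")
        object.__setattr__(self, "exclude_flags", frozenset(self.exclude_flags))


@dataclass
class FilterResult:
    """Filtered collection plus per-rule removal counts."""

    collection: TrackCollection
    report: dict


# ---------------------------------------------------------------------------
# TrackMate XML
# ---------------------------------------------------------------------------

def read_trackmate_xml(
    path, frame_interval: float | None = None, condition: str = ""
) -> TrackCollection:
    """Read a TrackMate results XML (v7 schema subset) into a collection.

    Spots are taken from ``Model/AllSpots`` (attributes ``ID``, ``FRAME``,
    ``POSITION_X``, ``POSITION_Y`` in µm, optionally ``POSITION_T``); track
    membership from the edges under ``Model/AllTracks``.  Times are derived
    as frame index x frame interval; gaps are preserved, not interpolated.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"unreadable TrackMate XML {path}: {exc}") from exc

    model = root.find("Model")
    if model is None:
        raise FormatError(f"{path}: no <Model> element")

    spots: dict[str, tuple[int, float, float, float]] = {}
    all_spots = model.find("AllSpots")
    if all_spots is not None:
        for sif in all_spots.iter("SpotsInFrame"):
            for spot in sif.iter("Spot"):
                sid = spot.get("ID")
                if sid is None:
                    raise ParseError(f"{path}: spot without ID attribute")
                try:
                    frame = int(float(spot.attrib["FRAME"]))
                    x = float(spot.attrib["POSITION_X"])
                    y = float(spot.attrib["POSITION_Y"])
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: spot {sid} lacks attribute {exc.args[0]}"
                    ) from exc
                t = float(spot.get("POSITION_T", "nan"))
                spots[sid] = (frame, x, y, t)

    if frame_interval is None:
        frame_interval = _infer_interval_from_spots(spots)

    tracks: list[Track] = []
    seen_ids: set[str] = set()
    all_tracks = model.find("AllTracks")
    if all_tracks is not None:
        for trk in all_tracks.iter("Track"):
            tid = trk.get("TRACK_ID") or trk.get("name")
            if tid is None:
                raise FormatError(f"{path}: track without TRACK_ID")
            if tid in seen_ids:
                raise FormatError(f"{path}: duplicated track id {tid!r}")
            seen_ids.add(tid)
            spot_ids: set[str] = set()
            for edge in trk.iter("Edge"):
                for key in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                    sid = edge.get(key)
                    if sid is not None:
                        spot_ids.add(sid)
            records = []
            for sid in spot_ids:
                if sid not in spots:
                    raise FormatError(f"{path}: track {tid} references unknown spot {sid}")
                frame, x, y, _ = spots[sid]
                records.append((frame, x, y))
            records.sort()
            frames = [r[0] for r in records]
            if len(frames) != len(set(frames)):
                raise FormatError(f"{path}: track {tid} has non-monotone/duplicate frames")
            if len(records) < 2:
                raise FormatError(f"{path}: track {tid} has fewer than 2 spots")
            arr = np.array(records, dtype=float)
            tracks.append(
                Track(
                    track_id=str(tid),
                    times=arr[:, 0] * frame_interval,
                    positions=arr[:, 1:3],
                    frame_interval=frame_interval,
                    condition=condition,
                    source=str(path),
                )
            )

    if not tracks:
        logger.warning("no tracks found in %s", path)
    return TrackCollection(
        tracks=tracks,
        metadata={"frame_interval": frame_interval, "source": str(path)},
    )


def _infer_interval_from_spots(spots) -> float:
    """Median POSITION_T increment per frame, falling back to 1.0."""
    by_frame: dict[int, float] = {}
    for frame, _, _, t in spots.values():
        if np.isfinite(t):
            by_frame.setdefault(frame, t)
    if len(by_frame) >= 2:
        frames = np.array(sorted(by_frame))
        ts = np.array([by_frame[f] for f in frames])
        dt = np.median(np.diff(ts) / np.diff(frames))
        if dt > 0:
            return float(dt)
    logger.warning("could not infer frame interval; defaulting to 1.0 min")
    return 1.0


# ---------------------------------------------------------------------------
# Tidy CSV
# ---------------------------------------------------------------------------

def read_tracks_csv(path, frame_interval: float | None = None) -> TrackCollection:
    """Read a tidy track CSV (track_id, frame, t_min, x_um, y_um[, ...])."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, OSError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc

    missing = [c for c in CSV_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        dupes = df[df.duplicated(subset=["track_id", "frame"], keep=False)]
        pairs = sorted(set(zip(dupes["track_id"], dupes["frame"])))[:5]
        raise FormatError(f"{path}: duplicate (track_id, frame) rows, e.g. {pairs}")

    if frame_interval is None:
        frame_interval = _infer_interval_from_table(df)

    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        flags = set()
        for col in _FLAG_COLUMNS:
            if col in grp.columns and grp[col].astype(bool).any():
                flags.add(col)
        condition = ""
        if "condition" in grp.columns and len(grp):
            condition = str(grp["condition"].iloc[0])
        tracks.append(
            Track(
                track_id=str(tid),
                times=grp["t_min"].to_numpy(dtype=float),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                frame_interval=frame_interval,
                condition=condition,
                flags=frozenset(flags),
                source=str(path),
            )
        )
    if not tracks:
        logger.warning("no tracks found in %s", path)
    return TrackCollection(
        tracks=tracks,
        metadata={"frame_interval": frame_interval, "source": str(path)},
    )


def _infer_interval_from_table(df: pd.DataFrame) -> float:
    deltas = []
    for _, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        dfr = np.diff(grp["frame"].to_numpy(dtype=float))
        dt = np.diff(grp["t_min"].to_numpy(dtype=float))
        ok = dfr > 0
        if ok.any():
            deltas.extend(dt[ok] / dfr[ok])
    if not deltas:
        logger.warning("could not infer frame interval; defaulting to 1.0 min")
        return 1.0
    return float(np.median(deltas))


def write_tracks_csv(collection: TrackCollection, path) -> None:
    """Write a collection in the tidy CSV layout; round-trips exactly."""
    path = Path(path)
    rows = []
    for track in collection:
        frames = np.round(track.times / track.frame_interval).astype(int)
        for i in range(track.n_points):
            row = {
                "track_id": track.track_id,
                "frame": frames[i],
                "t_min": track.times[i],
                "x_um": track.positions[i, 0],
                "y_um": track.positions[i, 1],
                "condition": track.condition,
            }
            for col in _FLAG_COLUMNS:
                row[col] = int(col in track.flags)
            rows.append(row)
    columns = list(CSV_REQUIRED_COLUMNS) + ["condition"] + list(_FLAG_COLUMNS)
    df = pd.DataFrame(rows, columns=columns)
    # repr() is shortest-round-trip exact; pandas' own float writer is not
    for col in ("t_min", "x_um", "y_um"):
        df[col] = df[col].map(repr)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_track_filters(
    collection: TrackCollection, config: TrackFilterConfig | None = None
) -> FilterResult:
    """Apply QC filtering: flag exclusion, gap handling, speed and length cuts.

    Rules, in order per track:

    1. tracks carrying any flag in ``config.exclude_flags`` are removed;
    2. gaps longer than ``max_gap_frames`` split the track into segments;
    3. remaining gaps (<= max_gap_frames) are linearly interpolated and the
       track flagged ``interpolated_frames``;
    4. tracks with any single-frame step implying speed > ``max_speed``
       (µm/min) are removed;
    5. tracks shorter than ``min_frames`` points are removed.

    Returns the surviving tracks plus a report of per-rule removal counts.
    Positions are never altered except at interpolated frames.
    """
    if config is None:
        config = TrackFilterConfig()
    report = {
        "n_input": len(collection),
        "excluded_flag": 0,
        "split_gaps": 0,
        "max_speed": 0,
        "min_frames": 0,
        "n_output": 0,
    }
    kept: list[Track] = []
    for track in collection:
        if track.flags & config.exclude_flags:
            report["excluded_flag"] += 1
            continue
        segments = _split_at_large_gaps(track, config.max_gap_frames)
        if len(segments) > 1:
            report["split_gaps"] += 1
        for seg in segments:
            seg = _interpolate_gaps(seg)
            steps = np.linalg.norm(np.diff(seg.positions, axis=0), axis=1)
            if np.any(steps / seg.frame_interval > config.max_speed):
                report["max_speed"] += 1
                continue
            if seg.n_points < config.min_frames:
                report["min_frames"] += 1
                continue
            kept.append(seg)
    report["n_output"] = len(kept)
    if not kept:
        logger.warning("all tracks removed by filtering: %s", report)
    filtered = TrackCollection(tracks=kept, metadata=dict(collection.metadata))
    return FilterResult(collection=filtered, report=report)


def _split_at_large_gaps(track: Track, max_gap: int) -> list:
    frames = track.frames
    gap_sizes = np.diff(frames) - 1
    cut_points = np.nonzero(gap_sizes > max_gap)[0]
    if len(cut_points) == 0:
        return [track]
    segments = []
    start = 0
    boundaries = list(cut_points + 1) + [track.n_points]
    for seg_idx, end in enumerate(boundaries):
        if end - start >= 2:
            segments.append(
                replace(
                    track,
                    track_id=f"{track.track_id}/s{seg_idx}"
                    if len(boundaries) > 1
                    else track.track_id,
                    times=track.times[start:end],
                    positions=track.positions[start:end],
                )
            )
        start = end
    return segments


def _interpolate_gaps(track: Track) -> Track:
    if not track.has_gaps:
        return track
    frames = track.frames
    full = np.arange(frames[0], frames[-1] + 1)
    x = np.interp(full, frames, track.positions[:, 0])
    y = np.interp(full, frames, track.positions[:, 1])
    times = track.times[0] + (full - frames[0]) * track.frame_interval
    return replace(
        track,
        times=times,
        positions=np.column_stack([x, y]),
        flags=track.flags | {FLAG_INTERPOLATED},
    )


def validate_collection(collection: TrackCollection) -> dict:
    """Summarize a collection; Track/TrackCollection invariants were already
    enforced at construction, so this reports shape info for the CLI."""
    lengths = [t.n_points for t in collection]
    return {
        "n_tracks": len(collection),
        "frame_interval": collection.frame_interval if len(collection) else None,
        "min_length": int(min(lengths)) if lengths else 0,
        "max_length": int(max(lengths)) if lengths else 0,
        "n_with_gaps": sum(t.has_gaps for t in collection),
        "conditions": sorted({t.condition for t in collection}),
    }
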