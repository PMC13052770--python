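"""Shared fixtures: in-memory tracks and generated fixture files."""
from __future__ import annotations

import numpy as np
import pytest

from motisyn.track_io import Track, TrackCollection


def make_track(positions, frame_interval=1.0, track_id="t0", condition="", flags=(),
               times=None):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions)) * frame_interval
    return Track(
        track_id=track_id,
        times=np.asarray(times, dtype=float),
        positions=positions,
        frame_interval=frame_interval,
        condition=condition,
        flags=frozenset(flags),
    )


def make_trackmate_xml(path, tracks, frame_interval=2.0):
    """Write a minimal TrackMate results XML.

    ``tracks``: dict track_id -> list of (frame, x, y).
    """
    spot_id = 0
    spots_by_frame: dict[int, list] = {}
    track_edges: dict[str, list] = {}
    for tid, points in tracks.items():
        ids = []
        for frame, x, y in points:
            spot_id += 1
            spots_by_frame.setdefault(frame, []).append(
                (spot_id, frame, x, y, frame * frame_interval)
            )
            ids.append(spot_id)
        track_edges[tid] = [(a, b) for a, b in zip(ids, ids[1:])]

    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append('<TrackMate version="7.11.1">')
    lines.append('  <Model spatialunits="micron" timeunits="min">')
    lines.append("    <AllSpots>")
    for frame in sorted(spots_by_frame):
        lines.append(f'      <SpotsInFrame frame="{frame}">')
        for sid, fr, x, y, t in spots_by_frame[frame]:
            lines.append(
                f'        <Spot ID="{sid}" FRAME="{fr}" POSITION_X="{x}" '
                f'POSITION_Y="{y}" POSITION_T="{t}" />'
            )
        lines.append("      </SpotsInFrame>")
    lines.append("    </AllSpots>")
    lines.append("    <AllTracks>")
    for tid, edges in track_edges.items():
        lines.append(f'      <Track TRACK_ID="{tid}" NUMBER_SPOTS="{len(edges) + 1}">')
        for a, b in edges:
            lines.append(f'        <Edge SPOT_SOURCE_ID="{a}" SPOT_TARGET_ID="{b}" />')
        lines.append("      </Track>")
    lines.append("    </AllTracks>")
    lines.append("    <FilteredTracks>")
    for tid in track_edges:
        lines.append(f'      <TrackID TRACK_ID="{tid}" />')
    lines.append("    </FilteredTracks>")
    lines.append("  </Model>")
    lines.append("</TrackMate>")
    path.write_text("\n".join(lines))
    return path


@pytest.fixture
def straight_track():
    return make_track([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_collection(rng):
    tracks = []
    for i in range(5):
        n = int(rng.integers(10, 30))
        pos = np.cumsum(rng.normal(0, 1.0, size=(n, 2)), axis=0)
        tracks.append(make_track(pos, frame_interval=2.0, track_id=f"r{i}"))
    return TrackCollection(tracks=tracks, metadata={"frame_interval": 2.0})
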