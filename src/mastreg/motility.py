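"""Track linking and velocity quantification in µm/min.

Per-frame detections are linked into tracks by greedy globally-nearest-
neighbor matching: for each frame transition, all (open track, new
detection) pairs within a gating radius are considered in ascending
distance order (ties broken deterministically by track id then detection
label); unmatched detections open new tracks; tracks unmatched for more
than ``max_gap`` consecutive frames are closed.

Velocity is the mean frame-to-frame speed: total path length over total
linked time, so a cell wobbling in place still registers its true
instantaneous motility (net displacement over total time would report
near zero for a Treg circling a mast cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .detect import Detection

__all__ = ["Track", "TrackStats", "link_tracks", "track_velocity"]


@dataclass
class Track:
    """An identity followed through time: ordered (frame, y_um, x_um) points."""

    id: int
    channel_role: str
    points: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [p[0] for p in self.points]
        if frames and any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def end_frame(self) -> int:
        return self.points[-1][0]


@dataclass(frozen=True)
class TrackStats:
    track_id: int
    mean_speed_um_min: float
    path_length_um: float
    n_steps: int
    duration_min: float


def link_tracks(
    detections: list[Detection],
    max_disp_um: float,
    max_gap: int = 1,
) -> list[Track]:
    """Link detections across frames into tracks.

    ``max_disp_um`` is the gating radius per frame transition (a track
    absent for g frames may still be matched within the same radius until
    the gap exceeds ``max_gap``).  Deterministic: input order is
    irrelevant because candidates are sorted canonically.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    if not by_frame:
        return []

    tracks: list[Track] = []
    # open track state: track index -> (last frame, y, x)
    open_tracks: dict[int, tuple[int, float, float]] = {}

    for frame in range(min(by_frame), max(by_frame) + 1):
        dets = sorted(by_frame.get(frame, []), key=lambda d: d.label)
        # close tracks that have been silent too long
        for ti in [ti for ti, (lf, _, _) in open_tracks.items() if frame - lf > max_gap + 1]:
            del open_tracks[ti]

        candidates = []
        for ti, (lf, ty, tx) in open_tracks.items():
            for di, det in enumerate(dets):
                dist = math.hypot(det.y_um - ty, det.x_um - tx)
                if dist <= max_disp_um:
                    candidates.append((dist, ti, det.label, di))
        candidates.sort()

        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, _lab, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            det = dets[di]
            tracks[ti].points.append((frame, det.y_um, det.x_um))
            open_tracks[ti] = (frame, det.y_um, det.x_um)
            used_tracks.add(ti)
            used_dets.add(di)

        for di, det in enumerate(dets):
            if di in used_dets:
                continue
            ti = len(tracks)
            tracks.append(
                Track(id=ti, channel_role=det.channel_role,
                      points=[(frame, det.y_um, det.x_um)])
            )
            open_tracks[ti] = (frame, det.y_um, det.x_um)
    return tracks


def track_velocity(track: Track, frame_interval_min: float) -> TrackStats | None:
    """Mean frame-to-frame speed of a track.

    A step spanning a gap of g frames contributes g × frame_interval_min
    of elapsed time.  A single-point track has no defined speed and is
    reported as ``None`` (missing), never as zero.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if track.n_points < 2:
        return None
    path = 0.0
    elapsed_frames = 0
    for (f0, y0, x0), (f1, y1, x1) in zip(track.points, track.points[1:]):
        path += math.hypot(y1 - y0, x1 - x0)
        elapsed_frames += f1 - f0
    duration = elapsed_frames * frame_interval_min
    return TrackStats(
        track_id=track.id,
        mean_speed_um_min=path / duration,
        path_length_um=path,
        n_steps=track.n_points - 1,
        duration_min=duration,
    )
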