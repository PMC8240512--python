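"""Centroid tracking of plots across pan-video frames.

Each detected plot box is reduced to its centre point. Between consecutive
frames, active tracks and fresh detections are matched greedily on the
pairwise Euclidean distance matrix: the globally smallest distance is taken,
its row and column removed, and so on, subject to a maximum-distance gate.
Unmatched detections open new tracks with fresh IDs; an unmatched track keeps
its last centroid as its matching anchor and retires after ``expiry_frames``
consecutive misses (default 5). IDs are never reused, so each plot is counted
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import BoundingBox


@dataclass
class Track:
    track_id: int
    centroid_history: list[tuple[int, float, float]] = field(default_factory=list)
    box_history: list[tuple[int, BoundingBox]] = field(default_factory=list)
    missed_frames: int = 0
    state: str = "active"

    @property
    def last_centroid(self) -> tuple[float, float]:
        _, x, y = self.centroid_history[-1]
        return (x, y)

    @property
    def first_frame(self) -> int:
        return self.centroid_history[0][0]

    @property
    def last_frame(self) -> int:
        return self.centroid_history[-1][0]


class CentroidTracker:
    """Tracker state: active tracks, retired tracks, and the next fresh ID."""

    def __init__(self, expiry_frames: int = 5, max_distance: float | None = None):
        if expiry_frames < 1:
            raise ValueError("expiry_frames must be >= 1")
        self.expiry_frames = expiry_frames
        self.max_distance = np.inf if max_distance is None else float(max_distance)
        self.active_tracks: list[Track] = []
        self.retired_tracks: list[Track] = []
        self.next_id = 0
        self._last_frame: int | None = None

    @classmethod
    def for_frame_width(cls, frame_width: int, expiry_frames: int = 5):
        """Gate at half the frame width, a sane bound for plot-to-plot jumps."""
        return cls(expiry_frames=expiry_frames, max_distance=frame_width / 2.0)

    def update(self, detections: list[BoundingBox], frame_idx: int) -> list[int]:
        """Ingest one frame's detections; returns the track ID per detection.

        Greedy global-minimum matching with ties broken toward the lower
        track index, then the lower detection index (NumPy argmin order on a
        track-major matrix).
        """
        if self._last_frame is not None and frame_idx <= self._last_frame:
            raise ValueError(
                f"frame index must increase: got {frame_idx} after {self._last_frame}"
            )
        self._last_frame = frame_idx

        cents = np.array([d.center for d in detections], float).reshape(-1, 2)
        assigned = [-1] * len(detections)
        matched_tracks: set[int] = set()

        if self.active_tracks and len(detections):
            anchors = np.array([t.last_centroid for t in self.active_tracks])
            dmat = np.linalg.norm(anchors[:, None, :] - cents[None, :, :], axis=2)
            work = dmat.copy()
            while True:
                flat = work.argmin()
                ti, di = np.unravel_index(flat, work.shape)
                if not np.isfinite(work[ti, di]) or work[ti, di] > self.max_distance:
                    break
                matched_tracks.add(ti)
                assigned[di] = self.active_tracks[ti].track_id
                t = self.active_tracks[ti]
                t.centroid_history.append((frame_idx, *detections[di].center))
                t.box_history.append((frame_idx, detections[di]))
                t.missed_frames = 0
                work[ti, :] = np.inf
                work[:, di] = np.inf
                if not np.isfinite(work).any():
                    break

        for di, d in enumerate(detections):
            if assigned[di] < 0:
                t = Track(self.next_id)
                t.centroid_history.append((frame_idx, *d.center))
                t.box_history.append((frame_idx, d))
                self.next_id += 1
                self.active_tracks.append(t)
                assigned[di] = t.track_id

        survivors = []
        for ti, t in enumerate(self.active_tracks):
            if t.centroid_history[-1][0] == frame_idx:
                survivors.append(t)
                continue
            t.missed_frames += 1
            if t.missed_frames >= self.expiry_frames:
                t.state = "retired"
                self.retired_tracks.append(t)
            else:
                survivors.append(t)
        self.active_tracks = survivors
        return assigned

    @property
    def all_tracks(self) -> list[Track]:
        return sorted(self.retired_tracks + self.active_tracks, key=lambda t: t.track_id)


def extract_plot_windows(tracks: list[Track] | CentroidTracker,
                         min_length: int = 1) -> dict[int, tuple[int, int]]:
    """Per track, the (first_frame, last_frame) window it was observed in.

    Tracks observed in fewer than ``min_length`` frames are dropped — these
    are typically spurious detections, not plots.
    """
    if isinstance(tracks, CentroidTracker):
        tracks = tracks.all_tracks
    out = {}
    for t in tracks:
        if len(t.centroid_history) >= min_length:
            out[t.track_id] = (t.first_frame, t.last_frame)
    return out


def run_tracker(frame_detections: list[list[BoundingBox]],
                expiry_frames: int = 5,
                max_distance: float | None = None) -> CentroidTracker:
    """Feed an ordered list of per-frame detection lists through a tracker."""
    tr = CentroidTracker(expiry_frames=expiry_frames, max_distance=max_distance)
    for f, dets in enumerate(frame_detections):
        tr.update(dets, f)
    return tr
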