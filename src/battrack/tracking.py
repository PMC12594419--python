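"""Track linking: detections -> per-object tracks -> motion/size features.

Detections are linked frame by frame under spatio-temporal gates: each open
track predicts its next position (constant velocity once two detections
exist), candidate track/detection pairs within ``max_link_distance_px`` are
matched by minimum-total-distance bipartite assignment, unmatched detections
open new tracks, and tracks unseen for more than ``max_gap_frames`` close.
Noise pruning then removes short or near-stationary tracks. Track features
summarize pixel-space kinematics (speed/acceleration statistics, descent
fraction, straightness) and mean detection size — the inputs to the
object-class and fatality classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import Detection

__all__ = [
    "GatingConfig",
    "Track",
    "TrackFeatures",
    "link_detections",
    "prune_noise",
    "compute_track_features",
    "tracks_to_frame",
    "FEATURE_NAMES",
]

_GATE_PENALTY = 1e9


@dataclass(frozen=True)
class GatingConfig:
    max_link_distance_px: float = 20.0
    max_gap_frames: int = 3
    min_track_detections: int = 5
    noise_prune_distance_px: float = 5.0

    def __post_init__(self) -> None:
        if (
            self.max_link_distance_px <= 0
            or self.max_gap_frames <= 0
            or self.min_track_detections <= 0
            or self.noise_prune_distance_px <= 0
        ):
            raise ValueError("gating parameters must be positive")


@dataclass
class Track:
    track_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def t_start(self) -> float:
        return self.detections[0].timestamp_s

    @property
    def t_end(self) -> float:
        return self.detections[-1].timestamp_s

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.centroid_px for d in self.detections])

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([d.timestamp_s for d in self.detections])

    @property
    def path_length_px(self) -> float:
        pos = self.positions
        if len(pos) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())

    def last_position(self) -> np.ndarray:
        return np.asarray(self.detections[-1].centroid_px, dtype=float)

    def predict(self, frame_index: int) -> np.ndarray:
        """Constant-velocity position prediction for a future frame.

        Falls back to the last observed position until two detections exist.
        """
        if len(self.detections) < 2:
            return self.last_position()
        a, b = self.detections[-2], self.detections[-1]
        df = b.frame_index - a.frame_index
        vel = (np.asarray(b.centroid_px) - np.asarray(a.centroid_px)) / max(df, 1)
        return self.last_position() + vel * (frame_index - b.frame_index)


def link_detections(
    detections: list[Detection],
    gating: GatingConfig | None = None,
) -> list[Track]:
    """Link detections into tracks by gated per-frame optimal assignment.

    Returns every track, including sub-threshold fragments — pruning is a
    separate step so that detection counts always reconcile exactly.
    Deterministic: assignment ties break toward lower track_id then lower
    detection_id (guaranteed by sorted candidate ordering and an
    infinitesimal index bias in the cost).
    """
    if gating is None:
        gating = GatingConfig()
    dets = sorted(detections, key=lambda d: (d.frame_index, d.detection_id))
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_track_id = 0
    frames: dict[int, list[Detection]] = {}
    for d in dets:
        frames.setdefault(d.frame_index, []).append(d)
    for frame_index in sorted(frames):
        frame_dets = frames[frame_index]
        # retire stale tracks
        still_open = []
        for tr in open_tracks:
            if frame_index - tr.detections[-1].frame_index > gating.max_gap_frames:
                tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        open_tracks.sort(key=lambda tr: tr.track_id)
        if open_tracks and frame_dets:
            preds = np.array([tr.predict(frame_index) for tr in open_tracks])
            obs = np.array([d.centroid_px for d in frame_dets])
            cost = np.linalg.norm(preds[:, None, :] - obs[None, :, :], axis=2)
            gated = cost > gating.max_link_distance_px
            cost = np.where(gated, _GATE_PENALTY, cost)
            # tiny index bias for deterministic tie-breaking
            ii, jj = np.indices(cost.shape)
            cost = cost + 1e-9 * (ii * cost.shape[1] + jj)
            rows, cols = linear_sum_assignment(cost)
            matched_dets = set()
            for r, c in zip(rows, cols):
                if gated[r, c]:
                    continue
                open_tracks[r].detections.append(frame_dets[c])
                matched_dets.add(c)
            unmatched = [d for j, d in enumerate(frame_dets) if j not in matched_dets]
        else:
            unmatched = list(frame_dets)
        for d in unmatched:
            open_tracks.append(Track(next_track_id, [d]))
            next_track_id += 1
    tracks.extend(open_tracks)
    tracks.sort(key=lambda tr: tr.track_id)
    # renumber for stable, gap-free ids
    for i, tr in enumerate(tracks):
        tr.track_id = i
    return tracks


def prune_noise(
    tracks: list[Track],
    gating: GatingConfig | None = None,
) -> tuple[list[Track], list[Track]]:
    """Split tracks into (kept, pruned-as-noise).

    A track is noise when it has fewer than ``min_track_detections``
    detections or its total path length is below
    ``noise_prune_distance_px`` — disconnected or flickering clutter.
    """
    if gating is None:
        gating = GatingConfig()
    kept, pruned = [], []
    for tr in tracks:
        if (
            len(tr.detections) < gating.min_track_detections
            or tr.path_length_px < gating.noise_prune_distance_px
        ):
            pruned.append(tr)
        else:
            kept.append(tr)
    return kept, pruned


FEATURE_NAMES = [
    "mean_speed", "max_speed", "sd_speed",
    "mean_accel", "max_accel", "sd_accel",
    "mean_area", "mean_aspect_ratio",
    "net_vertical_px", "straightness", "descent_fraction",
    "duration_s",
]


@dataclass(frozen=True)
class TrackFeatures:
    """Kinematic and size summary of one track (pixel units)."""

    mean_speed: float
    max_speed: float
    sd_speed: float
    mean_accel: float
    max_accel: float
    sd_accel: float
    mean_area: float
    mean_aspect_ratio: float      # width/length per detection, averaged (<= 1)
    net_vertical_px: float        # image-down positive
    straightness: float           # net / total displacement, in [0, 1]
    descent_fraction: float       # fraction of steps moving image-down
    duration_s: float
    accel_defined: bool = True

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def compute_track_features(track: Track) -> TrackFeatures:
    """Finite-difference features over actual inter-detection intervals.

    Speeds use real timestamp gaps so frame drops do not inflate velocity.
    Tracks need >= 2 detections; with < 3 the acceleration statistics are
    zero-filled and flagged via ``accel_defined``. A stationary track has
    straightness 0 by convention.
    """
    if len(track.detections) < 2:
        raise ValueError("track features need at least 2 detections")
    pos = track.positions
    t = track.timestamps
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("track timestamps must be strictly increasing")
    steps = np.diff(pos, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    speeds = step_len / dt
    vel = steps / dt[:, None]
    if len(vel) >= 2:
        t_mid = (t[:-1] + t[1:]) / 2
        accel = np.linalg.norm(np.diff(vel, axis=0) / np.diff(t_mid)[:, None], axis=1)
        accel_defined = True
    else:
        accel = np.zeros(1)
        accel_defined = False
    total = float(step_len.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    straightness = net / total if total > 0 else 0.0
    descent = float(np.mean(steps[:, 1] > 0)) if len(steps) else 0.0
    areas = [d.area_px for d in track.detections]
    aspects = [
        (d.width_px / d.length_px if d.length_px > 0 else 1.0)
        for d in track.detections
    ]
    return TrackFeatures(
        mean_speed=float(speeds.mean()),
        max_speed=float(speeds.max()),
        sd_speed=float(speeds.std()),
        mean_accel=float(accel.mean()),
        max_accel=float(accel.max()),
        sd_accel=float(accel.std()),
        mean_area=float(np.mean(areas)),
        mean_aspect_ratio=float(np.mean(aspects)),
        net_vertical_px=float(pos[-1, 1] - pos[0, 1]),
        straightness=min(1.0, straightness),
        descent_fraction=descent,
        duration_s=float(t[-1] - t[0]),
        accel_defined=accel_defined,
    )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Track database rows: id, span, detection ids, features."""
    rows = []
    for tr in tracks:
        feat = compute_track_features(tr) if len(tr.detections) >= 2 else None
        row = {
            "track_id": tr.track_id,
            "n_detections": len(tr.detections),
            "t_start": tr.t_start,
            "t_end": tr.t_end,
            "detection_ids": ";".join(str(d.detection_id) for d in tr.detections),
            "last_x": tr.detections[-1].centroid_px[0],
            "last_y": tr.detections[-1].centroid_px[1],
        }
        for name in FEATURE_NAMES:
            row[name] = getattr(feat, name) if feat is not None else np.nan
        rows.append(row)
    cols = [
        "track_id", "n_detections", "t_start", "t_end", "detection_ids",
        "last_x", "last_y", *FEATURE_NAMES,
    ]
    return pd.DataFrame(rows, columns=cols)
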