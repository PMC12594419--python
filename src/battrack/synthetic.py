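"""Synthetic thermal scenes: falling carcasses, flying bats, insects, rendering.

Real validation of a fatality-detection camera is handicapped by the lack of
ground truth — nobody knows exactly when and where a bat fell. This module
supplies that ground truth synthetically: physically simulated fall
trajectories (quadratic aerodynamic drag), correlated-random-walk flight for
bats and insects, and a renderer that turns trajectories into noisy thermal
frame stacks through the camera model. Every generated object carries its
class label, so the detector, tracker and classifiers can be scored against
known truth.

Fall physics
------------
A carcass of mass m falling through air obeys

    m dv/dt = m g_vec - c |v - w| (v - w)

with lumped quadratic-drag constant c (kg/m) and horizontal wind w. The
terminal speed is v_t = sqrt(m g / c); for a vertical drop from rest the
speed follows the closed form v(t) = v_t tanh(g t / v_t), which the test
suite uses as an independent oracle. Defaults are scaled to a Brazilian
free-tailed bat: m = 12 g and c set for v_t ~= 10 m/s. Tumbling/fluttering
can be emulated by per-step Gaussian perturbation of c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CameraModel, project_points

__all__ = [
    "FallModel",
    "FlightModel",
    "SceneObject",
    "SceneTruth",
    "Trajectory",
    "simulate_fall",
    "simulate_flight",
    "render_frames",
    "generate_labeled_dataset",
    "project_truth_detections",
    "DEFAULT_BAT_MASS_KG",
    "DEFAULT_TERMINAL_SPEED",
]

GRAVITY = 9.81
DEFAULT_BAT_MASS_KG = 0.012
DEFAULT_TERMINAL_SPEED = 10.0
# c = m g / v_t^2
DEFAULT_DRAG_C = DEFAULT_BAT_MASS_KG * GRAVITY / DEFAULT_TERMINAL_SPEED**2

BAT_BODY_SIZE_M = 0.30     # apparent warm extent (wings included)
INSECT_BODY_SIZE_M = 0.02
BAT_PEAK_INTENSITY = 40.0   # sensor counts above background
INSECT_PEAK_INTENSITY = 15.0

CLASS_BAT_FLIGHT = "bat_flight"
CLASS_BAT_FALL = "bat_fall"
CLASS_INSECT = "insect"


@dataclass(frozen=True)
class Trajectory:
    """Timestamped world-frame path of one object."""

    t: np.ndarray          # (n,) seconds from scene start, strictly increasing
    pos: np.ndarray        # (n, 3) meters
    vel: np.ndarray | None = None  # (n, 3) m/s when the simulator provides it

    def __post_init__(self) -> None:
        if len(self.t) != len(self.pos):
            raise ValueError("t and pos length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass(frozen=True)
class FallModel:
    """Quadratic-drag model of a falling bat carcass."""

    mass_kg: float = DEFAULT_BAT_MASS_KG
    drag_coefficient: float = DEFAULT_DRAG_C   # lumped c, kg/m
    gravity: float = GRAVITY
    release_point: tuple[float, float, float] = (0.0, 0.0, 50.0)
    release_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    wind: tuple[float, float] = (0.0, 0.0)
    drag_jitter_sd: float = 0.0   # fractional per-step perturbation of c (tumbling)

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")
        if self.drag_coefficient < 0:
            raise ValueError("drag coefficient must be non-negative")
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")

    @property
    def terminal_speed(self) -> float:
        if self.drag_coefficient == 0:
            return math.inf
        return math.sqrt(self.mass_kg * self.gravity / self.drag_coefficient)


def _fall_accel(vel: np.ndarray, c: float, m: float, g: float, wind3: np.ndarray) -> np.ndarray:
    v_rel = vel - wind3
    speed = np.linalg.norm(v_rel)
    return np.array([0.0, 0.0, -g]) - (c / m) * speed * v_rel


def simulate_fall(
    model: FallModel,
    dt: float = 1.0 / 30.0,
    max_time: float = 120.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Integrate a carcass fall with fixed-step RK4 until ground impact.

    The trajectory ends exactly on the ground plane: the first step crossing
    z <= 0 is linearly interpolated back to z = 0. ``rng`` is only consulted
    when ``drag_jitter_sd > 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if model.release_point[2] <= 0:
        raise ValueError("release point must be above the ground")
    wind3 = np.array([model.wind[0], model.wind[1], 0.0])
    pos = np.asarray(model.release_point, dtype=float)
    vel = np.asarray(model.release_velocity, dtype=float)
    m, g = model.mass_kg, model.gravity
    times = [0.0]
    positions = [pos.copy()]
    velocities = [vel.copy()]
    t = 0.0
    n_max = int(math.ceil(max_time / dt))
    for _ in range(n_max):
        c = model.drag_coefficient
        if model.drag_jitter_sd > 0:
            if rng is None:
                raise ValueError("drag_jitter_sd > 0 requires an rng")
            c = max(0.0, c * (1.0 + rng.normal(0.0, model.drag_jitter_sd)))
        # RK4 on (pos, vel)
        k1v = _fall_accel(vel, c, m, g, wind3)
        k1p = vel
        k2v = _fall_accel(vel + 0.5 * dt * k1v, c, m, g, wind3)
        k2p = vel + 0.5 * dt * k1v
        k3v = _fall_accel(vel + 0.5 * dt * k2v, c, m, g, wind3)
        k3p = vel + 0.5 * dt * k2v
        k4v = _fall_accel(vel + dt * k3v, c, m, g, wind3)
        k4p = vel + dt * k3v
        new_pos = pos + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        new_vel = vel + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += dt
        if new_pos[2] <= 0.0:
            # interpolate the crossing to z = 0
            frac = pos[2] / (pos[2] - new_pos[2])
            impact_pos = pos + frac * (new_pos - pos)
            impact_pos[2] = 0.0
            impact_vel = vel + frac * (new_vel - vel)
            times.append(t - dt + frac * dt)
            positions.append(impact_pos)
            velocities.append(impact_vel)
            break
        pos, vel = new_pos, new_vel
        times.append(t)
        positions.append(pos.copy())
        velocities.append(vel.copy())
    else:
        raise RuntimeError(f"fall did not reach the ground within {max_time} s")
    return Trajectory(np.array(times), np.vstack(positions), np.vstack(velocities))


@dataclass(frozen=True)
class FlightModel:
    """Correlated random walk for flying objects (bats or insects).

    One step is one frame. Heading evolves by Gaussian turn increments with
    standard deviation ``turn_rate_sd`` (rad/step); speed is resampled
    uniformly within ``speed_range`` each step; altitude takes Gaussian
    jitter reflected into ``altitude_band``.
    """

    speed_range: tuple[float, float] = (3.0, 8.0)
    turn_rate_sd: float = 0.15
    vertical_jitter_m: float = 0.15
    altitude_band: tuple[float, float] = (2.0, 45.0)

    def __post_init__(self) -> None:
        lo, hi = self.speed_range
        if not (0 < lo <= hi):
            raise ValueError("speed range must be positive with lo <= hi")
        if self.turn_rate_sd < 0 or self.vertical_jitter_m < 0:
            raise ValueError("jitter parameters must be non-negative")
        if not np.isfinite([lo, hi, self.turn_rate_sd, self.vertical_jitter_m]).all():
            raise ValueError("parameters must be finite")


def simulate_flight(
    model: FlightModel,
    duration_s: float,
    seed: int | np.random.Generator,
    dt: float = 1.0 / 30.0,
    start: Sequence[float] = (0.0, 0.0, 15.0),
    initial_heading: float | None = None,
) -> Trajectory:
    """Simulate a correlated-random-walk flight; reproducible under a seed."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s / dt))
    lo, hi = model.speed_range
    z_lo, z_hi = model.altitude_band
    pos = np.empty((n + 1, 3))
    pos[0] = np.asarray(start, dtype=float)
    heading = rng.uniform(0, 2 * math.pi) if initial_heading is None else float(initial_heading)
    z = float(pos[0, 2])
    for i in range(n):
        heading += rng.normal(0.0, model.turn_rate_sd)
        speed = lo if lo == hi else rng.uniform(lo, hi)
        z += rng.normal(0.0, model.vertical_jitter_m) if model.vertical_jitter_m > 0 else 0.0
        if z_hi > z_lo:  # reflect into the altitude band
            z = z_lo + abs((z - z_lo) % (2 * (z_hi - z_lo)))
            if z > z_hi:
                z = 2 * z_hi - z
        pos[i + 1, 0] = pos[i, 0] + speed * dt * math.cos(heading)
        pos[i + 1, 1] = pos[i, 1] + speed * dt * math.sin(heading)
        pos[i + 1, 2] = z
    t = np.arange(n + 1) * dt
    return Trajectory(t, pos)


# ---------------------------------------------------------------------------
# Scene truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneObject:
    object_id: int
    class_label: str                 # bat_flight | bat_fall | insect
    trajectory: Trajectory
    t_offset_s: float = 0.0          # when the object appears in the scene
    body_size_m: float = BAT_BODY_SIZE_M
    peak_intensity: float = BAT_PEAK_INTENSITY


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered scene: objects plus scene timing."""

    objects: tuple[SceneObject, ...]
    duration_s: float
    t0: datetime = datetime(2022, 8, 15, 21, 0, 0)

    def label_table(self) -> pd.DataFrame:
        rows = [
            {
                "object_id": o.object_id,
                "class": o.class_label,
                "t_start": o.t_offset_s,
                "t_end": o.t_offset_s + float(o.trajectory.t[-1]),
            }
            for o in self.objects
        ]
        return pd.DataFrame(rows, columns=["object_id", "class", "t_start", "t_end"])


def _object_position_at(obj: SceneObject, t_scene: float) -> np.ndarray | None:
    """World position at scene time, or None outside the object's lifespan."""
    tl = t_scene - obj.t_offset_s
    traj = obj.trajectory
    if tl < traj.t[0] or tl > traj.t[-1]:
        return None
    return np.array(
        [np.interp(tl, traj.t, traj.pos[:, k]) for k in range(3)]
    )


def apparent_sigma_px(camera: CameraModel, body_size_m: float, range_m: float,
                      floor_px: float = 0.7) -> float:
    """Gaussian blob sigma from apparent angular size (FWHM = apparent extent)."""
    fx, _ = camera.focal_px
    extent_px = fx * body_size_m / max(range_m, 1e-6)
    return max(floor_px, extent_px / 2.355)


def project_truth_detections(truth: SceneTruth, camera: CameraModel) -> pd.DataFrame:
    """Per-frame ground-truth blob table (frame, object, pixel, size, range).

    Rows exist only for frames where the object is alive, in front of the
    camera and inside the image rectangle.
    """
    n_frames = int(round(truth.duration_s * camera.fps))
    w, h = camera.resolution_px
    fps = camera.fps
    floor_sig = 0.7
    fx, _ = camera.focal_px
    parts = []
    for obj in truth.objects:
        traj = obj.trajectory
        f_lo = int(np.ceil((obj.t_offset_s + traj.t[0]) * fps))
        f_hi = int(np.floor((obj.t_offset_s + traj.t[-1]) * fps))
        f_lo, f_hi = max(0, f_lo), min(n_frames - 1, f_hi)
        if f_hi < f_lo:
            continue
        frames = np.arange(f_lo, f_hi + 1)
        ts = frames / fps
        tl = ts - obj.t_offset_s
        pos = np.column_stack([np.interp(tl, traj.t, traj.pos[:, k]) for k in range(3)])
        uv, depth = project_points(camera, pos)
        vis = (
            (depth > 0)
            & np.isfinite(uv).all(axis=1)
            & (uv[:, 0] >= 0) & (uv[:, 0] < w)
            & (uv[:, 1] >= 0) & (uv[:, 1] < h)
        )
        if not vis.any():
            continue
        rng_m = np.linalg.norm(pos - np.asarray(camera.position), axis=1)
        sig = np.maximum(floor_sig, fx * obj.body_size_m / np.maximum(rng_m, 1e-6) / 2.355)
        parts.append(
            pd.DataFrame(
                {
                    "frame_index": frames[vis],
                    "timestamp_s": ts[vis],
                    "object_id": obj.object_id,
                    "class": obj.class_label,
                    "u": uv[vis, 0],
                    "v": uv[vis, 1],
                    "range_m": rng_m[vis],
                    "sigma_px": sig[vis],
                    "peak_intensity": obj.peak_intensity,
                    "x_m": pos[vis, 0],
                    "y_m": pos[vis, 1],
                    "z_m": pos[vis, 2],
                }
            )
        )
    cols = [
        "frame_index", "timestamp_s", "object_id", "class", "u", "v",
        "range_m", "sigma_px", "peak_intensity", "x_m", "y_m", "z_m",
    ]
    if not parts:
        return pd.DataFrame(columns=cols)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["frame_index", "object_id"], kind="stable").reset_index(drop=True)[cols]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def make_background(camera: CameraModel, rng: np.random.Generator | None = None,
                    tower_column: bool = True) -> np.ndarray:
    """Static background: sky-to-ground gradient, fixed texture, warm tower.

    The tower appears as a fixed warm column (the study framed it at the
    left edge of each image as a reference); being static, it is absorbed by
    the background model and never produces detections.
    """
    w, h = camera.resolution_px
    v = np.linspace(0.0, 1.0, h)[:, None]
    bg = 100.0 + 30.0 * v * np.ones((1, w))  # ground warmer than sky
    if rng is not None:
        bg = bg + rng.normal(0.0, 1.0, size=(h, w)).cumsum(axis=1) * 0.05
    if tower_column:
        uv, depth = project_points(camera, np.array([[0.0, 0.0, 1.0]]))
        if depth[0] > 0 and np.isfinite(uv[0]).all():
            u0 = uv[0][0]
            fx, _ = camera.focal_px
            half_w = max(2.0, fx * 2.5 / depth[0])
            lo = int(max(0, math.floor(u0 - half_w)))
            hi = int(min(w, math.ceil(u0 + half_w)))
            if hi > lo:
                bg[:, lo:hi] += 25.0
    return bg.astype(np.float32)


def render_frames(
    truth: SceneTruth,
    camera: CameraModel,
    noise_sd: float = 2.0,
    seed: int | np.random.Generator = 0,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the scene into a (T, H, W) float32 frame stack plus timestamps.

    Each live object becomes a 2-D Gaussian intensity blob whose sigma scales
    inversely with range; additive Gaussian sensor noise is applied per
    frame. Objects outside the field of view are simply absent. The
    timestamp table carries frame_index and ISO timestamps at 1/fps spacing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = camera.resolution_px
    if background is None:
        background = make_background(camera)
    if background.shape != (h, w):
        raise ValueError("background shape does not match camera resolution")
    n_frames = int(round(truth.duration_s * camera.fps))
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    dets = project_truth_detections(truth, camera)
    by_frame = dict(tuple(dets.groupby("frame_index"))) if len(dets) else {}
    yy_full, xx_full = np.mgrid[0:h, 0:w]
    for frame in range(n_frames):
        img = background.copy()
        for _, row in by_frame.get(frame, pd.DataFrame()).iterrows():
            sig = row["sigma_px"]
            u, v = row["u"], row["v"]
            r = int(math.ceil(4 * sig))
            x0, x1 = max(0, int(u) - r), min(w, int(u) + r + 1)
            y0, y1 = max(0, int(v) - r), min(h, int(v) + r + 1)
            if x1 <= x0 or y1 <= y0:
                continue
            xs = xx_full[y0:y1, x0:x1]
            ys = yy_full[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += row["peak_intensity"] * np.exp(
                -((xs - u) ** 2 + (ys - v) ** 2) / (2 * sig**2)
            ).astype(np.float32)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
        frames[frame] = img
    ts = pd.DataFrame(
        {
            "frame_index": np.arange(n_frames),
            "timestamp_s": np.arange(n_frames) / camera.fps,
            "iso_timestamp": [
                (truth.t0 + timedelta(seconds=i / camera.fps)).isoformat()
                for i in range(n_frames)
            ],
        }
    )
    return frames, ts


# ---------------------------------------------------------------------------
# Labeled corpus generation
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Per-object substreams: adding objects never reshuffles earlier ones."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


DEFAULT_INSECT_MODEL = FlightModel(
    speed_range=(0.3, 2.0), turn_rate_sd=0.6, vertical_jitter_m=0.08,
    altitude_band=(1.0, 20.0),
)


def generate_labeled_dataset(
    n_fall: int,
    n_flight: int,
    n_insect: int,
    seed: int,
    camera: CameraModel | None = None,
    flight_duration_s: float = 6.0,
    release_height_range: tuple[float, float] = (30.0, 55.0),
    area_half_extent_m: tuple[float, float] = (18.0, 30.0),
    drag_jitter_sd: float = 0.15,
) -> SceneTruth:
    """Generate a labeled object corpus around the turbine airspace.

    Falls release inside the monitored airspace (below the rotor-swept area
    once they descend into view) with modest lateral velocity and tumbling
    drag jitter; flights and insects start within the field of view's rough
    ground extent. Fully reproducible from ``seed``; the label table links
    every object to its class.
    """
    for name, n in (("n_fall", n_fall), ("n_flight", n_flight), ("n_insect", n_insect)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    total = n_fall + n_flight + n_insect
    if total == 0:
        raise ValueError("at least one object count must be positive")
    if camera is None:
        camera = CameraModel()
    dt = 1.0 / camera.fps
    rngs = _spawn_rngs(seed, total)
    ex, ey = area_half_extent_m
    objects: list[SceneObject] = []
    oid = 0
    duration = 0.0
    for i in range(n_fall):
        rng = rngs[oid]
        release = (
            rng.uniform(-ex, ex),
            rng.uniform(-ey, ey),
            rng.uniform(*release_height_range),
        )
        v0 = (rng.uniform(-4, 4), rng.uniform(-4, 4), rng.uniform(-2, 0))
        model = FallModel(
            release_point=release, release_velocity=v0,
            wind=(rng.uniform(-3, 3), rng.uniform(-3, 3)),
            drag_jitter_sd=drag_jitter_sd,
        )
        traj = simulate_fall(model, dt=dt, rng=rng)
        objects.append(SceneObject(oid, CLASS_BAT_FALL, traj))
        duration = max(duration, float(traj.t[-1]))
        oid += 1
    for i in range(n_flight):
        rng = rngs[oid]
        start = (rng.uniform(-ex, ex), rng.uniform(-ey, ey), rng.uniform(3, 40))
        traj = simulate_flight(FlightModel(), flight_duration_s, rng, dt=dt, start=start)
        objects.append(SceneObject(oid, CLASS_BAT_FLIGHT, traj))
        duration = max(duration, float(traj.t[-1]))
        oid += 1
    for i in range(n_insect):
        rng = rngs[oid]
        start = (rng.uniform(-ex, ex), rng.uniform(-ey, ey), rng.uniform(1, 15))
        traj = simulate_flight(DEFAULT_INSECT_MODEL, flight_duration_s, rng, dt=dt, start=start)
        objects.append(
            SceneObject(
                oid, CLASS_INSECT, traj,
                body_size_m=INSECT_BODY_SIZE_M, peak_intensity=INSECT_PEAK_INTENSITY,
            )
        )
        duration = max(duration, float(traj.t[-1]))
        oid += 1
    return SceneTruth(tuple(objects), duration_s=duration + dt)


# ---------------------------------------------------------------------------
# Truth -> track features (the fast synthetic-track path for classifier training)
# ---------------------------------------------------------------------------

def _expected_blob_shape(sigma_px: float, peak: float, threshold: float,
                         rng: np.random.Generator) -> tuple[int, float, float]:
    """Area and principal extents a thresholding detector would report.

    A Gaussian blob of peak ``p`` exceeds an absolute threshold ``thr``
    inside radius r* with r*^2 = 2 sigma^2 ln(p/thr), so the detected area
    is ~ pi r*^2 and the extent ~ 2 r*. Small multiplicative noise emulates
    pixel discretization.
    """
    if peak <= threshold:
        return 0, 0.0, 0.0
    r2 = 2.0 * sigma_px**2 * math.log(peak / threshold)
    area = math.pi * r2
    area = max(1, int(round(area * rng.uniform(0.85, 1.15))))
    extent = 2.0 * math.sqrt(r2)
    length = max(1.0, extent * rng.uniform(0.95, 1.15))
    width = max(1.0, min(length, extent * rng.uniform(0.85, 1.05)))
    return area, width, length


def truth_to_feature_table(
    truth: SceneTruth,
    camera: CameraModel,
    seed: int,
    centroid_noise_px: float = 0.3,
    threshold_k: float = 4.0,
    noise_sd: float = 2.0,
    min_detections: int = 5,
) -> pd.DataFrame:
    """Project truth objects into per-track feature rows with class labels.

    This is the physics-generated training corpus: each object's trajectory
    is projected through the camera into an idealized detection sequence
    (centroid jitter plus threshold-consistent blob sizes), then summarized
    by the same track features the real detector/tracker pipeline produces.
    Objects visible for fewer than ``min_detections`` frames are dropped
    (they could never form a track). Columns: the feature vector plus
    ``object_id``, ``object_class`` (bat/insect) and ``fate_class``
    (activity/fatality/not_applicable).
    """
    from .detection import Detection
    from .tracking import FEATURE_NAMES, Track, compute_track_features

    rng = np.random.default_rng(seed)
    dets = project_truth_detections(truth, camera)
    threshold = threshold_k * noise_sd
    rows = []
    for oid, group in dets.groupby("object_id"):
        obj = truth.objects[int(oid)] if truth.objects[int(oid)].object_id == oid else next(
            o for o in truth.objects if o.object_id == oid
        )
        det_objs = []
        for k, (_, r) in enumerate(group.sort_values("frame_index").iterrows()):
            area, width, length = _expected_blob_shape(
                r["sigma_px"], r["peak_intensity"], threshold, rng
            )
            if area == 0:
                continue
            det_objs.append(
                Detection(
                    detection_id=k,
                    frame_index=int(r["frame_index"]),
                    timestamp_s=float(r["timestamp_s"]),
                    centroid_px=(
                        float(r["u"]) + rng.normal(0, centroid_noise_px),
                        float(r["v"]) + rng.normal(0, centroid_noise_px),
                    ),
                    area_px=area,
                    width_px=width,
                    length_px=length,
                    mean_intensity=float(r["peak_intensity"]) / 2.0,
                )
            )
        if len(det_objs) < min_detections:
            continue
        feat = compute_track_features(Track(int(oid), det_objs))
        row = {name: getattr(feat, name) for name in FEATURE_NAMES}
        row["object_id"] = int(oid)
        if obj.class_label in (CLASS_BAT_FALL, CLASS_BAT_FLIGHT):
            row["object_class"] = "bat"
            row["fate_class"] = "fatality" if obj.class_label == CLASS_BAT_FALL else "activity"
        else:
            row["object_class"] = "insect"
            row["fate_class"] = "not_applicable"
        rows.append(row)
    from .tracking import FEATURE_NAMES as _names
    return pd.DataFrame(rows, columns=[*_names, "object_id", "object_class", "fate_class"])
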