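"""Camera geometry: world frame, pinhole projection, ground footprint, occlusion.

World frame convention
----------------------
Origin at the turbine tower base; x points east, y north, z up; units are
meters; the ground is the plane z = 0. The frame is right-handed. Headings
are compass azimuths (0 deg = north, 90 deg = east), and camera tilt is
measured upward from the horizon.

The study layout this reproduces: two thermal cameras on tripods ~75 m from
the turbine on opposite sides, each looking back at the tower, tilted ~15
degrees above the horizon so the field of view spans the airspace just
above the ground and below the rotor-swept area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "CameraModel",
    "FovFootprint",
    "OperationalSchedule",
    "default_camera_pair",
    "project_world_to_pixel",
    "project_points",
    "pixel_to_ground",
    "fov_ground_footprint",
    "is_operational",
    "night_of",
    "night_interval",
]

# Standoff and tilt of the study deployment; resolution and sensor size are
# package defaults (the camera hardware's exact optics are not modeled).
DEFAULT_STANDOFF_M = 75.0
DEFAULT_TILT_DEG = 15.0
DEFAULT_FOCAL_MM = 35.0
DEFAULT_SENSOR_MM = (32.0, 24.0)
DEFAULT_RESOLUTION = (640, 480)
DEFAULT_FPS = 30.0
DEFAULT_CAMERA_HEIGHT_M = 1.5
DEFAULT_TOWER_RADIUS_M = 2.5


@dataclass(frozen=True)
class CameraModel:
    """A pinhole thermal camera placed in the world frame.

    Attributes
    ----------
    position : (3,) array-like, meters
        Optical center in the world frame (tripod head).
    tilt_deg : float
        Elevation of the optical axis above the horizon, degrees, in [0, 90).
    heading_deg : float
        Compass azimuth of the optical axis (0 = north, 90 = east).
    focal_length_mm, sensor_width_mm, sensor_height_mm : float
        Optics; pixel focal lengths derive from these and the resolution.
    resolution_px : (width, height) ints
    fps : float
        Frame rate; 30 fps means each detection spans 1/30 s.
    """

    position: tuple[float, float, float] = (0.0, -DEFAULT_STANDOFF_M, DEFAULT_CAMERA_HEIGHT_M)
    tilt_deg: float = DEFAULT_TILT_DEG
    heading_deg: float = 0.0
    focal_length_mm: float = DEFAULT_FOCAL_MM
    sensor_width_mm: float = DEFAULT_SENSOR_MM[0]
    sensor_height_mm: float = DEFAULT_SENSOR_MM[1]
    resolution_px: tuple[int, int] = DEFAULT_RESOLUTION
    fps: float = DEFAULT_FPS
    name: str = "camera"

    def __post_init__(self) -> None:
        if not (self.fps > 0):
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.resolution_px[0] < 1 or self.resolution_px[1] < 1:
            raise ValueError(f"resolution components must be >= 1, got {self.resolution_px}")
        if not (0.0 <= self.tilt_deg < 90.0):
            raise ValueError(f"tilt_deg must be in [0, 90), got {self.tilt_deg}")
        if not (self.focal_length_mm > 0):
            raise ValueError("focal length must be positive")
        if self.sensor_width_mm <= 0 or self.sensor_height_mm <= 0:
            raise ValueError("sensor dimensions must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def focal_px(self) -> tuple[float, float]:
        """Focal length in pixels along image x and y."""
        w, h = self.resolution_px
        return (
            self.focal_length_mm * w / self.sensor_width_mm,
            self.focal_length_mm * h / self.sensor_height_mm,
        )

    @property
    def principal_point(self) -> tuple[float, float]:
        return (self.resolution_px[0] / 2.0, self.resolution_px[1] / 2.0)

    @property
    def rotation(self) -> np.ndarray:
        """World-to-camera rotation; rows are camera right, down, forward axes."""
        az = math.radians(self.heading_deg)
        el = math.radians(self.tilt_deg)
        forward = np.array(
            [math.sin(az) * math.cos(el), math.cos(az) * math.cos(el), math.sin(el)]
        )
        right = np.array([math.cos(az), -math.sin(az), 0.0])
        down = np.cross(forward, right)
        return np.vstack([right, down, forward])

    @property
    def frame_interval_s(self) -> float:
        return 1.0 / self.fps


def default_camera_pair(
    standoff_m: float = DEFAULT_STANDOFF_M,
    tilt_deg: float = DEFAULT_TILT_DEG,
    height_m: float = DEFAULT_CAMERA_HEIGHT_M,
    **kwargs,
) -> tuple[CameraModel, CameraModel]:
    """The study's two-camera layout: north camera facing south and vice versa."""
    north = CameraModel(
        position=(0.0, standoff_m, height_m),
        tilt_deg=tilt_deg,
        heading_deg=180.0,
        name="north",
        **kwargs,
    )
    south = CameraModel(
        position=(0.0, -standoff_m, height_m),
        tilt_deg=tilt_deg,
        heading_deg=0.0,
        name="south",
        **kwargs,
    )
    return north, south


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_points(camera: CameraModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project (n, 3) world points to (n, 2) fractional pixels plus depths.

    Returns ``(uv, depth)``; points at or behind the image plane get NaN
    pixel coordinates and their (non-positive) depth is preserved so callers
    can distinguish behind-camera from merely outside the image rectangle.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    cam = (pts - np.asarray(camera.position)) @ camera.rotation.T
    depth = cam[:, 2]
    fx, fy = camera.focal_px
    cx, cy = camera.principal_point
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cx + fx * cam[:, 0] / depth
        v = cy + fy * cam[:, 1] / depth
    uv = np.column_stack([u, v])
    uv[depth <= 0] = np.nan
    return uv, depth


def project_world_to_pixel(camera: CameraModel, point) -> np.ndarray | None:
    """Project one world point; ``None`` marks points behind the image plane.

    Pixel origin is the top-left corner, x right, y down. The returned
    coordinate may lie outside the image rectangle; use
    :func:`in_image_bounds` to test visibility.
    """
    uv, depth = project_points(camera, np.asarray(point, dtype=float).reshape(1, 3))
    if depth[0] <= 0:
        return None
    return uv[0]


def in_image_bounds(camera: CameraModel, uv) -> bool:
    u, v = float(uv[0]), float(uv[1])
    w, h = camera.resolution_px
    return 0.0 <= u < w and 0.0 <= v < h


def pixel_to_ground(camera: CameraModel, uv) -> np.ndarray | None:
    """Back-project a pixel ray onto the ground plane z = 0.

    Returns the (3,) world point, or ``None`` when the ray does not descend
    (points at or above the horizon never meet the ground).
    """
    fx, fy = camera.focal_px
    cx, cy = camera.principal_point
    ray_cam = np.array([(uv[0] - cx) / fx, (uv[1] - cy) / fy, 1.0])
    ray_world = camera.rotation.T @ ray_cam
    if ray_world[2] >= -1e-12:
        return None
    t = -camera.position[2] / ray_world[2]
    if t <= 0:
        return None
    return np.asarray(camera.position) + t * ray_world


# ---------------------------------------------------------------------------
# Field-of-view ground footprint and tower occlusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FovFootprint:
    """Ground-plane footprint of one camera plus the tower's hidden region."""

    polygon: Polygon
    tower_occlusion_polygon: Polygon
    camera_name: str = "camera"

    @property
    def is_empty(self) -> bool:
        return self.polygon.is_empty or self.polygon.area <= 0

    def is_in_fov(self, xy) -> bool:
        return self.polygon.covers(Point(float(xy[0]), float(xy[1])))

    def is_occluded(self, xy) -> bool:
        if self.tower_occlusion_polygon.is_empty:
            return False
        return self.tower_occlusion_polygon.covers(Point(float(xy[0]), float(xy[1])))

    def sees(self, xy) -> bool:
        """In the footprint and not hidden behind the tower."""
        return self.is_in_fov(xy) and not self.is_occluded(xy)


def _boundary_pixels(camera: CameraModel, n_per_edge: int = 64) -> np.ndarray:
    w, h = camera.resolution_px
    s = np.linspace(0.0, 1.0, n_per_edge, endpoint=False)
    top = np.column_stack([s * w, np.zeros_like(s)])
    right = np.column_stack([np.full_like(s, float(w)), s * h])
    bottom = np.column_stack([(1 - s) * w, np.full_like(s, float(h))])
    left = np.column_stack([np.zeros_like(s), (1 - s) * h])
    return np.vstack([top, right, bottom, left])


def fov_ground_footprint(
    camera: CameraModel,
    near_m: float = 5.0,
    far_m: float = 100.0,
    tower_xy: tuple[float, float] = (0.0, 0.0),
    tower_radius_m: float = DEFAULT_TOWER_RADIUS_M,
) -> FovFootprint:
    """Intersect the view frustum with the ground plane, clipped to [near, far].

    Rays through the image boundary are dropped onto z = 0; rays at or above
    the horizon are extended to a sentinel range well beyond ``far_m`` before
    the range clip. The tower-occlusion polygon is the ground region hidden
    behind the tower cylinder (tangent wedge plus the tower disc itself),
    intersected with the footprint. A frustum that never meets the ground
    inside the range band yields an empty footprint (``is_empty``).
    """
    if not (0 < near_m < far_m):
        raise ValueError("require 0 < near_m < far_m")
    cam_xy = np.asarray(camera.position[:2])
    far_sentinel = 20.0 * far_m
    fx, fy = camera.focal_px
    cx, cy = camera.principal_point
    verts = []
    any_ground_hit = False
    for u, v in _boundary_pixels(camera):
        ray_cam = np.array([(u - cx) / fx, (v - cy) / fy, 1.0])
        ray_world = camera.rotation.T @ ray_cam
        horiz = ray_world[:2]
        hnorm = np.linalg.norm(horiz)
        if ray_world[2] < -1e-12:
            t = -camera.position[2] / ray_world[2]
            ground = np.asarray(camera.position) + t * ray_world
            gxy = ground[:2]
            # even descending edge rays can land implausibly far; clamp
            if np.linalg.norm(gxy - cam_xy) > far_sentinel and hnorm > 0:
                gxy = cam_xy + horiz / hnorm * far_sentinel
            else:
                any_ground_hit = True
        elif hnorm > 0:
            gxy = cam_xy + horiz / hnorm * far_sentinel
        else:
            continue  # straight-up ray contributes nothing on the ground
        verts.append(gxy)
    if len(verts) < 3 or not any_ground_hit:
        # frustum never meets the ground inside the range band
        return FovFootprint(Polygon(), Polygon(), camera.name)
    raw = Polygon(verts).buffer(0)  # buffer(0) repairs self-touching rings
    band = Point(cam_xy).buffer(far_m, quad_segs=64).difference(
        Point(cam_xy).buffer(near_m, quad_segs=64)
    )
    footprint = raw.intersection(band)
    if footprint.is_empty or footprint.area <= 0:
        return FovFootprint(Polygon(), Polygon(), camera.name)
    if footprint.geom_type != "Polygon":  # keep the dominant piece
        footprint = max(footprint.geoms, key=lambda g: g.area)
    occlusion = _tower_shadow(cam_xy, np.asarray(tower_xy), tower_radius_m, far_sentinel)
    occlusion = occlusion.intersection(footprint)
    if occlusion.geom_type not in ("Polygon",) and not occlusion.is_empty:
        occlusion = unary_union([g for g in getattr(occlusion, "geoms", []) if g.area > 0])
        if occlusion.geom_type != "Polygon":
            occlusion = occlusion.convex_hull
    return FovFootprint(footprint, occlusion if not occlusion.is_empty else Polygon(), camera.name)


def _tower_shadow(cam_xy: np.ndarray, tower_xy: np.ndarray, radius: float, reach: float) -> Polygon:
    """Ground region hidden behind a cylindrical tower, seen from ``cam_xy``."""
    d_vec = tower_xy - cam_xy
    d = np.linalg.norm(d_vec)
    disc = Point(tower_xy).buffer(radius, quad_segs=32)
    if d <= radius:  # camera inside the tower: degenerate, everything hidden
        return Point(cam_xy).buffer(reach, quad_segs=32)
    alpha = math.asin(min(1.0, radius / d))
    theta = math.atan2(d_vec[1], d_vec[0])
    # tangent points on the circle, then extend the wedge far past the tower
    wedge_pts = [tuple(cam_xy)]
    for sign in (1.0, -1.0):
        ang = theta + sign * alpha
        wedge_pts.append(
            (cam_xy[0] + reach * math.cos(ang), cam_xy[1] + reach * math.sin(ang))
        )
    wedge = Polygon(wedge_pts)
    # hidden region: wedge beyond the tower plus the tower disc itself
    behind = wedge.difference(Point(tuple(cam_xy)).buffer(d, quad_segs=64))
    return unary_union([behind, disc])


# ---------------------------------------------------------------------------
# Operational schedule (nights, outages)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperationalSchedule:
    """Nightly recording schedule with logged outages.

    Nights run sunset-to-sunrise and are attributed to the evening's calendar
    date. Sunset/sunrise are fixed clock times (a configurable simplification
    of the seasonal ephemeris); cameras were programmed with generous
    twilight margins so the fixed times bound every study night.
    Outage intervals are half-open ``[start, end)``.
    """

    start_night: date
    end_night: date
    sunset: time = time(19, 30)
    sunrise: time = time(7, 0)
    outages: tuple[tuple[datetime, datetime], ...] = ()

    def __post_init__(self) -> None:
        if self.end_night < self.start_night:
            raise ValueError("end_night precedes start_night")
        for start, end in self.outages:
            if end <= start:
                raise ValueError(f"outage interval reversed: {start} .. {end}")

    def covers_night(self, night: date) -> bool:
        return self.start_night <= night <= self.end_night

    def night_is_recorded(self, night: date) -> bool:
        """True when any part of the night's sunset-to-sunrise span is recorded."""
        if not self.covers_night(night):
            raise ValueError(f"night {night} outside schedule range")
        start, end = night_interval(night, self.sunset, self.sunrise)
        covered = timedelta(0)
        for o_start, o_end in self.outages:
            lo = max(start, o_start)
            hi = min(end, o_end)
            if hi > lo:
                covered += hi - lo
        return covered < (end - start)

    def in_outage(self, t: datetime) -> bool:
        return any(start <= t < end for start, end in self.outages)


def night_of(t: datetime, sunset: time = time(19, 30), sunrise: time = time(7, 0)) -> date:
    """Calendar date of the night containing ``t`` (evening's date).

    Raises for daytime timestamps, which belong to no recording night.
    """
    if t.time() >= sunset:
        return t.date()
    if t.time() < sunrise:
        return t.date() - timedelta(days=1)
    raise ValueError(f"{t} is a daytime timestamp, not within any night")


def night_interval(night: date, sunset: time = time(19, 30), sunrise: time = time(7, 0)) -> tuple[datetime, datetime]:
    """The [sunset, next-morning sunrise) span of a night, by evening date."""
    start = datetime.combine(night, sunset)
    end = datetime.combine(night + timedelta(days=1), sunrise)
    return start, end


def is_operational(camera: CameraModel, schedule: OperationalSchedule, t: datetime) -> bool:
    """Whether ``camera`` was recording at instant ``t``.

    True iff ``t`` falls in the sunset-to-sunrise span of a scheduled night
    and is not inside a logged outage. Daytime timestamps and nights outside
    the schedule range raise ``ValueError``.
    """
    night = night_of(t, schedule.sunset, schedule.sunrise)
    if not schedule.covers_night(night):
        raise ValueError(f"night {night} outside schedule range for {camera.name}")
    return not schedule.in_outage(t)
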