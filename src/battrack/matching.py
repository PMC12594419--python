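"""Carcass-to-track matching and detection-performance metrics.

A carcass found by a human searcher carries an estimated age range (days),
which maps to a *fatality window*: the union of nights during which the
death could have occurred. Carcasses are first accounted against the camera
geometry and schedule — outside the field of view, hidden behind the tower,
or found while no covering camera was recording — and the remainder are
matched one-to-one to machine-flagged fatality tracks whose timestamp falls
inside the window and whose estimated ground position lies within a spatial
radius. The outcome classes are

* MP  (matched positive): carcass and flagged track agree;
* CN  (camera negative): carcass with no matching flagged track;
* CFP (camera false positive): flagged track with no matching carcass;

and the summary rates are sensitivity-style percentages::

    matched detection rate       = MP / (MP + CN)  * 100
    camera missed detection rate = CN / (MP + CN)  * 100
    camera false detection rate  = CFP / (MP + CFP) * 100
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import FovFootprint, OperationalSchedule, night_interval

__all__ = [
    "CarcassRecord",
    "FatalityWindow",
    "MatchResult",
    "EvalSummary",
    "fatality_window",
    "account_carcasses",
    "match_tracks_to_carcasses",
    "compute_rates",
]

DEFAULT_MATCH_RADIUS_M = 15.0
_BIG = 1e12

DISPOSITION_OUTSIDE = "outside_fov"
DISPOSITION_OCCLUDED = "occluded"
DISPOSITION_OFFLINE = "camera_nonoperational"
DISPOSITION_MATCHED = "matched"
DISPOSITION_UNMATCHED = "unmatched"


@dataclass(frozen=True)
class CarcassRecord:
    """A searcher-discovered carcass with location and estimated age."""

    carcass_id: str
    discovered: datetime
    location_xy: tuple[float, float]   # world meters (tower-origin frame)
    age_min_days: int
    age_max_days: int
    species: str | None = None

    def __post_init__(self) -> None:
        if self.age_min_days < 0:
            raise ValueError("carcass age cannot be negative")
        if self.age_max_days < self.age_min_days:
            raise ValueError("age range reversed")


@dataclass(frozen=True)
class FatalityWindow:
    """Possible time-of-death interval, as a union of whole nights."""

    earliest: datetime
    latest: datetime
    nights: tuple[date, ...]

    def __post_init__(self) -> None:
        if self.latest < self.earliest:
            raise ValueError("window reversed")

    def contains(self, t: datetime) -> bool:
        return self.earliest <= t < self.latest


def fatality_window(
    record: CarcassRecord,
    sunset: time = time(19, 30),
    sunrise: time = time(7, 0),
) -> FatalityWindow:
    """Map a carcass's estimated age to its span of candidate nights.

    A carcass ``a`` days old discovered on day D died during the night with
    evening date D - 1 - a (fatalities happen at night; a fresh carcass,
    age 0, fell during the night preceding its discovery). The window is
    the union of the nights for every age in [age_min, age_max], expressed
    as the [first sunset, last sunrise) envelope plus the explicit night
    list.
    """
    d = record.discovered.date()
    nights = tuple(
        d - timedelta(days=1 + a)
        for a in range(record.age_max_days, record.age_min_days - 1, -1)
    )
    first_start, _ = night_interval(nights[0], sunset, sunrise)
    _, last_end = night_interval(nights[-1], sunset, sunrise)
    return FatalityWindow(first_start, last_end, nights)


def account_carcasses(
    records: list[CarcassRecord],
    footprints: dict[str, FovFootprint],
    schedules: dict[str, OperationalSchedule],
    sunset: time = time(19, 30),
    sunrise: time = time(7, 0),
) -> pd.DataFrame:
    """Pre-matching disposition of every carcass against geometry + schedule.

    Exclusion precedence: a carcass is *outside_fov* when no camera's
    footprint contains it; *occluded* when every camera that could see the
    spot has it inside its tower-shadow polygon; *camera_nonoperational*
    when no unoccluded covering camera recorded during any night of the
    fatality window; otherwise it *proceeds* to matching. Footprints and
    schedules are keyed by camera name.
    """
    rows = []
    for rec in records:
        if rec.location_xy is None or not np.all(np.isfinite(rec.location_xy)):
            rows.append({"carcass_id": rec.carcass_id, "disposition": "missing_coordinates"})
            continue
        window = fatality_window(rec, sunset, sunrise)
        covering = [name for name, fp in footprints.items() if fp.is_in_fov(rec.location_xy)]
        if not covering:
            disp = DISPOSITION_OUTSIDE
        else:
            seeing = [name for name in covering if not footprints[name].is_occluded(rec.location_xy)]
            if not seeing:
                disp = DISPOSITION_OCCLUDED
            else:
                operated = False
                for name in seeing:
                    sched = schedules.get(name)
                    if sched is None:
                        continue
                    for night in window.nights:
                        if sched.covers_night(night) and sched.night_is_recorded(night):
                            operated = True
                            break
                    if operated:
                        break
                disp = "proceed" if operated else DISPOSITION_OFFLINE
        rows.append(
            {
                "carcass_id": rec.carcass_id,
                "disposition": disp,
                "window_earliest": window.earliest,
                "window_latest": window.latest,
                "x_m": rec.location_xy[0],
                "y_m": rec.location_xy[1],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching outcome between flagged tracks and carcasses."""

    pairs: tuple[tuple[str, str], ...]        # (track_id, carcass_id)
    carcass_disposition: dict[str, str]       # carcass_id -> matched | unmatched
    track_disposition: dict[str, str]         # track_id -> matched | unmatched

    @property
    def mp(self) -> int:
        return len(self.pairs)

    @property
    def cn(self) -> int:
        return sum(1 for v in self.carcass_disposition.values() if v == DISPOSITION_UNMATCHED)

    @property
    def cfp(self) -> int:
        return sum(1 for v in self.track_disposition.values() if v == DISPOSITION_UNMATCHED)


def match_tracks_to_carcasses(
    tracks: pd.DataFrame,
    records: list[CarcassRecord],
    spatial_radius_m: float = DEFAULT_MATCH_RADIUS_M,
    sunset: time = time(19, 30),
    sunrise: time = time(7, 0),
) -> MatchResult:
    """Match flagged fatality tracks to carcasses, maximizing match count.

    ``tracks`` needs columns ``track_id``, ``timestamp`` (datetime of the
    track, e.g. its final detection) and ``ground_x``/``ground_y`` (meters,
    the track's final point projected onto the ground). A (track, carcass)
    pair is eligible when the timestamp lies inside the carcass's fatality
    window and the ground distance is within ``spatial_radius_m``. The
    one-to-one assignment maximizes the number of eligible pairs; among
    maximum matchings, smaller total distance wins, then earlier tracks.
    """
    if spatial_radius_m <= 0:
        raise ValueError("spatial_radius_m must be positive")
    track_ids = [str(t) for t in tracks["track_id"]] if len(tracks) else []
    windows = [fatality_window(r, sunset, sunrise) for r in records]
    n_t, n_c = len(track_ids), len(records)
    pairs: list[tuple[str, str]] = []
    if n_t and n_c:
        cost = np.full((n_t, n_c), _BIG)
        order = np.argsort(pd.to_datetime(tracks["timestamp"]).to_numpy(), kind="stable")
        rank = np.empty(n_t)
        rank[order] = np.arange(n_t)
        for i in range(n_t):
            t_time = pd.to_datetime(tracks["timestamp"].iloc[i]).to_pydatetime()
            tx, ty = float(tracks["ground_x"].iloc[i]), float(tracks["ground_y"].iloc[i])
            for j, (rec, win) in enumerate(zip(records, windows)):
                if not win.contains(t_time):
                    continue
                dist = float(np.hypot(tx - rec.location_xy[0], ty - rec.location_xy[1]))
                if dist <= spatial_radius_m:
                    # distance dominates; earlier-track rank breaks exact ties
                    cost[i, j] = dist + 1e-9 * rank[i]
        rows_idx, cols_idx = linear_sum_assignment(cost)
        for i, j in zip(rows_idx, cols_idx):
            if cost[i, j] < _BIG:
                pairs.append((track_ids[i], records[j].carcass_id))
    matched_tracks = {p[0] for p in pairs}
    matched_carcasses = {p[1] for p in pairs}
    return MatchResult(
        pairs=tuple(pairs),
        carcass_disposition={
            r.carcass_id: (
                DISPOSITION_MATCHED if r.carcass_id in matched_carcasses else DISPOSITION_UNMATCHED
            )
            for r in records
        },
        track_disposition={
            tid: (DISPOSITION_MATCHED if tid in matched_tracks else DISPOSITION_UNMATCHED)
            for tid in track_ids
        },
    )


@dataclass(frozen=True)
class EvalSummary:
    """MP/CFP/CN counts and the three detection-rate percentages.

    Rates are stored at full precision; the ``*_display`` properties round
    to 0.1 %. An undefined rate (zero denominator) is ``None``.
    """

    mp: int
    cfp: int
    cn: int
    matched_detection_rate: float | None
    camera_missed_detection_rate: float | None
    camera_false_detection_rate: float | None

    @staticmethod
    def _disp(x: float | None) -> float | None:
        return None if x is None else round(x, 1)

    @property
    def matched_detection_rate_display(self) -> float | None:
        return self._disp(self.matched_detection_rate)

    @property
    def camera_missed_detection_rate_display(self) -> float | None:
        return self._disp(self.camera_missed_detection_rate)

    @property
    def camera_false_detection_rate_display(self) -> float | None:
        return self._disp(self.camera_false_detection_rate)

    def to_text(self) -> str:
        fmt = lambda x: "undefined" if x is None else f"{x:.1f}%"
        return (
            f"Matched Positives (MP):        {self.mp}\n"
            f"Camera False Positives (CFP):  {self.cfp}\n"
            f"Camera Negatives (CN):         {self.cn}\n"
            f"Matched detection rate:        {fmt(self.matched_detection_rate_display)}\n"
            f"Camera missed detection rate:  {fmt(self.camera_missed_detection_rate_display)}\n"
            f"Camera false detection rate:   {fmt(self.camera_false_detection_rate_display)}\n"
        )


def compute_rates(mp: int, cfp: int, cn: int) -> EvalSummary:
    """Detection-performance rates from MP/CFP/CN counts.

    matched = MP/(MP+CN)*100, missed = CN/(MP+CN)*100,
    false detection = CFP/(MP+CFP)*100; zero denominators yield ``None``
    rather than a division error.
    """
    for name, v in (("MP", mp), ("CFP", cfp), ("CN", cn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    mp, cfp, cn = int(mp), int(cfp), int(cn)
    found = mp + cn
    flagged = mp + cfp
    matched = mp / found * 100.0 if found else None
    missed = cn / found * 100.0 if found else None
    false_det = cfp / flagged * 100.0 if flagged else None
    return EvalSummary(mp, cfp, cn, matched, missed, false_det)
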