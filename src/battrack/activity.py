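"""Bat-seconds activity metric.

Each bat-class detection spans one frame, i.e. 1/fps seconds of presence in
the field of view, so summing detections over a period and dividing by the
frame rate yields "bat-seconds" of activity: 1,234 detections in a
ten-minute period at 30 fps is 1234/30 = 41.1 bat-seconds. Counts are
exact; bat-seconds keep full precision internally and are rounded to 0.1 s
only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import night_of

__all__ = ["ActivityBin", "bin_activity", "nightly_hourly_profile"]


@dataclass(frozen=True)
class ActivityBin:
    start: datetime
    end: datetime
    detection_count: int

    def bat_seconds(self, fps: float) -> float:
        return self.detection_count / fps


def bin_activity(
    timestamps: Sequence[datetime] | pd.Series,
    bin_width: timedelta,
    fps: float = 30.0,
    start: datetime | None = None,
    end: datetime | None = None,
) -> pd.DataFrame:
    """Count bat detections into half-open [start, end) bins.

    ``timestamps`` are the per-detection times of bat-class detections.
    Bins tile [start, end) at ``bin_width``; detections outside the range
    raise (they must be flagged upstream, never silently dropped).
    Returns columns bin_start, bin_end, detections, bat_seconds (full
    precision) and bat_seconds_display (rounded to 0.1 s).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if bin_width <= timedelta(0):
        raise ValueError("bin_width must be positive")
    ts = pd.Series(pd.to_datetime(list(timestamps)))
    if start is None:
        start = ts.min().to_pydatetime() if len(ts) else datetime(1970, 1, 1)
    if end is None:
        # just past the last detection, so bins tile [start, end) minimally
        end = (ts.max().to_pydatetime() + timedelta(microseconds=1)) if len(ts) else start + bin_width
    if len(ts):
        outside = (ts < start) | (ts >= end)
        if outside.any():
            raise ValueError(
                f"{int(outside.sum())} detections fall outside the binning range "
                f"[{start}, {end}); widen the range or filter explicitly"
            )
    n_bins = int(np.ceil((end - start) / bin_width))
    edges = [start + i * bin_width for i in range(n_bins + 1)]
    if len(ts):
        idx = ((ts - start) // bin_width).astype(int)
        counts = idx.value_counts()
    else:
        counts = pd.Series(dtype=int)
    rows = []
    for i in range(n_bins):
        c = int(counts.get(i, 0))
        rows.append(
            {
                "bin_start": edges[i],
                "bin_end": edges[i + 1],
                "detections": c,
                "bat_seconds": c / fps,
                "bat_seconds_display": round(c / fps, 1),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_start", "bin_end", "detections", "bat_seconds", "bat_seconds_display"]
    )


def nightly_hourly_profile(
    bins: pd.DataFrame,
    sunset: time = time(19, 30),
    sunrise: time = time(7, 0),
    fps: float = 30.0,
) -> pd.DataFrame:
    """Re-aggregate activity bins per night and hour-from-sunset.

    Hour 0 starts at sunset of each night. Bins must not straddle hour
    boundaries coarser than their own width for totals to stay exact; with
    the usual 1–10 minute bins this always holds. Totals are conserved:
    summing the hourly table reproduces the summed input bins. Nights whose
    coverage is partial (bins do not reach both sunset and sunrise) are
    flagged in the ``partial_coverage`` column.
    """
    if len(bins) == 0:
        return pd.DataFrame(
            columns=["night_date", "hour_of_night", "detections", "bat_seconds", "partial_coverage"]
        )
    rows = []
    for _, b in bins.iterrows():
        mid = b["bin_start"] + (b["bin_end"] - b["bin_start"]) / 2
        night = night_of(mid.to_pydatetime() if hasattr(mid, "to_pydatetime") else mid,
                         sunset, sunrise)
        sunset_dt = datetime.combine(night, sunset)
        hour = int((b["bin_start"] - sunset_dt) // timedelta(hours=1))
        rows.append({"night_date": night, "hour_of_night": hour, "detections": b["detections"]})
    df = pd.DataFrame(rows)
    prof = (
        df.groupby(["night_date", "hour_of_night"], as_index=False)["detections"].sum()
    )
    prof["bat_seconds"] = prof["detections"] / fps
    # coverage check per night
    coverage = {}
    for night, grp in pd.DataFrame(
        {"night": [r["night_date"] for r in rows],
         "start": bins["bin_start"].to_numpy(),
         "end": bins["bin_end"].to_numpy()}
    ).groupby("night"):
        sunset_dt = datetime.combine(night, sunset)
        sunrise_dt = datetime.combine(night + timedelta(days=1), sunrise)
        coverage[night] = not (
            grp["start"].min() <= sunset_dt and grp["end"].max() >= sunrise_dt
        )
    prof["partial_coverage"] = prof["night_date"].map(coverage)
    return prof
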