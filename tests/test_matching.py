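"""Fatality windows, carcass accounting, track matching and rate metrics."""

from __future__ import annotations

import itertools
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

import battrack as bt
from battrack.matching import (
    CarcassRecord,
    account_carcasses,
    compute_rates,
    fatality_window,
    match_tracks_to_carcasses,
)
from battrack.pipeline import study_accounting_fixture


def rec(cid="c0", day=20, age=(0, 0), xy=(0.0, 0.0)):
    return CarcassRecord(cid, datetime(2022, 8, day, 9, 0), xy, age[0], age[1])


def track_row(tid, night: date, xy, hour=23):
    return {
        "track_id": tid,
        "timestamp": datetime.combine(night, time(hour, 0)),
        "ground_x": xy[0],
        "ground_y": xy[1],
    }


def brute_force_max_matching(tracks, records, radius):
    """Enumerate all one-to-one assignments; return max eligible-match count."""
    n_t, n_c = len(tracks), len(records)
    elig = np.zeros((n_t, n_c), dtype=bool)
    for i, tr in tracks.reset_index(drop=True).iterrows():
        for j, r in enumerate(records):
            win = fatality_window(r)
            d = np.hypot(tr["ground_x"] - r.location_xy[0], tr["ground_y"] - r.location_xy[1])
            if win.contains(pd.to_datetime(tr["timestamp"]).to_pydatetime()) and d <= radius:
                elig[i, j] = True
    best = 0
    for k in range(min(n_t, n_c), 0, -1):
        for t_idx in itertools.combinations(range(n_t), k):
            for c_idx in itertools.permutations(range(n_c), k):
                if all(elig[t, c] for t, c in zip(t_idx, c_idx)):
                    return k
    return best


class TestFatalityWindow:
    def test_two_to_three_day_old_carcass_spans_two_nights(self):
        """Age 2-3 days, discovered morning of day D: nights D-3 and D-2."""
        w = fatality_window(rec(age=(2, 3)))
        assert w.nights == (date(2022, 8, 16), date(2022, 8, 17))
        assert w.earliest == datetime(2022, 8, 16, 19, 30)
        assert w.latest == datetime(2022, 8, 18, 7, 0)

    def test_fresh_carcass_maps_to_preceding_night(self):
        w = fatality_window(rec(age=(0, 0)))
        assert w.nights == (date(2022, 8, 19),)

    def test_age_zero_to_two_gives_three_contiguous_nights(self):
        w = fatality_window(rec(age=(0, 2)))
        assert w.nights == (date(2022, 8, 17), date(2022, 8, 18), date(2022, 8, 19))
        assert w.latest - w.earliest == timedelta(days=2, hours=11, minutes=30)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            rec(age=(-1, 0))
        with pytest.raises(ValueError):
            rec(age=(2, 1))


class TestAccounting:
    def test_study_layout_dispositions(self):
        """40 records: 10 outside FOV, 2 occluded, 2 outage, 26 proceed."""
        records, footprints, schedules, _ = study_accounting_fixture(seed=0)
        acct = account_carcasses(records, footprints, schedules)
        counts = acct["disposition"].value_counts().to_dict()
        assert len(acct) == 40
        assert counts["outside_fov"] == 10
        assert counts["occluded"] == 2
        assert counts["camera_nonoperational"] == 2
        assert counts["proceed"] == 26
        # conservation: categories partition the records exactly
        assert sum(counts.values()) == 40

    def test_occluded_requires_every_covering_camera_blocked(self):
        records, footprints, schedules, _ = study_accounting_fixture(seed=0)
        # a point in the north camera's shadow but visible to the south camera
        pt = (0.0, 6.0)
        assert footprints["south"].is_occluded(pt)
        assert footprints["north"].is_in_fov(pt) and not footprints["north"].is_occluded(pt)
        acct = account_carcasses(
            [CarcassRecord("x", datetime(2022, 9, 5, 9, 0), pt, 0, 0)],
            footprints, schedules,
        )
        assert acct.loc[0, "disposition"] == "proceed"

    def test_missing_coordinates_flagged(self):
        records, footprints, schedules, _ = study_accounting_fixture(seed=0)
        bad = CarcassRecord("bad", datetime(2022, 9, 5, 9, 0), (np.nan, 0.0), 0, 0)
        acct = account_carcasses([bad], footprints, schedules)
        assert acct.loc[0, "disposition"] == "missing_coordinates"


class TestMatching:
    def test_single_eligible_pair_matches(self):
        r = rec(xy=(3.0, 4.0))
        tracks = pd.DataFrame([track_row("t0", date(2022, 8, 19), (5.0, 5.0))])
        res = match_tracks_to_carcasses(tracks, [r])
        assert (res.mp, res.cfp, res.cn) == (1, 0, 0)
        assert res.pairs == (("t0", "c0"),)

    def test_no_tracks_all_carcasses_negative(self):
        records = [rec(cid=f"c{i}", xy=(i * 5.0, 0.0)) for i in range(4)]
        res = match_tracks_to_carcasses(pd.DataFrame(
            columns=["track_id", "timestamp", "ground_x", "ground_y"]
        ), records)
        assert (res.mp, res.cfp, res.cn) == (0, 0, 4)

    def test_five_falls_three_decoys(self):
        """5 carcasses at impact points + 3 decoy tracks: MP 5, CFP 3, CN 0."""
        rng = np.random.default_rng(2)
        night = date(2022, 8, 19)
        records, rows = [], []
        for i in range(5):
            xy = tuple(rng.uniform(-20, 20, 2))
            records.append(rec(cid=f"c{i}", xy=xy))
            rows.append(track_row(f"t{i}", night, (xy[0] + 1.0, xy[1] - 1.0)))
        for j in range(3):  # decoys: right night, far away
            rows.append(track_row(f"d{j}", night, (400.0 + j * 50, 400.0)))
        tracks = pd.DataFrame(rows)
        res = match_tracks_to_carcasses(tracks, records)
        assert (res.mp, res.cfp, res.cn) == (5, 3, 0)
        assert res.mp == brute_force_max_matching(tracks, records, 15.0)

    def test_assignment_is_maximum_cardinality(self):
        """Greedy-looking geometry where only optimal assignment gets 2 matches."""
        night = date(2022, 8, 19)
        # t0 can match both carcasses; t1 only c0: optimal pairs t0-c1, t1-c0
        records = [rec(cid="c0", xy=(0.0, 0.0)), rec(cid="c1", xy=(12.0, 0.0))]
        tracks = pd.DataFrame(
            [track_row("t0", night, (6.0, 0.0)), track_row("t1", night, (-8.0, 0.0))]
        )
        res = match_tracks_to_carcasses(tracks, records)
        assert res.mp == 2 == brute_force_max_matching(tracks, records, 15.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        night = date(2022, 8, 19)
        for trial in range(10):
            n_c, n_t = rng.integers(1, 6), rng.integers(1, 6)
            records = [
                rec(cid=f"c{i}", xy=tuple(rng.uniform(-30, 30, 2))) for i in range(n_c)
            ]
            tracks = pd.DataFrame(
                [
                    track_row(f"t{i}", night, tuple(rng.uniform(-30, 30, 2)))
                    for i in range(n_t)
                ]
            )
            res = match_tracks_to_carcasses(tracks, records)
            assert res.mp == brute_force_max_matching(tracks, records, 15.0), f"trial {trial}"

    def test_mp_monotone_in_radius_and_window(self):
        rng = np.random.default_rng(9)
        night = date(2022, 8, 19)
        records = [rec(cid=f"c{i}", age=(0, 0), xy=tuple(rng.uniform(-30, 30, 2)))
                   for i in range(6)]
        tracks = pd.DataFrame(
            [
                track_row(f"t{i}", night - timedelta(days=i % 3), tuple(rng.uniform(-30, 30, 2)))
                for i in range(6)
            ]
        )
        mps = [
            match_tracks_to_carcasses(tracks, records, spatial_radius_m=r).mp
            for r in (2.0, 10.0, 30.0, 100.0)
        ]
        assert all(b >= a for a, b in zip(mps, mps[1:]))
        # widening the age range (hence the window) never loses matches
        mp_narrow = match_tracks_to_carcasses(tracks, records, spatial_radius_m=50).mp
        wide = [
            CarcassRecord(r.carcass_id, r.discovered, r.location_xy, 0, 3) for r in records
        ]
        mp_wide = match_tracks_to_carcasses(tracks, wide, spatial_radius_m=50).mp
        assert mp_wide >= mp_narrow

    def test_study_fixture_end_to_end_counts(self):
        records, footprints, schedules, flagged = study_accounting_fixture(seed=0)
        acct = account_carcasses(records, footprints, schedules)
        proceed_ids = set(acct.loc[acct["disposition"] == "proceed", "carcass_id"])
        proceed = [r for r in records if r.carcass_id in proceed_ids]
        res = match_tracks_to_carcasses(flagged, proceed)
        assert (res.mp, res.cn, res.cfp) == (23, 3, 0)


class TestRates:
    def test_reported_study_counts_reproduce_published_rates(self):
        """MP 23, CFP 165, CN 3 -> 88.5 / 11.5 / 87.8 percent."""
        s = compute_rates(23, 165, 3)
        assert s.matched_detection_rate_display == 88.5
        assert s.camera_missed_detection_rate_display == 11.5
        assert s.camera_false_detection_rate_display == 87.8

    def test_variant_with_unconfirmed_extra_false_positive(self):
        assert compute_rates(23, 166, 3).camera_false_detection_rate_display == 87.8

    def test_matched_and_missed_rates_sum_to_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mp, cn = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            if mp + cn == 0:
                continue
            s = compute_rates(mp, int(rng.integers(0, 200)), cn)
            assert s.matched_detection_rate + s.camera_missed_detection_rate == pytest.approx(100.0)

    def test_zero_denominators_yield_undefined_not_error(self):
        s = compute_rates(0, 0, 5)
        assert s.matched_detection_rate_display == 0.0
        assert s.camera_missed_detection_rate_display == 100.0
        assert s.camera_false_detection_rate is None
        assert "undefined" in s.to_text()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_rates(-1, 0, 0)


class TestRateProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        mp=st.integers(0, 500), cfp=st.integers(0, 500), cn=st.integers(0, 500)
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_rates_bounded_and_complementary(self, mp, cfp, cn):
        s = compute_rates(mp, cfp, cn)
        for rate in (
            s.matched_detection_rate,
            s.camera_missed_detection_rate,
            s.camera_false_detection_rate,
        ):
            assert rate is None or 0.0 <= rate <= 100.0
        if mp + cn > 0:
            assert s.matched_detection_rate + s.camera_missed_detection_rate == pytest.approx(100.0)
        else:
            assert s.matched_detection_rate is None
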