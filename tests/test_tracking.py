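"""Track linking, pruning and feature tests, with an exhaustive oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import battrack as bt
from battrack.detection import Detection
from battrack.tracking import (
    FEATURE_NAMES,
    GatingConfig,
    Track,
    compute_track_features,
    link_detections,
    prune_noise,
    tracks_to_frame,
)


def make_det(det_id, frame, x, y, ts=None, area=5, width=2.0, length=3.0):
    return Detection(
        detection_id=det_id,
        frame_index=frame,
        timestamp_s=frame / 30.0 if ts is None else ts,
        centroid_px=(float(x), float(y)),
        area_px=area,
        width_px=width,
        length_px=length,
        mean_intensity=50.0,
    )


def mover(det_id0, frame0, n, x0, y0, vx, vy):
    return [
        make_det(det_id0 + i, frame0 + i, x0 + vx * i, y0 + vy * i) for i in range(n)
    ]


def oracle_link(detections, gating: GatingConfig):
    """Exhaustive frame-by-frame optimal assignment (reference implementation).

    At each frame, enumerates every gated matching between open tracks and
    detections and picks the one with minimum total distance (nearest to
    last position for 1-detection tracks, constant-velocity prediction
    otherwise) — independent of the scipy-based production path. Returns
    tracks as frozensets of detection ids. Only viable for tiny instances.
    """
    frames: dict[int, list] = {}
    for d in sorted(detections, key=lambda d: (d.frame_index, d.detection_id)):
        frames.setdefault(d.frame_index, []).append(d)
    open_tracks: list[list] = []
    closed: list[list] = []
    for fi in sorted(frames):
        dets = frames[fi]
        still = []
        for tr in open_tracks:
            if fi - tr[-1].frame_index > gating.max_gap_frames:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still
        best = None
        n_t, n_d = len(open_tracks), len(dets)
        for k in range(min(n_t, n_d), -1, -1):
            # all ways to choose k tracks and k detections and pair them
            for t_idx in itertools.combinations(range(n_t), k):
                for d_idx in itertools.permutations(range(n_d), k):
                    total = 0.0
                    ok = True
                    for ti, di in zip(t_idx, d_idx):
                        tr = open_tracks[ti]
                        if len(tr) >= 2:
                            a, b = tr[-2], tr[-1]
                            df = b.frame_index - a.frame_index
                            vel = (
                                np.asarray(b.centroid_px) - np.asarray(a.centroid_px)
                            ) / df
                            pred = np.asarray(b.centroid_px) + vel * (fi - b.frame_index)
                        else:
                            pred = np.asarray(tr[-1].centroid_px)
                        dist = float(np.linalg.norm(pred - np.asarray(dets[di].centroid_px)))
                        if dist > gating.max_link_distance_px:
                            ok = False
                            break
                        total += dist
                    if ok and (best is None or (len(t_idx), -total) > (best[0], -best[1])):
                        # maximize matches, then minimize distance
                        if best is None or len(t_idx) > best[0] or (
                            len(t_idx) == best[0] and total < best[1]
                        ):
                            best = (len(t_idx), total, t_idx, d_idx)
            if best is not None and best[0] == k:
                break
        matched_d = set()
        if best is not None:
            for ti, di in zip(best[2], best[3]):
                open_tracks[ti].append(dets[di])
                matched_d.add(di)
        for di, d in enumerate(dets):
            if di not in matched_d:
                open_tracks.append([d])
    closed.extend(open_tracks)
    return [frozenset(d.detection_id for d in tr) for tr in closed]


class TestLinking:
    def test_two_separated_movers_give_two_clean_tracks(self):
        dets = mover(0, 0, 8, 10, 10, 3, 0) + mover(100, 0, 8, 200, 150, -3, 1)
        tracks = link_detections(dets)
        assert len(tracks) == 2
        sets = sorted(
            [sorted(d.detection_id for d in t.detections) for t in tracks]
        )
        assert sets == [list(range(8)), list(range(100, 108))]

    def test_matches_exhaustive_oracle_on_small_instances(self):
        """Production linking groups detections exactly as exhaustive search."""
        rng = np.random.default_rng(5)
        gating = GatingConfig()
        for trial in range(20):
            dets = []
            det_id = 0
            for m in range(rng.integers(1, 4)):
                n = int(rng.integers(2, 5))
                f0 = int(rng.integers(0, 3))
                x0, y0 = rng.uniform(20, 200, 2)
                vx, vy = rng.uniform(-8, 8, 2)
                for i in range(n):
                    if det_id >= 12:
                        break
                    dets.append(make_det(det_id, f0 + i, x0 + vx * i, y0 + vy * i))
                    det_id += 1
            got = sorted(
                frozenset(d.detection_id for d in t.detections)
                for t in link_detections(dets, gating)
            )
            want = sorted(oracle_link(dets, gating))
            assert got == want, f"trial {trial}"

    def test_constant_velocity_prediction_prevents_identity_swap(self):
        # two movers crossing at a shallow angle: nearest-neighbour linking
        # would swap identities at the crossing, prediction keeps them.
        a = mover(0, 0, 12, 0, 100, 10, 1.5)
        b = mover(100, 0, 12, 0, 115, 10, -1.5)
        tracks = link_detections(a + b, GatingConfig(max_link_distance_px=12))
        assert len(tracks) == 2
        for t in tracks:
            ids = {d.detection_id for d in t.detections}
            assert ids == set(range(12)) or ids == set(range(100, 112))

    def test_every_detection_in_exactly_one_track(self, detected_scene):
        _, detections, _ = detected_scene
        tracks = link_detections(detections)
        seen = [d.detection_id for t in tracks for d in t.detections]
        assert sorted(seen) == sorted(d.detection_id for d in detections)
        kept, pruned = prune_noise(tracks)
        n_kept = sum(len(t.detections) for t in kept)
        n_pruned = sum(len(t.detections) for t in pruned)
        assert n_kept + n_pruned == len(detections)

    def test_input_order_invariance(self, detected_scene):
        _, detections, _ = detected_scene
        shuffled = list(detections)
        np.random.default_rng(0).shuffle(shuffled)
        a = sorted(
            frozenset(d.detection_id for d in t.detections)
            for t in link_detections(detections)
        )
        b = sorted(
            frozenset(d.detection_id for d in t.detections)
            for t in link_detections(shuffled)
        )
        assert a == b

    def test_gap_tolerance_bridges_missed_frames(self):
        dets = [make_det(i, f, 10 + 3 * f, 50) for i, f in enumerate([0, 1, 2, 5, 6])]
        tracks = link_detections(dets, GatingConfig(max_gap_frames=3))
        assert len(tracks) == 1
        tracks = link_detections(dets, GatingConfig(max_gap_frames=2))
        assert len(tracks) == 2


class TestPruning:
    def test_single_detection_track_pruned(self):
        kept, pruned = prune_noise(link_detections([make_det(0, 0, 50, 50)]))
        assert kept == [] and len(pruned) == 1

    def test_long_fall_track_retained(self):
        dets = mover(0, 0, 30, 100, 10, 0.5, 4)
        kept, pruned = prune_noise(link_detections(dets))
        assert len(kept) == 1 and pruned == []

    def test_retained_count_monotone_in_prune_parameters(self, detected_scene):
        _, detections, _ = detected_scene
        tracks = link_detections(detections)
        counts_min = [
            len(prune_noise(tracks, GatingConfig(min_track_detections=m))[0])
            for m in (2, 5, 10, 20)
        ]
        assert all(b <= a for a, b in zip(counts_min, counts_min[1:]))
        counts_dist = [
            len(prune_noise(tracks, GatingConfig(noise_prune_distance_px=d))[0])
            for d in (1.0, 5.0, 20.0, 80.0)
        ]
        assert all(b <= a for a, b in zip(counts_dist, counts_dist[1:]))


class TestFeatures:
    def test_uniform_motion_closed_form(self):
        dets = mover(0, 0, 10, 0, 0, 10, 0)  # 10 px/frame at 30 fps
        f = compute_track_features(Track(0, dets))
        assert f.mean_speed == pytest.approx(300.0)
        assert f.max_accel == pytest.approx(0.0, abs=1e-6)
        assert f.straightness == pytest.approx(1.0)
        assert f.descent_fraction == 0.0
        assert f.duration_s == pytest.approx(9 / 30)

    def test_fall_track_descends(self, small_camera, training_table):
        falls = training_table[training_table["fate_class"] == "fatality"]
        assert (falls["descent_fraction"] >= 0.9).mean() > 0.9
        assert (falls["net_vertical_px"] > 0).all()

    def test_stationary_blinking_blob_convention(self):
        dets = [make_det(i, 2 * i, 50, 50) for i in range(4)]
        f = compute_track_features(Track(0, dets))
        assert f.mean_speed == 0.0
        assert f.straightness == 0.0
        assert f.descent_fraction == 0.0

    def test_single_detection_rejected(self):
        with pytest.raises(ValueError):
            compute_track_features(Track(0, [make_det(0, 0, 1, 1)]))

    def test_two_detection_track_flags_undefined_acceleration(self):
        f = compute_track_features(Track(0, mover(0, 0, 2, 0, 0, 5, 5)))
        assert not f.accel_defined
        assert f.mean_accel == 0.0

    def test_feature_vector_matches_names(self):
        f = compute_track_features(Track(0, mover(0, 0, 6, 0, 0, 2, 2)))
        vec = f.as_vector()
        assert vec.shape == (len(FEATURE_NAMES),)
        assert np.isfinite(vec).all()

    def test_track_table_schema(self, detected_scene):
        _, detections, _ = detected_scene
        kept, _ = prune_noise(link_detections(detections))
        df = tracks_to_frame(kept)
        assert set(FEATURE_NAMES).issubset(df.columns)
        assert (df["n_detections"] >= 5).all()


class TestGatingValidation:
    def test_invalid_gating_rejected(self):
        with pytest.raises(ValueError):
            GatingConfig(max_link_distance_px=0)
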