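"""Pipeline orchestration: config, logging, staged runs, fixtures.

Chains simulate -> detect -> track -> classify -> activity -> evaluate over
a run directory. Every stage writes CSV/JSON outputs plus a small meta file
carrying the configuration hash; downstream stages refuse inputs produced
under a different configuration, and the run manifest reconciles record
counts across stages so silent data loss is impossible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import classification as cls_mod
from . import detection as det_mod
from . import matching as match_mod
from . import synthetic as syn_mod
from . import tracking as trk_mod
from .geometry import (
    CameraModel,
    OperationalSchedule,
    fov_ground_footprint,
    pixel_to_ground,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "DEFAULT_CONFIG", "config_hash"]

log = logging.getLogger("battrack")

STAGES = ["simulate", "detect", "track", "classify", "activity", "evaluate"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "camera": {
        "position": [0.0, -75.0, 1.5],
        "tilt_deg": 15.0,
        "heading_deg": 0.0,
        "focal_length_mm": 35.0,
        "sensor_mm": [32.0, 24.0],
        "resolution_px": [320, 240],
        "fps": 30.0,
    },
    "scene": {
        "n_fall": 3,
        "n_flight": 4,
        "n_insect": 3,
        "noise_sd": 2.0,
        "t0": "2022-08-15T21:00:00",
    },
    "detection": {
        "threshold_k": 4.0,
        "min_area": 2,
        "learning_rate": 0.05,
        "warmup_frames": 30,
    },
    "gating": {
        "max_link_distance_px": 20.0,
        "max_gap_frames": 3,
        "min_track_detections": 5,
        "noise_prune_distance_px": 5.0,
    },
    "classifier": {
        "n_train_fall": 150,
        "n_train_flight": 150,
        "n_train_insect": 150,
        "fatality_threshold": 0.5,
    },
    "activity": {"bin_minutes": 10},
    "matching": {"spatial_radius_m": 15.0, "near_m": 5.0, "far_m": 100.0},
}


class PipelineConfig:
    """Validated pipeline configuration (deep-merged over defaults)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _deep_merge(DEFAULT_CONFIG, overrides or {})
        self._validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def _validate(self) -> None:
        cam = self.data["camera"]
        if cam["fps"] <= 0:
            raise ValueError("config error: camera.fps must be positive")
        if min(cam["resolution_px"]) < 1:
            raise ValueError("config error: camera.resolution_px components must be >= 1")
        if not (0 <= cam["tilt_deg"] < 90):
            raise ValueError("config error: camera.tilt_deg must be in [0, 90)")
        det = self.data["detection"]
        det_mod.DetectionConfig(
            threshold_k=det["threshold_k"], min_area=det["min_area"],
            learning_rate=det["learning_rate"], warmup_frames=det["warmup_frames"],
        )
        g = self.data["gating"]
        trk_mod.GatingConfig(**g)
        if not (0 <= self.data["classifier"]["fatality_threshold"] <= 1):
            raise ValueError("config error: classifier.fatality_threshold must be in [0, 1]")
        if self.data["matching"]["spatial_radius_m"] <= 0:
            raise ValueError("config error: matching.spatial_radius_m must be positive")

    def camera(self) -> CameraModel:
        c = self.data["camera"]
        return CameraModel(
            position=tuple(c["position"]),
            tilt_deg=c["tilt_deg"],
            heading_deg=c["heading_deg"],
            focal_length_mm=c["focal_length_mm"],
            sensor_width_mm=c["sensor_mm"][0],
            sensor_height_mm=c["sensor_mm"][1],
            resolution_px=tuple(c["resolution_px"]),
            fps=c["fps"],
        )

    def detection_config(self) -> det_mod.DetectionConfig:
        d = self.data["detection"]
        return det_mod.DetectionConfig(
            threshold_k=d["threshold_k"], min_area=d["min_area"],
            learning_rate=d["learning_rate"], warmup_frames=d["warmup_frames"],
        )

    def gating(self) -> trk_mod.GatingConfig:
        return trk_mod.GatingConfig(**self.data["gating"])

    @property
    def hash(self) -> str:
        return config_hash(self.data)


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for key, val in base.items():
        if key in override and isinstance(val, dict) and isinstance(override[key], dict):
            out[key] = _deep_merge(val, override[key])
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = val
    for key in override:
        if key not in base:
            raise ValueError(f"config error: unknown key '{key}'")
    return out


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage I/O with config-hash stamping
# ---------------------------------------------------------------------------

def _write_meta(out: Path, stage: str, cfg_hash: str, counts: dict) -> None:
    meta = {"stage": stage, "config_hash": cfg_hash, "counts": counts}
    (out / f"{stage}.meta.json").write_text(json.dumps(meta, indent=1))


def _check_meta(out: Path, stage: str, cfg_hash: str) -> dict:
    path = out / f"{stage}.meta.json"
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' output missing: {path} — run that stage first"
        )
    meta = json.loads(path.read_text())
    if meta["config_hash"] != cfg_hash:
        raise RuntimeError(
            f"config hash mismatch: '{stage}' outputs were produced under "
            f"{meta['config_hash']}, current config is {cfg_hash}; rerun upstream stages"
        )
    return meta


def _stage_timer(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            self.wall = _time.perf_counter() - self.t0
            log.info("stage %s: done in %.2f s", stage, self.wall)

    return _Timer()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    cam = cfg.camera()
    sc = cfg.data["scene"]
    truth = syn_mod.generate_labeled_dataset(
        sc["n_fall"], sc["n_flight"], sc["n_insect"], seed, camera=cam
    )
    frames, ts = syn_mod.render_frames(
        truth, cam, noise_sd=sc["noise_sd"], seed=seed + 1
    )
    np.save(out / "frames.npy", frames)
    ts.to_csv(out / "timestamps.csv", index=False)
    truth.label_table().to_csv(out / "labels.csv", index=False)
    truth_dets = syn_mod.project_truth_detections(truth, cam)
    truth_dets.to_csv(out / "truth_detections.csv", index=False)
    # plant carcass records at fall impact points, discovered next morning
    t0 = datetime.fromisoformat(sc["t0"])
    rows = []
    for obj in truth.objects:
        if obj.class_label != syn_mod.CLASS_BAT_FALL:
            continue
        impact = obj.trajectory.pos[-1]
        rows.append(
            {
                "carcass_id": f"c{obj.object_id}",
                "iso_discovery": (
                    datetime.combine(t0.date() + timedelta(days=1), datetime.min.time())
                    + timedelta(hours=9)
                ).isoformat(),
                "x_m": float(impact[0]),
                "y_m": float(impact[1]),
                "age_min_days": 0,
                "age_max_days": 0,
                "species": "Tadarida brasiliensis",
            }
        )
    pd.DataFrame(
        rows,
        columns=["carcass_id", "iso_discovery", "x_m", "y_m",
                 "age_min_days", "age_max_days", "species"],
    ).to_csv(out / "carcasses.csv", index=False)
    counts = {"frames": int(len(frames)), "objects": len(truth.objects), "carcasses": len(rows)}
    _write_meta(out, "simulate", cfg.hash, counts)
    return counts


def _stage_detect(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    _check_meta(out, "simulate", cfg.hash)
    frames = np.load(out / "frames.npy")
    cam = cfg.camera()
    detections, model = det_mod.run_detector(
        frames, cfg.detection_config(), fps=cam.fps, keep_pixels=False
    )
    det_mod.detections_to_frame(detections).to_csv(out / "detections.csv", index=False)
    _write_meta(out, "detect", cfg.hash, {"detections": len(detections)})
    return {"detections": len(detections)}


def _detections_from_csv(path: Path) -> list[det_mod.Detection]:
    df = pd.read_csv(path)
    return [
        det_mod.Detection(
            detection_id=int(r.detection_id),
            frame_index=int(r.frame_index),
            timestamp_s=float(r.timestamp),
            centroid_px=(float(r.x), float(r.y)),
            area_px=int(r.area),
            width_px=float(r.width),
            length_px=float(r.length),
            mean_intensity=float(r.mean_intensity),
        )
        for r in df.itertuples()
    ]


def _stage_track(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    _check_meta(out, "detect", cfg.hash)
    dets = _detections_from_csv(out / "detections.csv")
    gating = cfg.gating()
    tracks = trk_mod.link_detections(dets, gating)
    kept, pruned = trk_mod.prune_noise(tracks, gating)
    trk_mod.tracks_to_frame(kept).to_csv(out / "tracks.csv", index=False)
    counts = {
        "detections_in": len(dets),
        "tracks": len(kept),
        "pruned_tracks": len(pruned),
        "detections_in_tracks": sum(len(t.detections) for t in kept),
        "detections_pruned": sum(len(t.detections) for t in pruned),
    }
    if counts["detections_in_tracks"] + counts["detections_pruned"] != counts["detections_in"]:
        raise RuntimeError("tracking lost detections — conservation violated")
    _write_meta(out, "track", cfg.hash, counts)
    return counts


def train_default_bundle(cfg: PipelineConfig, seed: int) -> cls_mod.ClassifierBundle:
    """Train both classifier stages on a physics-generated corpus."""
    cam = cfg.camera()
    cc = cfg.data["classifier"]
    truth = syn_mod.generate_labeled_dataset(
        cc["n_train_fall"], cc["n_train_flight"], cc["n_train_insect"],
        seed + 1000, camera=cam,
    )
    table = syn_mod.truth_to_feature_table(truth, cam, seed + 2000)
    bundle = cls_mod.train_object_classifier(table, seed)
    bats = table[table["object_class"] == "bat"]
    cls_mod.train_fate_classifier(bats, seed, bundle=bundle)
    return bundle


def _stage_classify(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    _check_meta(out, "track", cfg.hash)
    tracks = pd.read_csv(out / "tracks.csv")
    bundle = train_default_bundle(cfg, seed)
    cls_mod.save_bundle(bundle, out / "classifier_bundle.pkl")
    classified = cls_mod.classify_tracks(
        bundle, tracks, fatality_threshold=cfg.data["classifier"]["fatality_threshold"]
    )
    classified.to_csv(out / "classified_tracks.csv", index=False)
    counts = {
        "tracks": len(classified),
        "bat_tracks": int((classified["object_class"] == "bat").sum()) if len(classified) else 0,
        "flagged_fatalities": int(classified["is_fatality"].sum()) if len(classified) else 0,
    }
    _write_meta(out, "classify", cfg.hash, counts)
    return counts


def _stage_activity(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    _check_meta(out, "classify", cfg.hash)
    classified = pd.read_csv(out / "classified_tracks.csv")
    dets = pd.read_csv(out / "detections.csv")
    t0 = datetime.fromisoformat(cfg.data["scene"]["t0"])
    bat_det_ids: set[int] = set()
    for _, row in classified[classified.get("object_class", pd.Series(dtype=str)) == "bat"].iterrows():
        bat_det_ids.update(int(x) for x in str(row["detection_ids"]).split(";"))
    bat_dets = dets[dets["detection_id"].isin(bat_det_ids)]
    stamps = [t0 + timedelta(seconds=float(s)) for s in bat_dets["timestamp"]]
    width = timedelta(minutes=cfg.data["activity"]["bin_minutes"])
    bins = activity_mod.bin_activity(
        stamps, width, fps=cfg.camera().fps, start=t0,
    ) if stamps else pd.DataFrame(
        columns=["bin_start", "bin_end", "detections", "bat_seconds", "bat_seconds_display"]
    )
    bins.to_csv(out / "activity.csv", index=False)
    counts = {"bat_detections": int(len(bat_dets)), "bins": int(len(bins))}
    _write_meta(out, "activity", cfg.hash, counts)
    return counts


def _stage_evaluate(cfg: PipelineConfig, out: Path, seed: int) -> dict:
    _check_meta(out, "classify", cfg.hash)
    _check_meta(out, "simulate", cfg.hash)
    classified = pd.read_csv(out / "classified_tracks.csv")
    carc = pd.read_csv(out / "carcasses.csv")
    cam = cfg.camera()
    m = cfg.data["matching"]
    footprint = fov_ground_footprint(cam, near_m=m["near_m"], far_m=m["far_m"])
    t0 = datetime.fromisoformat(cfg.data["scene"]["t0"])
    night = t0.date()
    schedule = OperationalSchedule(start_night=night, end_night=night)
    records = [
        match_mod.CarcassRecord(
            carcass_id=str(r.carcass_id),
            discovered=datetime.fromisoformat(r.iso_discovery),
            location_xy=(float(r.x_m), float(r.y_m)),
            age_min_days=int(r.age_min_days),
            age_max_days=int(r.age_max_days),
            species=str(r.species),
        )
        for r in carc.itertuples()
    ]
    accounting = match_mod.account_carcasses(
        records, {cam.name: footprint}, {cam.name: schedule}
    )
    accounting.to_csv(out / "carcass_accounting.csv", index=False)
    flagged = classified[classified["is_fatality"]] if len(classified) else classified
    rows = []
    for _, r in flagged.iterrows():
        ground = pixel_to_ground(cam, (r["last_x"], r["last_y"]))
        if ground is None:
            continue
        rows.append(
            {
                "track_id": str(int(r["track_id"])),
                "timestamp": t0 + timedelta(seconds=float(r["t_end"])),
                "ground_x": ground[0],
                "ground_y": ground[1],
            }
        )
    flagged_df = pd.DataFrame(rows, columns=["track_id", "timestamp", "ground_x", "ground_y"])
    proceed = [
        rec for rec in records
        if accounting.loc[accounting["carcass_id"] == rec.carcass_id, "disposition"].iloc[0]
        == "proceed"
    ]
    result = match_mod.match_tracks_to_carcasses(
        flagged_df, proceed, spatial_radius_m=m["spatial_radius_m"]
    )
    summary = match_mod.compute_rates(result.mp, result.cfp, result.cn)
    (out / "evaluation.txt").write_text(summary.to_text())
    pd.DataFrame(
        [{
            "MP": summary.mp, "CFP": summary.cfp, "CN": summary.cn,
            "matched_detection_rate": summary.matched_detection_rate_display,
            "camera_missed_detection_rate": summary.camera_missed_detection_rate_display,
            "camera_false_detection_rate": summary.camera_false_detection_rate_display,
        }]
    ).to_csv(out / "evaluation.csv", index=False)
    counts = {
        "carcasses": len(records),
        "flagged_tracks": len(flagged_df),
        "MP": summary.mp, "CFP": summary.cfp, "CN": summary.cn,
    }
    _write_meta(out, "evaluate", cfg.hash, counts)
    return counts


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "track": _stage_track,
    "classify": _stage_classify,
    "activity": _stage_activity,
    "evaluate": _stage_evaluate,
}


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    stages: list[str] | None = None,
    out_dir: str | Path = "battrack_run",
    seed: int | None = None,
) -> dict:
    """Run the requested stages in order; returns the run manifest.

    Each stage is idempotent given identical inputs and configuration.
    The manifest records the config hash, seed, and per-stage record
    counts; it is also written to ``manifest.json`` in the run directory.
    """
    if config is None or isinstance(config, dict):
        config = PipelineConfig(config)
    if stages is None:
        stages = STAGES
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]
    seed = int(config.data["seed"] if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.hash,
        "seed": seed,
        "stages": {},
        "config": config.data,
    }
    for stage in stages:
        with _stage_timer(stage) as timer:
            counts = _STAGE_FUNCS[stage](config, out, seed)
        manifest["stages"][stage] = {"counts": counts, "wall_s": round(timer.wall, 3)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("tiny", "demo", "edge-cases")


def make_fixture(profile: str, seed: int, out_dir: str | Path | None = None) -> dict:
    """Deterministic miniature datasets for tests and demos.

    ``tiny``: a 15 s scene (<= 1000 frames) with one of each object class.
    ``demo``: a short synthetic night slice with several objects.
    ``edge-cases``: carcass records engineered to land one in each
    pre-matching exclusion category (outside FOV, occluded, outage) plus
    matchable ones. Same seed -> identical bundles.
    """
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown fixture profile '{profile}'; choose from {FIXTURE_PROFILES}")
    if profile == "tiny":
        overrides = {"seed": seed, "scene": {"n_fall": 1, "n_flight": 1, "n_insect": 1}}
    elif profile == "demo":
        overrides = {"seed": seed, "scene": {"n_fall": 3, "n_flight": 5, "n_insect": 4}}
    else:
        overrides = {"seed": seed, "scene": {"n_fall": 2, "n_flight": 2, "n_insect": 1}}
    cfg = PipelineConfig(overrides)
    cam = cfg.camera()
    sc = cfg.data["scene"]
    truth = syn_mod.generate_labeled_dataset(
        sc["n_fall"], sc["n_flight"], sc["n_insect"], seed, camera=cam
    )
    bundle = {
        "profile": profile,
        "config": cfg,
        "truth": truth,
        "camera": cam,
    }
    if profile == "edge-cases":
        bundle["carcasses"] = _edge_case_records(cam, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.label_table().to_csv(out / "labels.csv", index=False)
        if "carcasses" in bundle:
            pd.DataFrame(
                [
                    {
                        "carcass_id": r.carcass_id,
                        "iso_discovery": r.discovered.isoformat(),
                        "x_m": r.location_xy[0],
                        "y_m": r.location_xy[1],
                        "age_min_days": r.age_min_days,
                        "age_max_days": r.age_max_days,
                        "species": r.species or "",
                    }
                    for r in bundle["carcasses"]
                ]
            ).to_csv(out / "carcasses.csv", index=False)
    return bundle


def _edge_case_records(cam: CameraModel, cfg: PipelineConfig) -> list:
    """One carcass per exclusion category plus one matchable record."""
    in_outage = datetime(2022, 8, 20, 9, 0)   # night of Aug 19: logged outage
    clear = datetime(2022, 9, 10, 9, 0)       # night of Sep 9: fully recorded
    return [
        # far east: no footprint reaches it
        match_mod.CarcassRecord("edge_outside", clear, (200.0, 0.0), 0, 0),
        # at the tower base: inside the occlusion shadow
        match_mod.CarcassRecord("edge_occluded", clear, (0.5, 0.0), 0, 0),
        # in view, but its whole window sits inside a logged outage
        match_mod.CarcassRecord("edge_outage", in_outage, (5.0, -40.0), 0, 0),
        # ordinary in-view carcass that proceeds to matching
        match_mod.CarcassRecord("edge_match", clear, (-5.0, -30.0), 0, 0),
    ]


def study_accounting_fixture(seed: int = 0):
    """Carcass-accounting fixture mirroring a full field season's dispositions.

    Builds the two-camera layout plus 40 carcass records engineered so the
    geometry/schedule accounting produces 10 outside-FOV, 2 occluded and 2
    outage records, and supplies flagged fatality tracks eligible for all
    but 3 of the remaining carcasses. Returns
    ``(records, footprints, schedules, flagged_tracks)``; running
    ``account_carcasses`` then ``match_tracks_to_carcasses`` on it exercises
    the full disposition accounting with known expected counts.
    """
    from datetime import time as _time

    from .geometry import default_camera_pair

    rng = np.random.default_rng(seed)
    north, south = default_camera_pair()
    footprints = {
        cam.name: fov_ground_footprint(cam, near_m=5.0, far_m=100.0)
        for cam in (north, south)
    }
    season = dict(start_night=datetime(2022, 7, 15).date(),
                  end_night=datetime(2022, 10, 31).date())
    outage = (datetime(2022, 8, 12, 19, 30), datetime(2022, 8, 29, 7, 0))
    schedules = {
        "north": OperationalSchedule(**season, outages=(outage,)),
        "south": OperationalSchedule(**season),
    }
    records = []
    k = 0
    # 10 outside any footprint (east/west of the monitored rectangle)
    for i in range(10):
        x = 70.0 + 5.0 * rng.uniform() if i % 2 == 0 else -70.0 - 5.0 * rng.uniform()
        records.append(
            match_mod.CarcassRecord(
                f"c{k:02d}", datetime(2022, 9, 1 + i, 9, 0), (x, rng.uniform(-20, 20)),
                0, 1,
            )
        )
        k += 1
    # 2 hidden at the tower base (inside every camera's occlusion shadow)
    for dx, dy in ((0.6, 0.4), (-0.8, -0.3)):
        records.append(
            match_mod.CarcassRecord(
                f"c{k:02d}", datetime(2022, 9, 12, 9, 0), (dx, dy), 0, 1
            )
        )
        k += 1
    # 2 in the north-only strip, whole fatality window inside the outage
    for dx in (5.0, -8.0):
        records.append(
            match_mod.CarcassRecord(
                f"c{k:02d}", datetime(2022, 8, 20, 9, 0), (dx, 40.0), 0, 1
            )
        )
        k += 1
    # 26 well inside the overlap zone on operational nights
    plain = []
    for i in range(26):
        loc = (float(rng.uniform(-25, 25)), float(rng.uniform(-20, 20)))
        rec = match_mod.CarcassRecord(
            f"c{k:02d}", datetime(2022, 9, 1, 9, 0) + timedelta(days=int(i % 20)),
            loc, 0, 0,
        )
        records.append(rec)
        plain.append(rec)
        k += 1
    # flagged fatality tracks for all but the last 3 in-view carcasses
    rows = []
    for j, rec in enumerate(plain[:-3]):
        night = rec.discovered.date() - timedelta(days=1)
        rows.append(
            {
                "track_id": f"t{j:02d}",
                "timestamp": datetime.combine(night, _time(23, 0)),
                "ground_x": rec.location_xy[0] + float(rng.uniform(-3, 3)),
                "ground_y": rec.location_xy[1] + float(rng.uniform(-3, 3)),
            }
        )
    flagged = pd.DataFrame(rows, columns=["track_id", "timestamp", "ground_x", "ground_y"])
    return records, footprints, schedules, flagged
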