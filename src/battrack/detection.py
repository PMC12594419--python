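"""Warm-object detection: dynamic background model, frame differencing, blobs.

The detector maintains per-pixel running mean and variance of the thermal
stream (exponential moving average after a cumulative-average warmup). A
pixel is foreground when its deviation from the background mean exceeds
``threshold_k`` local noise standard deviations; 8-connected foreground
components of at least ``min_area`` pixels become detections carrying
centroid, area, principal-axis extents and mean intensity. Composite images
summarize all detections in a time window as a maximum-intensity projection
over the background, mirroring the review images human analysts scan in
place of raw video.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "BackgroundModel",
    "Detection",
    "DetectionConfig",
    "update_background",
    "detect_frame",
    "run_detector",
    "composite_image",
    "detections_to_frame",
]

VAR_EPS = 1e-6  # variance floor: avoids dead-pixel divisions


@dataclass
class DetectionConfig:
    threshold_k: float = 4.0      # foreground threshold in noise-SD units
    min_area: int = 2             # pixels
    learning_rate: float = 0.05   # EMA weight of the newest frame
    warmup_frames: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.threshold_k <= 0 or self.min_area < 1 or self.warmup_frames < 1:
            raise ValueError("invalid detection config")


@dataclass
class BackgroundModel:
    """Per-pixel Gaussian background: running mean and variance."""

    shape: tuple[int, int]
    learning_rate: float = 0.05
    warmup_frames: int = 30
    mean: np.ndarray = field(init=False)
    var: np.ndarray = field(init=False)
    n_seen: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        self.mean = np.zeros(self.shape, dtype=np.float64)
        self.var = np.zeros(self.shape, dtype=np.float64)

    @property
    def warmed_up(self) -> bool:
        return self.n_seen >= self.warmup_frames


def update_background(
    model: BackgroundModel,
    frame: np.ndarray,
    freeze_mask: np.ndarray | None = None,
) -> BackgroundModel:
    """Fold one frame into the model (in place; returns the model).

    During warmup, straight cumulative mean/variance; afterwards an
    exponential moving average with the configured learning rate. A
    learning rate of 1 makes the model track the latest frame exactly.
    Pixels where ``freeze_mask`` is True keep their statistics — used to
    stop detected foreground from contaminating the background (a warm
    object lingering on a pixel would otherwise inflate its variance and
    raise the local detection threshold).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != model.shape:
        raise ValueError(f"frame shape {frame.shape} != model shape {model.shape}")
    n = model.n_seen
    if freeze_mask is not None:
        frozen_mean = model.mean[freeze_mask]
        frozen_var = model.var[freeze_mask]
    if n < model.warmup_frames and model.learning_rate < 1:
        # cumulative (Welford) updates
        new_mean = model.mean + (frame - model.mean) / (n + 1)
        model.var = (n * model.var + (frame - model.mean) * (frame - new_mean)) / (n + 1)
        model.mean = new_mean
    else:
        lr = model.learning_rate
        diff = frame - model.mean
        model.mean = model.mean + lr * diff
        model.var = (1 - lr) * (model.var + lr * diff * diff)
    if freeze_mask is not None:
        model.mean[freeze_mask] = frozen_mean
        model.var[freeze_mask] = frozen_var
    model.n_seen = n + 1
    return model


@dataclass
class Detection:
    """One warm-object observation in one frame."""

    detection_id: int
    frame_index: int
    timestamp_s: float
    centroid_px: tuple[float, float]   # (x, y), intensity-weighted
    area_px: int
    width_px: float                    # minor principal-axis extent
    length_px: float                   # major principal-axis extent (>= width)
    mean_intensity: float
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # (y0, x0, y1, x1)
    mask: np.ndarray | None = None     # component mask within bbox
    pixels: np.ndarray | None = None   # frame values within bbox (for composites)


def _principal_extents(coords: np.ndarray) -> tuple[float, float]:
    """(length, width): pixel-coordinate extents along principal axes."""
    pts = coords.astype(float)
    if len(pts) == 1:
        return 1.0, 1.0
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs  # columns ordered by ascending eigenvalue
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0
    width, length = float(extents[0]), float(extents[1])
    return (length, width) if length >= width else (width, length)


def detect_frame(
    model: BackgroundModel,
    frame: np.ndarray,
    threshold_k: float = 4.0,
    min_area: int = 2,
    frame_index: int = 0,
    timestamp_s: float = 0.0,
    start_id: int = 0,
    keep_pixels: bool = True,
) -> list[Detection]:
    """Extract foreground blobs from one frame against the background model.

    Foreground mask: |frame - mean| > threshold_k * sqrt(var + eps). The
    centroid is intensity-weighted by the absolute deviation; width/length
    are extents along the component's principal axes. Raises if the model
    has not completed warmup.
    """
    if not model.warmed_up:
        raise RuntimeError(
            f"background model needs {model.warmup_frames} warmup frames, saw {model.n_seen}"
        )
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != model.shape:
        raise ValueError("frame shape mismatch")
    deviation = np.abs(frame - model.mean)
    mask = deviation > threshold_k * np.sqrt(model.var + VAR_EPS)
    labels = measure.label(mask, connectivity=2)
    detections: list[Detection] = []
    det_id = start_id
    for region in measure.regionprops(labels, intensity_image=deviation):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        length, width = _principal_extents(region.coords)
        y0, x0, y1, x1 = region.bbox
        detections.append(
            Detection(
                detection_id=det_id,
                frame_index=frame_index,
                timestamp_s=timestamp_s,
                centroid_px=(float(cx), float(cy)),
                area_px=int(region.area),
                width_px=width,
                length_px=length,
                mean_intensity=float(frame[region.slice][region.image].mean()),
                bbox=(y0, x0, y1, x1),
                mask=region.image.copy() if keep_pixels else None,
                pixels=frame[region.slice].copy() if keep_pixels else None,
            )
        )
        det_id += 1
    return detections


def run_detector(
    frames: np.ndarray,
    config: DetectionConfig | None = None,
    fps: float = 30.0,
    keep_pixels: bool = False,
) -> tuple[list[Detection], BackgroundModel]:
    """Run background learning + detection over a (T, H, W) frame stack.

    The first ``warmup_frames`` frames only train the background; detection
    starts afterwards (the background keeps adapting). Deterministic:
    identical stacks and config give identical detection tables.
    """
    if config is None:
        config = DetectionConfig()
    model = BackgroundModel(
        shape=frames.shape[1:],
        learning_rate=config.learning_rate,
        warmup_frames=config.warmup_frames,
    )
    detections: list[Detection] = []
    next_id = 0
    for i, frame in enumerate(frames):
        freeze = None
        if model.warmed_up:
            dets = detect_frame(
                model, frame, config.threshold_k, config.min_area,
                frame_index=i, timestamp_s=i / fps, start_id=next_id,
                keep_pixels=keep_pixels,
            )
            detections.extend(dets)
            next_id += len(dets)
            # shield detected blobs (slightly dilated) from the background
            fg = np.abs(np.asarray(frame, float) - model.mean) > (
                config.threshold_k * np.sqrt(model.var + VAR_EPS)
            )
            freeze = ndimage.binary_dilation(fg, iterations=1)
        update_background(model, frame, freeze_mask=freeze)
    return detections, model


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Flatten detections to the CSV schema used by downstream stages."""
    rows = [
        {
            "detection_id": d.detection_id,
            "frame_index": d.frame_index,
            "timestamp": d.timestamp_s,
            "x": d.centroid_px[0],
            "y": d.centroid_px[1],
            "area": d.area_px,
            "width": d.width_px,
            "length": d.length_px,
            "mean_intensity": d.mean_intensity,
        }
        for d in detections
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "detection_id", "frame_index", "timestamp", "x", "y",
            "area", "width", "length", "mean_intensity",
        ],
    )


def composite_image(
    background: np.ndarray,
    detections: list[Detection],
    mark_centroids: bool = True,
    marker_value: float | None = None,
) -> np.ndarray:
    """Maximum-intensity projection of detection pixels over the background.

    Detections must carry their pixel patches (``keep_pixels=True`` at
    detection time). An empty window returns the background unchanged.
    Composites of concatenated windows equal the pixelwise max of the
    windows' composites (max is associative), so review periods can be
    re-binned freely; the study reviewed 5- or 10-minute composites.
    """
    comp = np.array(background, dtype=np.float64, copy=True)
    for det in detections:
        if det.pixels is None or det.mask is None:
            raise ValueError(
                f"detection {det.detection_id} lacks pixel data; "
                "run detection with keep_pixels=True"
            )
        y0, x0, y1, x1 = det.bbox
        patch = comp[y0:y1, x0:x1]
        comp[y0:y1, x0:x1] = np.where(det.mask, np.maximum(patch, det.pixels), patch)
    if mark_centroids and detections:
        mv = marker_value if marker_value is not None else float(comp.max())
        h, w = comp.shape
        for det in detections:
            x, y = int(round(det.centroid_px[0])), int(round(det.centroid_px[1]))
            if 0 <= y < h and 0 <= x < w:
                comp[y, x] = mv
    return comp
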