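"""Shared fixtures: a small camera, labeled corpora, trained classifiers.

Everything is generated programmatically and seeded; session scope keeps
the expensive pieces (corpus generation, classifier training) to one run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import battrack as bt


@pytest.fixture(scope="session")
def small_camera() -> bt.CameraModel:
    """Reduced-resolution camera: same optics/geometry, faster rendering."""
    return bt.CameraModel(resolution_px=(320, 240))


@pytest.fixture(scope="session")
def training_table(small_camera) -> pd.DataFrame:
    """Labeled track-feature corpus from physics-simulated objects."""
    truth = bt.generate_labeled_dataset(150, 150, 150, seed=101, camera=small_camera)
    return bt.truth_to_feature_table(truth, small_camera, seed=102)


@pytest.fixture(scope="session")
def trained_bundle(training_table) -> bt.ClassifierBundle:
    bundle = bt.train_object_classifier(training_table, seed=1)
    bats = training_table[training_table["object_class"] == "bat"]
    bt.train_fate_classifier(bats, seed=1, bundle=bundle)
    return bundle


@pytest.fixture(scope="session")
def rendered_scene(small_camera):
    """One rendered mixed scene (2 falls, 2 flights, 2 insects) + truth."""
    truth = bt.generate_labeled_dataset(2, 2, 2, seed=3, camera=small_camera)
    frames, timestamps = bt.render_frames(truth, small_camera, seed=5)
    return truth, frames, timestamps


@pytest.fixture(scope="session")
def detected_scene(small_camera, rendered_scene):
    truth, frames, _ = rendered_scene
    detections, model = bt.run_detector(
        frames, bt.DetectionConfig(), fps=small_camera.fps, keep_pixels=True
    )
    return truth, detections, model
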