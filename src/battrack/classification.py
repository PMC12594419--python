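"""Two-stage track classification: object class, then activity vs fatality.

Stage one labels every track as bat or insect (extendable to bird/blade/
other) from its kinematic and size features. Stage two runs only on bat
tracks and separates ordinary flight activity from fatality falls — a rare
event, so the training set is augmented with physics-simulated fall tracks.
Both stages use seeded random-forest classifiers behind a feature-scaling
pipeline; the fitted pair travels as a :class:`ClassifierBundle` whose
metadata records everything needed to retrain reproducibly.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .tracking import FEATURE_NAMES

__all__ = [
    "ClassifierBundle",
    "train_object_classifier",
    "train_fate_classifier",
    "classify_tracks",
    "save_bundle",
    "load_bundle",
]

BUNDLE_VERSION = 1
MIN_PER_CLASS = 20
DEFAULT_FATALITY_THRESHOLD = 0.5

OBJECT_CLASSES = ("bat", "insect", "bird", "blade", "other")
FATE_CLASSES = ("activity", "fatality", "not_applicable")


@dataclass
class ClassifierBundle:
    """Fitted object-class and fate models plus training metadata."""

    object_model: Pipeline | None = None
    fate_model: Pipeline | None = None
    feature_names: tuple[str, ...] = tuple(FEATURE_NAMES)
    metadata: dict = field(default_factory=dict)

    def require(self, which: str) -> Pipeline:
        model = getattr(self, f"{which}_model")
        if model is None:
            raise RuntimeError(f"{which} classifier has not been trained")
        return model


def _feature_matrix(table: pd.DataFrame, feature_names) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}")
    X = table.loc[:, list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def _make_model(seed: int, class_weight=None) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "forest",
                RandomForestClassifier(
                    n_estimators=200,
                    random_state=seed,
                    class_weight=class_weight,
                    n_jobs=1,
                ),
            ),
        ]
    )


def _train(
    table: pd.DataFrame,
    label_col: str,
    seed: int,
    feature_names,
    min_per_class: int,
    class_weight=None,
    holdout_fraction: float = 0.25,
) -> tuple[Pipeline, dict]:
    labels = table[label_col].astype(str)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"need at least 2 classes to train, got {list(counts.index)}; "
            "generate more synthetic classes or relabel"
        )
    thin = counts[counts < min_per_class]
    if len(thin):
        raise ValueError(
            f"classes below the {min_per_class}-example minimum: "
            f"{thin.to_dict()}; generate more labeled tracks"
        )
    X = _feature_matrix(table, feature_names)
    y = labels.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    model = _make_model(seed, class_weight=class_weight)
    model.fit(X_tr, y_tr)
    acc = float(np.mean(model.predict(X_te) == y_te))
    meta = {
        "seed": seed,
        "class_counts": counts.to_dict(),
        "holdout_accuracy": acc,
        "n_train": len(y_tr),
        "n_holdout": len(y_te),
    }
    return model, meta


def train_object_classifier(
    labeled: pd.DataFrame,
    seed: int,
    bundle: ClassifierBundle | None = None,
    min_per_class: int = MIN_PER_CLASS,
) -> ClassifierBundle:
    """Fit the bat/insect/other stage on a labeled feature table.

    ``labeled`` needs the track feature columns plus ``object_class``.
    Stratified held-out accuracy is recorded in the bundle metadata.
    """
    if bundle is None:
        bundle = ClassifierBundle()
    model, meta = _train(
        labeled, "object_class", seed, bundle.feature_names, min_per_class
    )
    bundle.object_model = model
    bundle.metadata["object"] = meta
    bundle.metadata["version"] = BUNDLE_VERSION
    bundle.metadata["feature_names"] = list(bundle.feature_names)
    return bundle


def train_fate_classifier(
    labeled_bats: pd.DataFrame,
    seed: int,
    bundle: ClassifierBundle | None = None,
    min_per_class: int = MIN_PER_CLASS,
) -> ClassifierBundle:
    """Fit the activity-vs-fatality stage on bat tracks.

    Fatalities are rare in real data, so the caller typically mixes
    physics-simulated fall tracks with flight-derived activity tracks;
    class weighting compensates for any residual imbalance.
    """
    if bundle is None:
        bundle = ClassifierBundle()
    rows = labeled_bats[labeled_bats["fate_class"].isin(["activity", "fatality"])]
    for cls in ("activity", "fatality"):
        if (rows["fate_class"] == cls).sum() == 0:
            raise ValueError(
                f"fate class '{cls}' absent from training data; "
                "simulate falls (fatality) and flights (activity) to supply it"
            )
    model, meta = _train(
        rows, "fate_class", seed, bundle.feature_names, min_per_class,
        class_weight="balanced",
    )
    bundle.fate_model = model
    bundle.metadata["fate"] = meta
    bundle.metadata["version"] = BUNDLE_VERSION
    bundle.metadata["feature_names"] = list(bundle.feature_names)
    return bundle


def classify_tracks(
    bundle: ClassifierBundle,
    features: pd.DataFrame,
    fatality_threshold: float = DEFAULT_FATALITY_THRESHOLD,
) -> pd.DataFrame:
    """Assign object_class to every track and fate_class to bat tracks.

    Returns a copy of ``features`` with ``object_class``, ``object_score``,
    ``fate_class``, ``fatality_score`` and ``is_fatality`` columns. The
    fatality flag fires when the fatality probability reaches
    ``fatality_threshold``; raising the threshold can only reduce flags
    (threshold 1.0 suppresses probabilities strictly below 1).
    """
    if not (0.0 <= fatality_threshold <= 1.0):
        raise ValueError("fatality_threshold must be in [0, 1]")
    out = features.copy()
    if len(out) == 0:
        for col, val in (
            ("object_class", ""), ("object_score", np.nan),
            ("fate_class", "not_applicable"), ("fatality_score", np.nan),
            ("is_fatality", False),
        ):
            out[col] = pd.Series([], dtype=type(val) if val != "" else str)
        return out
    obj_model = bundle.require("object")
    X = _feature_matrix(out, bundle.feature_names)
    obj_pred = obj_model.predict(X)
    obj_proba = obj_model.predict_proba(X).max(axis=1)
    out["object_class"] = obj_pred
    out["object_score"] = obj_proba
    out["fate_class"] = "not_applicable"
    out["fatality_score"] = np.nan
    out["is_fatality"] = False
    is_bat = out["object_class"] == "bat"
    if is_bat.any():
        fate_model = bundle.require("fate")
        classes = list(fate_model.classes_)
        fat_idx = classes.index("fatality")
        proba = fate_model.predict_proba(X[is_bat.to_numpy()])[:, fat_idx]
        if fatality_threshold < 1.0:
            flagged = proba >= fatality_threshold
        else:  # threshold 1.0 disables flagging entirely
            flagged = np.zeros(len(proba), dtype=bool)
        out.loc[is_bat, "fatality_score"] = proba
        out.loc[is_bat, "fate_class"] = np.where(flagged, "fatality", "activity")
        out.loc[is_bat, "is_fatality"] = flagged
    return out


def save_bundle(bundle: ClassifierBundle, path: str | Path) -> None:
    """Persist the fitted bundle (models + metadata) to disk."""
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)


def load_bundle(path: str | Path) -> ClassifierBundle:
    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    if not isinstance(bundle, ClassifierBundle):
        raise ValueError(f"{path} does not contain a classifier bundle")
    return bundle
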