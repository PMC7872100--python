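"""Two-stage phenotype classification (the combined workflow).

Stage one is supervised pixel classification on the intensity-summary (sum)
projection of the edge stack, separating background from object outlines;
thresholding the outline-probability map yields the mask handed to particle
analysis.  Stage two classifies each segmented object from features measured
on the minimum projection (plus the outline map) into one of eight phenotype
classes.  Both stages use seeded random-forest ensembles (100 trees), which
keeps the workflow reproducible and trainable from sparse annotations.

Exclusion policy: background-mislabeled, air-bubble, and plate-edge objects
are discarded at every timepoint; debris and clusters are additionally
discarded from 72 h onward, when genuine organoids dominate those classes'
size range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import structure_tensor, structure_tensor_eigenvalues
from sklearn.ensemble import RandomForestClassifier

from .stacks import Projection

__all__ = [
    "ObjectClass",
    "ALWAYS_EXCLUDED",
    "LATE_EXCLUDED",
    "LATE_EXCLUSION_START_H",
    "PixelModel",
    "ObjectModel",
    "DEFAULT_PIXEL_SCALES",
    "OBJECT_FEATURES",
    "compute_pixel_features",
    "train_pixel_classifier",
    "predict_pixel_map",
    "object_feature_table",
    "train_object_classifier",
    "classify_objects",
    "apply_exclusions",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ObjectClass(str, Enum):
    """The eight phenotype label classes used for object classification."""

    ORGANOID = "organoid"
    BIG_SPHERE = "big_sphere"
    SMALL_SPHERE = "small_sphere"
    CLUSTER = "cluster"
    DEBRIS = "debris"
    BACKGROUND_MISLABELED = "background_mislabeled"
    AIR_BUBBLE = "air_bubble"
    PLATE_EDGE = "plate_edge"


#: Classes excluded at every timepoint.
ALWAYS_EXCLUDED = frozenset(
    {ObjectClass.BACKGROUND_MISLABELED, ObjectClass.AIR_BUBBLE, ObjectClass.PLATE_EDGE}
)
#: Classes additionally excluded at late timepoints.
LATE_EXCLUDED = frozenset({ObjectClass.DEBRIS, ObjectClass.CLUSTER})
#: Inclusive hour from which the late exclusions apply (72-96 h window).
LATE_EXCLUSION_START_H = 72.0

# Two fine scales: coarser sigmas smear the outline response across the gap
# between adjacent objects and merge them after hole filling.
DEFAULT_PIXEL_SCALES = (1.0, 2.0)

#: Object features the second-stage classifier consumes.
OBJECT_FEATURES = (
    "area_px",
    "mean_gray",
    "sd_gray",
    "perimeter_px",
    "circularity",
    "solidity",
    "mean_outline_prob",
)

PIXEL_CLASS_BACKGROUND = 1
PIXEL_CLASS_OUTLINE = 2


@dataclass
class PixelModel:
    """Trained stage-one pixel classifier (background vs object outline)."""

    scales: tuple
    classifier: RandomForestClassifier
    seed: int
    feature_names: tuple = ()


@dataclass
class ObjectModel:
    """Trained stage-two object classifier over a subset of the eight classes."""

    feature_names: tuple
    classes: tuple
    classifier: RandomForestClassifier | None
    seed: int
    single_class: str | None = None


def compute_pixel_features(image: Projection | np.ndarray, scales: Sequence[float]) -> np.ndarray:
    """Per-pixel filter bank: at each scale sigma, Gaussian-smoothed intensity,
    gradient magnitude, Laplacian, and the two structure-tensor eigenvalues.

    Returns an ``(H, W, 5 * n_scales)`` array.
    """
    img = image.pixels if isinstance(image, Projection) else np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("pixel features require a 2-D image")
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    planes = []
    for s in scales:
        planes.append(ndimage.gaussian_filter(img, s))
        planes.append(ndimage.gaussian_gradient_magnitude(img, s))
        planes.append(ndimage.gaussian_laplace(img, s))
        tensor = structure_tensor(img, sigma=s, order="rc", mode="reflect")
        eigvals = structure_tensor_eigenvalues(tensor)
        planes.append(eigvals[0])
        planes.append(eigvals[1])
    return np.stack(planes, axis=-1)


def _feature_names(scales: Sequence[float]) -> tuple:
    names = []
    for s in scales:
        for base in ("gaussian", "gradient_magnitude", "laplacian", "st_eig1", "st_eig2"):
            names.append(f"{base}_s{s:g}")
    return tuple(names)


def train_pixel_classifier(
    image: Projection | np.ndarray,
    annotations: np.ndarray,
    scales: Sequence[float] = DEFAULT_PIXEL_SCALES,
    seed: int = 0,
    n_estimators: int = 100,
) -> PixelModel:
    """Train the background/outline pixel classifier from sparse annotations.

    ``annotations`` is an integer image: 0 unlabeled, 1 background,
    2 object outline.  Both classes need at least one annotated pixel
    overall.  Lists of images with matching annotation images are pooled
    into one training set.  Training images must not re-enter downstream
    evaluation.
    """
    images = image if isinstance(image, (list, tuple)) else [image]
    annotation_list = (
        annotations if isinstance(annotations, (list, tuple)) else [annotations]
    )
    if len(images) != len(annotation_list):
        raise ValueError("need one annotation image per input image")
    X_parts, y_parts = [], []
    for img, ann in zip(images, annotation_list):
        ann = np.asarray(ann)
        features = compute_pixel_features(img, scales)
        if ann.shape != features.shape[:2]:
            raise ValueError("annotation image shape does not match the input image")
        labeled = ann > 0
        X_parts.append(features[labeled])
        y_parts.append(ann[labeled])
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)
    present = set(np.unique(y).tolist())
    for cls, name in ((PIXEL_CLASS_BACKGROUND, "background"), (PIXEL_CLASS_OUTLINE, "object_outline")):
        if cls not in present:
            raise ValueError(f"no annotated pixels for class {name!r}")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=int(seed), n_jobs=1)
    clf.fit(X, y)
    return PixelModel(
        scales=tuple(float(s) for s in scales),
        classifier=clf,
        seed=int(seed),
        feature_names=_feature_names(scales),
    )


def predict_pixel_map(model: PixelModel, image: Projection | np.ndarray) -> np.ndarray:
    """Per-pixel object-outline probability in [0, 1] (deterministic)."""
    features = compute_pixel_features(image, model.scales)
    h, w, k = features.shape
    proba = model.classifier.predict_proba(features.reshape(-1, k))
    outline_col = list(model.classifier.classes_).index(PIXEL_CLASS_OUTLINE)
    return proba[:, outline_col].reshape(h, w)


def object_feature_table(
    records_frame: pd.DataFrame,
    labeled_pixels: np.ndarray | None = None,
    outline_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the stage-two feature table from measured object records.

    ``mean_outline_prob`` is averaged per object from the stage-one map when
    the labeled mask and map are given; otherwise it is filled with 0.5 so
    the simple workflow can reuse object models trained without it.
    """
    features = records_frame[
        ["area_px", "mean_gray", "sd_gray", "perimeter_px", "circularity", "solidity"]
    ].copy()
    if labeled_pixels is not None and outline_map is not None:
        labeled_pixels = np.asarray(labeled_pixels)
        means = ndimage.mean(
            outline_map, labels=labeled_pixels, index=records_frame["object_id"].to_numpy()
        )
        features["mean_outline_prob"] = np.asarray(means, dtype=float)
    else:
        features["mean_outline_prob"] = 0.5
    features.index = records_frame.index
    return features


def _check_features(features: pd.DataFrame) -> None:
    for name in features.columns:
        if features[name].isna().any():
            raise ValueError(f"feature {name!r} contains missing values")


def train_object_classifier(
    features: pd.DataFrame,
    labels: Sequence[str | ObjectClass],
    seed: int = 0,
    n_estimators: int = 100,
) -> ObjectModel:
    """Train the object phenotype classifier on measured features.

    ``labels`` may cover any subset of the eight classes; a single-class
    training set yields a degenerate model that always predicts that class
    (warned).  Missing feature values raise, naming the feature.
    """
    labels = [ObjectClass(l).value for l in labels]
    if len(labels) == 0:
        raise ValueError("empty label set")
    if len(labels) != len(features):
        raise ValueError("labels and feature rows differ in length")
    _check_features(features)
    classes = tuple(sorted(set(labels)))
    if len(classes) == 1:
        warnings.warn(
            f"training labels contain the single class {classes[0]!r}; "
            "the model will always predict it",
            stacklevel=2,
        )
        return ObjectModel(
            feature_names=tuple(features.columns),
            classes=classes,
            classifier=None,
            seed=int(seed),
            single_class=classes[0],
        )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=int(seed), n_jobs=1)
    clf.fit(features.to_numpy(dtype=float), labels)
    return ObjectModel(
        feature_names=tuple(features.columns),
        classes=classes,
        classifier=clf,
        seed=int(seed),
    )


def classify_objects(model: ObjectModel, features: pd.DataFrame) -> pd.DataFrame:
    """Assign one phenotype class plus class probabilities to every object.

    Returns a frame indexed like ``features`` with a ``predicted_class``
    column and one ``prob_<class>`` column per trained class.
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing model features: {missing}")
    out = pd.DataFrame(index=features.index)
    if len(features) == 0:
        out["predicted_class"] = pd.Series(dtype=str)
        for cls in model.classes:
            out[f"prob_{cls}"] = pd.Series(dtype=float)
        return out
    X = features[list(model.feature_names)]
    _check_features(X)
    if model.single_class is not None:
        out["predicted_class"] = model.single_class
        out[f"prob_{model.single_class}"] = 1.0
        return out
    proba = model.classifier.predict_proba(X.to_numpy(dtype=float))
    order = list(model.classifier.classes_)
    out["predicted_class"] = [order[i] for i in np.argmax(proba, axis=1)]
    for j, cls in enumerate(order):
        out[f"prob_{cls}"] = proba[:, j]
    return out


def apply_exclusions(objects: pd.DataFrame, timepoint_h: float | None = None) -> pd.DataFrame:
    """Drop excluded phenotype classes according to the timepoint policy.

    Background-mislabeled, air-bubble, and plate-edge objects are removed at
    every timepoint; debris and cluster objects are removed from
    ``LATE_EXCLUSION_START_H`` (inclusive) onward.  If ``timepoint_h`` is
    None, each row's own ``timepoint_h`` column is used.
    """
    if "predicted_class" not in objects.columns:
        raise ValueError("objects frame has no predicted_class column")
    always = {c.value for c in ALWAYS_EXCLUDED}
    late = {c.value for c in LATE_EXCLUDED}
    cls = objects["predicted_class"]
    if timepoint_h is None:
        if "timepoint_h" not in objects.columns:
            raise ValueError("timepoint_h column required when timepoint_h is not given")
        t = objects["timepoint_h"].astype(float)
    else:
        t = pd.Series(float(timepoint_h), index=objects.index)
    keep = ~cls.isin(always) & ~(cls.isin(late) & (t >= LATE_EXCLUSION_START_H))
    return objects[keep]


def save_model(model: PixelModel | ObjectModel, path: str | Path) -> None:
    """Serialize a trained model to a single versioned file."""
    kind = "pixel" if isinstance(model, PixelModel) else "object"
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "kind": kind, "model": model}, path)


def load_model(path: str | Path) -> PixelModel | ObjectModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version in {path}")
    return payload["model"]
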