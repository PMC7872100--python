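"""Training helpers: derive classifier training data from ground truth.

The interactive step of the combined workflow — a user sparsely painting
background/outline pixels and labeling example objects — is emulated here
from synthetic-scene ground truth, so end-to-end training and evaluation can
run unattended.  The resulting models are ordinary :mod:`organoscreen.phenotype`
models; nothing downstream distinguishes them from interactively trained
ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .phenotype import (
    DEFAULT_PIXEL_SCALES,
    ObjectClass,
    ObjectModel,
    PixelModel,
    object_feature_table,
    train_object_classifier,
    train_pixel_classifier,
)
from .pipeline import RunConfig, quantify_stack
from .stacks import project, sobel_edges
from .synth import GroundTruth

__all__ = [
    "pixel_annotations_from_truth",
    "match_objects_to_truth",
    "train_models_from_scenes",
]


def pixel_annotations_from_truth(
    truth: GroundTruth,
    rim_width: int = 2,
    n_per_class: int = 1500,
    seed: int = 0,
) -> np.ndarray:
    """Sparse pixel annotations (1 background, 2 outline) from a truth map.

    Outline pixels are sampled from a band of ``rim_width`` around each
    object boundary; background pixels from at least 3 px away from any
    object.  Interior pixels stay unlabeled, as a human annotator would
    leave them.
    """
    rng = np.random.default_rng(seed)
    objects = truth.label_map > 0
    eroded = ndimage.binary_erosion(objects, structure=disk(rim_width))
    outline = objects & ~eroded
    background = ~ndimage.binary_dilation(objects, structure=disk(3))
    annotations = np.zeros(truth.label_map.shape, dtype=np.uint8)
    for value, mask in ((1, background), (2, outline)):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        chosen = rng.choice(idx, size=min(n_per_class, len(idx)), replace=False)
        annotations.flat[chosen] = value
    return annotations


def match_objects_to_truth(labeled_pixels: np.ndarray, truth: GroundTruth) -> list[str]:
    """Assign each segmented object its majority-overlap ground-truth class.

    Objects whose pixels mostly fall on truth background are labeled
    ``background_mislabeled``.
    """
    labeled_pixels = np.asarray(labeled_pixels)
    n = int(labeled_pixels.max())
    class_by_id = {o.object_id: o.object_class for o in truth.objects}
    out = []
    for obj in range(1, n + 1):
        overlap = truth.label_map[labeled_pixels == obj]
        counts = np.bincount(overlap)
        winner = int(np.argmax(counts))
        if winner == 0:
            out.append(ObjectClass.BACKGROUND_MISLABELED.value)
        else:
            out.append(class_by_id[winner])
    return out


def train_models_from_scenes(
    scenes: list[tuple],
    config: RunConfig | None = None,
    scales=DEFAULT_PIXEL_SCALES,
    seed: int = 0,
    n_pixel_scenes: int = 3,
    n_annotations_per_class: int = 1500,
) -> tuple[PixelModel, ObjectModel]:
    """Train both stages of the combined workflow from (stack, truth) scenes.

    The pixel classifier is trained on sparse annotations from the first
    ``n_pixel_scenes`` scenes; every training scene is then segmented in
    combined mode and its objects, labeled by majority truth overlap, train
    the object classifier.  Scenes used here must be excluded from any
    evaluation set.
    """
    if config is None:
        config = RunConfig(mode="combined", min_area_px=50)
    images, annotations = [], []
    for i, (stack, truth) in enumerate(scenes[:n_pixel_scenes]):
        edges = sobel_edges(stack)
        images.append(project(edges, "sum"))
        annotations.append(
            pixel_annotations_from_truth(
                truth, n_per_class=n_annotations_per_class, seed=seed + i
            )
        )
    pixel_model = train_pixel_classifier(images, annotations, scales=scales, seed=seed)

    features_parts, labels = [], []
    for stack, truth in scenes:
        objects, _post, labeled, extras = quantify_stack(
            stack, config, pixel_model=pixel_model, object_model=_passthrough_model()
        )
        feats = object_feature_table(objects, labeled.pixels, extras["pixel_map"])
        features_parts.append(feats)
        labels.extend(match_objects_to_truth(labeled.pixels, truth))
    features = pd.concat(features_parts, ignore_index=True)
    object_model = train_object_classifier(features, labels, seed=seed)
    return pixel_model, object_model


def _passthrough_model() -> ObjectModel:
    """Stand-in object model used while collecting training features."""
    return ObjectModel(
        feature_names=(
            "area_px", "mean_gray", "sd_gray", "perimeter_px",
            "circularity", "solidity", "mean_outline_prob",
        ),
        classes=(ObjectClass.ORGANOID.value,),
        classifier=None,
        seed=0,
        single_class=ObjectClass.ORGANOID.value,
    )
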