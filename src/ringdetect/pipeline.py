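"""End-to-end training and detection (the two-stage cascade).

Training: dense SIFT from all 45x45 query and background patches -> K-means
dictionary -> per-word discriminative capability d(k) from the bag-of-words
histograms -> LLC/max-pooled descriptors -> linear SVM with CV-chosen
regularization.

Detection on a test image: voting-map localization over the scale set ->
min-max normalization and gamma-thresholding -> one candidate box per
retained pixel (sized by the pixel's winning scale) -> greedy NMS -> SVM
classification of each surviving candidate crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bow import build_dictionary, compute_weights, vq_histogram
from .config import DetectorConfig
from .dsift import InvalidInputError, extract_dense
from .identification import (
    build_candidate,
    classify_candidates,
    nms,
    normalize_and_threshold,
    pooled_descriptor,
    train_identifier,
)
from .localization import localize, make_query_patch

logger = logging.getLogger("ringdetect")

__all__ = ["TrainedDetector", "StageCounts", "train_detector", "detect_image"]


@dataclass
class TrainedDetector:
    dictionary: object
    weights: object
    queries: list
    svm: object
    config: DetectorConfig


@dataclass
class StageCounts:
    """Candidate counts through the pipeline; non-increasing by construction."""

    n_thresholded: int = 0
    n_after_nms: int = 0
    n_positive: int = 0


def train_detector(query_patches, background_patches, config: DetectorConfig | None = None):
    """Train both stages from 45x45 query (target) and background patches."""
    config = config or DetectorConfig()
    if len(query_patches) == 0 or len(background_patches) == 0:
        raise InvalidInputError("need non-empty query and background patch sets")
    spec = config.grid_spec

    q_feats = [extract_dense(np.asarray(p, dtype=np.float64), spec) for p in query_patches]
    b_feats = [extract_dense(np.asarray(p, dtype=np.float64), spec) for p in background_patches]
    all_desc = np.vstack([f.descriptors for f in q_feats + b_feats])
    logger.info("training: %d descriptors from %d query + %d background patches",
                all_desc.shape[0], len(q_feats), len(b_feats))

    dictionary = build_dictionary(all_desc, config.K, seed=config.seed)
    q_hists = np.stack([vq_histogram(f, dictionary) for f in q_feats])
    b_hists = np.stack([vq_histogram(f, dictionary) for f in b_feats])
    weights = compute_weights(q_hists, b_hists)

    queries = [make_query_patch(p, dictionary, spec) for p in query_patches]

    pos_desc = np.stack(
        [pooled_descriptor(p, dictionary, spec, config.llc_C) for p in query_patches]
    )
    neg_desc = np.stack(
        [pooled_descriptor(p, dictionary, spec, config.llc_C) for p in background_patches]
    )
    svm = train_identifier(
        pos_desc, neg_desc, c_grid=config.svm_c_grid,
        cv_folds=config.cv_folds, seed=config.seed,
    )
    logger.info("training: SVM chose C = %g", svm.chosen_C)
    return TrainedDetector(
        dictionary=dictionary, weights=weights, queries=queries, svm=svm, config=config
    )


def detect_image(image, detector: TrainedDetector, keep_negative: bool = True):
    """Run the full cascade on one image.

    Returns (detections, counts).  ``keep_negative=False`` drops candidates
    the SVM labels background; otherwise they are returned with their
    (negative) scores so evaluation can sweep thresholds across the label
    boundary.
    """
    config = detector.config
    image = np.asarray(image, dtype=np.float64)
    scales = config.scale_set
    vmap = localize(
        image, detector.queries, detector.dictionary, detector.weights,
        scales, config.grid_spec,
    )
    centers, values = normalize_and_threshold(vmap, config.gamma)
    candidates = [
        build_candidate(
            int(r), int(c), scales[vmap.scale_index[r, c]],
            w=config.patch_w, h=config.patch_h,
            vote_value=v, image_shape=image.shape,
        )
        for (r, c), v in zip(centers, values)
    ]
    kept = nms(
        candidates,
        overlap_threshold=config.nms_threshold,
        containment_threshold=config.nms_containment,
    )
    detections = classify_candidates(
        image, kept, detector.dictionary, detector.svm,
        config.grid_spec, config.llc_C,
        patch_shape=(config.patch_h, config.patch_w),
    )
    counts = StageCounts(
        n_thresholded=len(candidates),
        n_after_nms=len(kept),
        n_positive=sum(d.label for d in detections),
    )
    logger.info("detect: %d thresholded -> %d after NMS -> %d positive",
                counts.n_thresholded, counts.n_after_nms, counts.n_positive)
    if not keep_negative:
        detections = [d for d in detections if d.label]
    return detections, counts
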