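"""Identification stage: LLC patch encoding, linear SVM, candidate boxes, NMS.

A candidate patch is represented by locality-constrained linear coding
(LLC): each dense SIFT descriptor f is encoded as an affine (sum-to-one)
combination of its C nearest visual words, solving

    min_c || f - B_f c ||^2   s.t.  1^T c = 1

in closed form over the local base B_f.  The per-feature codes are
max-pooled component-wise into one K-length descriptor per patch, which a
linear SVM classifies as target vs background.  Candidate boxes come from
the thresholded, [0,1]-normalized voting map: every retained pixel becomes
a box sized by the pixel's winning scale factor (ceil on the min corner,
floor on the max corner); greedy non-maximum suppression keeps the
highest-vote box among mutual overlaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .bow import Dictionary
from .dsift import GridSpec, InvalidInputError, SiftFeatures, extract_dense
from .evaluation import overlap_alpha0
from .localization import VotingMap

__all__ = [
    "LlcCode",
    "SvmModel",
    "Candidate",
    "Detection",
    "SVM_C_GRID",
    "llc_encode",
    "llc_encode_batch",
    "pool_codes",
    "pooled_descriptor",
    "train_identifier",
    "normalize_and_threshold",
    "build_candidate",
    "nms",
    "classify_candidates",
]

#: SVM regularization grid searched by cross-validation: 2^-8 ... 2^8
SVM_C_GRID = tuple(2.0**p for p in range(-8, 9))


@dataclass
class LlcCode:
    """C nearest-word indices and their sum-to-one coefficients."""

    base_indices: np.ndarray
    coefficients: np.ndarray


@dataclass
class SvmModel:
    """Linear decision function score(x) = w . x + b over pooled descriptors."""

    weights: np.ndarray
    bias: float
    chosen_C: float
    cv_folds: int = 5

    def decision_values(self, X) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=np.float64)) @ self.weights + self.bias


@dataclass
class Candidate:
    """Voting-map candidate box with inclusive integer pixel corners."""

    box: tuple  # (x_min, y_min, x_max, y_max); x = row, y = col
    vote_value: float
    center: tuple  # (x_o, y_o)
    scale: float


@dataclass
class Detection:
    """Classified candidate: signed SVM score, label True = target (endosome)."""

    box: tuple
    score: float
    label: bool


def _nearest_base(feature: np.ndarray, words: np.ndarray, C: int) -> np.ndarray:
    """Indices of the C nearest words, distance-then-index ordered (stable)."""
    d2 = np.einsum("kd,kd->k", words - feature, words - feature)
    # stable argsort: equal distances keep ascending index order
    return np.argsort(d2, kind="stable")[:C]


def _solve_llc(feature: np.ndarray, base: np.ndarray, ridge_scale: float = 1e-6) -> np.ndarray:
    """Closed-form solution of the sum-to-one constrained least squares.

    Shifted-covariance system with ridge lambda = ridge_scale * trace / C;
    coefficients renormalized to sum exactly 1.
    """
    C = base.shape[0]
    z = base - feature[None, :]
    G = z @ z.T
    tr = np.trace(G)
    G = G + np.eye(C) * (ridge_scale * tr / C if tr > 0 else ridge_scale)
    try:
        w = np.linalg.solve(G, np.ones(C))
    except np.linalg.LinAlgError:
        w = np.ones(C)
    ssum = w.sum()
    if ssum == 0 or not np.isfinite(ssum):
        w = np.ones(C)
        ssum = float(C)
    return w / ssum


def llc_encode(feature, dictionary: Dictionary, C: int = 5) -> LlcCode:
    """LLC code of one descriptor over its C-word local base."""
    f = np.asarray(feature, dtype=np.float64).ravel()
    if C < 1 or C > dictionary.K:
        raise InvalidInputError(f"C must satisfy 1 <= C <= K (C={C}, K={dictionary.K})")
    if f.shape[0] != dictionary.words.shape[1]:
        raise InvalidInputError("descriptor length does not match dictionary")
    idx = _nearest_base(f, dictionary.words, C)
    if C == 1:
        return LlcCode(base_indices=idx, coefficients=np.array([1.0]))
    coeff = _solve_llc(f, dictionary.words[idx])
    return LlcCode(base_indices=idx, coefficients=coeff)


def llc_encode_batch(features, dictionary: Dictionary, C: int = 5):
    """Vectorized LLC over a feature batch.

    Returns (indices (n, C), coefficients (n, C)); equivalent to calling
    :func:`llc_encode` per row.
    """
    X = features.descriptors if isinstance(features, SiftFeatures) else np.atleast_2d(features)
    n = X.shape[0]
    if C < 1 or C > dictionary.K:
        raise InvalidInputError(f"C must satisfy 1 <= C <= K (C={C}, K={dictionary.K})")
    W = dictionary.words
    d2 = (
        np.einsum("kd,kd->k", W, W)[None, :]
        - 2.0 * (X @ W.T)
        + np.einsum("nd,nd->n", X, X)[:, None]
    )
    idx = np.argsort(d2, axis=1, kind="stable")[:, :C]
    if C == 1:
        return idx, np.ones((n, 1))
    Z = W[idx] - X[:, None, :]  # (n, C, d)
    G = Z @ Z.transpose(0, 2, 1)  # (n, C, C)
    tr = np.einsum("ncc->n", G)
    lam = np.where(tr > 0, 1e-6 * tr / C, 1e-6)
    G = G + lam[:, None, None] * np.eye(C)[None, :, :]
    ones = np.ones((n, C, 1))
    try:
        w = np.linalg.solve(G, ones)[:, :, 0]
    except np.linalg.LinAlgError:  # pragma: no cover - ridge keeps G SPD
        w = np.stack([_solve_llc(X[i], W[idx[i]]) * 1.0 for i in range(n)])
    sums = w.sum(axis=1, keepdims=True)
    bad = (sums == 0) | ~np.isfinite(sums)
    w = np.where(bad, 1.0, w)
    sums = np.where(bad, float(C), sums)
    return idx, w / sums


def pool_codes(codes, K: int) -> np.ndarray:
    """Component-wise max over a patch's LLC codes, then L2-normalized.

    Words never selected by any code stay 0.  Accepts a list of
    :class:`LlcCode` or an (indices, coefficients) array pair.
    """
    if isinstance(codes, tuple):
        idx, coeff = codes
    else:
        if len(codes) == 0:
            raise InvalidInputError("cannot pool an empty code list")
        idx = np.stack([c.base_indices for c in codes])
        coeff = np.stack([c.coefficients for c in codes])
    if idx.size == 0:
        raise InvalidInputError("cannot pool an empty code list")
    pooled = np.full(K, -np.inf)
    np.maximum.at(pooled, idx.ravel(), coeff.ravel())
    pooled[pooled == -np.inf] = 0.0
    norm = np.linalg.norm(pooled)
    return pooled / norm if norm > 0 else pooled


def pooled_descriptor(
    patch, dictionary: Dictionary, spec: GridSpec | None = None, C: int = 5
) -> np.ndarray:
    """Dense SIFT -> LLC -> max-pool pipeline for one patch."""
    feats = extract_dense(np.asarray(patch, dtype=np.float64), spec or GridSpec())
    if len(feats) == 0:
        raise InvalidInputError("patch smaller than one descriptor grid")
    return pool_codes(llc_encode_batch(feats, dictionary, C), dictionary.K)


def train_identifier(
    pos_descriptors,
    neg_descriptors,
    c_grid=SVM_C_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> SvmModel:
    """Train the linear SVM on pooled patch descriptors.

    The regularization parameter is chosen by stratified ``cv_folds``-fold
    cross-validation accuracy over ``c_grid`` (ties to the smallest C); the
    final model is refit on all data.  Deterministic given the seed.
    """
    X_pos = np.atleast_2d(np.asarray(pos_descriptors, dtype=np.float64))
    X_neg = np.atleast_2d(np.asarray(neg_descriptors, dtype=np.float64))
    if X_pos.shape[0] == 0 or X_neg.shape[0] == 0:
        raise InvalidInputError("both classes must be non-empty")
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(X_pos.shape[0]), -np.ones(X_neg.shape[0])])

    folds = min(cv_folds, X_pos.shape[0], X_neg.shape[0])
    best_c, best_acc = None, -1.0
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
        for c in c_grid:
            acc = 0.0
            for train_idx, val_idx in splits:
                clf = SVC(kernel="linear", C=c)
                clf.fit(X[train_idx], y[train_idx])
                acc += (clf.predict(X[val_idx]) == y[val_idx]).mean()
            acc /= len(splits)
            if acc > best_acc + 1e-12:  # strict improvement; ties keep smaller C
                best_acc, best_c = acc, c
    else:  # degenerate tiny classes: fall back to C = 1
        best_c = 1.0

    clf = SVC(kernel="linear", C=best_c)
    clf.fit(X, y)
    w = clf.coef_.ravel() * (1.0 if clf.classes_[1] == 1 else -1.0)
    b = float(clf.intercept_[0]) * (1.0 if clf.classes_[1] == 1 else -1.0)
    return SvmModel(weights=w, bias=b, chosen_C=float(best_c), cv_folds=folds)


def normalize_and_threshold(voting_map, gamma: float = 0.2):
    """Min-max normalize the final voting map and keep pixels > gamma.

    Returns (centers (n, 2) int array, retained normalized values (n,)).
    A constant (e.g. all-zero) map yields an empty result.
    """
    if not 0.0 <= gamma <= 1.0:
        raise InvalidInputError("gamma must lie in [0, 1]")
    V = voting_map.values if isinstance(voting_map, VotingMap) else np.asarray(voting_map)
    vmin, vmax = V.min(), V.max()
    if vmax == vmin:
        return np.empty((0, 2), dtype=np.intp), np.empty(0)
    Vn = (V - vmin) / (vmax - vmin)
    rows, cols = np.nonzero(Vn > gamma)
    return np.stack([rows, cols], axis=1).astype(np.intp), Vn[rows, cols]


def build_candidate(
    x_o: int,
    y_o: int,
    s_star: float,
    w: int = 45,
    h: int = 45,
    vote_value: float = 0.0,
    image_shape=None,
) -> Candidate:
    """Candidate box around (x_o, y_o) at the pixel's optimal scale.

    x_min = ceil(x_o - s*/2 * w), x_max = floor(x_o + s*/2 * w) and likewise
    for y with h.  The corner expressions are rounded to 9 decimals before
    ceil/floor so binary representation fuzz in s* (e.g. 0.7) cannot move a
    corner off its exact-arithmetic value.  The box is clipped to the image
    when a shape is given.
    """
    if s_star <= 0:
        raise InvalidInputError("scale factor must be positive")
    if w < 1 or h < 1:
        raise InvalidInputError("box width/height must be >= 1")
    half_w = 0.5 * s_star * w
    half_h = 0.5 * s_star * h
    x_min = math.ceil(round(x_o - half_w, 9))
    y_min = math.ceil(round(y_o - half_h, 9))
    x_max = math.floor(round(x_o + half_w, 9))
    y_max = math.floor(round(y_o + half_h, 9))
    if image_shape is not None:
        H, W = image_shape
        x_min, x_max = max(x_min, 0), min(x_max, H - 1)
        y_min, y_max = max(y_min, 0), min(y_max, W - 1)
    return Candidate(
        box=(x_min, y_min, x_max, y_max),
        vote_value=float(vote_value),
        center=(int(x_o), int(y_o)),
        scale=float(s_star),
    )


def _intersection_over_min_area(box_a, box_b) -> float:
    ix = min(box_a[2], box_b[2]) - max(box_a[0], box_b[0]) + 1
    iy = min(box_a[3], box_b[3]) - max(box_a[1], box_b[1]) + 1
    if ix <= 0 or iy <= 0:
        return 0.0
    area_a = (box_a[2] - box_a[0] + 1) * (box_a[3] - box_a[1] + 1)
    area_b = (box_b[2] - box_b[0] + 1) * (box_b[3] - box_b[1] + 1)
    return ix * iy / min(area_a, area_b)


def nms(candidates, overlap_threshold: float = 0.5, containment_threshold: float = 0.8):
    """Greedy suppression of candidate patches containing the same target.

    Candidates are visited in descending vote value (ties: row-major center
    order); one is dropped when, against an already-kept candidate, either
    its inclusive-IoU overlap exceeds ``overlap_threshold`` or its
    intersection over the smaller box's area exceeds
    ``containment_threshold``.  The second criterion handles concentric
    boxes of one target proposed at different scale factors: a box nested
    inside a kept box covers the same target yet its IoU can stay below 0.5
    whenever the scale factors differ by more than sqrt(2)
    (IoU = (s_small / s_large)^2 for concentric squares), so an IoU-only
    rule would keep it as a duplicate.  ``containment_threshold=1.0``
    disables the containment rule.
    """
    if len(candidates) == 0:
        return []
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].vote_value, candidates[i].center[0], candidates[i].center[1]),
    )
    kept_idx: list[int] = []
    kept_boxes: list[tuple] = []
    for i in order:
        b = candidates[i].box
        if all(
            overlap_alpha0(b, kb) <= overlap_threshold
            and _intersection_over_min_area(b, kb) <= containment_threshold
            for kb in kept_boxes
        ):
            kept_idx.append(i)
            kept_boxes.append(b)
    return [candidates[i] for i in kept_idx]


def _crop_patch(image: np.ndarray, box, out_shape) -> np.ndarray | None:
    x_min, y_min, x_max, y_max = box
    x0, y0 = max(x_min, 0), max(y_min, 0)
    x1, y1 = min(x_max, image.shape[0] - 1), min(y_max, image.shape[1] - 1)
    if x0 > x1 or y0 > y1:
        return None
    crop = image[x0 : x1 + 1, y0 : y1 + 1]
    if crop.shape != out_shape:
        crop = _sk_resize(
            crop, out_shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True
        )
    return crop


def classify_candidates(
    image,
    candidates,
    dictionary: Dictionary,
    model: SvmModel,
    spec: GridSpec | None = None,
    C: int = 5,
    patch_shape=(45, 45),
):
    """Score each candidate with the SVM; label target iff score > 0.

    Crops outside the 45x45 geometry are bilinearly resampled to the patch
    shape before encoding; candidates whose clipped crop is empty are
    skipped with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    spec = spec or GridSpec()
    detections = []
    for cand in candidates:
        crop = _crop_patch(image, cand.box, tuple(patch_shape))
        if crop is None:
            warnings.warn(f"candidate box {cand.box} lies outside the image; skipped",
                          stacklevel=2)
            continue
        desc = pooled_descriptor(crop, dictionary, spec, C)
        score = float(model.decision_values(desc)[0])
        detections.append(Detection(box=cand.box, score=score, label=score > 0))
    return detections
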