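"""Bag-of-visual-words model with per-word discriminative capability.

The visual dictionary is built by K-means clustering of dense SIFT
descriptors; a descriptor is then assigned to its nearest word (vector
quantization) and a patch becomes a K-bin count histogram.

Each word k additionally carries a discriminative capability

    d(k) = alpha(k) / (delta(k) + eps),

where alpha(k) is the mean histogram-intersection similarity between pairs
of query (target-class) patches and delta(k) the mean intersection between
query and background patches.  A large d(k) marks a word that is both
representative of the target class and rare in the background; d(k) is the
vote weight in the localization stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .dsift import InvalidInputError, SiftFeatures

__all__ = [
    "Dictionary",
    "DiscriminativeWeights",
    "EPSILON",
    "build_dictionary",
    "vq_assign",
    "vq_histogram",
    "within_class_similarity",
    "between_class_similarity",
    "discriminative_capability",
]

#: regularizer added to the between-class similarity denominator in d(k)
EPSILON = 1e-12


@dataclass
class Dictionary:
    """K visual words (K-means centroids in 128-dim descriptor space)."""

    words: np.ndarray  # (K, 128)
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        self.words = np.asarray(self.words, dtype=np.float64)
        if self.words.ndim != 2 or self.words.shape[0] < 1:
            raise InvalidInputError("dictionary needs a (K, d) word matrix, K >= 1")
        if not np.all(np.isfinite(self.words)):
            raise InvalidInputError("dictionary words must be finite")

    @property
    def K(self) -> int:
        return self.words.shape[0]


@dataclass
class DiscriminativeWeights:
    """Per-word within/between-class similarities and their ratio d."""

    alpha: np.ndarray
    delta: np.ndarray
    d: np.ndarray


def _descriptor_matrix(features) -> np.ndarray:
    if isinstance(features, SiftFeatures):
        return features.descriptors
    return np.atleast_2d(np.asarray(features, dtype=np.float64))


def build_dictionary(features, K: int, seed: int = 0) -> Dictionary:
    """Cluster descriptors into K visual words with seeded k-means++.

    Requires at least K descriptors.  Deterministic for a given seed.
    """
    X = _descriptor_matrix(features)
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    if X.shape[0] < K:
        raise InvalidInputError(
            f"need at least K={K} features to build the dictionary, got {X.shape[0]}"
        )
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=1,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    ).fit(X)
    return Dictionary(words=km.cluster_centers_.astype(np.float64), kmeans_seed=seed)


def vq_assign(features, dictionary: Dictionary, chunk: int = 4096) -> np.ndarray:
    """Index of the nearest visual word (Euclidean) per descriptor.

    Ties break to the lowest word index.  Accepts a single descriptor, a
    (n, d) matrix or a :class:`SiftFeatures` batch; returns an int array of
    word indices (scalar-shaped input still yields a length-n array, n=1).
    """
    X = _descriptor_matrix(features)
    W = dictionary.words
    if X.shape[1] != W.shape[1]:
        raise InvalidInputError(
            f"descriptor length {X.shape[1]} does not match dictionary "
            f"word length {W.shape[1]}"
        )
    w_sq = np.einsum("kd,kd->k", W, W)
    out = np.empty(X.shape[0], dtype=np.intp)
    for start in range(0, X.shape[0], chunk):
        block = X[start : start + chunk]
        # squared distance up to the constant ||x||^2; argmin takes the
        # first (lowest-index) word on exact ties
        dist = w_sq[None, :] - 2.0 * (block @ W.T)
        out[start : start + chunk] = np.argmin(dist, axis=1)
    return out


def vq_histogram(features, dictionary: Dictionary) -> np.ndarray:
    """K-bin count histogram of word assignments; counts sum to n features."""
    X = _descriptor_matrix(features)
    if X.shape[0] == 0:
        return np.zeros(dictionary.K, dtype=np.int64)
    assign = vq_assign(X, dictionary)
    return np.bincount(assign, minlength=dictionary.K).astype(np.int64)


def _histogram_matrix(histograms) -> np.ndarray:
    H = np.asarray(histograms)
    if H.ndim != 2:
        raise InvalidInputError("expected a (n_patches, K) histogram matrix")
    if np.any(H < 0):
        raise InvalidInputError("histogram counts must be non-negative")
    return H


def within_class_similarity(query_histograms) -> np.ndarray:
    """Mean pairwise histogram intersection over ordered query-patch pairs.

    alpha(k) = 1/(M(M-1)) * sum_{m != l} min(h_Qm(k), h_Ql(k)); needs M >= 2.
    Integer arithmetic until the final division.
    """
    H = _histogram_matrix(query_histograms)
    M = H.shape[0]
    if M < 2:
        raise InvalidInputError("within-class similarity needs at least 2 histograms")
    pair_min = np.minimum(H[:, None, :], H[None, :, :]).sum(axis=(0, 1))
    diag = H.sum(axis=0)  # m == l terms: min(h, h) = h
    return (pair_min - diag) / (M * (M - 1))


def between_class_similarity(query_histograms, background_histograms) -> np.ndarray:
    """delta(k) = 1/(MN) * sum_{m,n} min(h_Qm(k), h_Bn(k)); needs M, N >= 1."""
    Q = _histogram_matrix(query_histograms)
    B = _histogram_matrix(background_histograms)
    if Q.shape[0] < 1 or B.shape[0] < 1:
        raise InvalidInputError("both classes must be non-empty")
    if Q.shape[1] != B.shape[1]:
        raise InvalidInputError("histogram lengths differ between classes")
    total = np.minimum(Q[:, None, :], B[None, :, :]).sum(axis=(0, 1))
    return total / (Q.shape[0] * B.shape[0])


def discriminative_capability(alpha, delta, eps: float = EPSILON) -> np.ndarray:
    """d(k) = alpha(k) / (delta(k) + eps), elementwise."""
    a = np.asarray(alpha, dtype=np.float64)
    d = np.asarray(delta, dtype=np.float64)
    if a.shape != d.shape:
        raise InvalidInputError("alpha and delta must have the same length")
    if np.any(a < 0) or np.any(d < 0):
        raise InvalidInputError("similarities must be non-negative")
    return a / (d + eps)


def compute_weights(query_histograms, background_histograms) -> DiscriminativeWeights:
    """Convenience: alpha, delta and d in one call."""
    alpha = within_class_similarity(query_histograms)
    delta = between_class_similarity(query_histograms, background_histograms)
    return DiscriminativeWeights(
        alpha=alpha, delta=delta, d=discriminative_capability(alpha, delta)
    )
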