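"""Voting-map localization of candidate ring centers.

Every query patch is compared locally against the test image: a query
feature f and a test feature g "match" when vector quantization assigns
both to the same visual word k.  Each matched pair casts a vote of weight
d(k) (the word's discriminative capability) at the test-image pixel where
the query patch's center would sit if the target appeared at scale s:

    vote location = round(L(g) - s * (L(f) - L(c_Q)))

Summing votes over all pairs and all query patches gives one voting map per
scale factor; the final map takes, per pixel, the maximum over scales and
records the winning scale index.  Peaks of the final map are candidate
target centroids, consumed by the identification stage.

Votes that land outside the image are discarded (and counted).  Vote
locations are rounded half-up per axis.  Scale-argmax ties break to the
smallest scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bow import Dictionary, DiscriminativeWeights, vq_assign, vq_histogram
from .dsift import GridSpec, InvalidInputError, SiftFeatures, extract_dense

__all__ = [
    "QueryPatch",
    "ScaleSet",
    "VotingMap",
    "make_query_patch",
    "vote_single",
    "vote_all_queries",
    "fuse_scales",
    "localize",
]


@dataclass(frozen=True)
class ScaleSet:
    """Strictly increasing positive scale factors searched during voting."""

    scales: tuple = tuple(np.round(np.arange(0.5, 1.51, 0.1), 10))

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=np.float64)
        if s.size == 0 or np.any(s <= 0):
            raise InvalidInputError("scales must be positive")
        if np.any(np.diff(s) <= 0):
            raise InvalidInputError("scales must be strictly increasing")
        object.__setattr__(self, "scales", tuple(float(x) for x in s))

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def __getitem__(self, i):
        return self.scales[i]


@dataclass
class QueryPatch:
    """A hand-selected exemplar patch of the target with its features.

    ``centroid`` is the patch center pixel ((h-1)//2, (w-1)//2); feature
    ``offsets`` = L(f) - L(c_Q) are precomputed for voting geometry.
    """

    pixels: np.ndarray
    centroid: np.ndarray
    features: SiftFeatures
    assignments: np.ndarray
    histogram: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return self.features.locations - self.centroid[None, :]


def make_query_patch(pixels, dictionary: Dictionary, spec: GridSpec | None = None) -> QueryPatch:
    """Extract dense features from an exemplar patch and assign them to words."""
    spec = spec or GridSpec()
    pixels = np.asarray(pixels, dtype=np.float64)
    feats = extract_dense(pixels, spec)
    if len(feats) == 0:
        raise InvalidInputError("query patch smaller than one descriptor grid")
    assign = vq_assign(feats, dictionary)
    hist = np.bincount(assign, minlength=dictionary.K).astype(np.int64)
    centroid = np.array([(pixels.shape[0] - 1) // 2, (pixels.shape[1] - 1) // 2])
    return QueryPatch(pixels, centroid, feats, assign, hist)


@dataclass
class VotingMap:
    """Per-pixel vote accumulation; ``scale_index`` is set after scale fusion."""

    values: np.ndarray
    scale_index: np.ndarray | None = None
    n_discarded: int = 0  # votes that fell outside the image


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.intp)


def _accumulate_pairs(
    values: np.ndarray,
    query_offsets: np.ndarray,
    test_locs: np.ndarray,
    weight: float,
    s: float,
) -> int:
    """Cast one vote per (f, g) pair, f-major order; returns #discarded.

    Sequential ``np.add.at`` in f-major pair order reproduces the literal
    nested-loop accumulation (and hence its floating-point sum order).
    """
    h, w = values.shape
    # centers[i, j] = round(L(g_j) - s * offset_i)
    centers = _round_half_up(test_locs[None, :, :] - s * query_offsets[:, None, :])
    rows = centers[..., 0].ravel()
    cols = centers[..., 1].ravel()
    valid = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    flat = rows[valid] * w + cols[valid]
    np.add.at(values.ravel(), flat, weight)
    return int(valid.size - valid.sum())


def vote_single(
    query: QueryPatch,
    test_features: SiftFeatures,
    test_assignments: np.ndarray,
    weights: DiscriminativeWeights,
    s: float,
    shape,
) -> VotingMap:
    """Voting map V(s, Q_m, D) for one query patch at one scale."""
    if s <= 0:
        raise InvalidInputError("scale factor must be positive")
    values = np.zeros(shape, dtype=np.float64)
    discarded = 0
    K = len(weights.d)
    q_assign = query.assignments
    for k in np.unique(q_assign):
        g_mask = test_assignments == k
        if not g_mask.any():
            continue
        discarded += _accumulate_pairs(
            values,
            query.offsets[q_assign == k],
            test_features.locations[g_mask],
            float(weights.d[k]),
            s,
        )
    return VotingMap(values=values, n_discarded=discarded)


def vote_all_queries(
    queries,
    test_features: SiftFeatures,
    test_assignments: np.ndarray,
    weights: DiscriminativeWeights,
    s: float,
    shape,
) -> VotingMap:
    """Sum of per-query voting maps at scale s (Eq: V(s, Qset, D) = sum_m V(s, Qm, D))."""
    if len(queries) == 0:
        raise InvalidInputError("need at least one query patch")
    total = np.zeros(shape, dtype=np.float64)
    discarded = 0
    for q in queries:
        vm = vote_single(q, test_features, test_assignments, weights, s, shape)
        total += vm.values
        discarded += vm.n_discarded
    return VotingMap(values=total, n_discarded=discarded)


def fuse_scales(per_scale_maps, scales: ScaleSet) -> VotingMap:
    """Per-pixel max over scales; argmax ties break to the smallest scale."""
    maps = [m.values if isinstance(m, VotingMap) else np.asarray(m) for m in per_scale_maps]
    if len(maps) != len(scales):
        raise InvalidInputError("need exactly one map per scale")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise InvalidInputError("all per-scale maps must share the same shape")
    stack = np.stack(maps, axis=0)
    scale_index = np.argmax(stack, axis=0)  # first max = smallest scale
    values = np.max(stack, axis=0)
    discarded = sum(m.n_discarded for m in per_scale_maps if isinstance(m, VotingMap))
    return VotingMap(values=values, scale_index=scale_index, n_discarded=discarded)


def localize(
    test_image,
    queries,
    dictionary: Dictionary,
    weights: DiscriminativeWeights,
    scales: ScaleSet | None = None,
    spec: GridSpec | None = None,
    test_features: SiftFeatures | None = None,
) -> VotingMap:
    """Full localization stage: dense features, VQ, per-scale voting, fusion.

    Iterates scale (outer), visual word, query patch, then feature pairs in
    f-major order, exactly mirroring the reference quadruple loop; the
    per-word grouping is an inverted index that changes the cost, not the
    arithmetic.
    """
    scales = scales or ScaleSet()
    spec = spec or GridSpec()
    if len(queries) == 0:
        raise InvalidInputError("need at least one query patch")
    test_image = np.asarray(test_image, dtype=np.float64)
    if test_features is None:
        test_features = extract_dense(test_image, spec)
    test_assign = (
        vq_assign(test_features, dictionary) if len(test_features) else np.empty(0, np.intp)
    )

    # inverted index: word -> test feature locations
    K = dictionary.K
    test_by_word = [test_features.locations[test_assign == k] for k in range(K)]
    query_by_word = [
        [q.offsets[q.assignments == k] for q in queries] for k in range(K)
    ]

    per_scale = []
    for s in scales:
        values = np.zeros(test_image.shape, dtype=np.float64)
        discarded = 0
        for k in range(K):
            g_locs = test_by_word[k]
            if g_locs.shape[0] == 0:
                continue
            for offs in query_by_word[k]:
                if offs.shape[0] == 0:
                    continue
                discarded += _accumulate_pairs(values, offs, g_locs, float(weights.d[k]), s)
        per_scale.append(VotingMap(values=values, n_discarded=discarded))
    return fuse_scales(per_scale, scales)
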