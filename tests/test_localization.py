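"""Voting-map generation, scale fusion and the full localization stage."""

import math

import numpy as np
import pytest

from ringdetect.bow import Dictionary, DiscriminativeWeights, vq_assign
from ringdetect.dsift import GridSpec, InvalidInputError, SiftFeatures, extract_dense
from ringdetect.localization import (
    QueryPatch,
    ScaleSet,
    VotingMap,
    fuse_scales,
    localize,
    make_query_patch,
    vote_all_queries,
    vote_single,
)


def manual_query(offsets, assignments, centroid=(22, 22)):
    """QueryPatch with hand-set feature geometry (pixels unused by voting)."""
    centroid = np.asarray(centroid)
    locs = np.asarray(offsets) + centroid
    n = len(locs)
    feats = SiftFeatures(np.zeros((n, 128)), locs.astype(np.intp))
    return QueryPatch(
        pixels=np.zeros((45, 45)),
        centroid=centroid,
        features=feats,
        assignments=np.asarray(assignments, dtype=np.intp),
        histogram=np.bincount(assignments, minlength=5),
    )


def uniform_weights(K, value=1.0):
    d = np.full(K, float(value))
    return DiscriminativeWeights(alpha=d.copy(), delta=d.copy(), d=d)


def localize_oracle(image, queries, dictionary, weights, scales, spec):
    """Literal quadruple loop: scale, word, query, (f, g) pairs in order."""
    feats = extract_dense(image, spec)
    assign = vq_assign(feats, dictionary)
    h, w = image.shape
    maps = []
    for s in scales:
        V = np.zeros((h, w))
        for k in range(dictionary.K):
            for q in queries:
                f_idx = [i for i in range(len(q.features)) if q.assignments[i] == k]
                g_idx = [j for j in range(len(feats)) if assign[j] == k]
                for i in f_idx:
                    off = q.features.locations[i] - q.centroid
                    for j in g_idx:
                        loc = feats.locations[j] - s * off
                        r = math.floor(loc[0] + 0.5)
                        c = math.floor(loc[1] + 0.5)
                        if 0 <= r < h and 0 <= c < w:
                            V[r, c] += weights.d[k]
        maps.append(V)
    stack = np.stack(maps)
    return stack, stack.max(axis=0), stack.argmax(axis=0)


class TestVoteSingle:
    def test_no_shared_words_zero_map(self):
        q = manual_query([(0, 0)], [0])
        test = SiftFeatures(np.zeros((1, 128)), np.array([[30, 30]]))
        vm = vote_single(q, test, np.array([1]), uniform_weights(5), 1.0, (64, 64))
        assert vm.values.sum() == 0

    def test_single_matched_pair_geometry(self):
        # offset L(f) - L(c_Q) = (10, -4); L(g) = (50, 50); s = 1
        q = manual_query([(10, -4)], [2])
        test = SiftFeatures(np.zeros((1, 128)), np.array([[50, 50]]))
        vm = vote_single(q, test, np.array([2]), uniform_weights(5), 1.0, (64, 64))
        assert vm.values[40, 54] == 1.0
        assert vm.values.sum() == 1.0

    def test_scaled_vote_position(self):
        q = manual_query([(10, -4)], [2])
        test = SiftFeatures(np.zeros((1, 128)), np.array([[50, 50]]))
        vm = vote_single(q, test, np.array([2]), uniform_weights(5), 0.5, (64, 64))
        assert vm.values[45, 52] == 1.0

    def test_self_match_peaks_at_crop_center(self, rng):
        image = rng.random((64, 64)) * 50
        p = (32, 32)
        patch = image[p[0] - 22 : p[0] + 23, p[1] - 22 : p[1] + 23]
        spec = GridSpec()
        feats = extract_dense(image, spec)
        words = feats.descriptors[rng.permutation(len(feats))[:20]]
        dictionary = Dictionary(words=words)
        q = make_query_patch(patch, dictionary, spec)
        assign = vq_assign(feats, dictionary)
        vm = vote_single(q, feats, assign, uniform_weights(20), 1.0, image.shape)
        assert np.unravel_index(vm.values.argmax(), vm.values.shape) == p

    def test_nonpositive_scale_rejected(self):
        q = manual_query([(0, 0)], [0])
        test = SiftFeatures(np.zeros((1, 128)), np.array([[5, 5]]))
        with pytest.raises(InvalidInputError):
            vote_single(q, test, np.array([0]), uniform_weights(5), 0.0, (64, 64))

    def test_out_of_image_votes_discarded(self):
        q = manual_query([(40, 0)], [0])  # vote lands at row -10
        test = SiftFeatures(np.zeros((1, 128)), np.array([[30, 30]]))
        vm = vote_single(q, test, np.array([0]), uniform_weights(5), 1.0, (64, 64))
        assert vm.values.sum() == 0 and vm.n_discarded == 1


class TestVoteAllQueries:
    def test_single_query_equals_vote_single(self, rng):
        q = manual_query([(1, 2), (-3, 4)], [0, 1])
        test = SiftFeatures(np.zeros((3, 128)), rng.integers(10, 50, (3, 2)))
        assign = np.array([0, 1, 1])
        w = uniform_weights(5, 0.7)
        a = vote_single(q, test, assign, w, 1.2, (64, 64)).values
        b = vote_all_queries([q], test, assign, w, 1.2, (64, 64)).values
        np.testing.assert_array_equal(a, b)

    def test_duplicated_query_doubles_map(self, rng):
        q = manual_query([(5, 5), (0, -2)], [2, 3])
        test = SiftFeatures(np.zeros((4, 128)), rng.integers(10, 50, (4, 2)))
        assign = np.array([2, 3, 2, 0])
        w = uniform_weights(5, 1.3)
        single = vote_all_queries([q], test, assign, w, 0.8, (64, 64)).values
        double = vote_all_queries([q, q], test, assign, w, 0.8, (64, 64)).values
        np.testing.assert_allclose(double, 2 * single)

    def test_linearity_over_queries(self, rng):
        queries = [
            manual_query(rng.integers(-10, 10, (3, 2)), rng.integers(0, 5, 3))
            for _ in range(3)
        ]
        test = SiftFeatures(np.zeros((6, 128)), rng.integers(5, 55, (6, 2)))
        assign = rng.integers(0, 5, 6)
        w = uniform_weights(5, 2.0)
        total = vote_all_queries(queries, test, assign, w, 1.1, (64, 64)).values
        parts = sum(
            vote_single(q, test, assign, w, 1.1, (64, 64)).values for q in queries
        )
        np.testing.assert_allclose(total, parts)

    def test_empty_query_set_rejected(self):
        test = SiftFeatures(np.zeros((1, 128)), np.array([[5, 5]]))
        with pytest.raises(InvalidInputError):
            vote_all_queries([], test, np.array([0]), uniform_weights(5), 1.0, (64, 64))


class TestFuseScales:
    def test_single_scale_identity(self, rng):
        m = rng.random((8, 8))
        fused = fuse_scales([VotingMap(m)], ScaleSet((1.0,)))
        np.testing.assert_array_equal(fused.values, m)
        assert np.all(fused.scale_index == 0)

    def test_dominant_map_wins_everywhere(self, rng):
        b = rng.random((8, 8))
        a = b + 1.0
        fused = fuse_scales([VotingMap(a), VotingMap(b)], ScaleSet((0.5, 1.0)))
        np.testing.assert_array_equal(fused.values, a)
        assert np.all(fused.scale_index == 0)

    def test_elementwise_max_argmax_oracle(self, rng):
        stack = rng.random((11, 12, 12))
        maps = [VotingMap(s) for s in stack]
        fused = fuse_scales(maps, ScaleSet(tuple(np.arange(0.5, 1.51, 0.1))))
        for r in range(12):
            for c in range(12):
                col = stack[:, r, c]
                assert fused.values[r, c] == col.max()
                assert fused.scale_index[r, c] == int(np.argmax(col))

    def test_tie_takes_smallest_scale(self):
        m = np.ones((4, 4))
        fused = fuse_scales([VotingMap(m.copy()), VotingMap(m.copy())], ScaleSet((0.5, 1.5)))
        assert np.all(fused.scale_index == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            fuse_scales([VotingMap(np.ones((4, 4))), VotingMap(np.ones((5, 5)))],
                        ScaleSet((0.5, 1.0)))

    def test_fused_dominates_each_scale(self, rng):
        stack = rng.random((5, 9, 9))
        fused = fuse_scales([VotingMap(s) for s in stack],
                            ScaleSet((0.6, 0.8, 1.0, 1.2, 1.4)))
        for s in stack:
            assert np.all(fused.values >= s)


class TestScaleSet:
    def test_default_has_11_factors(self):
        s = ScaleSet()
        assert len(s) == 11
        np.testing.assert_allclose(list(s), np.arange(0.5, 1.51, 0.1), atol=1e-9)

    def test_rejects_nonincreasing(self):
        with pytest.raises(InvalidInputError):
            ScaleSet((1.0, 0.5))


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(7)
    image = rng.random((64, 64)) * 40
    spec = GridSpec()
    queries_px = [
        image[2:47, 4:49],
        image[15:60, 10:55],
    ]
    feats = extract_dense(image, spec)
    words = feats.descriptors[rng.permutation(len(feats))[:10]]
    dictionary = Dictionary(words=words)
    queries = [make_query_patch(p, dictionary, spec) for p in queries_px]
    d = rng.random(10) * 3
    weights = DiscriminativeWeights(alpha=d, delta=np.ones(10), d=d)
    scales = ScaleSet((0.5, 1.0, 1.5))
    return image, queries, dictionary, weights, scales, spec


class TestLocalize:
    def test_bit_identical_to_quadruple_loop(self, small_problem):
        image, queries, dictionary, weights, scales, spec = small_problem
        fused = localize(image, queries, dictionary, weights, scales, spec)
        _stack, v_ref, idx_ref = localize_oracle(
            image, queries, dictionary, weights, scales, spec
        )
        np.testing.assert_array_equal(fused.values, v_ref)
        np.testing.assert_array_equal(fused.scale_index, idx_ref)

    def test_no_matching_words_zero_map(self):
        # query assigned to word 0; all test features quantize to word 1
        words = np.zeros((2, 128))
        words[1] = 1.0
        dictionary = Dictionary(words=words)
        q = manual_query([(0, 0), (3, -2)], [0, 0])
        test = SiftFeatures(np.ones((4, 128)), np.array([[10, 10], [20, 20], [30, 30], [40, 40]]))
        weights = uniform_weights(2)
        fused = localize(
            np.zeros((64, 64)), [q], dictionary, weights,
            ScaleSet((0.5, 1.0)), GridSpec(), test_features=test,
        )
        assert fused.values.sum() == 0

    def test_monotone_in_d(self, small_problem):
        image, queries, dictionary, weights, scales, spec = small_problem
        fused1 = localize(image, queries, dictionary, weights, scales, spec)
        w2 = DiscriminativeWeights(
            alpha=weights.alpha, delta=weights.delta, d=weights.d * 2.5
        )
        fused2 = localize(image, queries, dictionary, w2, scales, spec)
        np.testing.assert_allclose(fused2.values, fused1.values * 2.5, rtol=1e-12)

    def test_mass_conservation_bound(self, small_problem):
        image, queries, dictionary, weights, scales, spec = small_problem
        feats = extract_dense(image, spec)
        assign = vq_assign(feats, dictionary)
        n_pairs = 0
        for q in queries:
            for k in range(dictionary.K):
                n_pairs += int((q.assignments == k).sum() * (assign == k).sum())
        for s in scales:
            vm = vote_all_queries(queries, feats, assign, weights, s, image.shape)
            assert vm.values.sum() <= n_pairs * weights.d.max() + 1e-6
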