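"""Geometric primitives against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sowmorph.neighborhood import (ball_group, farthest_point_sample, knn_coord,
                                   knn_feat)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_knn(candidates, queries, k, exclude_idx=None):
    out = []
    for qi, q in enumerate(queries):
        d = np.linalg.norm(candidates - q, axis=1)
        if exclude_idx is not None:
            d = d.copy()
            d[exclude_idx[qi]] = np.inf
        order = np.argsort(d, kind="stable")[:k]
        out.append(sorted(zip(np.round(d[order], 12), order)))
    return out


def oracle_fps_best_two(points):
    """Exhaustively find the max-min-distance pair of points."""
    n = len(points)
    best, best_d = None, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(points[i] - points[j])
            if d > best_d:
                best_d, best = d, {i, j}
    return best, best_d


class TestFarthestPointSample:
    def test_collinear_picks_extreme(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        sel = farthest_point_sample(pts, 2)
        # start: nearest to centroid (x=4/3) is x=1; farthest from it is x=3
        assert sel[0] == 1
        assert sel[1] == 2

    def test_unit_square_m2_opposite_corners(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        sel = farthest_point_sample(pts, 2)
        _, best_d = oracle_fps_best_two(pts)
        assert np.linalg.norm(pts[sel[0]] - pts[sel[1]]) == pytest.approx(best_d)

    def test_m_equals_n_returns_all(self, rng):
        pts = rng.normal(size=(17, 3))
        sel = farthest_point_sample(pts, 17)
        assert sorted(sel) == list(range(17))

    def test_m_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="outside"):
            farthest_point_sample(rng.normal(size=(5, 3)), 6)

    def test_greedy_max_min_rule_holds_stepwise(self, rng):
        pts = rng.normal(size=(40, 3))
        sel = farthest_point_sample(pts, 10)
        for j in range(1, 10):
            chosen = pts[sel[:j]]
            min_d = np.linalg.norm(pts[:, None] - chosen[None], axis=2).min(axis=1)
            assert min_d[sel[j]] == pytest.approx(min_d.max())

    def test_permutation_invariant_as_set(self, rng):
        pts = rng.normal(size=(60, 3))
        perm = rng.permutation(60)
        a = farthest_point_sample(pts, 12)
        b = farthest_point_sample(pts[perm], 12)
        assert set(map(tuple, pts[a])) == set(map(tuple, pts[perm][b]))

    def test_spreads_better_than_random_subsets(self, rng):
        pts = rng.normal(size=(100, 3))
        sel = farthest_point_sample(pts, 8)

        def min_pairwise(sub):
            d = np.linalg.norm(sub[:, None] - sub[None], axis=2)
            return d[np.triu_indices(len(sub), 1)].min()

        fps_sep = min_pairwise(pts[sel])
        random_seps = [min_pairwise(pts[rng.choice(100, 8, replace=False)])
                       for _ in range(50)]
        assert fps_sep >= np.max(random_seps)


class TestKnnCoord:
    def test_three_four_five_triangle(self):
        nn = knn_coord(np.array([[3.0, 4.0, 0.0]]), np.array([[0.0, 0.0, 0.0]]), k=1)
        assert nn.distances[0, 0] == pytest.approx(5.0)

    def test_duplicate_points_tie_to_lower_index(self):
        pts = np.array([[1.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        nn = knn_coord(pts, np.array([[1.0, 0, 0]]), k=2)
        assert list(nn.indices[0]) == [0, 1]

    def test_matches_oracle_random_cloud(self, rng):
        pts = rng.normal(size=(200, 3))
        q = rng.normal(size=(20, 3))
        nn = knn_coord(pts, q, k=7)
        expected = oracle_knn(pts, q, 7)
        for qi in range(20):
            got = sorted(zip(np.round(nn.distances[qi], 12), nn.indices[qi]))
            assert got == expected[qi]

    def test_self_exclusion(self, rng):
        pts = rng.normal(size=(30, 3))
        nn = knn_coord(pts, k=3, exclude_self=True)
        assert not np.any(nn.indices == np.arange(30)[:, None])
        assert nn.self_excluded

    def test_strict_mode_raises_grouping_mode_pads(self, rng):
        pts = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="exceeds"):
            knn_coord(pts, k=5)
        nn = knn_coord(pts, k=6, strict=False)
        assert nn.indices.shape == (4, 6)
        # padding repeats the nearest neighbour
        assert np.all(nn.indices[:, 4] == nn.indices[:, 0])

    def test_distances_row_wise_sorted(self, rng):
        nn = knn_coord(rng.normal(size=(50, 3)), k=10, exclude_self=True)
        assert np.all(np.diff(nn.distances, axis=1) >= 0)


class TestKnnFeat:
    def test_identical_features_lowest_indices(self):
        f = np.ones((6, 4))
        nn = knn_feat(f, k=2)
        assert np.all(nn.distances == 0)
        for i in range(6):
            lowest = [j for j in range(6) if j != i][:2]
            assert sorted(nn.indices[i]) == lowest

    def test_1d_feature_line(self):
        f = np.array([[0.0], [1.0], [10.0]])
        nn = knn_feat(f, k=1)
        assert list(nn.indices[:, 0]) == [1, 0, 1]

    def test_matches_oracle(self, rng):
        f = rng.normal(size=(100, 16))
        nn = knn_feat(f, k=5)
        exclude = [[i] for i in range(100)]
        expected = oracle_knn(f, f, 5, exclude_idx=exclude)
        for i in range(100):
            got = sorted(zip(np.round(nn.distances[i], 12), nn.indices[i]))
            assert got == expected[i]


class TestBallGroup:
    def test_huge_radius_contains_all(self, rng):
        pts = rng.normal(size=(25, 3))
        idx, counts, empty = ball_group(pts, pts[:3], radius=1e6, max_samples=30)
        assert np.all(counts == 25)
        assert not empty.any()
        for row in idx:
            assert set(row[:25]) == set(range(25))

    def test_small_radius_only_center_on_grid(self):
        g = np.stack(np.meshgrid(range(3), range(3), [0]), -1).reshape(-1, 3).astype(float)
        idx, counts, empty = ball_group(g, g, radius=0.5, max_samples=4)
        assert np.all(counts == 1)
        for i, row in enumerate(idx):
            assert np.all(row == i)

    def test_set_equality_with_oracle_filter(self, rng):
        pts = rng.normal(size=(300, 3))
        centers = rng.normal(size=(10, 3))
        r = 0.8
        idx, counts, _ = ball_group(pts, centers, radius=r, max_samples=400)
        for ci, c in enumerate(centers):
            inside = set(np.nonzero(np.linalg.norm(pts - c, axis=1) <= r)[0])
            assert set(idx[ci, :counts[ci]]) == inside

    def test_nearest_first_and_padding(self, rng):
        pts = rng.normal(size=(50, 3))
        centers = pts[:2] + 0.01
        idx, counts, _ = ball_group(pts, centers, radius=0.5, max_samples=64)
        for ci in range(2):
            d = np.linalg.norm(pts[idx[ci, :counts[ci]]] - centers[ci], axis=1)
            assert np.all(np.diff(d) >= 0)
            assert np.all(idx[ci, counts[ci]:] == idx[ci, 0])

    def test_empty_ball_flagged_and_padded_with_nearest(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        centers = np.array([[100.0, 0, 0]])
        idx, counts, empty = ball_group(pts, centers, radius=1.0, max_samples=3)
        assert empty[0] and counts[0] == 0
        assert np.all(idx[0] == 1)  # nearest point to the center

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ball_group(np.zeros((2, 3)), np.zeros((1, 3)), radius=0.0, max_samples=1)


class TestPermutationInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_knn_sets_invariant_to_storage_order(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(40, 3))
        perm = rng.permutation(40)
        q = rng.normal(size=(5, 3))
        a = knn_coord(pts, q, k=4)
        b = knn_coord(pts[perm], q, k=4)
        for qi in range(5):
            assert (set(map(tuple, pts[a.indices[qi]]))
                    == set(map(tuple, pts[perm][b.indices[qi]])))
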