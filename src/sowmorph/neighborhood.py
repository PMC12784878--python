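"""Deterministic neighbourhood primitives shared by both networks.

Farthest point sampling, coordinate-space and feature-space k-nearest
neighbours, and radius (ball) grouping.  All four are exact (no spatial
acceleration structures) and fully deterministic, including tie-breaks,
so that every downstream network output is reproducible and invariant to
the storage order of the input points.

Conventions:

* distances are computed and compared as squared distances internally
  and returned as true Euclidean distances;
* distance ties are broken by canonical (lexicographic-coordinate, then
  index) order;
* deficient neighbourhoods are padded by repeating the nearest member
  (grouping mode) or raise in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeighborIndex", "farthest_point_sample", "knn_coord", "knn_feat", "ball_group"]


@dataclass
class NeighborIndex:
    """k-NN result: per-query neighbour indices and sorted distances."""

    query_count: int
    k: int
    indices: np.ndarray     # (query_count, k) int
    distances: np.ndarray   # (query_count, k) float, row-wise non-decreasing
    self_excluded: bool


def _canonical_rank(points: np.ndarray) -> np.ndarray:
    """rank[i] = position of point i in (lexicographic coords, index) order."""
    order = np.lexsort((np.arange(len(points)), points[:, 2], points[:, 1], points[:, 0]))
    rank = np.empty(len(points), dtype=np.int64)
    rank[order] = np.arange(len(points))
    return rank


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (len(a), len(b))."""
    d = (a**2).sum(1)[:, None] + (b**2).sum(1)[None, :] - 2.0 * (a @ b.T)
    np.maximum(d, 0.0, out=d)
    return d


def farthest_point_sample(points, m: int) -> np.ndarray:
    """Iteratively select ``m`` well-spread point indices.

    Start at the point nearest the centroid; each subsequent selection
    maximises the minimum distance to the already-selected set.  All
    ties resolve by lexicographic coordinate order then index, which
    makes the selected set invariant to permutations of the input.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, {n}]")
    rank = _canonical_rank(points)

    def _pick(score):
        # argmax of score; ties by smallest canonical rank
        best = score.max()
        cands = np.nonzero(score == best)[0]
        return cands[np.argmin(rank[cands])]

    centroid = points.mean(axis=0)
    d0 = ((points - centroid) ** 2).sum(1)
    selected = np.empty(m, dtype=np.int64)
    selected[0] = _pick(-d0)
    min_d = ((points - points[selected[0]]) ** 2).sum(1)
    for j in range(1, m):
        selected[j] = _pick(min_d)
        np.minimum(min_d, ((points - points[selected[j]]) ** 2).sum(1), out=min_d)
    return selected


def _knn_from_sq(sq, cand_points, k, strict, exclude_diag):
    nq, nc = sq.shape
    rank = _canonical_rank(cand_points)
    avail = nc - (1 if exclude_diag else 0)
    if k > avail:
        if strict:
            raise ValueError(f"k={k} exceeds {avail} available candidates")
        k_eff = avail
    else:
        k_eff = k
    if exclude_diag:
        sq = sq.copy()
        np.fill_diagonal(sq, np.inf)
    # sort each row by (distance, canonical rank) for deterministic ties
    idx = np.empty((nq, k_eff), dtype=np.int64)
    for i in range(nq):
        order = np.lexsort((rank, sq[i]))
        idx[i] = order[:k_eff]
    dist = np.sqrt(np.take_along_axis(sq, idx, axis=1))
    if k_eff < k:  # pad by repeating the nearest neighbour
        pad = k - k_eff
        idx = np.hstack([idx, np.repeat(idx[:, :1], pad, axis=1)])
        dist = np.hstack([dist, np.repeat(dist[:, :1], pad, axis=1)])
    return idx, dist


def knn_coord(points, queries=None, k: int = 1, exclude_self: bool = False,
              strict: bool = True) -> NeighborIndex:
    """Exact k nearest neighbours in coordinate space.

    With ``queries=None`` the points query themselves and
    ``exclude_self`` removes the trivial zero-distance self match.  In
    non-strict (grouping) mode an over-large ``k`` pads by repeating the
    nearest neighbour instead of raising.
    """
    points = np.asarray(points, dtype=np.float64)
    self_query = queries is None
    q = points if self_query else np.asarray(queries, dtype=np.float64)
    sq = _sqdist(q, points)
    idx, dist = _knn_from_sq(sq, points, k, strict, exclude_diag=self_query and exclude_self)
    return NeighborIndex(len(q), k, idx, dist, self_excluded=self_query and exclude_self)


def knn_feat(features, k: int, strict: bool = True) -> NeighborIndex:
    """k nearest neighbours in C-dimensional feature space, self excluded.

    Feature-distance ties resolve by index order (features carry no
    natural lexicographic geometry at high C, so index is the canonical
    order here)."""
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("features must be 2-D (n, C)")
    n = len(f)
    avail = n - 1
    if k > avail and strict:
        raise ValueError(f"k={k} exceeds {avail} available candidates")
    sq = _sqdist(f, f)
    np.fill_diagonal(sq, np.inf)
    k_eff = min(k, avail)
    if k_eff < n - 1:
        # argpartition + in-candidate sort; exact provided no distance tie
        # straddles the selection boundary (checked; fall back otherwise)
        part = np.sort(np.argpartition(sq, k_eff - 1, axis=1)[:, :k_eff], axis=1)
        part_d = np.take_along_axis(sq, part, axis=1)
        boundary = part_d.max(axis=1)
        ambiguous = (sq <= boundary[:, None]).sum(axis=1) > k_eff
        order = np.argsort(part_d, axis=1, kind="stable")
        idx = np.take_along_axis(part, order, axis=1)
        if ambiguous.any():  # ties at the k-th distance: exact stable sort
            rows = np.nonzero(ambiguous)[0]
            idx[rows] = np.argsort(sq[rows], axis=1, kind="stable")[:, :k_eff]
    else:
        idx = np.argsort(sq, axis=1, kind="stable")[:, :k_eff]
    dist = np.sqrt(np.take_along_axis(sq, idx, axis=1))
    if k_eff < k:
        pad = k - k_eff
        idx = np.hstack([idx, np.repeat(idx[:, :1], pad, axis=1)])
        dist = np.hstack([dist, np.repeat(dist[:, :1], pad, axis=1)])
    return NeighborIndex(n, k, idx, dist, self_excluded=True)


def ball_group(points, centers, radius: float, max_samples: int):
    """Group point indices within ``radius`` of each center, nearest first.

    Each row of the returned index matrix holds ``max_samples`` entries:
    the in-radius members sorted by distance (canonical tie-break),
    truncated or padded by repeating the nearest member.  A center with
    an empty ball is padded with its single nearest neighbour in the
    cloud and flagged.

    Returns ``(indices (M, max_samples), counts (M,), empty_flags (M,))``
    where ``counts`` is the pre-truncation ball occupancy.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.asarray(points, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    rank = _canonical_rank(points)
    sq = _sqdist(centers, points)
    r2 = radius * radius
    m = len(centers)
    idx = np.empty((m, max_samples), dtype=np.int64)
    counts = np.empty(m, dtype=np.int64)
    empty = np.zeros(m, dtype=bool)
    for i in range(m):
        row = sq[i]
        inside = np.nonzero(row <= r2)[0]
        counts[i] = len(inside)
        if len(inside) == 0:
            empty[i] = True
            nearest = np.lexsort((rank, row))[0]
            idx[i] = nearest
            continue
        order = inside[np.lexsort((rank[inside], row[inside]))]
        if len(order) >= max_samples:
            idx[i] = order[:max_samples]
        else:
            idx[i, :len(order)] = order
            idx[i, len(order):] = order[0]
    return idx, counts, empty
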