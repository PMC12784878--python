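"""Point Activation Mapping: per-point saliency for point-cloud networks.

Given per-point feature matrices tapped from any layer of a network, the
map is built in four steps:

1. align every tapped level to the n original points by nearest-neighbour
   upsampling (a coarse level's feature is inherited by each original
   point from its nearest coarse point) and concatenate the aligned
   features (n x 384 under the default regression-network tap);
2. compress channels per point by the maximum, f_i = max_j f_ij;
3. normalise to weights w_i = f_i / (max f - min f).  This is the
   literal published form — the minimum is *not* subtracted, so weights
   may exceed 1; pass ``minmax=True`` for the conventional min-subtracted
   variant.  A degenerate zero range falls back to uniform weights with
   a warning flag;
4. encode a heat map: after a min-max rescale to [0, 1], R rises with
   the weight, B falls, and G peaks mid-scale (blue -> cyan/green -> red).

The map is model-agnostic: any (coords, features) levels work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LabeledCloud, write_cloud
from .neighborhood import knn_coord

__all__ = ["PAMap", "align_features", "compress_features", "weight_points",
           "heatmap", "pam_from_taps"]


@dataclass
class PAMap:
    """Per-point activation weights and their heat-map colours."""

    weights: np.ndarray          # (n,)
    rgb: np.ndarray              # (n, 3) in [0, 1]
    tap_channels: int
    degenerate: bool = False     # zero feature range -> uniform fallback


def align_features(levels, original_points) -> np.ndarray:
    """Align per-level features to the original points.

    ``levels`` is a sequence of ``(coords (m, 3), features (m, C))``; each
    original point takes the features of its nearest level point.  Levels
    already at the original points pass through unchanged.  Returns the
    concatenated (n, sum C) matrix.
    """
    original_points = np.asarray(original_points, dtype=np.float64)
    n = len(original_points)
    aligned = []
    for coords, feats in levels:
        coords = np.asarray(coords, dtype=np.float64)
        feats = np.asarray(feats, dtype=np.float64)
        if len(coords) == 0:
            raise ValueError("level with zero points cannot be aligned")
        if len(coords) != len(feats):
            raise ValueError("level coords/features length mismatch")
        if len(coords) == n and np.array_equal(coords, original_points):
            aligned.append(feats)
            continue
        nn = knn_coord(coords, original_points, k=1)
        aligned.append(feats[nn.indices[:, 0]])
    return np.concatenate(aligned, axis=1)


def compress_features(feature_matrix) -> np.ndarray:
    """Channel-wise per-point maximum: (n, C) -> (n,)."""
    fm = np.asarray(feature_matrix, dtype=np.float64)
    if fm.ndim != 2 or fm.shape[1] < 1:
        raise ValueError("feature matrix must be (n, C) with C >= 1")
    return fm.max(axis=1)


def weight_points(f, minmax: bool = False):
    """Normalise compressed features to per-point weights.

    Literal form (default): w_i = f_i / (max f - min f).  With
    ``minmax=True``: w_i = (f_i - min f) / (max f - min f).  Returns
    ``(weights, degenerate)``; a zero range yields uniform weights and
    sets the degenerate flag.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.size < 2:
        raise ValueError("need at least two points to normalise weights")
    rng = f.max() - f.min()
    if rng == 0:
        return np.full_like(f, 0.5), True
    if minmax:
        return (f - f.min()) / rng, False
    return f / rng, False


def heatmap(weights) -> np.ndarray:
    """RGB heat colours for activation weights.

    Weights are min-max rescaled to w_hat in [0, 1]; R = w_hat,
    B = 1 - w_hat, G = 1 - |2 w_hat - 1|.  The maximum-weight point is
    pure red, the minimum pure blue; R is monotone non-decreasing and B
    monotone non-increasing in the weight.
    """
    w = np.asarray(weights, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    rng = w.max() - w.min()
    what = np.full_like(w, 0.5) if rng == 0 else (w - w.min()) / rng
    rgb = np.column_stack([what, 1.0 - np.abs(2.0 * what - 1.0), 1.0 - what])
    return rgb


def pam_from_taps(levels, original_points, minmax: bool = False,
                  out_ply=None, out_csv=None) -> PAMap:
    """Full pipeline: align -> compress -> weight -> colour.

    Optionally writes the coloured cloud as PLY and the (index, weight)
    table as CSV.
    """
    fm = align_features(levels, original_points)
    f = compress_features(fm)
    w, degenerate = weight_points(f, minmax=minmax)
    rgb = heatmap(w)
    pmap = PAMap(weights=w, rgb=rgb, tap_channels=fm.shape[1], degenerate=degenerate)
    if out_ply is not None:
        write_cloud(LabeledCloud(points=np.asarray(original_points, dtype=np.float64),
                                 rgb=rgb), out_ply)
    if out_csv is not None:
        import pandas as pd
        pd.DataFrame({"point_index": np.arange(len(w)), "weight": w}).to_csv(
            out_csv, index=False)
    return pmap
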