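"""Dual-branch multi-output regression network for body morphometry.

The network maps a segmented back point cloud (n x 3) to the six-element
target (BW, CW, HW, BL, CH, HH).  Architecture:

* a spatial transform predicts a 3x3 matrix theta (identity at init) and
  applies it to the centred input, p' = p theta;
* a location branch performs two rounds of farthest point sampling (each
  reducing the point count by 1/4) with multi-scale ball grouping and
  shared MLPs, reaching n/16 points with 256 channels, then one shared
  MLP and a global max pool to a 1 x 1024 feature;
* a feature branch applies four EdgeConv layers whose k-NN graph is
  rebuilt in feature space after every layer (dynamic graph); layer-0
  features are the transformed coordinates; the four per-point outputs
  (64+64+128+128 = 384 channels, the saliency tap) are concatenated,
  lifted by a shared MLP and max-pooled to another 1 x 1024 feature;
* the two global features are fused to 1 x 2048 and a fully connected
  head emits the six outputs.

Training minimises the unweighted sum of the six per-metric mean squared
errors on raw label scales (kg, cm), with Adam.

Clouds are centred at their centroid and converted mm -> m before the
network; this is a fixed global unit change, identical for every sample,
so absolute body size remains encoded in the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as eg
from .metrics import METRIC_NAMES
from .neighborhood import ball_group, farthest_point_sample, knn_feat

__all__ = ["NetConfig", "DbmoNet", "RegressionSample", "forward", "loss",
           "train_regressor", "predict", "save_model", "load_model"]


@dataclass(frozen=True)
class NetConfig:
    """Every architectural free parameter, pinned for reproducible shapes.

    MSG radii are fractions of the (transformed) cloud's bounding-box
    diagonal, so the same config works across scene scales.
    """

    n_points: int = 1024
    downsample_ratio: int = 4
    sa1_radii: tuple = (0.1, 0.2)
    sa1_max_samples: tuple = (16, 32)
    sa1_mlp: tuple = ((32, 32, 64), (32, 32, 64))
    sa2_radii: tuple = (0.2, 0.4)
    sa2_max_samples: tuple = (16, 32)
    sa2_mlp: tuple = ((64, 64, 128), (64, 64, 128))
    location_global: int = 1024
    edgeconv_k: int = 20
    edgeconv_channels: tuple = (64, 64, 128, 128)
    feature_global: int = 1024
    head: tuple = (512, 128)
    tnet_hidden: tuple = (32, 64)
    tnet_fc: int = 32
    unit_scale: float = 1e-3      # mm -> m
    resample_each_epoch: bool = True
    seed: int = 0

    @property
    def sa2_channels(self) -> int:
        """Per-point width after the second set-abstraction level."""
        return sum(p[-1] for p in self.sa2_mlp)

    @property
    def pam_tap_channels(self) -> int:
        return sum(self.edgeconv_channels)

    @property
    def fused_channels(self) -> int:
        return self.location_global + self.feature_global

    @classmethod
    def reduced(cls, seed: int = 0) -> "NetConfig":
        """Quarter-width preset for desk-scale training (n = 256)."""
        return cls(n_points=256,
                   sa1_mlp=((8, 8, 16), (8, 8, 16)),
                   sa2_mlp=((16, 16, 32), (16, 16, 32)),
                   location_global=256,
                   edgeconv_k=10,
                   edgeconv_channels=(16, 16, 32, 32),
                   feature_global=256,
                   head=(128, 32),
                   seed=seed)


@dataclass
class RegressionSample:
    """One training example: back points (mm), target vector, subject id."""

    points: np.ndarray
    target: np.ndarray            # (6,) on raw scales, METRIC_NAMES order
    subject_id: int = 0


class DbmoNet:
    """Dual-branch morphometric regression network."""

    def __init__(self, config: NetConfig | None = None):
        self.config = config or NetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        # spatial transform: per-point MLP -> global max -> FC -> 9 values;
        # final layer zero weights + identity bias, so theta starts exactly
        # at the identity.
        self.tnet_point = eg.MLP([3, *cfg.tnet_hidden], rng, activation="leaky")
        self.tnet_fc = eg.Linear(cfg.tnet_hidden[-1], cfg.tnet_fc, rng)
        self.tnet_out = eg.Linear(cfg.tnet_fc, 9, rng)
        self.tnet_out.W.data[:] = 0.0
        self.tnet_out.b.data[:] = np.eye(3).ravel()
        # location branch
        self.sa1 = [eg.MLP([3, *plan], rng, activation="leaky")
                    for plan in cfg.sa1_mlp]
        c1 = sum(p[-1] for p in cfg.sa1_mlp)
        self.sa2 = [eg.MLP([3 + c1, *plan], rng, activation="leaky")
                    for plan in cfg.sa2_mlp]
        self.location_lift = eg.Linear(cfg.sa2_channels, cfg.location_global, rng)
        # feature branch
        self.edge_layers = []
        c = 3
        for c_out in cfg.edgeconv_channels:
            self.edge_layers.append(eg.Linear(2 * c, c_out, rng))
            c = c_out
        self.feature_lift = eg.Linear(cfg.pam_tap_channels, cfg.feature_global, rng)
        # head
        widths = [cfg.fused_channels, *cfg.head, 6]
        self.head = eg.MLP(widths, rng, final_relu=False, activation="leaky")

    def parameters(self):
        ps = (self.tnet_point.parameters() + self.tnet_fc.parameters()
              + self.tnet_out.parameters())
        for m in self.sa1 + self.sa2:
            ps += m.parameters()
        ps += self.location_lift.parameters()
        for layer in self.edge_layers:
            ps += layer.parameters()
        ps += self.feature_lift.parameters()
        ps += self.head.parameters()
        return ps

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data[:] = s

    # -- components -----------------------------------------------------

    def spatial_transform(self, x: eg.Tensor):
        """Predict theta and apply it: rows of x are multiplied by theta."""
        h = self.tnet_point(x)
        g = eg.reshape(eg.amax(h, axis=0), (1, -1))
        theta = eg.reshape(self.tnet_out(eg.leaky_relu(self.tnet_fc(g))), (3, 3))
        if not np.all(np.isfinite(theta.data)):
            raise FloatingPointError("non-finite transform matrix")
        return eg.matmul(x, theta), theta

    def _set_abstraction(self, coords_np, feats, centers_idx, radii, max_samples,
                         mlps, transformed):
        """One FPS + multi-scale-grouping + shared-MLP + max level.

        ``transformed`` is the differentiable coordinate Tensor aligned
        with ``coords_np`` (its detached values)."""
        diag = max(np.linalg.norm(coords_np.max(axis=0) - coords_np.min(axis=0)),
                   1e-9)  # degenerate (all-coincident) clouds keep radius > 0
        centers_np = coords_np[centers_idx]
        centers_t = eg.take(transformed, centers_idx)
        m = len(centers_idx)
        scale_feats = []
        for radius_frac, max_s, mlp in zip(radii, max_samples, mlps):
            r = radius_frac * diag
            idx, _, _ = ball_group(coords_np, centers_np, r, max_s)
            rel = eg.sub(eg.take(transformed, idx),
                         eg.reshape(centers_t, (m, 1, 3)))
            if feats is not None:
                grouped = eg.concat([rel, eg.take(feats, idx)], axis=2)
            else:
                grouped = rel
            c_in = grouped.data.shape[2]
            h = mlp(eg.reshape(grouped, (m * max_s, c_in)))
            h = eg.reshape(h, (m, max_s, h.data.shape[1]))
            scale_feats.append(eg.amax(h, axis=1))
        return centers_np, eg.concat(scale_feats, axis=1), centers_t

    def location_branch(self, transformed: eg.Tensor):
        """FPS + MSG set abstraction; returns the 1 x G global feature and
        the per-level (coords, per-point features) for the saliency tap."""
        cfg = self.config
        x_np = transformed.data
        n = len(x_np)
        m1 = max(n // cfg.downsample_ratio, 1)
        idx1 = farthest_point_sample(x_np, m1)
        c1_np, f1, c1_t = self._set_abstraction(x_np, None, idx1, cfg.sa1_radii,
                                                cfg.sa1_max_samples, self.sa1,
                                                transformed)
        m2 = max(m1 // cfg.downsample_ratio, 1)
        idx2 = farthest_point_sample(c1_np, m2)
        c2_np, f2, _ = self._set_abstraction(c1_np, f1, idx2, cfg.sa2_radii,
                                             cfg.sa2_max_samples, self.sa2,
                                             c1_t)
        lifted = eg.leaky_relu(self.location_lift(f2))
        global_feat = eg.reshape(eg.amax(lifted, axis=0), (1, -1))
        levels = [(c1_np, f1), (c2_np, f2)]
        return global_feat, levels

    def feature_branch(self, transformed: eg.Tensor):
        """Four dynamic-graph EdgeConv layers; returns the 1 x G global
        feature, the per-layer per-point features, and the n x 384 tap."""
        cfg = self.config
        n = transformed.data.shape[0]
        if cfg.edgeconv_k >= n:
            raise ValueError(f"edgeconv_k={cfg.edgeconv_k} must be < n={n}")
        f = transformed
        layer_outputs = []
        for layer in self.edge_layers:
            nn = knn_feat(f.data, cfg.edgeconv_k)
            idx = nn.indices
            c = f.data.shape[1]
            fj = eg.take(f, idx)                          # (n, k, C)
            fi = eg.reshape(f, (n, 1, c))
            diff = eg.sub(fj, fi)
            fi_rep = eg.add(fi, eg.Tensor(np.zeros_like(fj.data)))
            edge = eg.concat([fi_rep, diff], axis=2)      # (n, k, 2C)
            h = eg.leaky_relu(layer(eg.reshape(edge, (n * cfg.edgeconv_k, 2 * c))))
            h = eg.reshape(h, (n, cfg.edgeconv_k, -1))
            f = eg.amax(h, axis=1)
            layer_outputs.append(f)
        tap = eg.concat(layer_outputs, axis=1)            # (n, 384)
        lifted = eg.leaky_relu(self.feature_lift(tap))
        global_feat = eg.reshape(eg.amax(lifted, axis=0), (1, -1))
        return global_feat, layer_outputs, tap

    # -- full forward ----------------------------------------------------

    def forward(self, points_mm: np.ndarray, return_intermediates: bool = False):
        """Predict the six metrics for one cloud (n x 3, mm).

        The cloud must already be the segmented back and hold exactly
        ``config.n_points`` points (use :func:`subsample_points`)."""
        cfg = self.config
        pts = np.asarray(points_mm, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        x0 = (pts - pts.mean(axis=0)) * cfg.unit_scale
        transformed, theta = self.spatial_transform(eg.Tensor(x0))
        loc_global, loc_levels = self.location_branch(transformed)
        feat_global, edge_feats, tap = self.feature_branch(transformed)
        fused = eg.concat([loc_global, feat_global], axis=1)   # (1, 2048)
        pred = self.head(fused)                                # (1, 6)
        if not return_intermediates:
            return pred
        inter = {
            "theta": theta.data.copy(),
            "transformed": transformed.data.copy(),
            "fused_width": fused.data.shape[1],
            "location_levels": [(c, f.data.copy()) for c, f in loc_levels],
            "edgeconv_features": [f.data.copy() for f in edge_feats],
            "tap": tap.data.copy(),
        }
        return pred, inter


def save_model(model: DbmoNet, path) -> None:
    """Serialize a model (config + weights) with a format-version header."""
    import dataclasses

    payload = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, format_version=1,
             config=np.array([repr(dataclasses.asdict(model.config))]),
             **payload)


def load_model(path) -> DbmoNet:
    import ast

    with np.load(path, allow_pickle=False) as data:
        version = int(data["format_version"])
        if version != 1:
            raise ValueError(f"unsupported model format version {version}")
        cfg = NetConfig(**ast.literal_eval(str(data["config"][0])))
        model = DbmoNet(cfg)
        for i, p in enumerate(model.parameters()):
            p.data[:] = data[f"param_{i}"]
    return model


def subsample_points(points, n, rng: np.random.Generator):
    """Random subsample (without replacement) to n points; clouds smaller
    than n are padded by sampling with replacement."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) >= n:
        sel = rng.choice(len(points), size=n, replace=False)
    else:
        sel = rng.choice(len(points), size=n, replace=True)
    return points[sel]


def forward(model: DbmoNet, points_mm, **kw):
    return model.forward(points_mm, **kw)


def loss(pred: eg.Tensor, targets):
    """Summed per-metric MSE on raw scales.

    Returns (scalar loss Tensor, dict of per-metric MSE floats)."""
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if targets.shape != pred.data.shape:
        raise ValueError(f"shape mismatch {targets.shape} vs {pred.data.shape}")
    if targets.shape[0] == 0:
        raise ValueError("empty batch")
    diff = eg.sub(pred, eg.Tensor(targets))
    per_metric = eg.amean(eg.mul(diff, diff), axis=0)      # (6,)
    total = eg.asum(per_metric)
    components = dict(zip(METRIC_NAMES, per_metric.data.tolist()))
    return total, components


def predict(model: DbmoNet, points_mm, seed: int = 0) -> np.ndarray:
    """Predict the six metrics for an arbitrary-size back cloud (random
    seeded subsample to the model's n)."""
    rng = np.random.default_rng(seed)
    pts = subsample_points(points_mm, model.config.n_points, rng)
    return model.forward(pts).data[0]


def train_regressor(train_set, val_set, config: NetConfig | None = None, *,
                    epochs: int = 30, lr: float = 1e-3, batch_size: int = 8,
                    seed: int = 0):
    """Train the regressor; returns (model, history).

    ``train_set`` / ``val_set`` are sequences of :class:`RegressionSample`.
    Subjects must be disjoint between the two (hard error otherwise).
    Input clouds are randomly subsampled to ``config.n_points`` — afresh
    every epoch when ``config.resample_each_epoch`` (augmentation),
    otherwise once.  The final head bias starts at the training-set
    label mean.  The best-validation-loss parameter state is restored at
    the end.  Fully deterministic for a fixed seed.
    """
    config = config or NetConfig()
    train_subj = {s.subject_id for s in train_set}
    val_subj = {s.subject_id for s in val_set}
    overlap = train_subj & val_subj
    if overlap:
        raise ValueError(f"subject leakage between train and validation: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    model = DbmoNet(config)
    targets = np.stack([s.target for s in train_set])
    model.head.layers[-1].b.data[:] = targets.mean(axis=0)

    val_pts = [subsample_points(s.points, config.n_points, rng) for s in val_set]
    val_targets = np.stack([s.target for s in val_set]) if val_set else None
    fixed_train = None
    if not config.resample_each_epoch:
        fixed_train = [subsample_points(s.points, config.n_points, rng)
                       for s in train_set]

    opt = eg.Adam(model.parameters(), lr=lr)
    history = []
    best = (np.inf, None)
    order = np.arange(len(train_set))
    for epoch in range(epochs):
        rng.shuffle(order)
        if config.resample_each_epoch:
            epoch_pts = {i: subsample_points(train_set[i].points,
                                             config.n_points, rng)
                         for i in order}
        train_loss = 0.0
        comp_sum = dict.fromkeys(METRIC_NAMES, 0.0)
        n_batches = 0
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            opt.zero_grad()
            preds = []
            for i in batch:
                pts = epoch_pts[i] if fixed_train is None else fixed_train[i]
                preds.append(model.forward(pts))
            pred = eg.concat(preds, axis=0)
            total, comps = loss(pred, targets[batch])
            total.backward()
            opt.step()
            train_loss += float(total.data)
            for k, v in comps.items():
                comp_sum[k] += v
            n_batches += 1
        row = {"epoch": epoch, "train_loss": train_loss / n_batches,
               **{f"train_mse_{k}": v / n_batches for k, v in comp_sum.items()}}
        if val_set:
            vpred = np.stack([model.forward(p).data[0] for p in val_pts])
            verr = val_targets - vpred
            vmse = (verr**2).mean(axis=0)
            row["val_loss"] = float(vmse.sum())
            if row["val_loss"] < best[0]:
                best = (row["val_loss"], model.state())
        history.append(row)
    if best[1] is not None:
        model.load_state(best[1])
    return model, history
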