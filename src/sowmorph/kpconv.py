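"""Compact kernel-point-convolution encoder-decoder for back segmentation.

Each point is classified as back (1) or background (0).  The encoder
stacks three kernel-point convolution levels, each preceded by farthest
point sampling at a 1/4 ratio; the decoder propagates features back with
nearest-neighbour upsampling and skip concatenation, and a pointwise
head emits two logits per original point.

A kernel point convolution aggregates neighbour features through a set
of learnable weight matrices attached to 3D kernel points:

    (F * g)(x) = sum_{x_i in N_x} sum_k  infl(|| (x_i - x) - (kp_k + D_k(x)) ||) W_k f_i

with linear influence infl(d) = max(0, 1 - d/sigma) and spherical
neighbourhoods N_x of radius r.  In rigid mode the kernel offsets D are
identically zero; in deformable mode they are predicted per centre by a
rigid kernel convolution and smoothly bounded to +/- sigma.

The segmentation metric suite (overall accuracy, precision, recall, F1,
per-class IoU and their mean) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as eg
from ._kernel_points import KERNEL_POINTS_15
from .geometry import LabeledCloud
from .neighborhood import ball_group, farthest_point_sample, knn_coord

__all__ = [
    "KernelSpec",
    "SegConfig",
    "SegModel",
    "ConfusionCounts",
    "SegmentationReport",
    "kernel_point_conv",
    "segment",
    "train_segmentation",
    "segmentation_metrics",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel geometry: unit-radius dispositions, neighbourhood radius r
    (mm), influence width sigma (mm), and the deformable flag."""

    kernel_points: np.ndarray = field(default_factory=lambda: KERNEL_POINTS_15.copy())
    radius: float = 300.0
    sigma: float = 150.0
    deformable: bool = False

    def __post_init__(self):
        if len(self.kernel_points) < 1:
            raise ValueError("need at least one kernel point")
        if self.radius <= 0 or self.sigma <= 0:
            raise ValueError("radius and sigma must be positive")

    @property
    def positions(self) -> np.ndarray:
        """Kernel point positions in mm (dispositions scaled by radius)."""
        return self.kernel_points * self.radius


def kernel_point_conv(points, features, centers, kernel: KernelSpec, weights,
                      neighbor_idx=None, neighbor_counts=None, offsets=None,
                      max_samples: int = 16):
    """Apply one kernel point convolution.

    ``features`` is an autodiff Tensor (N, Cin); ``weights`` a list of K
    (Cin, Cout) Tensors, one per kernel point.  Neighbourhoods default to
    a ball query of the kernel's radius; precomputed ``neighbor_idx`` /
    ``neighbor_counts`` (from :func:`ball_group`) may be passed instead.
    ``offsets`` is an optional (M, K, 3) Tensor of kernel point offsets
    (deformable mode).  Centres with empty neighbourhoods produce zero
    output (the empty sum).
    """
    points = np.asarray(points, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    if features.data.shape[0] != points.shape[0]:
        raise ValueError(
            f"feature count {features.data.shape[0]} != point count {points.shape[0]}")
    if neighbor_idx is None:
        neighbor_idx, neighbor_counts, _ = ball_group(points, centers,
                                                      kernel.radius, max_samples)
    m, nn = neighbor_idx.shape
    valid = np.arange(nn)[None, :] < np.minimum(neighbor_counts, nn)[:, None]
    rel = points[neighbor_idx] - centers[:, None, :]          # (m, nn, 3)
    kp = kernel.positions                                     # (K, 3)
    K = len(kp)
    fn = eg.take(features, neighbor_idx)                      # (m, nn, Cin)
    out = None
    for k in range(K):
        if offsets is not None:
            kp_k = eg.add(eg.Tensor(kp[k][None, None, :]),
                          eg.reshape(_slice_k(offsets, k), (m, 1, 3)))
            diff = eg.sub(eg.Tensor(rel), kp_k)
            d = eg.sqrt(eg.asum(eg.mul(diff, diff), axis=2))
            infl = eg.relu(eg.sub(eg.Tensor(np.ones((m, nn))),
                                  eg.scale(d, 1.0 / kernel.sigma)))
            infl = eg.mul(infl, eg.Tensor(valid.astype(np.float64)))
            weighted = eg.mul(eg.reshape(infl, (m, nn, 1)), fn)
        else:
            d = np.linalg.norm(rel - kp[k][None, None, :], axis=2)
            infl = np.maximum(0.0, 1.0 - d / kernel.sigma) * valid
            weighted = eg.mul(eg.Tensor(infl[:, :, None]), fn)
        summed = eg.asum(weighted, axis=1)                    # (m, Cin)
        term = eg.matmul(summed, weights[k])
        out = term if out is None else eg.add(out, term)
    return out


def _slice_k(offsets, k):
    """Select kernel point k from an (M, K, 3) offsets Tensor."""
    m = offsets.data.shape[0]
    K = offsets.data.shape[1]
    flat = eg.reshape(offsets, (m * K, 3))
    return eg.take(flat, np.arange(m) * K + k)


@dataclass
class SegConfig:
    """Architectural free parameters of the compact segmenter.

    Radii are expressed as multiples of the cloud's mean point spacing
    (sqrt of floor-plane bounding-box area per point) so the same config
    works across scene scales; sigma is a fixed fraction of each radius.
    """

    n_points: int = 768
    channels: tuple = (32, 64, 128)
    radius_factors: tuple = (2.5, 5.0, 10.0)
    sigma_ratio: float = 0.5
    max_samples: int = 16
    n_kernel_points: int = 15
    downsample_ratio: int = 4
    deformable_level: int = 2   # 1-based level index using deformable kernels; 0 = none
    input_feature_mode: str = "height"  # "height" (1 + centred z) or "ones"
    seed: int = 0


class _KPLayer:
    def __init__(self, c_in, c_out, K, rng, deformable):
        std = np.sqrt(2.0 / (c_in * K))
        self.weights = [eg.Tensor(rng.normal(0.0, std, (c_in, c_out)), requires_grad=True)
                        for _ in range(K)]
        self.deformable = deformable
        self.offset_weights = None
        if deformable:
            # offsets predicted by a rigid kernel convolution, init ~0
            self.offset_weights = [eg.Tensor(rng.normal(0.0, 1e-3, (c_in, 3 * K)),
                                             requires_grad=True) for _ in range(K)]

    def parameters(self):
        ps = list(self.weights)
        if self.offset_weights:
            ps += self.offset_weights
        return ps


class SegModel:
    """Compact encoder-decoder segmentation network."""

    def __init__(self, config: SegConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        K = config.n_kernel_points
        kp = KERNEL_POINTS_15[:K].copy()
        self.kernel_dispositions = kp
        c_in = 2 if config.input_feature_mode == "height" else 1
        self.enc_layers = []
        prev_c = c_in
        for li, c_out in enumerate(config.channels, start=1):
            self.enc_layers.append(
                _KPLayer(prev_c, c_out, K, rng, deformable=(li == config.deformable_level)))
            prev_c = c_out
        # decoder: top level has no skip-refit; below, pointwise linear on
        # (upsampled + skip) concatenation
        chans = list(config.channels)
        self.dec_layers = []
        for li in range(len(chans) - 2, -1, -1):
            self.dec_layers.append(eg.Linear(chans[li + 1] + chans[li], chans[li], rng))
        self.head_hidden = eg.Linear(chans[0] + c_in, chans[0], rng)
        self.head_out = eg.Linear(chans[0], 2, rng)
        self._offset_penalty = None

    def parameters(self):
        ps = []
        for layer in self.enc_layers:
            ps += layer.parameters()
        for layer in self.dec_layers:
            ps += layer.parameters()
        ps += self.head_hidden.parameters()
        ps += self.head_out.parameters()
        return ps

    # -- geometry plan (weight-independent, cacheable per cloud) --------

    def plan(self, points: np.ndarray):
        """Precompute FPS pyramids, ball groups, radii and upsample maps."""
        cfg = self.config
        points = np.asarray(points, dtype=np.float64)
        n = len(points)
        if n // cfg.downsample_ratio ** len(cfg.channels) < 1:
            raise ValueError(
                f"cloud of {n} points is too small for {len(cfg.channels)} "
                f"levels at ratio 1/{cfg.downsample_ratio}")
        span = points[:, :2].max(axis=0) - points[:, :2].min(axis=0)
        spacing = np.sqrt(max(span[0] * span[1], 1e-9) / n)
        levels = [points]
        groups = []
        kernels = []
        m_prev = n
        for li, rf in enumerate(cfg.radius_factors):
            m = m_prev // cfg.downsample_ratio
            centers_idx = farthest_point_sample(levels[-1], m)
            centers = levels[-1][centers_idx]
            r = rf * spacing
            kspec = KernelSpec(kernel_points=self.kernel_dispositions, radius=r,
                               sigma=cfg.sigma_ratio * r,
                               deformable=(li + 1 == cfg.deformable_level))
            idx, counts, _ = ball_group(levels[-1], centers, r, cfg.max_samples)
            groups.append((idx, counts))
            kernels.append(kspec)
            levels.append(centers)
            m_prev = m
        ups = []
        for li in range(len(levels) - 1, 0, -1):
            nn = knn_coord(levels[li], levels[li - 1], k=1)
            ups.append(nn.indices[:, 0])
        return {"points": points, "levels": levels, "groups": groups,
                "kernels": kernels, "ups": ups}

    # -- forward --------------------------------------------------------

    def input_features(self, points: np.ndarray) -> np.ndarray:
        if self.config.input_feature_mode == "ones":
            return np.ones((len(points), 1))
        z = (points[:, 2] - np.median(points[:, 2])) / 1000.0
        return np.column_stack([np.ones(len(points)), z])

    def forward(self, plan) -> eg.Tensor:
        cfg = self.config
        feats = eg.Tensor(self.input_features(plan["points"]))
        skips = [feats]
        self._offset_penalty = None
        x = feats
        for li, layer in enumerate(self.enc_layers):
            idx, counts = plan["groups"][li]
            kspec = plan["kernels"][li]
            centers = plan["levels"][li + 1]
            offsets = None
            if layer.deformable:
                raw = kernel_point_conv(plan["levels"][li], x, centers,
                                        KernelSpec(kernel_points=self.kernel_dispositions,
                                                   radius=kspec.radius, sigma=kspec.sigma),
                                        layer.offset_weights, neighbor_idx=idx,
                                        neighbor_counts=counts)
                m = raw.data.shape[0]
                K = cfg.n_kernel_points
                bounded = eg.scale(eg.tanh(eg.scale(raw, 1.0 / kspec.sigma)), kspec.sigma)
                offsets = eg.reshape(bounded, (m, K, 3))
                pen = eg.amean(eg.mul(offsets, offsets))
                self._offset_penalty = (pen if self._offset_penalty is None
                                        else eg.add(self._offset_penalty, pen))
            x = eg.relu(kernel_point_conv(plan["levels"][li], x, centers, kspec,
                                          layer.weights, neighbor_idx=idx,
                                          neighbor_counts=counts, offsets=offsets))
            skips.append(x)
        # decoder
        for di, up_idx in enumerate(plan["ups"]):
            x = eg.take(x, up_idx)
            skip = skips[len(self.enc_layers) - 1 - di]
            if di < len(self.dec_layers):
                x = eg.relu(self.dec_layers[di](eg.concat([x, skip], axis=1)))
            else:
                x = eg.relu(self.head_hidden(eg.concat([x, skip], axis=1)))
        return self.head_out(x)


def segment(model: SegModel, cloud: LabeledCloud, plan=None):
    """Classify every point of ``cloud``; returns (classes, probabilities)
    in the original point order."""
    if plan is None:
        plan = model.plan(cloud.points)
    logits = model.forward(plan)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return probs.argmax(axis=1), probs


def train_segmentation(train_samples, config: SegConfig | None = None, *,
                       val_samples=None, epochs: int = 10, lr: float = 1e-3,
                       seed: int = 0, offset_reg: float = 0.1):
    """Train the segmenter on labeled clouds.

    ``train_samples`` / ``val_samples`` are sequences of objects with a
    ``cloud`` attribute (or LabeledCloud directly) carrying {0,1} labels.
    Each cloud is subsampled once to ``config.n_points`` with the run
    seed; geometry plans are cached across epochs (the pose of a sample
    does not change during training).  Cross-entropy is weighted by
    inverse class frequency over the training set.  Returns
    ``(model, history)`` with per-epoch train/validation loss and
    validation overall accuracy.
    """
    config = config or SegConfig()
    rng = np.random.default_rng(seed)
    model = SegModel(config)

    def prepare(samples):
        prepped = []
        for s in samples:
            cloud = s.cloud if hasattr(s, "cloud") else s
            if cloud.labels is None:
                raise ValueError("training requires labeled clouds")
            n = len(cloud)
            take_n = min(config.n_points, n)
            sel = rng.choice(n, size=take_n, replace=False)
            pts, labs = cloud.points[sel], cloud.labels[sel]
            prepped.append((model.plan(pts), labs))
        return prepped

    train = prepare(train_samples)
    val = prepare(val_samples) if val_samples else []
    all_labels = np.concatenate([labs for _, labs in train])
    freq = np.bincount(all_labels, minlength=2) / len(all_labels)
    class_weights = 1.0 / np.maximum(freq, 1e-6)
    class_weights /= class_weights.sum()

    opt = eg.Adam(model.parameters(), lr=lr)
    history = []
    order = np.arange(len(train))
    for epoch in range(epochs):
        rng.shuffle(order)
        total = 0.0
        for i in order:
            plan, labs = train[i]
            opt.zero_grad()
            logits = model.forward(plan)
            loss, _ = eg.softmax_cross_entropy(logits, labs, class_weights)
            if model._offset_penalty is not None:
                loss = eg.add(loss, eg.scale(model._offset_penalty, offset_reg))
            loss.backward()
            opt.step()
            total += float(loss.data)
        row = {"epoch": epoch, "train_loss": total / len(train)}
        if val:
            vloss, correct, count = 0.0, 0, 0
            for plan, labs in val:
                logits = model.forward(plan)
                loss, probs = eg.softmax_cross_entropy(logits, labs, class_weights)
                vloss += float(loss.data)
                correct += int((probs.argmax(axis=1) == labs).sum())
                count += len(labs)
            row["val_loss"] = vloss / len(val)
            row["val_oa"] = 100.0 * correct / count
        history.append(row)
    return model, history


# ---------------------------------------------------------------------------
# Segmentation metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; class 1 = sow back, class 0 = background."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN == 0:
            raise ValueError("confusion counts sum to zero")

    @classmethod
    def from_predictions(cls, truth, pred) -> "ConfusionCounts":
        truth = np.asarray(truth).astype(bool)
        pred = np.asarray(pred).astype(bool)
        return cls(TP=int((truth & pred).sum()), FP=int((~truth & pred).sum()),
                   FN=int((truth & ~pred).sum()), TN=int((~truth & ~pred).sum()))


@dataclass
class SegmentationReport:
    """All values in percent; nan marks an undefined (0/0) metric."""

    oa: float
    precision: float
    recall: float
    f1: float
    iou_body: float
    iou_background: float
    miou: float

    def to_dict(self):
        return {k: round(v, 2) if np.isfinite(v) else None
                for k, v in self.__dict__.items()}


def _ratio(num, den):
    return 100.0 * num / den if den > 0 else float("nan")


def segmentation_metrics(counts: ConfusionCounts) -> SegmentationReport:
    """Overall accuracy, precision, recall, F1, per-class IoU and mIoU.

    Zero denominators yield nan (undefined), never a silent zero.
    """
    c = counts
    oa = _ratio(c.TP + c.TN, c.TP + c.TN + c.FP + c.FN)
    precision = _ratio(c.TP, c.TP + c.FP)
    recall = _ratio(c.TP, c.TP + c.FN)
    if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0:
        f1 = 2.0 * recall * precision / (recall + precision)
    else:
        f1 = float("nan")
    iou1 = _ratio(c.TP, c.TP + c.FP + c.FN)
    iou2 = _ratio(c.TN, c.TN + c.FN + c.FP)
    miou = 0.5 * (iou1 + iou2)
    return SegmentationReport(oa=oa, precision=precision, recall=recall, f1=f1,
                              iou_body=iou1, iou_background=iou2, miou=miou)
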