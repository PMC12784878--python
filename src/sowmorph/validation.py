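"""Scaled-down synthetic recovery studies.

These two runs are the package's end-to-end validation: can the compact
segmenter and the reduced dual-branch regressor recover, from rendered
synthetic scenes alone, the segmentation labels and the six body metrics
the generator planted?  Problem sizes are desk-scale — half-resolution
rasters (200 x 120, same field of view), a few hundred scenes, reduced
channel widths and n = 256 input points — chosen so a full run completes
in minutes on one CPU while leaving every architectural mechanism
exercised.  The reduced regressor preset trains with lr 3e-3 (the
full-scale default of 1e-3 needs far more optimisation steps than the
scaled-down budget provides).
"""

from __future__ import annotations

import numpy as np

from .dbmonet import NetConfig, RegressionSample, predict, train_regressor
from .geometry import Intrinsics, LabeledCloud
from .kpconv import (ConfusionCounts, SegConfig, segment, segmentation_metrics,
                     train_segmentation)
from .metrics import regression_report
from .pipeline import split_subjects
from .synthetic import generate_dataset

__all__ = ["HALF_RES_INTRINSICS", "regression_recovery_study",
           "segmentation_recovery_study"]

# Same 87-degree field of view as the 400x240 sensor at a quarter the pixels.
HALF_RES_INTRINSICS = Intrinsics(fx=107.9673, fy=107.9673, width=200, height=120)


def _partitioned_dataset(n_subjects, frames_per_subject, seed):
    samples, manifest = generate_dataset(
        n_subjects, 1, frames_per_subject, seed=seed,
        scene_kwargs={"intrinsics": HALF_RES_INTRINSICS})
    split = split_subjects(sorted(manifest["subject_id"].unique()),
                           seed=seed + 1)
    manifest["split"] = manifest["subject_id"].map(split.assignment)
    parts = {}
    for p in ("train", "val", "test"):
        idx = manifest.index[manifest["split"] == p]
        parts[p] = [(samples[i], int(manifest.loc[i, "subject_id"])) for i in idx]
    return parts


def regression_recovery_study(seed: int = 0, n_subjects: int = 96,
                              frames_per_subject: int = 5, epochs: int = 48,
                              lr: float = 3e-3) -> dict:
    """Train the reduced regressor on synthetic scenes; report held-out errors.

    Returns a dict with per-metric MAPE/MAE/RMSE on the test subjects,
    the training history, and the partition sizes.
    """
    parts = _partitioned_dataset(n_subjects, frames_per_subject, seed)

    def build(part):
        return [RegressionSample(points=s.cloud.points[s.cloud.labels == 1],
                                 target=s.metrics.to_array(), subject_id=subj)
                for s, subj in parts[part]]

    train, val, test = build("train"), build("val"), build("test")
    model, history = train_regressor(train, val, NetConfig.reduced(seed=seed),
                                     epochs=epochs, lr=lr, seed=seed)
    truth = np.stack([s.target for s in test])
    preds = np.stack([predict(model, s.points, seed=seed + 100 + i)
                      for i, s in enumerate(test)])
    report = regression_report(truth, preds)
    return {"report": report, "history": history, "model": model,
            "sizes": {p: len(parts[p]) for p in parts}}


def segmentation_recovery_study(seed: int = 0, n_subjects: int = 50,
                                frames_per_subject: int = 4, epochs: int = 6,
                                lr: float = 1e-3) -> dict:
    """Train the compact segmenter on synthetic scenes; report held-out
    point-classification metrics."""
    parts = _partitioned_dataset(n_subjects, frames_per_subject, seed)
    config = SegConfig(n_points=768, seed=seed)
    model, history = train_segmentation([s for s, _ in parts["train"]], config,
                                        val_samples=[s for s, _ in parts["val"]],
                                        epochs=epochs, lr=lr, seed=seed)
    rng = np.random.default_rng(seed + 5)
    tp = fp = fn = tn = 0
    for s, _ in parts["test"]:
        sel = rng.choice(len(s.cloud), size=min(config.n_points, len(s.cloud)),
                         replace=False)
        pred, _ = segment(model, LabeledCloud(points=s.cloud.points[sel]))
        c = ConfusionCounts.from_predictions(s.cloud.labels[sel], pred)
        tp += c.TP; fp += c.FP; fn += c.FN; tn += c.TN
    report = segmentation_metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
    return {"report": report, "history": history, "model": model,
            "sizes": {p: len(parts[p]) for p in parts}}
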