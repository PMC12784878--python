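"""Train the compact kernel-point segmenter on a handful of scenes.

Renders a small synthetic dataset, trains for a few epochs, and prints
held-out point-classification metrics.  The segmenter labels each point
back (1) or background (0); floors dominate top-view scenes, so training
uses inverse-frequency class weights.  (A few minutes of CPU; the
full-scale study in scripts/acceptance.py uses more scenes and epochs.)
"""

import numpy as np

from sowmorph.geometry import LabeledCloud
from sowmorph.kpconv import (ConfusionCounts, SegConfig, segment,
                             segmentation_metrics, train_segmentation)
from sowmorph.synthetic import generate_dataset
from sowmorph.validation import HALF_RES_INTRINSICS

samples, _ = generate_dataset(12, 1, 2, seed=3,
                              scene_kwargs={"intrinsics": HALF_RES_INTRINSICS})
train, test = samples[:18], samples[18:]

model, history = train_segmentation(train, SegConfig(n_points=512),
                                    epochs=3, seed=0)
print("train loss per epoch:", [round(h["train_loss"], 3) for h in history])

rng = np.random.default_rng(0)
tp = fp = fn = tn = 0
for s in test:
    sel = rng.choice(len(s.cloud), 512, replace=False)
    pred, _ = segment(model, LabeledCloud(points=s.cloud.points[sel]))
    c = ConfusionCounts.from_predictions(s.cloud.labels[sel], pred)
    tp, fp, fn, tn = tp + c.TP, fp + c.FP, fn + c.FN, tn + c.TN

rep = segmentation_metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
print("held-out:", rep.to_dict())
# OA counts every point; mIoU averages the back and background IoUs and
# is the stricter number when the back is a small fraction of the scene.
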