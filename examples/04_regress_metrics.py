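"""Train the reduced dual-branch regressor on synthetic back clouds.

Uses ground-truth back labels as input (segmentation and regression are
separable stages), trains a quarter-width network at n = 256 points for
a few epochs, and prints held-out per-metric MAPE.  A short demo run —
the full scaled-down study lives in sowmorph.validation and takes a few
more minutes.
"""

import numpy as np

from sowmorph.dbmonet import NetConfig, RegressionSample, predict, train_regressor
from sowmorph.metrics import regression_report
from sowmorph.pipeline import split_subjects
from sowmorph.synthetic import generate_dataset
from sowmorph.validation import HALF_RES_INTRINSICS

samples, manifest = generate_dataset(20, 1, 3, seed=5,
                                     scene_kwargs={"intrinsics": HALF_RES_INTRINSICS})
split = split_subjects(sorted(manifest["subject_id"].unique()), seed=1)
manifest["split"] = manifest["subject_id"].map(split.assignment)


def build(part):
    idx = manifest.index[manifest["split"] == part]
    return [RegressionSample(points=samples[i].cloud.points[samples[i].cloud.labels == 1],
                             target=samples[i].metrics.to_array(),
                             subject_id=int(manifest.loc[i, "subject_id"]))
            for i in idx]


train, val, test = build("train"), build("val"), build("test")
model, history = train_regressor(train, val, NetConfig.reduced(),
                                 epochs=10, lr=3e-3, seed=0)
print("validation loss:", [round(h["val_loss"], 1) for h in history])

truth = np.stack([s.target for s in test])
pred = np.stack([predict(model, s.points, seed=i) for i, s in enumerate(test)])
rep = regression_report(truth, pred)
print("held-out MAPE (%):", {k: round(v, 2) for k, v in rep.mape.items()})
# The loss is the unweighted sum of six per-metric MSEs on raw scales
# (kg, cm); heights (CH, HH) are the easiest to recover because they map
# directly onto the depth span of the back cloud.
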