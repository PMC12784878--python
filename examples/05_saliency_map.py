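"""Point activation mapping: which points drive the network's features.

Taps the per-point features of the four EdgeConv layers of a regressor,
compresses channels by the maximum, normalises to weights, and writes a
heat-coloured PLY (blue = low activation, red = high).  Here the model
is untrained, so the map reflects the geometry-driven initial features;
tapping a trained model works identically.
"""

import numpy as np

from sowmorph.dbmonet import DbmoNet, NetConfig, subsample_points
from sowmorph.pam import pam_from_taps
from sowmorph.synthetic import SceneSpec, generate_scene

sample = generate_scene(SceneSpec(seed=2))
back = sample.cloud.points[sample.cloud.labels == 1]

model = DbmoNet(NetConfig.reduced(seed=0))
pts = subsample_points(back, model.config.n_points, np.random.default_rng(0))
_, inter = model.forward(pts, return_intermediates=True)

levels = [(pts, f) for f in inter["edgeconv_features"]]
pmap = pam_from_taps(levels, pts, out_ply="pam_demo.ply")

print(f"tap width          : {pmap.tap_channels} channels")
print(f"weight range       : {pmap.weights.min():.3f} .. {pmap.weights.max():.3f}")
top = np.argsort(pmap.weights)[-3:]
print(f"hottest points (mm): {np.round(pts[top], 0)}")
print("wrote pam_demo.ply (RGB heat map; open in any point-cloud viewer)")
# Weights use the literal normalisation f_i / (max f - min f); pass
# minmax=True to pam_from_taps for the conventional [0, 1] variant.
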