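"""Convert an overhead depth raster to a 3D point cloud.

Builds a small synthetic raster (floor at 2100 mm with a raised block),
back-projects it through the pinhole model, and prints the cloud extent.
Coordinates are millimetres in the camera frame: +x right, +y down,
+z away from the camera, z identical to the recorded depth.
"""

import numpy as np

from sowmorph import DepthFrame, Intrinsics, depth_to_cloud

K = Intrinsics(width=80, height=48)          # fx = fy = 215.9346 by default
depth = np.full((48, 80), 2100.0)            # floor plane, mm
depth[18:30, 25:55] = 1500.0                 # a block 600 mm above the floor
depth[0, 0] = 0.0                            # a dropout pixel (invalid)

frame = DepthFrame(intrinsics=K, depth=depth)
cloud = depth_to_cloud(frame)

print(f"valid pixels      : {frame.valid_mask.sum()}")
print(f"points in cloud   : {len(cloud)}")
print(f"x extent (mm)     : {cloud.points[:, 0].min():+.1f} .. {cloud.points[:, 0].max():+.1f}")
print(f"depth values (mm) : {sorted(set(map(float, cloud.points[:, 2])))}")
# One point per valid pixel; the two depth planes appear as the two z
# values, and the lateral extent follows depth * pixel-offset / focal.
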