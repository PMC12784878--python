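"""Frozen kernel-point disposition table.

Fifteen kernel points for the point convolution: one at the origin plus
fourteen arranged on a shell at 0.66 of the unit radius by deterministic
electrostatic repulsion on the sphere (minimum pairwise chord 0.89 before
shell scaling).  The table is frozen so that model shapes and outputs are
bit-reproducible; convolution layers scale these dispositions by their
neighbourhood radius.
"""

import numpy as np

KERNEL_POINTS_15 = np.array([
    (+0.00000000, +0.00000000, +0.00000000),
    (-0.58964041, -0.23703735, -0.17815017),
    (-0.09709515, -0.11191933, -0.64315363),
    (-0.43991136, -0.10395902, +0.48090593),
    (-0.52808550, +0.36896330, +0.14349837),
    (+0.06772601, +0.65632077, +0.01600720),
    (+0.51733565, -0.16969854, -0.37304990),
    (+0.58964041, +0.23703735, +0.17815017),
    (-0.35667740, +0.36498314, -0.41853141),
    (-0.00892100, -0.58484165, -0.30574607),
    (+0.22044810, -0.16280471, +0.60041424),
    (+0.31655841, +0.37868306, -0.43816654),
    (-0.18032911, -0.58086149, +0.25628371),
    (+0.46928050, -0.44044242, +0.14624049),
    (+0.01967085, +0.38557689, +0.53529760),
], dtype=np.float64)
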