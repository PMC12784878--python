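# sowmorph

Non-contact body morphometry of housed sows from overhead depth imaging.

A depth camera mounted about 2.1 m above a single-sow stall sees the
animal's back from directly overhead.  From that raster alone, this
package estimates six body metrics — body weight (BW, kg) and chest
width, hip width, body length, chest height and hip height (CW, HW, BL,
CH, HH, cm) — without touching the animal.  It is aimed at precision
livestock-farming researchers and engineers who want a fully
inspectable, CPU-only reference implementation of the point-cloud
pipeline, validated end to end on synthetic scenes with analytically
known ground truth.

The pipeline has four stages:

1. **Depth → cloud.**  Pinhole back-projection
   `x = D(u-cx)/fx, y = D(v-cy)/fy, z = D` (mm, camera frame), with
   PLY/XYZ/PGM I/O.
2. **Back segmentation.**  A compact kernel-point-convolution
   encoder–decoder labels each point back (1) or background (0):
   `(F*g)(x) = Σ_{x_i∈N_x} Σ_k max(0, 1-‖(x_i-x)-(κ_k+Δ_k(x))‖/σ) W_k f_i`,
   with 15 frozen kernel points, spherical neighbourhoods, FPS 1/4
   downsampling per level and deformable offsets Δ at the middle level.
3. **Metric regression.**  A dual-branch network: a spatial transform
   (p' = pθ, θ a learned 3×3 matrix starting at identity) feeds a
   *location* branch (two FPS + multi-scale-grouping set-abstraction
   levels, n → n/4 → n/16 × 256 channels → 1×1024 global feature) and a
   *feature* branch (four EdgeConv layers,
   `f_i' = max_{j∈N_k^feat(i)} h_Θ(f_i, f_j - f_i)`, k-NN graph rebuilt
   in feature space per layer → 1×1024); the fused 1×2048 feature runs
   through a fully connected head to the six outputs.  Loss =
   `MSE_BW + MSE_CW + MSE_HW + MSE_CH + MSE_HH + MSE_BL` on raw scales.
4. **Explanation.**  Point activation mapping: tapped per-point features
   (n×384 by default) are channel-max compressed, normalised to weights
   `ω_i = f_i / (max f - min f)`, and rendered as a blue→red heat PLY.

A parametric scene generator (floor, stall rails, superellipsoid sow
back with head/tail caps, sensor noise, per-point labels, labels tied
analytically to the shape parameters) makes the whole pipeline testable
without any animal data.  The networks run on a small reverse-mode
autodiff engine included in the package — no deep-learning framework is
required.

## Worked example

```bash
python examples/02_synthetic_scene.py
```

prints

```
points: 96000  back fraction: 0.068
metric    label  re-measured
    BW    211.5        212.8
    CW     36.4         36.4
    HW     36.9         36.9
    BL     86.6         87.1
    CH     90.1         90.1
    HH     84.6         84.6
```

One noiseless 400×240 scene back-projects to 96,000 points of which
6.8% belong to the sow's back.  The left column is the analytic label
attached to the scene; the right column re-measures each size purely
geometrically from the labeled body points (ridge heights at the chest
and hip stations, profile-inverted widths, principal-axis length) —
they agree to well under 1%, which is the generator's self-consistency
guarantee.  BW is an allometric proxy of the five sizes, so its
re-measured value inherits their small errors.

The other examples follow the same pattern: `01` depth conversion,
`03` segmenter training (held-out OA ≈ 99% after a few epochs), `04`
regressor training, `05` saliency maps, `06` the end-to-end pipeline
(also available as a CLI: `sowmorph all --seed 1 --out runs/demo`).

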