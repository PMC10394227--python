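# poselift

Uncertainty-aware heatmap decoding and 2D–3D skeletal correction for
markerless pose estimation.

Pose-estimation networks predict one heatmap per joint; turning those
heatmaps into coordinates, deciding how much to trust each joint, and
repairing implausible 2D skeletons against a 3D body prior are geometry
problems that deserve exact, testable implementations independent of any
particular network. `poselift` provides that geometric core for people
building or evaluating keypoint pipelines (movement science, behavioural
biology, clinical gait analysis):

- a **voting decoder** that reads a joint's subpixel position *and* a
  calibrated uncertainty off a whole heatmap,
- the **loss terms** of a shape/pose parametric body objective,
- closed-form **weighted rigid alignment** (Kabsch/Procrustes by SVD),
- an **iterative orthographic 2D–3D correction** that re-synthesises
  unreliable joints from body structure,
- **MPJPE / PA-MPJPE** evaluation and a Monte-Carlo ablation benchmark,
- a **synthetic kinematic body** that generates every fixture (skeletons,
  projections, heatmaps, occlusions) reproducibly from a seed — no dataset
  required.

## The method

**Decoding.** For a `w x h` heatmap, sum over rows and columns to get the
marginal vote vectors `z_u, z_v`; softmax each; with the enumeration
`e = [1..n]` the coordinate and its uncertainty are

    x = Σ_j z*_j e_j ,    c = sqrt( Σ_j z*_j (e_j − x)² ).

A concentrated vote gives small `c`; an occluded or noisy joint votes
diffusely and gets a large `c`. The training loss is the Gaussian negative
log-likelihood `Σ [ log(√(2π) c) + (x − x̂)²/(2c²) ] + ω_c Σ 1/(2c²)` with
`ω_c = 0.2`.

**Body parameters.** Shape is a 10-vector β scored with a Smooth-L1 loss
whose quadratic region is widened to `|Δ| ≤ 1.5`; per-joint rotations are
scalar-last unit quaternions `(x'sin α/2, y'sin α/2, z'sin α/2, cos α/2)`
scored with `‖θ − θ̂‖₁ + ω_p |1 − ‖θ‖₂²|`, `ω_p = 1`. The composite
objective weights are λ_shape = 0.2, λ_pose = 0.25, λ_SMPL = 0.15,
λ_KB = 0.3, λ_DET = 0.4.

**Alignment.** For matched point sets, the rotation minimising
`Σ ½ w_i ‖R p_i + t − q_i‖²` comes from the SVD of the weighted
cross-covariance `C = Σ w_i q̃_i p̃_iᵀ = UΣVᵀ` as `R = U diag(1,1,det UVᵀ) Vᵀ`
(the determinant factor forbids anatomically invalid reflections), with
`w_i = 1/c_i` from the decoder.

**Correction.** Decoded 2D joints are lifted to 3D as `(u, v, z)` under an
orthographic camera. Depths are initialised by least-squares planar
factorisation of the body prior, then a few sweeps alternate: normalise the
lifted cloud, rigidly align the prior onto it (weighted Kabsch), refresh
depths from the aligned prior. The prior's projection replaces the noisy
input; joints with diffuse votes barely influence the fit.

**Evaluation.** MPJPE is the mean per-joint Euclidean error; PA-MPJPE is
the same after the optimal rotation + translation + uniform-scale
(Procrustes) alignment of prediction onto truth.

## Worked example

```python
import numpy as np
from poselift import sample_scene, decode, iterative_correction, mpjpe

scene = sample_scene(seed=7, noise_sigma=0.05, occlusion_rate=0.2)
est = decode(scene.heatmaps)
print("occluded joints:", np.flatnonzero(scene.occluded).tolist())
print("decoded uncertainty c_i:", np.round(est.scalar_uncertainties(), 2).tolist())
print("raw decode MPJPE:   %.3f grid units" % mpjpe(est.coords(), scene.truth2d))
res = iterative_correction(est, scene.truth3d)
print("corrected MPJPE:    %.3f grid units" % mpjpe(res.corrected2d, scene.truth2d))
```

prints

```
occluded joints: [0, 1, 4, 11]
decoded uncertainty c_i: [8.4, 8.64, 0.66, 0.6, 8.34, 0.68, 0.63, 0.61, 0.66, 0.69, 0.67, 8.52, 0.56, 0.7, 0.64, 0.7, 0.7]
raw decode MPJPE:   0.770 grid units
corrected MPJPE:    0.546 grid units
```

The four occluded joints are flagged by their order-of-magnitude larger
uncertainties (≈ 8.5 vs ≈ 0.65 grid units); the weighted correction uses
`1/c_i` to discount them and pulls the overall 2D error down.

The same workflow is available from the shell:

```sh
poselift simulate --n 50 --seed 1 --noise 0.05 --occlusion 0.2 --out scenes
poselift decode  --scenes scenes --out keypoints
poselift correct --scenes scenes --keypoints keypoints --out corrected
poselift bench   --n 50 --seed 1
```

`bench` prints a comparison of raw decoding against unweighted and
uncertainty-weighted correction on identical seeded scenes:

```
condition      median     mean            95% CI       PA
raw            0.7967   0.8200 [ 0.6417, 0.9204]   1.0316
unweighted     0.7038   0.8235 [ 0.5295, 0.9686]   0.5500
weighted       0.2256   0.3863 [ 0.1295, 0.3550]   0.1699
```

(2D errors in grid units of the 32 × 32 heatmap; `PA` is the
Procrustes-aligned error.)

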