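# vesselseg

Hybrid level-set segmentation of bright tubular structures — cerebral
vessels in time-of-flight MR angiography and volumes like them — with a
synthetic vascular phantom generator, Hessian-based vesselness filtering,
and a Dice evaluation harness.

## The problem and the model

In TOF-MRA, flowing blood is bright: thick arteries sit well above a global
intensity threshold (here `mu0 = 200` on the raw scale), but thin branches
are dimmer — often between 150 and 200 — and partial-volume effects blur
their walls. A fixed threshold keeps the main arteries and loses the thin
branches; a purely local adaptive threshold captures thin branches but
hollows out the thick ones. The model combines both in one active contour.

The contour is the zero level of a scalar field φ (φ ≥ 0 inside), evolved
to minimize

    E(φ) = − α₁ ∫ (I − μ₀) H(φ)  − α₂ ∫ (I − μ(u)) H(φ)
           + β ∫ g(|∇I_σ|) |∇H(φ)|  + γ ∫ ½ (|∇φ| − 1)²

with H a smoothed Heaviside function `½(1 + (2/π) arctan(φ/ε))`. The first
term pulls the contour over voxels brighter than the global threshold μ₀;
the second uses the adaptive local threshold

    μ(u) = k · [K_σ ∗ (H(φ) I)](u) / [K_σ ∗ H(φ)](u),    k ∈ [0.5, 1],

a Gaussian-weighted mean of the intensities currently inside the contour,
so dim thin branches are still captured; the third is a geodesic edge term
with `g(x) = 1/(1+x²)` attracting the contour to high-gradient walls; the
fourth penalizes deviation of φ from a signed distance function so no
reinitialization is ever needed. Three variants are parameter
degenerations of the same engine: `hybrid` (both region terms), `global`
(α₂ = 0, fixed threshold only), `local` (α₁ = 0, adaptive threshold only).

Initialization and outlier removal use multiscale Hessian vesselness with a
tan-saturated line factor `1 − exp(−tan((π/2)·R_A))` that scores clean
tubes closer to 1 than the classic Gaussian factor; segmentation components
that contain no high-vesselness voxel are removed by a seeded connectivity
filter.

Reference parameters: `Δt = 2.0, α₁ = α₂ = 0.003, β = 0.02, γ = 1.0,
ε = 1.0, μ₀ = 200, σ_local = 3.24`.

## Worked example

Real clinical angiograms are rarely shareable, so the package ships a
phantom generator that emulates the regime the model assumes: a branching
tree of 5–15 tubes with radii 1–4 voxels, centerline intensities 150–300
over a background of 50 (most vessels above 200, the thinnest below),
Gaussian wall falloff, additive noise, and isolated bright non-vessel
blobs. The ground truth is exact and noise-independent.

```python
import vesselseg as vs

volume, gt = vs.make_branching_phantom((96, 96, 96), seed=3)
table = vs.compare_variants(volume, gt)
print(table.to_string(index=False))
```

```
  mode       dsc  iterations  mask_voxels
hybrid 85.574949          60         3404
global 79.946524          90         3092
 local 82.139482         160         6194
```

The Dice similarity coefficient (DSC, 0–100; `2|M∩G| / (|M|+|G|) × 100`)
shows the expected ordering: the fixed threshold (`global`) misses the dim
thin branches, the purely adaptive threshold (`local`) over-segments into
the background (6194 voxels against 4388 true vessel voxels), and the
hybrid of the two scores highest.

The same pipeline from a shell:

```bash
vesselseg phantom demo --shape 96,96,96 --seed 3
vesselseg segment demo_volume.nii.gz demo_seg.nii.gz --mode hybrid --diagnostics diag/
vesselseg evaluate demo_seg.nii.gz demo_gt.nii.gz     # prints 85.57
vesselseg enhance demo_volume.nii.gz demo_vesselness.nii.gz
vesselseg compare demo_volume.nii.gz demo_gt.nii.gz comparison.csv
vesselseg sweep demo_volume.nii.gz demo_gt.nii.gz sweep.csv --ratios 0.25,0.5,1,2,4
```

`--diagnostics` writes the per-iteration energy trace, the fully resolved
parameter set, and maximum-intensity-projection PNGs of input and result.

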