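# Methods

## Model

The segmentation is an active contour represented implicitly: the contour
is the zero level set of a scalar field φ on the image grid, with φ ≥ 0
inside the object. The energy has four terms (see the README for the
formula): a global region term driven by a fixed lower intensity bound μ₀
of the target, a local region term driven by the adaptive threshold μ(u),
a geodesic edge term, and a signed-distance penalty. Gradient descent on
this energy yields the evolution

    ∂φ/∂t = δ(φ)[α₁(I − μ₀) + α₂(I − μ(u))] + β δ(φ) div(g ∇φ/|∇φ|)
            + γ [Δφ − div(∇φ/|∇φ|)]

with the smoothed Heaviside/Dirac pair H(φ) = ½(1 + (2/π) arctan(φ/ε)),
δ(φ) = (1/π) ε/(ε² + φ²). The penalty enters unweighted by δ: it must act
on the whole domain to maintain the signed-distance property.

Assumptions: bright tubular objects on a darker background (the
angiographic convention); a single global intensity scale (intensities are
used as stored, no rescaling, since μ₀ is specified on the raw scale);
isotropic voxel units for all derivatives (anisotropic spacing is carried
through I/O but not into the stencils — a known limitation, acceptable at
the slice anisotropies typical of TOF-MRA and irrelevant on isotropic
phantoms).

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha1`, `alpha2` | 0.003 | weights of the global/local region terms |
| `beta` | 0.02 | geodesic edge weight |
| `gamma` | 1.0 | signed-distance penalty weight |
| `epsilon` | 1.0 | Heaviside/Dirac smoothing width (φ units) |
| `dt` | 2.0 | time step |
| `mu0` | 200 | global lower intensity bound of vessels (raw scale) |
| `k` | 0.9 | local-threshold coefficient, constrained to [0.5, 1] |
| `sigma_local` | 3.24 | Gaussian width of the μ(u) kernel (voxels) |
| `sigma_edge` | 1.0 | pre-smoothing for the edge map (voxels) |
| `v_threshold` | 0.2 | vesselness level defining the initial region |
| `band_value` | 6.0 | working band half-width for φ (voxels) |
| `seed_threshold` | 0.65 | vesselness level seeding the connectivity filter |
| `vessel_scales` | 1–4 | Hessian scales (voxels), covering radii ~1–4 |
| `max_iters` / `stop_tol` | 300 / 1e-3 | cap and relative mask-size change per 10 iterations |

The first block are the model's reference settings. `k` is not fixed by
the model's sources beyond its [0.5, 1] range; 0.9 keeps the local bound
just under the local interior mean so the contour does not stall inside
vessels. σ = 3.24 is interpreted in voxels. `v_threshold = 0.2` is chosen
inclusive: initialization should cover the whole tree including dim
branches, because evolution is local and cannot reach structures far from
the initial band; background included by a permissive threshold is removed
by the region forces. `seed_threshold = 0.65` separates the measured
response plateaus: planted spherical outliers peak at ~0.52–0.54 (the
tan-saturated line factor inflates blob-edge shells), clean tube
centerlines at ≥ 0.8.

## Numerics

**Five-part step.** One iteration: (i) recompute μ(u) (every iteration by
default) as a ratio of separable Gaussian convolutions of H(φ)·I and H(φ),
kernels truncated at 3σ, falling back to μ₀ where the inside weight is
below 1e−8; (ii)–(iv) explicit update of the region and penalty forces;
(v) the edge term, applied semi-implicitly.

**Penalty discretization.** Δφ − div(∇φ/|∇φ|) = div((1 − 1/|∇φ|)∇φ) is
discretized in conservative flux form: the flux (1 − 1/s)·d lives on voxel
faces, with d the axis difference across the face and s the face gradient
norm (axis difference plus transverse derivatives averaged from the
adjacent voxel centers, regularized by η = 1e−8); boundary faces carry
zero flux. Zeroing the *combined* flux — not the gradient — preserves the
functional's natural boundary condition, under which penalty-only
evolution relaxes |∇φ| → 1 instead of flattening; it also bounds the
normalized flux component by 1, so flat plateaus are inert. On an exact
signed distance function the update vanishes identically.

**Substepping.** The flux has unit sensitivity to the face slope even
where its diffusivity 1 − 1/s vanishes, so the explicit stability bound is
that of a unit-rate compact Laplacian: γ·τ ≲ 1/6. Step (iv) is therefore
split into 16 substeps of γ·τ = 0.125 for the default γ·Δt = 2; the scheme
is the single explicit step's limit and is what makes the nominal time
step usable at all.

**Working band.** With the arctan-family Dirac, the region forces have no
far-field fixed point: δ > 0 everywhere, so the background is pushed down
without bound, and the penalty transmits that drift across the interface
as a spurious shrinking force — unconstrained runs slowly eat the thin
branches and never converge. φ is therefore constrained to |φ| ≤
`band_value` whenever region forces are active, by projection after every
substep (so each projection is within one substep of the constraint
surface: projected gradient descent). The initialization already clamps to
the same band. Pure penalty or edge flows are left unconstrained.

**Edge sub-step.** Lagged-diffusivity semi-implicit solve: the scalar
diffusivity d = g/|∇φ| and the factor δ(φ) are frozen at the current
iterate, then (1 − Δt·β·δ·L_d)φ is solved axis by axis with batched
tridiagonal (Thomas) systems and Neumann ends, the three axis solutions
averaged (additive operator splitting). A plain explicit step with the
same lagged coefficients is available via `edge_scheme="explicit"` for
cross-checking; both reduce to δ·Δφ exactly in the unit-diffusivity limit.

**Energy accounting.** The reported energy uses the same face-based
discretization of the penalty integrand that the flow descends (axis
terms averaged, which recovers the continuum integral for smooth fields).
Measuring the penalty with a different stencil (composed central
differences) makes the trace appear to rise near kinks while the descended
functional is in fact decreasing; with the consistent measurement the
trace of a full hybrid run is non-increasing in every step on the 64³
reference phantom.

**Initialization.** The initial interior is the vesselness superlevel set
{V ≥ `v_threshold`} after closing of 1-voxel gaps; φ is the exact signed
Euclidean distance to its boundary (±0.5 voxel offset so the zero level
lies between interior and exterior voxel centers), clamped to the band. A
set of edge voxels alone does not define an interior, which is why the
superlevel set, not an edge detection, realizes the "start around the
vessels" intent.

**Stopping.** The run stops when the segmented voxel count changes by less
than `stop_tol` (relative) between checks every 10 iterations, or at
`max_iters`. The evolution is deterministic: repeated runs on the same
volume produce identical masks.

## Vesselness

Scale-space Hessians (Gaussian derivative filters, γ-normalization σ²),
per-voxel symmetric eigendecomposition, eigenvalues ordered by ascending
magnitude |λ₁| ≤ |λ₂| ≤ |λ₃| — the ordering under which the tube ratios
R_A = |λ₂|/|λ₃| ≈ 1 and R_B = |λ₁|/√|λ₂λ₃| ≈ 0 hold. Bright-structure
gate: response 0 wherever λ₂ > 0 or λ₃ > 0. Per scale, the strength
normalization c defaults to half the maximum of S = √(λ₁²+λ₂²+λ₃²) at that
scale; the multiscale response is the pointwise maximum with its argmax
scale. The `modified` mode replaces the Gaussian line factor
1 − exp(−R_A²/2a²) with 1 − exp(−tan((π/2)·R_A)) (ratio clamped at
1 − 1e−6 before the tangent pole), which dominates the original pointwise
for a = 0.5 and saturates to 1 on clean tubes. A constant volume is
short-circuited to zero response: truncated derivative kernels leave
O(|I|·σ²·1e−4)-scale residue that the half-max normalization would
otherwise inflate.

## Phantoms: what they emulate and what they do not

The branching phantom grows a deterministic (seeded) tree of 5–15 straight
cylindrical segments, trunk radius 4 voxels shrinking to ~1 at the leaves,
centerline intensity 160 + 35·r jittered and clipped to [150, 300] over a
background of 50 — so the bulk of the tree lies above μ₀ = 200 while the
thinnest branches fall into the 150–200 band that only the adaptive
threshold can capture (16% of vessel volume on the standard 96³ instance).
Cross-sections have a flat core with a Gaussian shoulder (σ = 0.5 voxel,
starting half a voxel inside the wall), so the intensity at the true wall
is ~60% of the centerline value, a partial-volume-like profile with finite
gradients for the edge term. Additive Gaussian noise (σ = 10 by default)
and a few bright spherical outlier blobs complete the volume; the ground
truth is the exact cylinder union, independent of noise and blobs.

Not emulated: curved/tapering vessels, anatomically realistic topology
(circle of Willis), Rician noise statistics, flow and shutter artifacts,
anisotropic voxels. Passing tests therefore demonstrate the machinery —
operators against oracles, variant ordering, thin-branch behavior, outlier
removal — on idealized geometry; they do not certify clinical accuracy,
and absolute Dice values on clinical angiograms will differ.

## Problem sizes

The test and reproduction runs use 96³ for the three-variant comparison
(standard phantom), 64³ for the energy-descent run and the α₂/α₁ ratio
sweep (five full runs), 48³ for the binary-phantom threshold-limit check
and the vesselness response, 32³ for the penalty relaxation, and 8³–16³
for the brute-force oracle comparisons — sizes at which every behavior of
interest is already expressed and a full suite completes in minutes on one
CPU.

## Known limitations

- The single-well penalty is ill-posed where |∇φ| < 1; the band constraint
  and the flux-form discretization tame it, but sub-voxel interface
  placement is penalty-influenced: expect ±1 voxel of wall rounding at
  high-curvature sites, which is also why Dice saturates around 97–98 on
  binary phantoms rather than at 100.
- The adaptive threshold scales with local brightness, so the model's
  response to a uniform intensity increase is monotone only up to one
  voxel of boundary jitter (the local threshold rises too).
- Derivatives ignore voxel spacing (isotropic assumption).
- The connectivity filter assumes the vessel tree is connected in the
  segmentation; a branch disconnected by noise and below the seed
  threshold everywhere would be discarded with it.
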