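# Methods

## The model

flowaug implements a registration-derived data-augmentation scheme for
multi-coil MRI reconstruction training sets.  The scarce, expensive object
is raw complex k-space data with coil sensitivity maps (CSMs); the abundant
object is anatomical magnitude imaging.  The scheme learns, from pairs of
anatomical volumes, two kinds of voxel-wise flow fields and then transplants
them onto one complex source acquisition:

* **Displacement flow** `phi = I + u`, a voxel-wise offset field (voxel
  units).  Volumes are warped by backward (pull) sampling,
  `out(x) = vol(x + u(x))`, with trilinear interpolation and border-clamp
  boundary by default.  Pull-warping is the convention of the
  displacement-field registration literature and avoids scatter holes; the
  direction is a package choice since `S ∘ phi` alone does not fix one.
* **Intensity flow** `psi`, an additive per-voxel delta applied as
  `vol + m·psi` (clipped at zero), with a scalar `m` that scales the
  contrast change when generating variants.

Three small 3D U-Nets are trained on (source, target) anatomy pairs with
pure mean-squared-error objectives:

1. forward displacement: `L_d = ||T − S ∘ phi||²`,
2. inverse displacement: the same loss with the roles swapped, yielding the
   field that pulls the target back into source geometry,
3. intensity: with the target pulled back through the inverse flow,
   `L_i = ||T ∘ phi_inv − (S + psi)||²`.

The intensity loss is deliberately read as regressing `psi` so that
`S + psi` matches the pulled-back target; this is the reading consistent
with the forward application `S + psi` and is stated here prominently
because the sign convention is genuinely ambiguous in loss-function
shorthand.

### Application to complex data

A complex volume is decomposed as `S = S_M · exp(i·S_P)`.  The augmentation
applies

* displacement only to CSM magnitude, CSM phase and DWI phase (intensities
  of the coil profiles and the phase structure must not change),
* intensity then displacement to the DWI magnitude:
  `(S_M + m·psi_j) ∘ phi_i`.

Phase grids are warped through their cos/sin channels and re-extracted with
`atan2`, which is immune to the ±π wrap (direct interpolation of a wrapped
angle invents values near 0 at the seam).  Away from the wrap the two
approaches agree to third order in the per-voxel phase step.

With N learned geometry targets, N intensity targets and |m| scales, one
raw acquisition yields N×N×|m| augmented k-space cases.

### Augmentation groups

Six plan groups are enumerated as exact Cartesian products
(lexicographic, lazy):

| group | factors | count |
|---|---|---|
| s | 4 shears × 5 brightness | 20 |
| r | 8 rotations × 5 brightness | 40 |
| t | 16 translations × 5 brightness | 80 |
| srt | 4 × 8 × 16 × 5 | 2560 |
| d | 26 geometry targets × 5 brightness × 16 translations | 2080 |
| di | 26 × 26 × 4 m-scales | 2704 (+26 displacement-only = 2730) |

The translation list (±12, ±24 pixels along x and y) is interpreted as the
4×4 grid of (dx, dy) — the only reading that yields 16.  For group `di`,
26×26×4 is 2704; a variant that prepends the 26 displacement-only cases
gives 2730.  Two m-scale lists circulate for the intensity scales; the
default is (0.8, 0.9, 1.1, 1.2) and (0.9, 1.1, 1.2, 1.3) ships as
`M_LIST_ALT`.  Neither is declared "the" correct one.

## Network and training

The regressors are 2-level 3D U-Nets (two 3×3×3 conv + leaky-ReLU blocks,
2× average-pool, a double-width bottleneck, nearest-neighbour upsampling
with skip concatenation), 8 base channels, implemented directly on numpy
with a small reverse-mode autodiff tape.  The head convolution is
zero-initialized so training starts from the identity flow; the
displacement loss differentiates through an analytic trilinear warp layer
(gradient = interpolation-weight derivative, zeroed where coordinates
clamp at the border).  Optimization is Adam.

Parameters that matter:

* `learning_rate` — default 1e-3 (the production profile); the scaled-down
  test profile uses 2e-3 to converge within a few hundred iterations.
* `iterations` / `batch_size` — desk-scale default 500 / 4 on grids of
  order 8×24×24–16×64×64; `PRODUCTION_SCALE_CONFIG` carries the
  production-scale settings (batch 40, 10⁴ iterations).
* `smoothness_weight` — optional diffusion penalty on the predicted field
  (mean squared forward difference), **off by default** since the training
  objectives are pure MSE.  It matters in two situations: where the true
  field is globally smooth (a rigid shift), and where a pair's difference
  is *not* explainable by any displacement (e.g. a pure contrast offset) —
  without the penalty the inverse network is free to contort flat regions
  and corrupt the pulled-back target that the intensity net consumes.
  The ψ-recovery validation therefore regularizes the inverse net
  (weight 0.2) while leaving the intensity net unregularized (the true
  ψ there is a sharp step whose gradient a smoothness penalty would bias
  downward).
* Each training pair is min–max normalized **on the source volume's
  scale**.  Normalizing source and target independently would cancel
  exactly the global contrast differences the intensity network exists to
  learn.  ψ is learned in normalized units and rescaled to source units on
  prediction.

Training is a pure function of (pairs, config): parameter initialization
and batch sampling derive from the config seed, and single-threaded numpy
arithmetic is deterministic.

### Where the learned flow is meaningful

A displacement field is only identifiable where the image has gradient.
Recovery statistics (endpoint error, recovered ψ) are therefore evaluated
inside the anatomy support eroded in-plane by 3 voxels: boundary voxels
mix background through interpolation, and background voxels constrain the
networks not at all.  This is an evaluation-mask choice, not a training
modification.

## Synthetic study conditions

The phantom generator supplies every input with exact ground truth:

* **Anatomy**: nested smooth ellipsoidal tissue compartments (default 3)
  with seeded per-tissue intensities in [0.3, 1.0], smooth boundary
  perturbation, and smooth intra-tissue texture (20 % multiplicative,
  σ = 3 voxels).  The texture matters: real T1w tissue is not piecewise
  constant, and without it a flow is unconstrained across compartment
  interiors.  A single-tissue spec degenerates to an exact constant
  ellipsoid.
* **Noise**: Gaussian, added on a pedestal of 6σ so magnitudes stay
  non-negative while the background sample standard deviation equals σ
  (clipping a zero-mean Gaussian at zero would bias the std by ≈ 40 %);
  the pedestal plays the role of a magnitude-image noise floor.
* **Pairs**: the ground-truth displacement is Gaussian-smoothed white
  noise scaled so the mean endpoint length equals `deform_amplitude`
  (default 2 voxels, smoothness 6); the intensity field is smoothed noise
  with RMS `intensity_amplitude × mean(source)` (default 10 %), supported
  inside the anatomy.  The target is constructed exactly as
  `(source + psi) ∘ phi`, so ground truth is exact by construction.
  Fields steep enough to fold (per-axis gradient ≥ 1) are rejected.
* **Coil maps** (default 8 coils): Gaussian magnitude lobes on a ring of
  virtual coils with low-order polynomial phase, normalized by
  root-sum-of-squares (RSS ≡ 1, per-coil magnitude ≤ 1, single coil →
  unit map) — the normalization convention of calibrated sensitivity
  estimates.
* **DWI**: b=0 magnitude is the anatomy; the diffusion-weighted magnitude
  is attenuated voxel-wise by `exp(−b·ADC)` with per-tissue ADC defaults
  in the physiological range 0.3–3.0 × 10⁻³ mm²/s (white ≈ 0.7, grey
  ≈ 0.9, oedema ≈ 1.3, CSF ≈ 3.0 × 10⁻³); both volumes share one smooth
  phase map (low-order polynomial plus smoothed noise, emulating
  shot-level DWI phase without EPI physics).  Complex noise is added after
  the forward model, so the noiseless case inverts exactly.

What the phantom does **not** emulate: EPI distortion and eddy currents,
multi-shot phase aliasing, realistic electromagnetic coil coupling,
Rician noise statistics of magnitude reconstruction, and real anatomical
variability.  Passing tests therefore demonstrate internal consistency of
the method and exact bookkeeping of the augmentation arithmetic — not
clinical image quality.

## K-space engine

2D, slice-wise, Cartesian: per coil, k-space is the centered unitary FFT
of the sensitivity-weighted image; undersampling selects phase-encode (ky)
lines.  Unitary normalization makes the Parseval and adjoint tests exact.

* Uniform masks sample every R-th line phased through DC plus a centered
  ACS block (default 24 lines at matrix 228, scaled by matrix size in the
  pipeline; the construction is declared, not inferred from any source).
* Variable-density masks always include the ACS block and draw the
  remaining budget `round(n/R)` without replacement with probability
  ∝ (1 − |ky|/(kmax+1))^2; deterministic per seed.
* CG-SENSE solves `EᴴE x = Eᴴ y` by conjugate gradients.  CG is monotone
  in the energy norm, not the residual 2-norm; the reported per-iteration
  relative residual may make small excursions, and a 10-iteration growth
  guard raises on divergence.  With RSS-normalized maps and full sampling
  the normal operator is the identity, so R=1 converges in one step.
* Zero-filled reconstruction combines coil images with
  `Σ conj(S)·x / Σ|S|²`, which coincides with CG-SENSE at R=1.
* CSM estimation uses the Hamming-apodized central ACS block divided by
  its RSS (the low-resolution-ratio method); a full eigen-decomposition
  calibration is out of scope.

## Evaluation

PSNR is `10·log10(data_range²/MSE)` with `data_range` defaulting to the
reference maximum (a declared convention; identical inputs report +∞).
SSIM uses the standard Gaussian 11×11, σ = 1.5 window with k1 = 0.01,
k2 = 0.03, computed slice-wise in the axial plane (the plane the
reconstruction operates in) and averaged, optionally restricted to a
mask.  ADC maps are fitted voxel-wise as `−ln(S_b/S_0)/b`, with
non-positive signals marked NaN.  Skull stripping is emulated by
thresholding plus largest connected component plus hole filling; metrics
default to the brain mask.

## Pipeline determinism

All randomness derives from one global seed through named SHA-256
substreams (`stage_seed(seed, stage, index)`), so two runs of the same
configuration produce byte-identical metrics tables.  The reported table
contains, per augmented case × acceleration × pattern: PSNR, SSIM and MSE
of the CG-SENSE b=1000 magnitude inside the brain mask, and the MSE
between ADC maps fitted from the reconstruction and from the reference.

## Problem sizes

The default validation sizes are 8×24×24–16×64×64 grids, 1–4 coil-pair
training examples, 60–500 Adam iterations and 2–8 coils; the production
profile (matrix 228×228×16, 26 targets, batch 40, 10⁴ iterations) is
configuration, not code.  These sizes were chosen so the full suite runs
on a single CPU at desk scale while every recovery statistic retains a
wide margin over its threshold.

## Known limitations

* The inverse-displacement problem is intrinsically harsher than the
  forward one when the target is an interpolation-smoothed warp of the
  source: no field reproduces sharp edges from smoothed data, and the
  unregularized optimum may contort.  Inverse-consistency guarantees are
  therefore stated (and tested) with the smoothness penalty enabled.
* Flow fields learned between magnitude anatomies carry no phase
  information; applying them to phase assumes anatomy and phase move
  together, which is an approximation of convenience for synthetic data.
* The deep-learning reconstruction consumer of the augmented sets is out
  of scope; CG-SENSE demonstrates that augmented cases are
  reconstruction-ready, and an HDF5 export (k-space + mask + CSM) is the
  hand-off surface for external training.
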