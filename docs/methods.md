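# Methods

This note documents the models implemented in `dbtpre`, their assumptions,
the tunable parameters that matter, and the numerical choices made where
the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Acquisition model

**Geometry.** A linear-sweep tomosynthesis system: the tube travels along
one detector axis over a 15° arc while the detector stays put, producing
15 projections in a single pass. Angles are evenly spaced over
[−7.5°, +7.5°], symmetric about 0°. The clinical detector is 2560 × 4096;
the package default is a desk-scale 256 × 512 grid (full size is a
configuration change, not a code change), and most tests shrink further.

**Forward model.** A shear (shifted parallel-ray) approximation: a voxel
at height *z* above the detector appears displaced along the sweep axis by
*z*·tan θ at tube angle θ, so each projection is a per-height shifted line
sum through the attenuation volume. At ±7.5° the maximum obliquity error
versus a cone beam is below 1 %, and the approximation buys an exact
operator pair: sub-pixel shifts use linear interpolation with zero fill,
whose transpose is the same shift reversed, so shift-and-add
backprojection (sum-weighted) is the exact adjoint of projection — the
test suite verifies ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ to floating-point precision.
Scatter, detector blur, the heel effect and compression-paddle geometry
are deliberately out of scope.

**Noise and dose indices.** Expected photon counts follow Beer–Lambert,
N = N₀·exp(−L); counts are Poisson-sampled and log-converted back to a
line-integral image (counts are floored at 0.5 before the log; at the
default dose levels zero-count pixels are vanishingly rare). The exposure
index EI is the calibrated mean detected signal over the breast region
(pixels above 1 % of the maximum attenuation signal), and
DI = 10·log₁₀(EI/EI_target) per the standard exposure-index convention.
An acquisition is labelled *reference* or *object* by comparing its mean
EI to a configured split (default EI_target/2). Default dose levels are
10⁴ photons/pixel (reference) and 10³ (object): a tenfold AEC dose gap
that reproduces the qualitative EI/DI separation of clinical reference
vs low-dose sets, with DI positive for reference and negative for object
passes. These defaults are free parameters of the simulator, not
clinical calibrations.

## Synthetic phantoms

A phantom is a half-ellipsoid breast pressed against the chest-wall edge
of the detector: adipose background (0.045 mm⁻¹), a fibroglandular
pattern obtained by thresholding a Gaussian-smoothed random field at a
type-dependent volume fraction (0.55 dense, 0.20 non-dense), optional
soft-contrast mass ellipsoids (0.095 mm⁻¹, just above fibroglandular) and
small microcalcification spheres (0.6 mm⁻¹). Attenuation values are
representative of ~20 keV mammographic energies; air is exactly zero.
Inclusions are placed by rejection sampling with a minimum separation so
the number of connected mass components equals the requested count.

What the generator does **not** emulate: anatomical ductal/vascular
texture, skin, compression deformation, patient-to-patient anatomy
correlations, or detector physics. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms (operators,
losses, metrics, training dynamics) — not clinical image quality claims.

## Preprocessing

Normalization standardizes an image with its mean and **population**
standard deviation, then affinely maps the result to a fixed range:

    I_temp = (I_org − mean) / σ
    I_norm = 1 + (I_temp − min)/(max − min)

The default (`as_printed`) range is [1, 2]; a `zero_one` mode drops the
offset. Both are one flag apart because the two available descriptions of
the mapping disagree by exactly that offset; the equation form wins by
default. Constant images are rejected (σ = 0).

Patch extraction draws `n_patches` fully-inside windows (default 128 of
128 × 128 px) uniformly at random with numpy's PCG64 generator and flips
each horizontally with probability 0.5 — stated only as "random selection
with horizontal flipping" upstream, so uniform origins without
breast-masking and a fair flip coin are the package's choices. Origins,
flips and the seed are persisted with every batch.

## Networks

All three generators share an encoder–bridge–decoder with skip
connections; `depth` downsampling levels (stride-2 convs), channel width
doubling from `base_channels` (capped at 8×), instance normalization,
nearest-neighbour-upsample + conv decoding, and a linear 1 × 1 output
head. Defaults are depth 4 / base 64 — standard cycleGAN practice, chosen
because the original architecture tables are not available; every element
is configurable so exact widths can be dropped in. Desk-scale tests use
depth 1–2 / base 4–8.

* **U-Net**: plain double-conv stages.
* **ResUNet**: every stage is a two-conv residual block with a 1 × 1
  projection where channels change.
* **rSEAG**: ResUNet plus (i) a squeeze-and-excitation block inside the
  bridge residual stage (reduction 16, the SE default) and (ii) an
  additive attention gate on every skip connection.

The attention gate computes f = ReLU(W_y·y + W_ω·ω) with 1 × 1 linear
maps (inter-channels = C/2), β = sigmoid(ψ·f), and returns y ⊙ β. The
gating signal ω is the decoder-side feature entering that skip's
concatenation; if its grid differs from y's, it is resampled by bilinear
interpolation. Gated skips are **concatenated** with decoder features (the
standard attention-U-Net choice; summation was the alternative). With all
gate parameters zero, β ≡ sigmoid(0) = 0.5 — a closed form the tests pin.

The discriminator is a PatchGAN: a stride-2 conv stack (leaky ReLU,
instance norm after the first layer) ending in a 1-channel conv, emitting
a spatial map of realness scores.

Because no deep-learning framework is part of the package's dependency
set, the networks run on a small reverse-mode autodiff core
(`dbtpre.nn.autograd`) written for exactly the operations used here;
gradients through the full rSEAG stack are validated against central
finite differences in the test suite. Everything is float64.

## Training

Standard cycleGAN with two generator/discriminator pairs (G_or: object →
reference, G_ro: reverse). Per minibatch the generator objective is

    λ_adv·(LSGAN real targets on both fakes)
  + λ_cyc·(L1 of both cycle reconstructions)
  + λ_fid·(1 − SSIM between each translation and its input)

with defaults λ_adv = 1, λ_cyc = 10, λ_fid = 5 (cycleGAN convention plus
a mid-weight fidelity term; the loss family is named upstream but not
weighted). The adversarial loss is least-squares (the cycleGAN default;
only "adversarial loss" is specified). Discriminators train on a 50-image
replay buffer of past fakes. Adam uses lr 10⁻⁴, β₁ = 0.5, β₂ = 0.999,
minibatch 16, no schedule — the published hyperparameter table. With the
full pools (86,400 patches per domain) this yields 5,400 iterations per
epoch; desk-scale runs shrink the pools, not the algorithm.

The fidelity term inside training uses a **global-statistics** SSIM
(whole-patch means/variances/covariance, C₁ = (0.01R)², C₂ = (0.03R)²)
because it is differentiable at negligible cost and adequate for 32–128 px
patches; the evaluation-path `ssim_fidelity_loss` uses the windowed
skimage estimator, which also serves as the independent reference in
tests.

**Optimal epoch.** After each epoch the mean MSE between held-out object
patches (a seeded 10 % split) and their translations is recorded; the
optimal epoch is the 1-based argmin, earliest on ties. Whether the
upstream MSE is patch- or projection-level against which target is
ambiguous; patch-level against the input is the default and both are
computable from the public API.

## Reconstruction

Filtered backprojection for linear-motion tomosynthesis: each projection
line along the sweep axis is multiplied by the Ramachandran–Lakshminarayanan
ramp |f| in the frequency domain, then shift-and-add backprojected onto
planes at configurable heights (default 1 mm spacing) and averaged over
angles. The ramp is applied 1-D along the sweep direction only, bare (no
apodization) by default with an optional Hann flag. Lines are edge-padded
to the next power of two ≥ 2n before the FFT: like zero-padding this
suppresses circular wraparound, but it additionally keeps a constant line
exactly constant so the ramp's DC zero annihilates it without boundary
leakage. The in-focus plane is the reconstructed slice nearest the
requested height; ties go to the lower plane.

## Quality metrics

**PIQE.** The image is min–max rescaled to [0, 255] and converted to MSCN
coefficients with 7 × 7 Gaussian local statistics (σ = 7/6, stabilizer
C = 1). 16 × 16 blocks with MSCN variance above 0.1 are spatially active;
an active block is *artifact-distorted* when any 6-sample segment along
its border is nearly flat (std < 0.1 — the signature of a blocking or
streak edge), else *noise-distorted* when its MSCN spread exceeds 0.35.
Distorted blocks incur penalty 1 and the score is
100·(Σ penalties + 1)/(N_blocks + 1), lower = better. One deliberate
deviation from the published formulation: the denominator counts **all**
blocks rather than only active ones, because the active-only average
degenerates to 100 on images so smooth that no block is active — exactly
the regime synthetic phantoms occupy — destroying the "lower is better"
ordering. The published normalization remains available
(`normalization="active_blocks"`), all thresholds are configurable, and
numeric parity with any specific vendor implementation is not claimed.

**GLCM texture.** The co-occurrence matrix counts quantized gray-level
pairs (linear min–max binning to 256 levels) over all eight neighbour
offsets, symmetrized and normalized to sum 1 (via
`skimage.feature.graycomatrix`; the features are computed here because the
homogeneity denominator is 1 + |i − j|, not the squared-difference form
some libraries call homogeneity):

    homogeneity = Σ T(i,j)/(1 + |i − j|)      contrast = Σ (i − j)²·T(i,j)

A constant image gives homogeneity 1 and contrast 0; additive noise moves
both monotonically, which the property tests check over three noise
levels.

**Gumbel streak statistics.** A rectangular window is placed near the
breast periphery with its long side along the sweep direction; pixel
profiles are read along the sweep at 1-pixel intervals and each profile
contributes its maximal absolute adjacent-pixel difference. Sorted maxima
are plotted against the reduced variate u = −ln(−ln Q) with symmetry-rank
positions Q_r = (r − 0.5)/l; a least-squares line estimates the Gumbel
location and scale, the Pearson correlation between sorted maxima and u
measures linearity, and the mean ± standard error (sample std/√l) of the
maxima summarizes artifact strength. The stated window arithmetic
(30 × 24 px yielding 29 profiles of sampling size 29) is internally
inconsistent; the convention here is one profile per row across the
window with l taken from the actual profile count, and the high-level
`streak_statistic` defaults to 29 profiles of 30 samples so l = 29
matches the published sampling size. Window size, origin and profile
count are all parameters.

## Pipeline

`simulate → train → translate → reconstruct → evaluate` are plain
functions over a single YAML config; every defaulted value is
materialized into a snapshot saved with the run, and each stage writes a
manifest with SHA-256 hashes of its outputs, so identical inputs + seed
reproduce identical files. Full-image inference tiles the projection with
the training patch size, blends overlapping tiles with a floored Hann
window and normalizes by the accumulated weights — any operator acting
identically on overlapping content (in particular the identity) is
reproduced exactly, independent of stride.

## Problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own default study conditions: 45 + 4 cases at a 64 × 128
detector for dataset bookkeeping; 32–64 px images for operator tests; toy
cycleGAN training on 200 patches of 32 × 32 (depth 2, base 8, three
epochs) for the loss-decrease and identity-domain-recovery checks; 500
replicates of l = 29 for Gumbel Monte-Carlo recovery. Full-scale,
300-epoch GPU training on clinical projections and the clinical
evaluation values that depend on it are outside the package's scope.

## Known limitations

* The shear forward model ignores magnification and depth-dependent
  blur; reconstructed heights are nominal, not calibrated.
* PIQE here is a faithful re-implementation of the published block logic
  with one documented normalization change; scores are comparable within
  this package, not across implementations.
* The autodiff core is single-threaded float64 numpy: ideal for
  correctness and desk-scale experiments, not for full-resolution
  training.
* The unpaired translator at toy scale preserves shape and reduces its
  training objective, but is not expected to improve reconstruction
  metrics over the raw low-dose input; that requires the full pools and
  epoch budget.
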