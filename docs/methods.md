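# Methods

## Problem and model

`cortseg` segments multiple-sclerosis lesions — white-matter lesions (WMLs)
and cortical lesions (CLs) jointly — from two co-registered 3T MRI
contrasts: a 3D FLAIR volume, in which WMLs are strongly hyperintense but
CLs are nearly invisible, and an MP2RAGE UNI volume, which carries the
T1 contrast that makes CLs detectable. The segmenter is a 3-level,
valid-padding 3D U-Net operating on two-channel patches.

### Architecture

All convolutions are unpadded ("valid") 3×3×3 with ReLU activations; there
are no normalization layers. The analysis path applies five convolutions
with 32, 64, 64, 128 and 128 filters, with 2×2×2 max pooling after the
second and the fourth; the fifth convolution plus a 128→256 expansion form
the bottleneck. The synthesis path mirrors it with feature-map widths
256, 128, 128, 64, 64 and a final 1×1×1 projection to a single sigmoid
channel (probability of "any lesion"). Skip connections concatenate
center-cropped encoder features, the only padding-free option.

Three derived quantities follow deterministically from this declaration
and are recomputed (never hard-coded) by the package:

* **Shape arithmetic.** Each valid conv removes 2 voxels per side, each
  pooling halves, each up-sampling doubles; an 88³ input yields a 48³
  output and the margin is a constant 40 for every feasible input side.
  Feasible sides are exactly the multiples of 4 ≥ 44 (pooling requires
  even sides; the bottleneck requires ≥ 1 voxel).
* **Spatial context.** The pooling stages are exactly compensated by the
  up-sampling stages, so the network is an overall stride-1 map and each
  output voxel depends on a contiguous input window of fixed width
  `input_side − output_side + 1 = 41`. Note that naive additive
  receptive-field accounting over the layer list yields 44–45 here: a
  stride-2 transposed convolution grows dependency windows sub-additively
  (each of its outputs depends on exactly one input), so the exact value
  must come from the trace identity. A corollary used by the tests and
  the tiling design: the network is shift-equivariant only for shifts
  that are multiples of 4 voxels (the product of the pooling strides),
  not 1.
* **Parameter budget.** Up-convolutions use 2×2×2 kernels and *halve*
  channels (256→128, 128→64) so that post-concatenation widths equal the
  paired encoder stage. Counting kernels and biases this gives exactly
  3,703,777 trainable parameters (≈ 3.70 M, within the 3.8 M design
  budget); channel-preserving up-convolutions would give ≈ 4.6 M and were
  therefore rejected.

### Numerical backend

No deep-learning framework is used: the forward and backward passes for
the four layer types (valid conv, 2³ max pool, 2³-stride-2 transposed
conv, ReLU) and the Adam optimizer are implemented directly in numpy
(`cortseg._nn`). Convolutions are evaluated as a sum of 27 kernel-offset
matrix products, which keeps peak memory low and routes the arithmetic
through BLAS. Backpropagation is verified against central finite
differences in float64 to ~1e-3 relative error; the residual is the
expected ReLU/max-pool kink noise (with zero-initialized biases many
pre-activations sit exactly on the ReLU kink, so the gradient check first
perturbs biases away from zero). Weights use He-uniform fan-in
initialization from a seeded generator; biases start at zero. Training
arithmetic is float32.

## Training recipe

* **Normalization**: every input volume is z-scored (population standard
  deviation) over *all* voxels. No brain mask is used because the
  pipeline deliberately performs no skull stripping; whole-volume
  statistics are the only mask-free choice.
* **Sampling**: each ground-truth connected component is equally likely
  regardless of size; the 88³ input window is centred on a uniformly
  drawn voxel of the chosen component plus an independent per-axis jitter
  of up to 12 voxels (clipped to the padded volume). The jitter prevents
  the network from learning "lesion always at patch centre"; a
  configurable fraction of pure-background windows is available but
  defaults to 0 (lesion-centred sampling only). Volumes are
  reflection-padded by 20 voxels so windows always fit.
* **Loss**: per-voxel weighted binary cross-entropy on the sigmoid
  output, weight 1 on background and WML voxels and 5 on CL voxels
  (CLs are about five times rarer), averaged over the 48³ output window;
  plus an L2 penalty of 1e-5 · ½‖w‖² on convolution kernels only (biases
  are exempt, the common convention).
* **Schedule**: learning rate ramps log-linearly (geometrically) from
  1e-8 at iteration 0 to 1e-4 at iteration 2000 — the end points are the
  published values, the geometric interpolation is this package's choice
  for a ramp spanning four orders of magnitude — then halves every
  10,000 iterations counted from the end of warm-up.
* **Optimizer**: Adam with default moments, batch size 2.
* **Augmentation** (on the fly): rotation about z uniform in ±90°,
  isotropic scaling uniform in [0.95, 1.05], independent flips along all
  three axes. Intensities are interpolated trilinearly; label and weight
  maps by nearest neighbour, so weights remain in {1, 5}. Input and
  output windows share a centre, so a single transform is consistent for
  both.
* **Early stopping**: the validation loss (same weighted cross-entropy,
  un-augmented, on a fixed deterministic tiling of the validation
  volumes) is evaluated every 1000 iterations; training stops after 5
  consecutive non-improving checks (both numbers are package defaults;
  the source recipe leaves them open) and the best checkpoint is
  restored.

## Inference

The volume is reflection-padded by 20 voxels per side; 48³ output tiles
cover it disjointly (edge tiles are shifted inward, later tiles overwrite
earlier ones — a deterministic lexicographic priority). Reflection
padding avoids presenting out-of-distribution zeros at the borders.
Because the model is shift-equivariant at stride 4, stitching is exactly
seamless whenever tile starts agree modulo 4 (always true for the regular
tiles, whose pitch is the output side, itself a multiple of 4); at
inward-shifted edge tiles the overwrite rule makes any residual
discrepancy deterministic and negligible. For small volumes the input
side is enlarged (up to a memory cap) so that one tile covers the whole
volume. The binary mask is `probability ≥ threshold`; the threshold is
selected on the validation set over the grid 0.05, 0.10, …, 0.95 by
maximizing the *mean per-subject* Dice after minimum-size filtering
(matching the per-patient reporting style), ties broken toward the lower
threshold to favour sensitivity.

## Evaluation

Lesions are connected components; the default connectivity is 18
(the MS-lesion-challenge convention; 6 and 26 are available). Components
smaller than 3 voxels are re-classified as background in ground truth and
predictions before every metric (3 µL at 1 mm³ voxels; 3.6 µL at
1×1×1.2 mm — both below the clinical 3-mm-diameter WML convention, which
corresponds to ≈ 14 mm³ in spherical approximation). Voxel metrics: Dice,
PPV, absolute volume difference on the pooled binary masks. Lesion
metrics: a ground-truth lesion is detected if ≥ 1 of its voxels is
covered by any predicted component (LTPR, and LTPR_WM / LTPR_CL with the
denominator restricted by type); a predicted component overlapping no
ground-truth lesion is a false positive (LFPR). A predicted component
bridging a WML and a CL detects both and is not a false positive.
Undefined metrics (empty denominators) are reported as NaN and excluded
from medians, never coerced to 0 or 1. Cohort comparisons use the
two-sided Wilcoxon signed-rank test (zeros dropped) with Bonferroni
correction at α = 0.05, and Pearson correlation with a least-squares line
for manual-vs-automatic total lesion volume.

Fold construction is stratified by acquisition site only: test folds
partition the cohort with per-site proportions within one subject
(scikit-learn's stratified k-fold behind the module interface), and 20%
of the non-test subjects — rounded to nearest, so 54 × 0.20 → 11 — form
the validation set. One model is trained from scratch per fold with a
fold seed derived from the master seed.

## Synthetic phantoms

The phantom generator exists so that every downstream stage is testable
without clinical data. It renders a nested-shell brain (ellipsoidal
cortex ribbon of configurable thickness, default 3 voxels, around a
white-matter core) and places ellipsoidal lesions by rejection sampling:
WMLs strictly inside the core, CLs seeded in the ribbon (they may extend
into adjacent white matter, as the dominant leukocortical subtype does).
Lesion volumes are log-normal, truncated below at the 3-voxel minimum;
per-subject lesion counts are Poisson draws around the template counts,
giving cohorts whose burden varies over a wide range. All lesions are
kept 26-disconnected from one another, so component counts are exact by
construction. Channel intensities follow the clinical contrast ordering
— the generator *enforces* that CL contrast in the FLAIR-like channel is
smaller than WML contrast there, and larger in the MP2RAGE-like channel —
with additive Gaussian noise (default σ = 4 against tissue means of
100–160 arbitrary units, i.e. contrast-to-noise ≈ 3–15 depending on
lesion type and channel).

What the phantoms do **not** emulate: MR physics (no bias field, no
partial-volume mixing, no k-space artefacts), realistic cortical folding,
lesion texture, or inter-rater label noise. Tests passing on phantoms
therefore demonstrate the correctness of the machinery (shapes,
gradients, sampling, tiling, metrics, reproducibility) and the learning
behaviour of the architecture under its intended contrast structure —
not clinical-grade accuracy.

## Desk-scale study conditions

The test suite and examples run a scaled-down configuration chosen once:
filters divided by 8, 52³ training patches, 48³ phantoms with 6 WMLs and
2 CLs per subject (log-normal size medians 60 and 40 voxels), 4 subjects
for training/validation, 400 iterations. Because the published warm-up
alone spans 2000 iterations, the small-scale recipe scales the schedule
too (warm-up 50 iterations, peak learning rate 2e-3); the full-scale
defaults in `TrainConfig` are unchanged. Under these conditions the
scaled-down network reaches Dice ≈ 0.7 on a held-out phantom and detects
every lesion above 50 voxels, and two identically seeded cross-validation
runs produce byte-identical report CSVs.

## Known limitations

* Single-channel sigmoid output: the network predicts "lesion vs
  background"; lesion *typing* in evaluation comes from the ground truth
  (CL subtypes are pooled).
* The numpy backend is CPU-only and single-sample; full-scale (88³,
  3.7 M parameter) training is supported by the code but is orders of
  magnitude slower than a GPU framework.
* Rigid FLAIR→MP2RAGE registration is assumed done upstream; the loader
  only verifies its postcondition.
* The stride-4 equivariance caveat above means stitched probabilities at
  inward-shifted edge tiles are implementation-defined (deterministic,
  but dependent on the tile priority rule).
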