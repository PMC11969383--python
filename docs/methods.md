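# Methods

This note documents the models, conventions and design choices behind
`cellcyclekit`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the bundled synthetic data can and
cannot establish.

## 1. Problem and pipeline

The task is binary staging of fixed interphase nuclei — G1 versus S/G2 —
from the DAPI channel of a 3D fluorescence stack, given an instance
segmentation produced by an external tool. Ground truth comes from a
Fucci2a reporter: mCherry-hCdt1 (RFP) marks G1, mVenus-hGeminin (GFP)
marks S/G2. The pipeline is

1. object QC on the instance mask,
2. per-nucleus quantification,
3. Fucci-based labeling (or the continuous angle target),
4. either handcrafted-feature SVMs or a 3D CNN on standardized
   single-nucleus crops.

Fucci2a cannot resolve S from G2, so three-class staging is out of scope,
as are instance segmentation itself, saliency analysis, and physical-unit
(nanometre) morphometry — all geometry is in voxel units, which is
harmless downstream because every feature consumer re-scales (z-scoring
for the SVMs, per-crop normalization for the CNN).

## 2. Object quality control

An object is removed if (a) any voxel lies on a tile face (truncated
nuclei), or (b) its solidity — voxel count divided by convex-hull voxel
count — is below 0.9 (doublets, debris). Solidity is computed in 3D on
voxel centers: the hull is the convex hull of the centers, and its
"volume" is the number of lattice points inside it, so the quantity is
exactly reproducible by a brute-force half-space test (the test suite
does exactly that). Degenerate objects (lines, planes) are measured
inside their affine span. The filter is applied once and is idempotent.

## 3. Quantification conventions

- Aggregate intensity: float64 sum over mask voxels; mean = aggregate / V.
- Centroid: arithmetic mean of voxel coordinates ((Z, Y, X) order
  everywhere in memory; file metadata records axis order).
- Axis lengths: 4·sqrt(eigenvalue) of the voxel-coordinate covariance
  (the ellipsoid-equivalent convention); reported as major/minor.
- Crops: a (Z, Y, X) = (90, 150, 150) window centered on the centroid
  rounded to the nearest integer with ties toward negative infinity;
  out-of-tile regions zero-padded; voxels of other objects and background
  zeroed. Masked crops make the conservation law "sum of crop equals
  aggregate intensity" exact, and they justify the "nonzero voxels"
  wording of the normalization step.

## 4. Fucci labeling

Filters run in a fixed order (low-intensity → ratio → volume); the
recorded exclusion reason is the first match, but survivorship is
order-invariant because a cell is excluded iff it meets at least one
criterion. All inequalities are strict. Two statistics are data-derived:

- **Channel normalizers** for the ratio filter (unspecified upstream):
  per-channel population **means** over QC-passing cells. Means rather
  than medians: the Fucci ratio distribution is bimodal with a sparse
  transition region, and a median can sit on a density-gap edge and swing
  wildly between samples, dragging the exclusion band onto clearly
  expressing cells. The normalizers are an explicit argument, so medians
  (or unit normalizers) remain one call away.
- **Volume statistics** (μ_V, σ_V): computed over cells that passed the
  low-intensity filter — "abnormal size" is a statement about expressing
  cells — before ratio filtering. Configurable via `VolumeStats`.

Labels use aggregate R versus G (equivalently means — V cancels); an
exact tie raises rather than guessing, since ties are unreachable after
the ratio filter under equal normalizers. The angle θ = atan2(G, R) in
degrees is the regression target; it is reported for every cell with
R + G > 0, and 45° binarizes it back to the class label.

## 5. Morphology features and SVM baselines

2D features are measured on the Z maximum-intensity projection of the
masked crop (so the 2D mask is the projected 3D mask); 3D features on the
crop itself. Conventions: pixel/voxel centers for hulls and Feret
diameter (a 1×20 pixel line has Feret 19); surface area from marching
cubes at level 0.5 on the binary mask after Gaussian smoothing with
σ = 0.8 voxel — a raw binary isosurface overestimates area by ~7%
(staircase artifact) and would bias sphericity to ~0.92 for a perfect
sphere; with smoothing a radius-10 sphere measures within 1% of 1.
Sphericity values above 1 (small objects, discretization) are clamped to
1 with a warning. Intensity features scale linearly with the image;
shape features are invariant — both properties are tested.

SVMs are RBF-kernel, scikit-learn backed. Features are z-scored with
statistics fitted on training rows only. Hyperparameters C ∈ {0.1, 1, 10,
100} and γ ∈ {1e-3 … 10} (log-spaced) are chosen by inner 5-fold
cross-validated AUROC; evaluation is on a shared stratified held-out
split (or outer CV folds). The grid and fold counts are package
defaults, not published values. S/G2 is the positive class everywhere;
ROC uses the decision-function margin (AUROC is rank-based, so
calibration would change nothing).

## 6. Volume preprocessing

Per platform: the crop is block-mean downsampled (epifluorescence 2× in
XY; confocal 2× in XYZ — chosen to equalize anisotropy across platforms),
divided by a single normalization constant, and zero-padded back to
(Z, Y, X) = (90, 75, 75) with any odd remainder on the trailing side.
Block means (not strided subsampling) conserve integrated intensity up to
edge effects. The normalization constant is the median over training
crops of each crop's median nonzero voxel ("median of medians"), fitted
on the training split only and applied unchanged to train/validation/test
— the upstream description wavers between "mean normalization" and a
median-based recipe; the operational median description is implemented.
The 70/20/10 split is seeded, unstratified uniform sampling with
largest-remainder rounding (a stratified option was considered
unnecessary at these sample sizes). Augmentation is an in-plane rotation
about Z, bilinear, zero-filled; 90° multiples are exact index
permutations, and nuclei are centered so corner mass loss is negligible
(asserted < 1% on blob fixtures).

## 7. Network architectures

The 3D classifier is the four-block encoder of a U-Net-style 3D CNN
retooled for staging:

| block | unit 1 | unit 2 |
|-------|--------|--------|
| 1 | GN(1) → conv 1→16 | GN(16) → conv 16→32 |
| 2 | GN(32) → conv 32→32 | GN(32) → conv 32→64 |
| 3 | GN(64) → conv 64→64 | GN(64) → conv 64→128 |
| 4 | GN(128) → conv 128→128 | GN(128) → conv 128→256 |

All convolutions are 3×3×3, stride 1, padding 1, **bias-free** (group
normalization precedes each one); group count 8, except 1 for the
single-channel input; ReLU after each conv; 2×2×2 max pooling between
blocks; head = adaptive max-pool to (1,1,1) → flatten → dropout 0.5 →
linear 256→1. Totals: 14,290 + 83,072 + 332,032 + 1,327,616 + 257 =
**1,757,267** trainable parameters. The 2D variant cannot be the literal
"same layers in 2D" — that would carry 586,547 parameters, not the
published 388,547 — so it is defined as four *single-unit* blocks
(1→32→64→128→256) with *biased* 3×3 convolutions and the identical head,
which reproduces 388,547 exactly; the printed parameter count is treated
as authoritative. Classification and regression heads share every
parameter shape; only the output interpretation and loss differ. A
name-mapping hook can load externally supplied encoder weights
(transfer learning from the published light-sheet model is otherwise out
of scope).

The implementation is pure numpy: im2col + GEMM convolutions with
hand-written backprop (gradients verified against central differences in
float64), group-norm backward in closed form, argmax-routed pooling
gradients, inverted dropout, and Adam with L2-coupled weight decay
(decay added to the gradient), β = (0.9, 0.999), ε = 1e-8. Parameters
are float32; Adam moments are float64. Initialization is fan-in uniform
(bound 1/√fan_in) from a seeded generator, so builds are reproducible.
GroupNorm ε = 1e-5. A "35 layers" summary count is framework-dependent
bookkeeping and is not asserted.

## 8. Training recipe

Batch size 4; Adam, learning rate 1e-5, weight decay 1e-1; binary
cross-entropy on logits (classification) or MSE in degrees (regression);
checkpoint selection by highest validation accuracy at probability
threshold 0.5 (classification; the decision threshold is a package
default — only "the selected decision threshold" is specified upstream)
or lowest validation RMSE (regression), with ties resolved toward the
earlier epoch. Shuffle order, augmentation angles and dropout masks all
derive from the run seed, so training is bit-reproducible. The reference
recipe trains 800 epochs; desk-scale runs use 30. Merged multi-platform
datasets concatenate per-source splits without re-splitting (no leakage
across the merge) and keep each source's own normalization constant;
joint renormalization of a merged set is deliberately not done.

## 9. The synthetic world

The simulator emulates what the pipeline needs to be exercised, not a
microscope. Each cell has a latent cycle progression p ~ U(0, 1) (G1
below 0.5). Along p: DAPI density ramps 1× → 2× across the S interval
[0.5, 0.9] (2N → 4N), volume ramps 1× → 1.6×, RFP decays and GFP
accumulates geometrically between 2,800 and 12,000 intensity units with
lognormal noise (σ_log = 0.12). Nuclei are ellipsoids (median physical
semi-axis 3.8 μm, lognormal σ = 0.05, per-axis jitter 5%, random
Z-rotation) converted to voxels through the profile's voxel size, so
epifluorescence nuclei are flat (~8 Z-planes) and confocal nuclei tall
(~19) at equal physical size. Rendering is uniform intensity inside the
ellipsoid plus additive Gaussian read noise, clipped to the bit-depth
range; channel means and densities are integers, so noiseless renders
obey exact conservation (integrated DAPI = density × voxel count). No
PSF, photobleaching, tiling overlap, or mitotic figures are simulated.

Three object kinds exercise the filters, injected at exact counts (10%
non-expressers, 3% volume outliers by default): non-expressers draw both
channels at 0.2–0.8× the platform thresholds; volume outliers are 8×
volume aggregates with a tight spread, independent of cycle stage;
expressing cells redraw (p, noise) until their raw GFP/RFP ratio clears a
guard band (0.55, 1.65) — the population analogue of omitting
indistinguishable transition cells from a ground-truth set — and their
channel means are floored at 1.15× the thresholds. These margins make
filter outcomes a deterministic function of the truth flags (verified on
50 seeds × 2 platforms), which is what lets the filter tests demand
exact agreement rather than approximate counts.

Two single-nucleus presets support the learning experiments:

- **easy** (classifier/regressor learnability): 16³-voxel masked crops,
  θ uniform on [8°, 38°] (G1) or [52°, 82°] (S/G2), density and volume
  ramping monotonically in θ. Strong separation by design: a green
  learnability test establishes that the training loop, loss, optimizer
  and evaluation are wired correctly and that the architecture can
  extract size/contrast cues at desk scale — it says nothing about
  real-data accuracy.
- **anisotropy stress** (2D-vs-3D direction): both classes share the XY
  semi-axis distribution (projected area carries no signal); S/G2 is
  elongated 1.5× along Z and its DAPI density is only modestly higher
  (1.25×, σ_log = 0.18, heavy overlap). Volume is thus hidden from
  projections, and the 3D feature pair (integrated intensity, volume)
  beats the 2D pair (projected intensity, area) — the direction, not the
  magnitude, of the published 2D/3D comparison.

What the synthetic data do **not** emulate: realistic intensity
histograms (no quantitative distributions were available to calibrate
against — only orderings and overlap structure are preserved), chromatin
texture (the real classifier may exploit heterochromatic foci; simulated
nuclei are homogeneous), segmentation errors other than border truncation
and doublet-like aggregates, and optical blur. Consequently the
published headline numbers (AUROC 0.94–0.95, accuracy gains, regression
RMSE 18.4 / Pearson 0.792) are not reproduced here; the architecture
parameter counts are the only quantities checked against published
values exactly.

## 10. Degenerate inputs and tie-breaks

- Empty mask → empty QC report and empty output, not an error.
- Single-voxel objects: axis lengths 0; solidity 1.
- σ_V = 0: a cell is volume-excluded iff V ≠ μ_V.
- R = G after filtering, or θ = 45° at binarization → error (unreachable
  in a filtered population; a silent guess would corrupt labels).
- All-zero crop → error naming the crop (cannot be normalized).
- Nucleus larger than the crop window, or with voxels outside the
  centered window → error naming the label.
- AUROC on a single-class set → error; constant regression predictions →
  NaN correlations with a warning.

## 11. Known limitations

- The CNN is CPU-bound numpy; it is meant for desk-scale experiments and
  fine-tuning small datasets, not 800-epoch full-resolution training.
- Solidity/convex counting is exact but O(bounding box) per object;
  pathological masks with huge boxes are slow.
- The simulator's class separations are generous; reported AUROCs on
  synthetic data are upper bounds on difficulty, by construction.
- Combined-platform training assumes per-source normalization constants;
  if a user's platforms differ in ways normalization cannot absorb
  (e.g., PSF shape), the merge helper will not fix that.
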