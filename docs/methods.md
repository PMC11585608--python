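# Methods

## Problem

Chest CT is routinely reconstructed at 5-mm slice thickness for storage
and cost reasons, although 1-mm reconstructions resolve small nodules,
fissures and vessels far better.  When both reconstructions exist they
come from identical raw data, so a thick volume is, to good
approximation, a known degradation of the thin volume: thick slice `i`
coincides with thin slice `5 i` and integrates the signal of the thin
slices around it.  `thinslice` treats thin-slice synthesis as
through-plane super-resolution at integer factor `r` (default 5): given
`D` thick slices, predict the `(D − 1) · r + 1` thin slices whose grid
interleaves them.

## Model

The synthesis network is a convolutional-transformer hybrid
encoder-decoder that casts the task as recovery of masked slice
positions from visible ones:

* **Encoder.**  Each voxel of the normalized thick cube (`L` slices) is
  embedded by a 1×1 linear projection to `embed_dim` channels, then
  passes through `enc_depth` 3-D CTH blocks.  A CTH
  (convolutional-transformer hybrid) block is four successive
  Swin-Transformer layers (STLs) — windowed multi-head self-attention
  alternating between regular (W-MSA) and cyclically shifted (SW-MSA)
  window arrangements, each followed by a pre-norm MLP — capped by a
  kernel-3 channel-preserving convolution, with a residual connection
  around the whole block.
* **Mask Token Add.**  The z axis is expanded from `L` to
  `(L − 1) r + 1`.  Positions `r·i` receive the encoder feature of
  visible slice `i`; all other positions receive a single shared
  learnable mask-token vector.  A learnable axial phase embedding
  (indexed by `z mod r`, zero-initialized) is added everywhere, so at
  initialization the visible positions are exact copies of the encoder
  features.
* **Decoder.**  `dec_depth` T-CTH (through-plane CTH) blocks.  Each has
  two parallel branches: the volume is permuted so that coronal
  (respectively sagittal) planes become a batch of 2-D images, a 2-D CTH
  block runs on the planes, and the permutation is inverted.  The two
  branch contributions are fused with the block input by element-wise
  sum, so zeroing both branches leaves the identity.
* **Head.**  A per-voxel linear projection back to one channel.

In-plane resolution is never changed.  Window attention keeps the Swin
relative-position bias.  By default the shifted layers compute attention
within each window of the shifted grid **without** the classic
cross-sub-window mask: for a reconstruction task the wrap-around mixing
is information, not contamination, and skipping the mask removes
computation (`use_attention_mask=True` restores the masked variant).

Intensities are clamped to [−1024, 2048] HU and mapped affinely to
[0, 1] before entering the model; outputs are clipped to [0, 1] and
mapped back.

### Design choices the architecture leaves open

The published description fixes the block structure but not the widths,
depths, window sizes, loss, or the parameterization of the mask tokens.
Choices made here, all configurable:

* loss: mean absolute error (L1) on normalized intensities by default —
  the common super-resolution default — with L2 selectable;
* branch fusion in the T-CTH block: residual element-wise sum;
* mask tokens: one shared vector plus a per-phase (`z mod r`) embedding;
* the convolution in a 3-D CTH block is a full 3-D kernel-3 convolution;
* the final projection is per-voxel (1×1), mixing no neighbourhood;
* two named presets: `tiny` (embed 32, depths 2/2, 4 heads, windows
  (2,4,4)/(8,8), MLP ratio 2, L=4) sized for CPU-scale tests, and
  `full` (embed 96, depths 4/4, 6 heads, windows (2,8,8)/(8,8), MLP
  ratio 4, L=8) as a plausible full-scale default.  The `tiny` numbers
  were chosen for single-CPU throughput (larger 2-D windows give the
  attention kernels better arithmetic intensity; the smaller MLP ratio
  trims the widest activations); neither preset claims to reproduce the
  original unpublished hyperparameters.

## Training protocol

AdamW (β = 0.9/0.999, ε = 1e-8), initial learning rate 3e-4, weight
decay 1e-4 (decoupled; applied to weight matrices only), mini-batch 1,
maximum 2000 epochs.  Augmentation: random aligned crops — a thick crop
starting at axial index `i` always pairs with the thin crop starting at
`r·i` — and horizontal flips applied identically to both with
probability 0.5.  Every 5 epochs the mean PSNR over fixed center crops
of the validation samples is evaluated; if three consecutive evaluations
fail to exceed the running best, the learning rate is multiplied by 0.1,
and training stops after the third reduction (or at the epoch cap).
The checkpoint with the highest validation PSNR is kept, earliest epoch
on ties.  "No improvement" is read strictly (not greater than the
running best), and the bad-evaluation counter resets after each drop.
Validation during training uses center crops rather than full
sliding-window synthesis to bound evaluation cost; final evaluation
always uses full inference.

The schedule is a pure function of the evaluation history
(`schedule_from_history`), so recorded runs can be replayed and audited.

## Inference

Full volumes are synthesized with a sliding window: axial windows of `L`
thick slices overlap by exactly 1 slice (stride `L − 1`), in-plane tiles
(default 256²) overlap by 0, and a final window/tile is anchored to the
far edge whenever the stride does not tile exactly.  Each window's
prediction lands at thin index `r · start`; coordinates covered by
several windows are averaged uniformly.  The output has
`(D − 1) r + 1` slices and `dz/r` spacing.

The comparison baseline interpolates along z only, with the Catmull-Rom
cubic convolution kernel (a = −0.5) at positions `k/r` in thick-index
coordinates.  Coincident positions are copied bit-exactly and edge
neighbours are obtained by linear extrapolation, which keeps degree-1
polynomials exact at the volume ends.

## Synthetic paired phantoms

No paired clinical reconstructions are distributed, so training and
evaluation run on a procedural lung phantom: a soft-tissue body
ellipsoid (≈40 HU) containing two air-density lungs (≈−900 HU),
random-walk vessel tubes (≈50 HU), oblique fissure plates (≈−700 HU) and
ellipsoidal nodules of three kinds — solid ≈0 HU, subsolid ≈−500 HU,
calcific ≈800 HU, mixed in proportions 0.62/0.07/0.31 following the
nodule-type distribution reported for the clinical cohort.  Gaussian
noise of 20 HU emulates thin-slice quantum noise; all values are clamped
to [−1024, 2048] HU.  The thick counterpart is produced by a
slice-sensitivity-profile average centred on every 5th thin slice —
a box profile of width `r` by default (triangle and Gaussian profiles
are available), truncated and renormalized at the volume ends.  The true
reconstruction kernel of any given scanner is unknown; the box profile
is the simplest choice consistent with the coincident-slice alignment,
and desk-scale conclusions depend mildly on it.

What the phantom does **not** emulate: scanner noise spectra and
artifacts, anatomical texture, contrast phases, breathing states, or any
CT forward projection physics.  Passing desk-scale tests therefore
demonstrates that the architecture, optimization protocol and evaluation
pipeline work end-to-end and that the network out-interpolates a bicubic
baseline on structured volumes — not clinical-grade synthesis quality.

## Evaluation

PSNR (`10 log10(1/MSE)` on [0, 1] intensities, +∞ for identical input)
and SSIM (2-D per axial slice, 11×11 Gaussian window σ = 1.5, K1 = 0.01,
K2 = 0.03, data range 1.0, averaged over slices) compare each synthetic
volume against the reference thin volume.  Metrics are computed in
normalized space so closed-form test values are exact; both functions
accept a `data_range` for other conventions.  Cohorts are compared with
the two-sided Wilcoxon signed-rank test, Bonferroni-corrected by
multiplying p by the number of comparisons (capped at 1).

## Diagnostic statistics

The reader-study toolkit reports accuracy, sensitivity, specificity,
precision and F1 on the 0–100 scale rounded to one decimal
(half-away-from-zero, matching table presentation); zero-denominator
metrics are flagged, not raised.  Paired tests:

* **Wilcoxon signed-rank** — exact null distribution for n ≤ 25 by
  dynamic programming over doubled midranks (the doubling makes tied
  average ranks integral), normal approximation with continuity
  correction above; zeros dropped.
* **McNemar** — exact two-sided binomial for b + c < 25, chi-square with
  continuity correction otherwise.
* **DeLong** — AUC by Mann-Whitney pair counting (ties ½) and the
  placement-value covariance estimator for the paired AUC difference.
* **Permutation test** for precision/F1 — per-case random swap of the
  two methods' predictions, p = (1 + hits)/(1 + B), default B = 10 000,
  seeded.
* **Likert non-inferiority** — one-sided Wilcoxon on
  `synth − real + margin` (margin 0.25 points on the 5-point scale);
  "non-inferior" when p < 0.05.  This shifted-median reading is an
  interpretation of the stated 0.25-point threshold; a
  proportion-based formulation would also be defensible.
* **Diagnostic-rate chi-square** — Yates-corrected 2×2 test, Fisher
  exact fallback (flagged) when an expected cell is below 1.
* **Bootstrap** — seeded percentile CIs (default 1000 resamples).

## Numerical engine

No deep-learning framework is assumed: the package carries a compact
reverse-mode autograd on float32 NumPy arrays (`thinslice.nn`) with the
primitives the model needs, an AdamW implementation, and fused
linear/convolution kernels (flattened GEMM, im2col).  Gradients of every
primitive and of the composed network are verified against central
finite differences in the test suite.  Inference runs under a no-graph
mode so memory stays at working-set size.

## Desk-scale problem sizes

The bundled tests train the `tiny` preset on 8 phantom pairs
(thin 41×64×64, thick 9×64×64) with 4×24×24 thick crops and the L2 loss,
validate on 2 pairs and test on 4 held-out pairs; full-volume synthesis
uses L=4 windows with axial overlap 1.  These sizes exercise every code
path — multi-window sliding inference, final-window anchoring, the LR
schedule — while keeping a complete train-and-evaluate cycle in minutes
on one CPU.  At this training budget (a few hundred optimizer steps on
the NumPy engine) the network already out-reconstructs the bicubic
baseline in high-through-plane-gradient regions (vessel, fissure and
boundary voxels), while its flat-region intensity calibration — a small
global bias that batch-1 Adam corrects only slowly — can still trail the
interpolation baseline on whole-volume averages; the corresponding test
asserts the whole-volume comparison and reports both medians when it
fails.

## Known limitations

* The `full`-scale preset is untested at full resolution here; only the
  architecture and protocol logic are exercised at that width.
* The phantom's regularity makes interpolation baselines strong; margins
  over bicubic at desk scale are smaller than those reported on clinical
  data at full scale.
* SSIM is computed 2-D per axial slice (the common convention); a 3-D
  SSIM would weight through-plane structure differently.
* The exact Wilcoxon branch treats tied midranks by enumeration over
  sign assignments with average ranks, which is one of several accepted
  tie conventions.
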