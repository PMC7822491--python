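# Methods

## The segmentation model

The package implements a two-stage ("successive encoder-decoder") cascade
for liver and tumor segmentation on axial CT slices.

**Stage 1 — liver localization.** A U-Net with five scaling levels. Each
encoder level is two 3×3 convolutions (ReLU) followed by 2×2 max pooling;
channel widths double per level from a base of 32 (32, 64, 128, 256, 512 at
spatial sizes 256² down to 16²). Each decoder level is a 2×2 transposed
convolution, concatenation with the same-resolution encoder output, and two
3×3 convolutions; decoder widths are 128, 64, 32, 16. The first transposed
convolution halves the bottleneck width (512→256) while the later ones
preserve their input width — this is what the published output-size ledger
dictates, and the builder verifies the resulting skip-concatenation widths
(512, 256, 128, 64) at construction time. A 1×1 convolution with sigmoid
emits the liver probability map. No batch normalization or dropout is used
in stage 1: the level description ("two convolutions and one pooling")
admits nothing more, so the smallest faithful reading was implemented.

**Stage 2 — tumor extraction.** An FC-DenseNet ("dense U-Net"). A 3×3
convolution lifts the masked input to 48 channels; five encoder stages each
apply a dense block and a transition down; a 15-layer dense block forms the
bottleneck; five decoder stages each apply a transition up, a skip
concatenation with the matching encoder dense block, and a decoder dense
block; a 1×1 convolution + sigmoid closes the network. Module definitions:

* *dense layer*: BN → ReLU → 3×3 conv producing `k` feature maps → dropout
  (p = 0.2), concatenated onto the running stack;
* *dense block*: `n` dense layers. Encoder blocks emit input ⊕ new features
  (`m + n·k` channels); decoder blocks emit only their new features (`n·k`),
  keeping the upsampling path from ballooning;
* *transition down*: BN → ReLU → 1×1 conv (channel-preserving) → dropout →
  2×2 max pool;
* *transition up*: 3×3 transposed convolution with stride 2, applied to the
  *new features* of the preceding dense block only.

The growth rate is nowhere stated explicitly in the source material; it is
forced by the channel ledger (48 + 4k = 112 ⇒ k = 16) and is consistent
with every other row. Block sizes are (4, 5, 7, 10, 12) encoder layers,
15 bottleneck, (12, 10, 7, 5, 4) decoder.

**Known table discrepancy.** The published per-layer table lists the
bottleneck dense-block output as 8² × 880. The same table's arithmetic gives
656 + 15·16 = 896, and the first transition-up width it prints (240 = 15·16)
confirms the 15-layer/growth-16 reading. 880 is treated as a typographical
error; the shape engine reports 896 and nothing special-cases 880.

**Cascade contract.** At inference the stage-1 probability map is binarized
at 0.5 (configurable), multiplied elementwise into the input, and the
stage-2 output is thresholded and intersected with the liver mask, so
`tumor_mask ⊆ liver_mask` holds exactly. Binary — rather than soft —
multiplication was chosen as the literal reading of "produce the liver mask,
multiply, segment". During stage-2 *training* the ground-truth liver mask is
used for the multiplication (teacher forcing); at inference the predicted
mask is used. The gap is inherent to the two-stage design and accepted.

## Loss, metrics, and conventions

Training minimizes the soft Dice loss
`1 − (2Σab + ε)/(Σa² + Σb² + ε)` with ε = 1, averaged per sample over the
batch. The smoothing term makes the empty-prediction/empty-truth case a
perfect score and keeps gradients finite; its value follows common practice
for sigmoid-output segmentation. The *reported* soft Dice (`soft_dice`)
defaults to ε = 0 so worked examples are exact formula evaluations, with
both-empty defined as 1 — the ε → 0 limit of the smoothed form.

Evaluation binarizes at 0.5 and uses count-based Accuracy, IoU and DSC, with
IoU = DSC = 1 when TP+FP+FN = 0 (nothing to find, nothing found). Per-case
tables are summarized by the unweighted mean over cases, so every test image
counts equally. ROC curves are computed over pooled pixels of the evaluation
set (the per-image-averaged alternative is not implemented); the trapezoidal
AUC then equals the pairwise concordance probability with ties counted half,
which the tests verify against a brute-force oracle.

## Training harness

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7 — framework defaults, since only the
optimizer name and initial rate are prescribed) with lr₀ = 1e-4. Schedules,
both stepping every second epoch: stage 1 multiplies by 0.9
(`lr(e) = 1e-4·0.9^⌊e/2⌋`, read as multiplicative step decay, not cumulative
subtraction); stage 2 multiplies by e^−0.9, accumulating
(`lr(e) = 1e-4·exp(−0.9⌊e/2⌋)`) to mirror the "per two epochs" wording of
the stage-1 schedule. Validation loss (mean per-sample Dice loss, inference
mode) is computed after every epoch; the checkpoint with the lowest
validation loss is returned, ties broken by the earlier epoch. Stage-1
training keeps slices without liver as negative examples; stage-2 pairs are
built only from slices with liver, since its input is defined on liver
regions.

Splits are drawn per-slice, not per-patient (the protocol describes an
image-level random split); this is a known limitation — adjacent slices of
one phantom can land in train and test, which inflates absolute scores.

## The NumPy engine

No deep-learning framework is used: `sedseg.nn` is a small channel-last
(NHWC, float32) neural-network engine with hand-derived reverse-mode
gradients for every layer the two architectures need. Convolutions are
lowered to K·K shifted BLAS matrix products; transposed convolutions to
zero-dilation plus a stride-1 correlation with the flipped kernel (k = 2,
stride 2 for U-Net upsampling; k = 3, stride 2, padding 1, output padding 1
for transition up); batch-norm statistics and normalization, and the ReLU
backward pass, run as numba-compiled single-pass kernels. Max-pool ties
route the gradient to a single winner deterministically. Weights use He
initialization; all randomness (init, dropout, shuffling) flows from
explicit seeds, so training histories are bit-reproducible on one thread.
The graph compiler consumes the same declarative `LayerGraph` that the
symbolic shape engine verifies, and the symbolic parameter count equals the
instantiated model's count — both facts are under test.

## Synthetic phantoms

`sedseg.phantom` generates LiTS-like volumes: 512×512 HU slices (size
configurable), an air background at −1000 HU, a soft-tissue body oval
(−20…40 HU), one liver-like region per slice (70…140 HU) built from a
radially perturbed ellipse that deforms coherently along the stack, a few
distractor organs whose intensity (60…120 HU) overlaps the liver range so
thresholding alone cannot localize the liver, zero to three hypodense
tumors (20…60 HU) placed strictly inside the liver as flattened spheres,
and additive Gaussian noise (σ = 10 HU by default). Intensities are drawn
as a per-region base level plus a bounded smooth field, so with σ = 0 every
liver voxel provably lies in the configured range. Labels follow the
{0 background, 1 liver, 2 tumor} convention with tumor nested in liver by
construction.

What the phantoms do *not* model: ribs, vessels, partial-volume effects,
breathing artifacts, scanner-dependent noise spectra, or inter-patient
anatomy variation. Passing the recovery test therefore shows that the
implementation can learn this cascade task end to end — not that it attains
clinical-grade accuracy on real CT.

## Desk-scale recovery experiment

`sedseg.experiments.phantom_recovery` runs the full pipeline at sizes a
single CPU handles in minutes: 64×64 phantom slices, 200 training / 50
validation / 30 test slices, stage-1 base width 8, stage-2 growth rate 4
(initial conv 12 = 48/4), 30 epochs per stage. Two protocol elements are
rescaled along with the data: both stages train at batch 4 and under the
step-decay schedule. At full scale (thousands of slices, 50–100 epochs)
batch sizes 16/4 and the stage-2 exponential decay are unremarkable, but a
30-epoch, 200-slice run under the exponential schedule performs essentially
all of its learning in the first six epochs (lr < 7e-6 afterwards) and at
batch 16 sees only ~390 optimizer updates in total — both starve the short
run rather than probe the method. The step schedule retains a useful rate
throughout (2.3e-5 at epoch 29) while every full-scale element — loss,
optimizer, lr₀, validation carve-out, best-epoch selection — is unchanged.
Stage 1 is scored by mean count-Dice
of the thresholded liver mask over all test slices; stage 2 over the test
slices that contain tumor (so an always-empty prediction cannot score
well), with ground-truth liver masking as in training. Full-scale results
on benchmark CT (thousands of 256×256 slices, GPU training) are out of
reach in this setting and are not claimed.

## Numerical and I/O choices

* HU window [−100, 200], then affine rescale to [0, 1]; bilinear resampling
  for images and nearest-neighbour for masks (preserves binarity and mask
  nesting) down to the network resolution.
* Volumes are (slice, row, col) grids; NIfTI I/O transposes to/from
  nibabel's (col, row, slice); DICOM series apply rescale slope/intercept
  and validate geometric consistency.
* Marching cubes at level 0.5 on the zero-padded binary grid (padding
  closes surfaces at array borders); mesh volume via the signed-tetrahedron
  sum (trimesh); voxel-count volume is exact and linear in spacing by
  definition.
* Renders use matplotlib's 3-D toolkit with per-mesh color and alpha;
  views are named for patient axes with the slice axis as z.

## Limitations

Single-channel axial 2-D slices only (no 2.5-D or 3-D context); no data
augmentation or post-processing morphology (neither is part of the
protocol); per-slice rather than per-patient splits; the NumPy engine is
CPU-bound and intended for desk-scale experiments, not production training.
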