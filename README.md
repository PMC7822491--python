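# sedseg

Two-stage liver and tumor segmentation for abdominal CT, built around a
*successive encoder-decoder* cascade: a U-Net first localizes the liver on a
windowed CT slice, the slice is multiplied by the predicted liver mask, and a
fully convolutional DenseNet then segments hepatocellular-carcinoma lesions
inside the localized liver. The package is aimed at medical-imaging
researchers who want a small, fully inspectable implementation of this
cascade — including its loss, metrics, training protocol, and 3-D
reconstruction — that runs end to end on a CPU with synthetic phantoms, no
benchmark download required.

## The method

**Cascade.** Stage 1 (SED-1) is a five-level U-Net: each encoder level applies
two 3×3 convolutions and 2×2 max pooling, doubling the feature maps
(32→64→128→256→512); the decoder mirrors it with transposed convolutions and
skip concatenations, ending in a 1×1 convolution + sigmoid that yields a
per-pixel liver probability `A ∈ [0,1]`. The thresholded mask multiplies the
input image, and stage 2 (SED-2) — an FC-DenseNet of dense blocks (DB),
transition-down (TD) and transition-up (TU) modules with growth rate k = 16 —
produces the tumor probability map. The predicted tumor mask is intersected
with the liver mask, so tumor ⊆ liver by construction.

**Loss.** Both stages train with the soft Dice loss

```
L(A, B) = 1 − (2 Σᵢ AᵢBᵢ + ε) / (Σᵢ Aᵢ² + Σᵢ Bᵢ² + ε),
```

`A` the probability map, `B` the binary ground truth, ε = 1 for empty-mask
stability. Evaluation uses the count metrics on binarized masks:
`Accuracy = (TP+TN)/N`, `IoU = TP/(TP+FP+FN)`, `DSC = 2TP/(2TP+FP+FN)`, plus
ROC/AUC over pooled pixel scores.

**Training protocol.** Adam, initial learning rate 1e-4 for both stages;
stage 1 trains 50 epochs at batch 16 with the rate multiplied by 0.9 every
second epoch, stage 2 trains 100 epochs at batch 4 with the rate multiplied by
e^−0.9 every second epoch; 20 % of the training pool is held out for
validation and the lowest-validation-loss epoch is kept.

The networks are described as declarative layer graphs
(`sedseg.netgraph.LayerGraph`) whose per-node output shapes are derived
symbolically, so both architectures are verified row by row against their
published per-layer tables without running a forward pass. The runnable
models are compiled from the same graphs by a compact NumPy neural-network
engine (`sedseg.nn`) with hand-derived gradients and numba-fused
normalization kernels.

## A worked example

```
$ python examples/02_architecture_tables.py
SED-1 (liver U-Net)
node           output size  channels
input          256x256       1
conv_block_1   256x256       32
...
conv_block_5   16x16        512
...
output         256x256       1
trainable parameters: 6,302,129

SED-2 (tumor dense U-Net)
...
db_5           16x16        656
td_5           8x8          656
db_6           8x8          896
tu_1           16x16        240
...
trainable parameters: 9,318,465
```

These are the published channel ledgers of the two stages; `db_6` is the
bottleneck dense block (656 input channels + 15 layers × growth 16 = 896 —
see `docs/methods.md` for the one known discrepancy in the printed table).
The other scripts in `examples/` generate and preprocess a phantom
(`01`), walk through the loss and metrics (`03`), train a miniature cascade
and evaluate it on an unseen volume (`04`), and reconstruct translucent 3-D
liver/tumor views with volume estimates (`05`). A thin CLI (`sedseg phantom |
preprocess | train | predict | evaluate | reconstruct`) wraps the same
functions for shell use.

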