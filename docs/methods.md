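# Methods

## Problem and model

`slhardnet` segments pigmented skin lesions in RGB dermoscopy images as a
binary per-pixel classification. The network is an encoder–decoder with
three specialised fusion stages:

**Encoder.** A HarDNet68 backbone: five 8-layer harmonic dense blocks behind
a stride-4 stem (3×3 stride-2 conv → 3×3 conv → max-pool). In a harmonic
block, layer ℓ receives input only from layers ℓ − 2^i for every power of
two dividing ℓ (layer 0 is the block input); the width of layer ℓ is
`growth · 1.7^v₂(ℓ)` rounded to the nearest even integer, where v₂ is the
2-adic valuation. The block output concatenates the odd-indexed layers plus
the last and passes a 1×1 transition. Stage growths 14/16/20/40/160 with
transition widths 128/256/320/640/1024 reproduce the published HarDNet68
stage widths; spatial pooling after blocks 1, 3 and 4 puts blocks 2 and 3 at
the same resolution. Taps X1..X4 are taken after the transitions of blocks
1, 3, 4, 5 at strides 4/8/16/32 with 128/320/640/1024 channels. X2..X4 are
reduced to 32 channels by three independent 1×1 conv+BN+ReLU stacks.

**Cascaded Fusion Module (CFM).** Two cascaded stages fuse the reduced taps
into the stride-8 semantic map O1 (32 ch). Each branch runs through a
Feature Pyramid Module (FPM): 1×1 entry conv, split into four 8-channel
chunks, a *sequential* cascade of four DDCM branches with dilations 1/3/5/7
(chunk j sees its own input plus the previous branch output), concat, 1×1
exit conv, and a residual add of the FPM input — so an FPM with all weights
zero is exactly the identity. A DDCM branch is 1×D conv (pad (0,(D−1)/2)) →
D×1 conv (pad ((D−1)/2,0)) → 3×3 dilated conv (dilation D, pad D). Pad = D
is the unique "same" padding for a dilated 3×3 kernel; the printed pad pair
(D,D) is read that way, which is the only shape-consistent interpretation.
Every FPM occurrence is independently parameterised (five instances); the
fusion convolutions are 3×3 + BN + ReLU; all resampling is bilinear with
corner alignment off.

**Spatial-Channel Attention Module (SCAM).** Applied to the untouched X1:
O2 = SAM(X1) + CAM(X1), a *parallel* sum (not the CBAM serial composition).
SAM gates by a sigmoid of a 7×7 conv over the concatenated channel-mean and
channel-max maps. CAM pools globally by average and by max, feeds each
descriptor its *own* 1×1 bottleneck (C → C/16 → C, unshared), sums and
sigmoids. Both gates lie strictly in (0,1), so ‖O2‖∞ ≤ 2‖X1‖∞.

**Feature Aggregation Module (FAM).** O2 is bilinearly aligned to stride 8
once, shared by both consumers. Two independent 1×1 convs embed O1 into
16-channel maps Q and P (both views come from O1; the detail branch enters
only through the attention map and the MEM). A 1×1 conv + channel softmax
over the aligned detail map yields a 32-way per-pixel distribution whose
second channel (0-based index 1) is the detail attention. P gated by that
map is adaptively average-pooled to a 4×4 grid — K = 16 anchor nodes of 16
dims (the configurable `pool_grid` pools to a larger grid first and centre-
crops; default is the direct 4×4 pool). S = softmax over pixels of V·Pᵀ
assigns pixels to nodes; node features S·Q pass one graph-reasoning unit
(learned residual adjacency (I − A), zero-initialised, then a channel
linear map and ReLU) and are projected back by Sᵀ. The Mutual Embedding
Module cross-injects a global channel descriptor of the semantic branch
into a 32-channel detail view L and a spatial descriptor of L into a
semantic view Hf: R = Hf′⊙L + Hf⊙L′ (the 1×1 conv producing L is bias-free
so a silent detail branch contributes an exactly-zero L). Output:
Z = R + Conv1×1(Y).

**Heads.** main = Conv1×1(Conv1×1(Z) + Conv1×1(O1)) at stride 8, upsampled
×8 to full resolution; aux = Conv1×1(O1) upsampled ×8. Elementwise addition
is the default fusion ("concat" is available behind `fuse_mode`). Losses
consume raw logits; the sigmoid lives only in prediction and metrics.

**Ablation variants** mirror the incremental study design: baseline =
encoder + naive top-down upsample-add decoder; +CFM replaces the decoder
and adds the aux head; +CFM+SCAM projects O2 to 32 channels, aligns it to
stride 8 and sums it into the decoder feature; full adds the FAM. Parameter
counts grow strictly along this ladder.

## Loss

Per-pixel boundary weights w = 1 + ω·|meanpool_k(G) − G| with k = 31,
ω = 5 and reflective padding (interior-constant masks keep w = 1 at image
borders). The weight formula follows the boundary-weighting convention
established in the salient-object/polyp decoder lineage this architecture
descends from; k and ω are exposed as configuration. With p = σ(z):

    BL = Σ w·bce(z, g) / Σ w          (stable from logits)
    IL = 1 − (Σ w·p·g + 1) / (Σ w·(p + g − p·g) + 1)

Both are reduced **per image and averaged over the batch**, so small
lesions are not drowned out by large ones in the same mini-batch — the
batch-global alternative measurably degrades small-lesion recall. The
training objective is (IL+BL)(main) + (IL+BL)(aux). Unweighted IoU, BCE,
Dice and their printed combinations are provided for the loss-comparison
harness; "iou+bce" as a config name selects the weighted combination above.

## Metrics

DIC = 2TP/(2TP+FP+FN), JAC = TP/(TP+FP+FN), ACC, SEN, SPE from pixel
confusion counts at threshold 0.5. When a ratio's reference class is empty
the value is 1 if the prediction agrees and 0 otherwise. Evaluation averages
per-image metrics (challenge-style); pooled-count aggregation is available
by flag. DIC = 2·JAC/(1+JAC) holds exactly on counts.

## Training recipe

Defaults follow the published setup: 512×512 inputs, mini-batch 8, AdamW
(decoupled weight decay 1e-2 — the optimiser's conventional default, the
recipe does not print one) at initial lr 1e-4, cosine annealing to zero
over 200 epochs without restarts, augmentation (vertical flip, horizontal
flip, rotation uniform in ±90°, Gaussian noise σ = 10/255 — each applied
independently with probability 0.5; rotation range and noise level are the
package's choices, only the probabilities are prescribed), 5-fold
cross-validation, best-epoch selection by mean validation Dice. Geometric
transforms act identically on image and mask; the mask is resampled
nearest-neighbour to stay binary; noise touches the image only. Inputs are
standardised as (x/255 − 0.5)/0.25.

## Synthetic data

The generator renders what makes dermoscopy segmentation hard: lesions as
unions of 1–3 Fourier-perturbed ellipses (low-order radial wobble ≤ 35%),
placed fully interior by construction; a jittered skin tone with a mild
linear intensity gradient; lesion/skin contrast in (0,1] with a
Gaussian-blurred boundary band (the stored mask is the sharp pre-blur
union, so image boundaries are ambiguous but labels are not); dark
Bézier hair strokes drawn over lesion and skin but never added to the mask;
additive Gaussian pixel noise. Dataset generation draws ~half "hard"
samples (contrast 0.10–0.25 or 3–8 hair strokes) and half easy ones
(contrast 0.30–0.70, ≤2 strokes); base radii span 0.06–0.24 of the canvas
so mask areas cover more than a 10× range. Identical parameters yield
bit-identical samples.

What the generator does **not** emulate: camera vignetting, bubbles, ruler
and gel artefacts, multi-modal lesion textures, colour charts. Passing the
synthetic tests therefore demonstrates that the architecture, losses and
pipeline work end-to-end and can generalise across lesion size, shape,
contrast and occlusion — not that the model reaches clinical accuracy on
real dermoscopy; the published ISIC-scale scores require the real
challenge data and GPU-scale training, which are out of scope here.

## Numerical engine

The network runs on a compact reverse-mode autograd engine over float32
numpy arrays (`slhardnet.nn`). Convolution is im2col + one BLAS product per
batch (weight gradients fold the batch into a single GEMM); bilinear
resizing and adaptive average pooling are separable row/column matrices so
their adjoints are exact transposes; batch-norm uses biased batch variance
with unbiased running estimates (momentum 0.1, eps 1e-5). Max-pool breaks
ties by first index. He-normal initialisation, seeded through
`nn.manual_seed`; training is deterministic given seed and thread-count-
independent in practice since all reductions are BLAS or ufunc based.

## Desk-scale problem sizes

The test-suite and acceptance-script training runs use the package's own
desk-scale harness: 96×96 canvases with early stop once the target score is
reached. The overfit check fits 4 samples (batch 4, AdamW lr 1e-3, cosine,
no augmentation) for at most 200 steps. The generalisation check trains on
64 samples and evaluates 16 held-out ones for at most 15 epochs with
batch 2, lr 1.5e-3 and augmentation on — small batches and a higher rate
than the 200-epoch recipe because the budget is two orders of magnitude
shorter, and augmentation because 64 images underdetermine a 26M-parameter
network. At this scale the stride-8 main head makes lesions
below ~150 px² genuinely hard — boundary cells dominate their area — which
bounds the attainable held-out Dice; see the discussion above about what
synthetic results do and do not show.

## Known limitations

* CPU-only: a 512×512 forward pass takes seconds, so the published
  200-epoch 512² recipe is impractical here; the defaults still express it.
* Binary masks only; no multi-class support, no test-time augmentation, no
  ensembling, no learnable upsampling (all deliberate).
* The encoder supports loading pretrained weights from a checkpoint file
  but ships with random initialisation; no ImageNet weights are bundled.
* Checkpoints are numpy archives tied to this package's layer naming.
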