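# Methods

## Problem and model family

The task is binary segmentation of dermoscopic images: produce a mask
separating the lesion from healthy skin.  It is framed as two-class
per-pixel classification — the background is treated as a class of its own —
so every network ends in a 1×1 convolution and a per-pixel softmax over two
channels.  Inputs are RGB images resized to 384×512 and normalised to
[0, 1]; predictions are binarized by per-pixel argmax (equivalent to
foreground probability > 0.5) and resized back to each image's native
resolution with nearest-neighbour interpolation before scoring.

Four architectures share this contract:

- **U-Net**: two 3×3 convolutions (ReLU) per stage, filters 64–1024, 2×2
  max-pool downsampling, 2×2 stride-2 transposed-convolution upsampling with
  skip concatenation.  ~31.0M trainable parameters.
- **Attention U-Net**: U-Net with an additive attention gate on each skip,
  intermediate gate width = skip channels / 2 (the conventional choice).
- **Squeeze U-Net**: fire blocks in place of plain convolution stages (below).
  ~2.53M parameters.
- **Attention Squeeze U-Net**: Squeeze U-Net with attention gates in the
  decoder; +87,404 parameters (~0.09M) over Squeeze U-Net.

## Blocks

**Fire block** (contraction): 1×1 convolution to C_S "squeeze" channels,
then a two-branch inception — one 3×3 and one 1×1 convolution, each with
C_O/2 channels — concatenated to C_O outputs.  ReLU follows every
convolution; all convolutions are same-padded.  C_O must be even.

**Transposed fire block** (expansion): 1×1 *transposed* convolution to C_S
channels (stride 2 when the block upsamples, with the output size forced to
exactly double), then parallel 2×2 and 1×1 convolutions to C_O/2 channels
each, concatenated.  The asymmetric 2×2 branch (versus 3×3 in the
contraction block) is implemented as specified for the expansion path.

**Attention block**: inputs are a gating signal g (already at the skip's
spatial size) and skip features x.  Both are projected by 1×1 convolutions
to a common intermediate width, summed, passed through ReLU and a 1×1
convolution to a single channel, and squashed by a sigmoid into an attention
map in [0, 1] that multiplies x pixel-wise (broadcast over channels).

**Upsampling block**: ĝ = stride-2 transposed fire block applied to g;
a = attention(ĝ, x) (attention variant) or a = x (squeeze baseline);
output = fire(concat(a, ĝ)).  Using the transposed *fire* module as the
upsampler in both variants keeps the squeeze baseline and the attention
variant identical except for the gates, so their parameter difference is
exactly the attention cost.

## Network wiring and channel schedule

The channel schedule is not fully determined by the source material; the
published trainable-parameter budgets (U-Net > 30M, Squeeze U-Net ≈ 2.5M,
attention variant ≈ +100k) were used as the yardstick for the
reconstruction.  The adopted squeeze-variant schedule, exposed as
`dermseg.architectures.SQUEEZE_SCHEDULE`:

| stage | resolution | channels | C_S |
|---|---|---|---|
| stem conv 3×3, stride 2 | /2 | 64 | — |
| fire ×2 | /4 | 128 | 16 |
| fire ×2 | /8 | 256 | 32 |
| fire ×2 | /16 | 512 | 64 |
| fire ×2 (bridge) | /32 | 1024 | 128 |

Decoder: four upsampling blocks consume the skips at /16, /8, /4 and /2
(output channels mirroring the skip), then a 3×3 convolution (64→32), one
nearest-neighbour ×2 resize, a 3×3 convolution (32→16) and the 1×1
classifier.  This yields 2,533,794 parameters for Squeeze U-Net — 2.5M to
the nearest 0.1M — and 2,621,198 for the attention variant.

Two wiring points were genuinely open and were settled as follows:

- *Nearest-neighbour tail.*  A description with four stride-2 upsampling
  blocks **and two** nearest-neighbour ×2 stages implies a total upsampling
  factor of 64 and hence inputs divisible by 64, which would exclude both
  the 96×128 test fixture size and common dataset resolutions.  This
  implementation uses one nearest-neighbour stage (total factor 32, matching
  the five downsamplings) and keeps the two trailing convolutions.  The
  parameter budget is insensitive to this choice.
- *Attention gate width.*  For the squeeze variants the gate's intermediate
  width is skip-channels / 8; the conventional /2 would cost ~0.35M extra
  parameters, incompatible with the ~100k attention budget.  The Attention
  U-Net baseline keeps the conventional /2 (no budget constrains it).

Weights are Glorot-uniform, drawn from a single `numpy` generator seeded by
`NetworkSpec.seed` in construction order, so identical specs build identical
networks.  Batch normalisation is not used.

## Loss

The Focal Tversky loss is computed on the foreground channel of the softmax
output.  Per image, with soft counts TP = Σ p·g, FN = Σ (1−p)·g,
FP = Σ p·(1−g):

TI = (TP + ε) / (TP + α·FN + β·FP + ε),   FTL = (1 − TI)^γ,

with ε = 1e-6 guarding the empty-mask 0/0 case, and the batch loss the
*mean of per-image* FTL values rather than a pooled ratio — pooling would
let large lesions swamp images with small ones, the very imbalance the loss
exists to counter.  Defaults α = 0.7, β = 0.3 (false negatives — missed
lesion pixels — cost more) and γ = 4/3, the usual choices in the focal
Tversky literature; all are configurable and nothing enforces α + β = 1
(the Jaccard special case α = β = 1 itself violates it).

## Metrics

All hard-mask metrics derive from integer TP/FP/TN/FN pixel counts:
accuracy (TP+TN)/total, Dice 2TP/(2TP+FP+FN), Jaccard TP/(TP+FP+FN),
Tversky TP/(TP+α·FN+β·FP).  Threshold Jaccard is 0 when Jaccard < 0.65 and
the Jaccard value otherwise — the boundary 0.65 itself passes through.  When
prediction and ground truth are both empty the overlap ratios are 0/0; the
package scores this as 1.0 (perfect agreement), configurable per call.
Dataset aggregation is macro (mean of per-image values), overall and per
class; the failure list is exactly the ids with Jaccard below the cutoff.

## Training loop

Adam (lr 1e-3) with batch size 8 and 100 epochs by default; the source
material specifies none of these, so they are explicit config fields.
Shuffling, weight init and synthetic data all derive from config seeds, so a
run is bit-reproducible on one platform.  Model selection is by the best
*validation* Dice (selecting on a test set, as sometimes done, is leakage;
this package deliberately does not).  Checkpoints are `.npz` archives of the
named parameter arrays plus the JSON network spec.  A non-finite loss aborts
the run with the last finite epoch reported.  Flip augmentation
(vertical, horizontal, both — 4× the sample count) is materialized ahead of
training rather than sampled per epoch, keeping the effective dataset size
fixed and the run deterministic.

## Synthetic data

The generator emulates the *structure* of dermoscopy, not its photographic
appearance: a warm-toned skin field with low-frequency tone drift and fine
texture; one darker lesion whose boundary is an ellipse modulated by random
radial harmonics (amplitude = "irregularity"); optional artifact overlays —
dark curved hairs, bright bubble rings, pen-mark arcs outside the lesion,
saturated specular patches.  The mask is the exact rendered lesion support
(no label noise).  The lesion's pixel-area fraction is controlled exactly by
thresholding the radial field at the quantile matching the sampled target
fraction.  Class presets give the seven lesion classes distinguishable
morphology statistics (melanoma: high boundary irregularity; nevi: low;
actinic keratoses: low contrast; vascular lesions: red tint; dermatofibroma:
small), so per-class reporting is exercisable end to end.

What passing on synthetic data shows: the networks, loss, pipeline and
metrics are internally correct and the model has the capacity to fit
lesion-like structure.  What it does not show: performance on real
dermoscopy — real lesions have colour/texture distributions, annotation
ambiguity and artifact correlations the generator does not model, so scores
on synthetic fixtures must not be read as dataset benchmarks.

Default fixture size is 96×128: it preserves the 3:4 aspect of 384×512, is
divisible by 2^5 as the squeeze networks require, and keeps CPU tests fast.

## Numerical choices

- float32 everywhere in the network stack; metrics in float64.
- Same-padding convolutions place extra padding bottom/right; transposed
  convolutions specify their output size explicitly (no inference), so
  encoder/decoder pairings cannot drift by one pixel.
- Max-pool ties route the gradient to the first maximal element.
- Softmax is computed with max subtraction; sigmoids clip logits at ±60.
- Mask binarization threshold on 8-bit PNGs is 127; image resizing is
  bilinear, mask resizing nearest-neighbour (preserves binarity).
- Test-suite problem sizes: networks are exercised at 96×128 (and 384×512
  for the output-contract checks), the overfit check uses 4 images with a
  300-step cap and early stop at training Dice 0.96.

## Known limitations

- No GPU path; the numpy engine is single-process and im2col-based, fine
  for fixtures and small studies, not for full-scale 384×512×8000 training.
- Only 2-class segmentation; no boundary-distance metrics (e.g. Hausdorff).
- The exact stage layout of the reference networks is reconstructed from
  prose and parameter budgets, not from published code; other channel
  schedules reaching the same budgets exist.
- Bilinear/nearest resize choices for preprocessing are conventions; the
  source material does not state them.
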