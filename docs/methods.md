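# Methods

`semssl` implements a low-annotation pipeline for classifying the
constituents of SEM biofilm images — microbial cells (and clusters),
microbially-induced-corrosion (MIC) byproducts, and non-occluded metal
surface — at the level of m×m image patches. Representations are learned
from unlabeled patches with two self-supervised objectives; three binary
classifiers (binary relevance) then turn them into multi-label patch
predictions using only a small labeled subset.

## Pipeline

1. **Preprocessing.** The black metadata strip (magnification, scale bar)
   is cropped off the bottom of each frame; the strip height is a
   per-image metadata field because instruments differ. Contrast-limited
   adaptive histogram equalization (CLAHE, `skimage.exposure`) sharpens
   local structure; defaults `clip_limit=2.0` (OpenCV convention, divided
   by 100 for skimage) with an 8×8 tile grid. Frames acquired at a coarse
   scale (≥ 10 μm) **and** low magnification (< 1000×) are up-sampled 4×
   to normalize object sizes across magnifications; the default backend is
   bicubic for pixels and nearest-neighbor for the annotation (which
   provably preserves the label set), and a learned super-resolution model
   can be registered as a pluggable backend.
2. **Patchify.** A sliding window of size `kernel` with stride
   `kernel/2` by default (overlap reduces feature loss at patch borders)
   yields `(⌊(H−k)/s⌋+1)·(⌊(W−k)/s⌋+1)` patches. Per-class *object masks*
   keep source intensity where the pixel annotation equals the target
   class and are black elsewhere; they audit the labels and define them:
   a class is present in a patch when its pixel fraction reaches
   `min_fraction` (default 1%, suppressing single-pixel annotation
   noise). Classifiers consume the **original** patch; masks are not used
   past label derivation (a `masked` input mode exists for ablation).
3. **Split.** 80% of patches for representation learning, 10% for
   fine-tuning, 10% for testing. `random_patch` sampling is exact to ±1
   patch. Because overlapping windows share pixels, a patch-wise random
   split lets labeled training windows overlap test windows; the
   `spatial_block` strategy instead assigns whole source images to pools,
   which guarantees zero pixel sharing between pools at the cost of pool
   sizes only approximating the fractions (granularity = one image). An
   exhaustive patch-level split that is simultaneously leakage-free and
   exact to ±1 does not exist when stride < kernel — any cut of a
   contiguous patch order places overlapping windows on both sides.
4. **Self-supervised pretraining** (below).
5. **Binary relevance.** One binary classifier per class on the encoder's
   pooled features; independent thresholding (default 0.5) of the three
   sigmoid scores — a patch may receive any subset of labels, including
   none. Rare positives are up-weighted in the loss by the
   negative-to-positive count ratio, clamped to [1, 5]; majority-positive
   classes (surface is present in nearly every patch) are never
   down-weighted, which on small labeled pools collapses heads onto the
   minority side.
6. **Evaluation.** Accuracy = correct / total, per class; the *overall*
   figure is the arithmetic mean of the three per-class accuracies,
   computed per repeat. Repeated cross-validation (default 10 repeats,
   fresh random splits; classic k-fold selectable) reports mean ± sample
   standard deviation (ddof = 1). Class activation maps are the
   head-weighted sum of the final convolutional feature maps, upsampled
   to the patch and min-max normalized; per-image class-distribution
   heatmaps place each patch's decision (or score) on the sliding-window
   grid.

## Self-supervised objectives

Both variants share a convolutional encoder and differ in objective and
head. The desk-scale default encoder is four 3×3/stride-2
conv→BatchNorm→ReLU stages with channels (8, 16, 32, 64) and global
average pooling (64-d features); channel widths are configurable for
larger backbones.

**Contrastive (momentum contrast).** A query encoder embeds one augmented
view, a momentum encoder — an exponential moving average
`θ_m ← m·θ_m + (1−m)·θ_q` — embeds the other. With row-L2-normalized
embeddings, the InfoNCE loss

    L(q) = −log [ exp(q·k⁺/τ) / (exp(q·k⁺/τ) + Σ_{k⁻} exp(q·k⁻/τ)) ]

treats the matching key as class 0 of a softmax over the positive plus a
FIFO queue of past keys (negatives). The objective is symmetrized: each
view acts once as query and once as momentum-encoded key per step and the
two losses are averaged, doubling the learning signal per batch — which
matters at desk-scale step counts. Both key batches are enqueued. The
projector is a two-layer MLP. The queue is warmed with momentum-encoder
keys of randomly chosen patches before the first epoch, so that
first-epoch losses are measured against representative negatives rather
than random vectors.

**Non-contrastive (redundancy reduction).** Both views pass through the
same encoder and a three-linear-layer projector; the batch-normalized
embeddings z^A, z^B form the cross-correlation matrix

    C_ij = Σ_b z^A_{b,i} z^B_{b,j} / (√Σ_b (z^A_{b,i})² · √Σ_b (z^B_{b,j})²)

and the loss Σ_i (1−C_ii)² + λ·Σ_{i≠j} C_ij² drives C toward identity:
the invariance term aligns the views, the redundancy-reduction term
decorrelates embedding dimensions. The denominator is treated as a
constant normalizer in the gradient (with batch-normalized inputs it
equals the batch size), matching common practice.

**Augmentations.** Training views are random resized crops plus
horizontal flips (p = 0.5), output 56 px from 64-px patches; evaluation
uses a center crop. The crop-area range is per objective — 0.4–1.0 for
the redundancy-reduction variant (its published recipe crops far more
aggressively than the contrastive one tolerates at this scale), 0.6–1.0
for the contrastive variant and the supervised comparator.

### Hyperparameters and units

| parameter | default | notes |
|---|---|---|
| τ (temperature) | 0.2 | scales cosine similarities in InfoNCE |
| m (momentum coefficient) | 0.99 | 0.999 is customary for ~10⁵-step runs; desk-scale runs are ~10²–10³ steps, where 0.999 would leave the momentum encoder at initialization |
| queue capacity | 512 | negatives held; 4096+ is typical at datacenter scale |
| λ (redundancy weight) | 0.02 | the published 5·10⁻³ was tuned for an 8192-dim projector; with a 64-dim projector the off-diagonal term needs more weight — 0.02 measurably improves downstream accuracy (85.3% vs 81.4% overall in the reference study) |
| optimizer | SGD, momentum 0.9, weight decay 10⁻⁵ | constant learning rate |
| learning rate | 0.02 contrastive / 0.003 non-contrastive | the cross-correlation objective produces larger gradients and needs the smaller step |
| pretraining | 30 epochs, batch 64 | |
| fine-tuning | 20 epochs, head lr 0.05, encoder lr ×0.1 | the reduced encoder rate refines rather than overwrites the representation |
| decision threshold | 0.5 | on the sigmoid score |

## Training substrate

All models run on an in-repo reverse-mode automatic-differentiation
engine over NumPy (`semssl.nn`): a `Tensor` tape with broadcasting-aware
gradients, im2col convolution (matrix-multiply forward and backward, with
an explicit col2im scatter), BatchNorm2d with running statistics, linear
layers, and SGD with classical momentum. Gradients of every composite
(conv→BN→ReLU→GAP→linear→BCE, the InfoNCE path through L2
normalization, and the batch-norm→cross-correlation→loss path) are
verified against central finite differences in the test suite.

## Synthetic scenes

The generator renders annotated SEM-like frames so every stage is
testable without the restricted microscope data. What it emulates:

- dark, textured metal background (smoothed noise at two spatial scales)
  whose base level, amplitude and correlation length vary per frame, as
  they do across real acquisitions;
- mid-grey **byproduct** blobs: noise-perturbed discs with strong
  fine-grained granularity and dark speckle — corrosion products have no
  canonical shape but a distinctly granular texture. Each deposit draws
  its own grain scale, granularity strength, speckle density and grey
  level: corrosion products are heterogeneous mixtures, and this
  intra-class diversity is what makes a small labeled sample insufficient
  to cover the class — the regime self-supervised pretraining exists for;
- bright **cells**: randomly oriented ellipses (major axis 8–24 px at
  base scale, rod-like aspect 0.35–0.65) with smooth interiors and darker
  rims of per-cell depth and brightness, singly and in Poisson-scattered
  clusters;
- **colony structure**: blob and cluster centers concentrate around a few
  per-frame hotspots. This makes per-window class coverage bimodal —
  bare metal between colonies, full occlusion inside them — so presence
  labels are well conditioned rather than hinging on sub-percent coverage
  differences, and windows with no visible surface actually occur (the
  surface binary problem has both classes);
- a black bottom metadata strip with synthetic tick marks, annotated as
  surface, plus per-image magnification/scale metadata driving the
  super-resolution rule;
- additive Gaussian grey-level noise (σ = 8 by default).

The annotation records the topmost object class per pixel (cells over
byproduct over surface) and always partitions the frame. Determinism:
each layer and each object draws from a child generator keyed by
`(seed, layer, index)`, so scenes are bit-identical given (spec, seed)
and raising an object count only appends objects — class pixel counts
are monotone in the corresponding count parameter.

Texture, not absolute grey level, carries most of the class signal by
design: CLAHE (correctly) flattens local intensity histograms, so a
generator whose classes differ only in brightness yields an
unclassifiable dataset after preprocessing. What the scenes do **not**
emulate: electron-optics physics (charging, edge effects, depth of
field), extracellular polymeric substance strands, magnification-dependent
appearance changes, or annotation errors. Passing tests therefore
demonstrate that the pipeline's machinery and its relative comparisons
behave correctly, not that any particular accuracy transfers to real
micrographs.

## The reference study (`semssl.study`, `scripts/acceptance.py`)

Conditions: 12 frames of 512×512 (40 px strip), 64×64 patches at stride
32, 80/10/10 budget; both variants pretrained 30 epochs at batch 64 on
the unlabeled 80%; three binary heads fine-tuned 20 epochs on a labeled
subset amounting to ~10% of all patches; the supervised comparator — the
same architecture trained from random initialization with the same
augmentations, loss and labeled subset — evaluated on the held-out pool.
Each method is fine-tuned three times — per repeat the four held-out
images are re-assigned between labeled and test roles and a fresh ~10%
labeled subset is drawn (pretrained encoders shared) — and the reported
accuracies are means over repeats, mirroring the repeated-cross-validation
convention of this literature's accuracy tables. Labeled and test pools
are image-granular (`spatial_block`): under
patch-wise random splits the overlapping windows share pixels between
fine-tuning and test sets, and the measured comparison rewards
memorization — the supervised baseline then matches the self-supervised
pipelines, while the leakage-free protocol shows their genuine
generalization advantage. Problem sizes were chosen to keep a full run in
minutes on one CPU; accuracies at this scale sit in the 75–90% band and
are not comparable to any published full-scale figures.

## Numerical choices and degenerate inputs

- InfoNCE subtracts the per-row maximum logit (detached) before
  exponentiation; the softmax is shift-invariant so the value is exact.
- `cross_correlation` raises on a zero-variance embedding dimension
  rather than dividing by ~0.
- CLAHE output is rescaled to the full 8-bit range; a constant image maps
  to a constant image.
- A constant class-activation map (uniform feature maps) normalizes to
  all-zeros rather than 0/0.
- Sigmoid clips inputs at ±500 to avoid overflow at saturation; BCE
  floors probabilities at 10⁻¹².
- `min_fraction = 0` means "at least one pixel" for label derivation.
- Sample standard deviation (n−1) throughout; a single repeat reports 0.

## Known limitations

- The desk-scale encoder (4 conv stages, 64-d features) cannot represent
  the fine-grained distinctions a ResNet-50 would; the pipeline accepts
  wider channel configurations but has no residual blocks.
- Binary relevance ignores label correlations by construction.
- The learned super-resolution models used on real data are not bundled;
  the pluggable backend interface accepts one.
- `spatial_block` pool sizes are approximate (image granularity); with
  few images the labeled share can deviate noticeably from 10%, which the
  reference study compensates for by subsampling.
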