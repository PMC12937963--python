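# Methods

This note documents the models and procedures implemented in `wedseg`, the
parameters that matter, the numerical conventions, and the choices made
where the design was genuinely open.

## Problem setting

The task is 3-class semantic segmentation of H&E histology tiles:
background (0), nucleus (1), and nucleus edge (2). The edge class exists
because touching and overlapping nuclei are the dominant failure mode of
binary nucleus segmentation; supervising an explicit boundary class forces
the model to separate adjacent instances. Rather than requiring manual
3-class annotation, the training targets are *derived* from the images by a
classical marker-controlled watershed chain, and the network learns to
reproduce (and smooth) that chain's output.

## Watershed target generation

For each RGB tile the chain runs:

1. **Grayscale** — luma weights 0.299/0.587/0.114, rounded to uint8.
2. **Otsu binarization** — the threshold t is the *smallest* intensity
   maximizing the between-class variance of the (≤ t) / (> t) split;
   choosing the smallest argmax makes ties deterministic. Nuclei are
   hematoxylin-dark on an eosin-light background, so the default polarity
   marks (pixel ≤ t) as foreground. A constant image is a single-class
   histogram; by convention t equals the constant, so the dark-foreground
   mask is all-ones (the full chain still returns an all-background mask for
   zero-contrast tiles, which have nothing to segment).
3. **Opening** (3×3 ones, 2 iterations) removes speckle; erosion pads
   out-of-frame pixels as foreground and dilation pads as background, so an
   all-foreground mask is a fixed point.
4. **Dilation** (3 iterations) produces the region whose complement is
   *sure background*.
5. **Euclidean distance transform** of the opened mask, exact, with the
   frame treated as background (implemented by zero-padding one pixel; the
   exact EDT propagates the frame distance correctly from a single ring).
6. **Sure foreground** — pixels strictly above `fg_fraction` (default 0.7)
   of the distance-map maximum. The threshold is global, so in scenes with
   very heterogeneous nucleus sizes the smallest nuclei can fall below the
   cut and lose their seed; the synthetic training scenes therefore use
   narrow radius ranges. The fraction is configurable.
7. **Unknown band** = dilated mask minus sure foreground.
8. **Connected components** of the sure foreground (8-connectivity by
   default), relabeled into row-major first-encounter order so labels are
   reproducible across runs and implementations.
9. **Markers** — background 1, component k → k+1, unknown band 0.
10. **Watershed flooding** on an elevation surface, by default the negated
    distance transform (`gradient` of the grayscale image is available as an
    alternative; which surface the classical recipe "should" flood is an
    open choice, and the negated distance map is the variant that separates
    touching convex nuclei most reliably). Flooding is a priority queue
    ordered by (elevation, insertion counter); the initial frontier is
    pushed in row-major order and neighbors are visited up/down/left/right
    (4-neighborhood), which makes the output bit-reproducible. A pixel
    whose already-labeled neighbors carry two distinct labels becomes a
    watershed line. Pockets fully enclosed by watershed lines (possible
    only for adversarial marker layouts, not for marker maps produced by
    the chain) are also assigned the line code so no pixel stays unknown.
11. **Encoding** — background label → 0, nucleus labels (≥ 2) → 1,
    watershed lines → 2.

Every stage preserves the grid shape, and the test suite checks
`sure_foreground ⊆ opened ⊆ dilated` as set inclusions, plus exact
agreement of the flooding and the component labeling with brute-force
oracles on small random grids.

## Network

A 4-stage encoder–decoder over (N, C, H, W) arrays, H and W divisible by
2⁴. Channel plan: encoder 8 → 16 → 32 → 64, bottleneck 128, symmetric
decoder, all 3×3 convolutions same-padded with biases.

- **Encoder stage**: residual DoubleConv — conv → ReLU → dropout → conv →
  ReLU with an identity shortcut around the second convolution
  (H(x) = f(wx+b) + x; the shortcut is parameter-free and only placed where
  input and output channel counts match), then 2×2 max pooling.
- **Bottleneck**: plain DoubleConv, c₅ = σ(W₂ ∗ D(σ(W₁∗X + b₁)) + b₂); no
  shortcut — identity kernels reproduce a non-negative input exactly, which
  pins this down.
- **Decoder stage**: 2×2 stride-2 transposed convolution (with bias,
  ReLU-activated), channel concatenation with the matching encoder output,
  then conv → ReLU → dropout → conv → ReLU. Dropout rates mirror the
  encoder in reverse (0.4 … 0.1). The shortcut is confined to the encoder,
  whose blocks are the designated residual feature extractors.
- **Head**: 1×1 convolution to the class channels, per-pixel softmax.

With a 2-class head this totals exactly 485,826 trainable parameters; the
3-class head used for background/nucleus/edge adds 9 (8·3+3 − 8·2−2 =
485,835). Both counts are computed two ways — from the ordered layer
specification and from the instantiated arrays — and asserted equal.
Batch normalization can be inserted after every convolution via a flag; it
is off by default because its scale/shift terms change the parameter total.

The layers are implemented directly in NumPy with hand-derived analytic
gradients (im2col + BLAS matmuls for convolutions; the input gradient of a
same-padded stride-1 convolution is the same-padded correlation with the
flipped, axis-swapped kernel). The test suite checks backprop against
central finite differences to < 10⁻⁴ relative error on sampled parameters;
the check first moves biases off zero because zero-initialized biases
combined with dead upstream ReLU patches place conv outputs exactly at the
ReLU kink, where the loss is genuinely non-differentiable and a finite
difference measures a subgradient average instead.

Numerical conventions: inputs are scaled to [0,1] by dividing by 255 (no
mean/std standardization); weights use He initialization; the head is
zero-initialized so the untrained network outputs the uniform distribution
and the first optimization steps are not spent desaturating the softmax;
training runs in float32, verification in float64.

## Training

Loss = w_d · dice_loss + w_ce · CE (both weights default 1):

- CE = −mean over pixels of Σ_c target_c · log(pred_c + 10⁻⁷);
- dice_loss = 1 − mean over classes of (2·Σ pred·target + s) /
  (Σ pred + Σ target + s), pixel sums pooled over the batch, s = 10⁻⁶.

Both smoothing constants are pure numerical-stability choices. The
gradient is injected analytically at the logits (softmax Jacobian applied
in closed form).

Optimization is Adam (β = 0.9/0.999, lr 4·10⁻⁴) with *decoupled* weight
decay (default 10⁻⁵) applied to convolution kernels only — biases are
excluded, which the tests verify by comparing one-step trajectories with
decay on and off. After every epoch the validation loss on the held-out
partition drives reduce-on-plateau (× 0.5 after 5 non-improving epochs,
floor 10⁻⁶) and early stopping (after 10 non-improving epochs); the best
validation weights are restored at the end. "Improvement" is a strict
decrease of validation loss; both callbacks share the monitor. The 80/20
split is a seeded permutation with train size round(0.8·N) — 3000 pairs
give 2400/600, and the held-out 600 serve as the validation set (the
pipeline has no third partition).

Defaults left open by the training regime and fixed here: batch size 16,
plateau/early-stop patiences 5/10, loss weights 1:1.

## Synthetic fixtures

The generator emulates what the pipeline needs from H&E data and nothing
more: dark purple elliptical nuclei (per-nucleus ±10 color jitter, so Otsu
separation stays easy) on a pink background, i.i.d. Gaussian sensor noise
(σ = 6 by default), optional touching pairs (with probability
`overlap_fraction` a center is placed within 1.5 radii of an existing
nucleus), and a pixel-center rasterization rule that decides boundary
pixels deterministically. Per-pair seeds are `seed + index`. It does *not*
model stain physics, texture, chromatin structure, scanner characteristics,
or annotation noise — so green tests demonstrate that the pipeline and
optimizer are correct and that watershed targets are learnable, not that
the trained weights transfer to real slides.

Default scene parameters (128×128, 8 nuclei of radius 6–14) exercise the
full pipeline; the *easy* learnability scenes used in the acceptance tests
are 64×64 with 4 well-separated nuclei of radius 7–9 and σ = 4, chosen so
that (a) every nucleus survives the global distance-core threshold and
(b) a 200-pair, 70-epoch CPU run finishes in minutes. Tile size only
changes the spatial extent of the fully convolutional computation, not the
parameter count or the per-pixel task.

## Evaluation

IoU and pixel accuracy pool pixel counts across the dataset (micro); dice
is pooled per class and then macro-averaged — mirroring the three
separately reported scores. When a class is absent from both prediction
and truth, its IoU/dice is 1.0 by convention and the class is excluded
from the means, so background-only tiles contribute no spurious zeros. The
printed dice/IoU identity dice = 2·IoU/(1+IoU) is property-tested against
a confusion-matrix oracle. The post-hoc threshold T = 0.35 (strict >)
applies to the nucleus-class probability channel and yields a binary
nucleus mask alongside the argmax labeling; which channel the scalar
threshold addresses is a convention, fixed here to class 1.

## Known limitations

- The watershed chain assumes dark, roughly convex nuclei; its global
  distance threshold under-seeds scenes with strongly heterogeneous nucleus
  sizes (lower `fg_fraction` mitigates at the cost of merged seeds).
- Watershed lines are one pixel wide, so the edge class is extremely
  imbalanced; edge-class dice is the slowest metric to rise and dominates
  the macro-dice gap.
- The NumPy implementation is single-device and synchronous; it is sized
  for 64–128 px tiles and tens of thousands of gradient steps, not for
  large-scale training.
- Training is reproducible per platform (seeded shuffling, dropout, and
  initialization) but only up to floating-point reassociation across BLAS
  builds; all pre-model stages are bit-exact.
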