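# wedseg

Watershed-supervised encoder–decoder segmentation of cell nuclei in
hematoxylin & eosin (H&E) histology tiles.

Pixel-accurate nucleus annotation is the bottleneck of histology image
analysis: datasets are small, nuclei touch and overlap, and their edges are
inhomogeneous. `wedseg` implements a pipeline that addresses all three at
once, aimed at researchers who want a fully inspectable, dependency-light
(NumPy/SciPy/scikit-image) reference implementation:

1. **Paired augmentation** grows a small image–mask dataset to a target
   size (affine, flip, Gaussian noise, brightness/contrast, HSV shifts;
   geometric transforms applied jointly to image and mask, nearest-neighbor
   for labels).
2. **Classical watershed supervision** converts each image into a 3-class
   training target — 0 background, 1 nucleus, 2 edge — via Otsu
   thresholding, morphological opening, dilation (sure background),
   Euclidean distance transform (sure foreground), connected-component seed
   labeling, and marker-controlled watershed flooding. Edges appear exactly
   where flood fronts meet, i.e. where touching nuclei must be split.
3. **A lightweight residual encoder–decoder network** (485,826 parameters
   with a 2-class head; 485,835 with the 3-class head) learns the mapping
   from RGB tile to 3-class mask. Encoder stages are residual DoubleConv
   blocks, H(x) = f(wx + b) + x, with 2×2 max pooling
   Z_{i,j} = max{Y_{m,n} : m ∈ [2i, 2i+1], n ∈ [2j, 2j+1]}; the decoder
   upsamples with learnable 2×2 stride-2 transposed convolutions and skip
   concatenation; the head is a 1×1 convolution with per-pixel softmax,
   Ŷ = softmax(W_out ∗ Z + b_out).
4. **Training** minimizes dice + categorical cross-entropy with Adam
   (lr 4·10⁻⁴), decoupled weight decay on convolution kernels, dropout
   increasing 0.1–0.4 with encoder depth, reduce-on-plateau scheduling and
   early stopping on validation loss.
5. **Evaluation** reports per-class IoU_k = |Ŷ=k ∧ Y=k| / |Ŷ=k ∨ Y=k|,
   macro dice 2|Ŷ∩Y| / (|Ŷ|+|Y|), and pooled pixel accuracy, plus a
   post-hoc nucleus-probability threshold (T = 0.35, strict).

A deterministic synthetic-fixture generator (dark purple elliptical nuclei,
possibly touching, on a noisy pink background, with exact ground-truth
masks) makes the whole pipeline testable without any external dataset.

## Worked example

```python
import numpy as np
from wedseg import (SyntheticConfig, generate_dataset, make_watershed_mask,
                    NucleiSegmenter)

config = SyntheticConfig(height=64, width=64, n_nuclei=4, radius_range=(7, 9),
                         overlap_fraction=0.0, noise_sigma=4.0)
pairs = generate_dataset(config, 100, seed=7)
X = np.stack([p.image for p in pairs])                      # (100, 64, 64, 3)
y = np.stack([make_watershed_mask(p.image) for p in pairs]) # (100, 64, 64)

model = NucleiSegmenter(epochs=60, random_state=0, verbose=True)
model.fit(X, y)          # holds out 20% as the monitored validation set
print("parameters:", model.n_parameters_)
test = model.split_.test_indices
print(model.evaluate(X[test], y[test]))
```

prints per-epoch lines such as

```
epoch   1 lr 4.00e-04 train 1.7225 val 1.6914 dice 0.2774
...
epoch  49 lr 2.00e-04 train 0.3990 val 0.5225 dice 0.6673
...
epoch  60 lr 2.00e-04 train 0.3548 val 0.4606 dice 0.7194
parameters: 485835
MetricsReport(iou_per_class=(0.946, 0.852, 0.153), mean_iou=0.650,
              dice_macro=0.719, pixel_accuracy=0.929, n_images=20)
```

Reading the numbers: the training loss (dice + cross-entropy) falls from
1.72 toward 0.35; the scheduler halves the learning rate at epoch 49 after
a validation plateau. On the 20 held-out tiles the model recovers the
background (IoU 0.946) and nucleus (IoU 0.852) classes well; the one-pixel
edge class is hardest (IoU 0.153 after 60 epochs on 80 training tiles) and
keeps improving with more data and epochs — the test suite's learnability
check (200 pairs, 70 epochs, ≈7 min on one CPU) reaches validation macro
dice ≥ 0.85.

The same pipeline is scriptable from the shell:

```bash
wedseg synth --out data --n-pairs 221 --seed 0
wedseg augment --in data --out aug --target 3000 --seed 0
wedseg watershed-masks --in aug/images --out ws
wedseg train --images aug/images --masks ws --out run --seed 0
wedseg evaluate --run run --images aug/images --masks ws --threshold 0.35 --out metrics.json
wedseg summary            # per-layer parameter table
wedseg pipeline --out run_all   # everything end to end + manifest
```

## Layout

- `wedseg.synthetic` — H&E-like fixture generator with exact masks
- `wedseg.augment` — paired augmentation policy and transforms
- `wedseg.watershed` — the classical chain and `WatershedMasker` transformer
- `wedseg.nn` / `wedseg.network` — NumPy layers with analytic gradients and
  the encoder–decoder architecture with exact parameter accounting
- `wedseg.train` — loss, Adam with decoupled weight decay, callbacks
- `wedseg.estimator` — `NucleiSegmenter`, a scikit-learn-style estimator
- `wedseg.metrics` — IoU / dice / accuracy and threshold refinement
- `wedseg.io`, `wedseg.config`, `wedseg.pipeline`, `wedseg.cli` — PNG
  dataset layout, YAML run configuration, orchestration, CLI

See `docs/methods.md` for the modeling choices and their rationale.
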