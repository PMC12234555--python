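# tonguenet

Binary tongue-body segmentation for tongue-diagnosis imaging. In Traditional
Chinese Medicine workflows the tongue body must be isolated from the face,
lips and background before any colour/coating analysis; this package
implements a transformer-based encoder–decoder segmenter designed for that
task under small-sample training, together with the full evaluation
protocol (Dice/IoU/Precision/Recall with 95% confidence intervals, k-fold
splitting), the paired training-augmentation suite, and a synthetic
tongue-scene generator so that every stage runs and is testable at desk
scale with no downloads.

The whole network stack — layers, reverse-mode automatic differentiation
and the AdamW optimiser — is implemented in NumPy inside the package
(`tonguenet.autodiff`, `tonguenet.nn`), so there is no deep-learning
framework dependency.

## The model

Three parts:

* **Backbone** — a hierarchical mix-vision transformer encoder: four stages
  of overlapped patch embedding + spatial-reduction self-attention +
  mix-FFN, producing a feature pyramid at strides 4/8/16/32.
* **Neck (DiFP)** — feature-pyramid fusion (1×1 laterals, top-down 2×
  upsample + add) in which every post-merge 3×3 convolution is **dilated**
  with rates d = 1, 2, 4, 6 over the four levels and rate-matched padding
  p = d. The receptive field of a dilated kernel is

      RF = (k − 1)·d + 1,

  and the output size

      Ho = ⌊(Hi + 2p − (k−1)·d − 1)/s⌋ + 1

  equals Hi when p = d, k = 3, s = 1 — context grows at zero cost in
  resolution and parameters.
* **Head (MDi)** — each level is 1×1-projected and upsampled to stride 4
  (Z_i), then passed through m parallel dilated 3×3 convolutions, giving
  m+1 maps (the branches plus the original), fused by a 1×1 convolution:

      Z = σ(W_f ∗ concat(Z_i, Z_{i,1}, …, Z_{i,m}) + b_f).

  The fused level maps are concatenated, fused again, classified per pixel
  and bilinearly upsampled to the input resolution.

Two boolean switches (`use_difp`, `use_mdi`) generate the four ablation
variants (baseline / +MDi / +DiFP / full). Metrics are the standard
overlap scores Dice = 2|X∩Y|/(|X|+|Y|), IoU = |X∩Y|/|X∪Y|,
Precision = TP/(TP+FP), Recall = TP/(TP+FN).

## Worked example

```python
import numpy as np
from tonguenet import TongueSegmenter, generate_pairs, evaluate_pair

train = generate_pairs(60, "A", seed=0)   # standardized-capture scenes
test = generate_pairs(10, "A", seed=1)

est = TongueSegmenter(preset="tiny", epochs=4, batch_size=8, lr=1e-3, seed=0)
est.fit([p.image for p in train], [p.mask for p in train])
print("parameters:", est.n_parameters_)
print("final training loss:", round(est.history_[-1].loss, 4))

masks = est.predict([p.image for p in test])
rec = evaluate_pair(masks[0], test[0].mask, id=test[0].id)
print("first test image:", rec)
print("mean Dice:", round(est.score([p.image for p in test],
                                    [p.mask for p in test]), 4))
```

prints

```
parameters: 336370
final training loss: 0.0528
first test image: SegMetricsRecord(id='A0000', dice=0.9657364888731896,
    iou=0.9337431693989071, precision=0.9378001372055796,
    recall=0.9953883495145631)
mean Dice: 0.9658
```

i.e. a 0.34M-parameter tiny model trained for four epochs on 60 synthetic
standardized scenes already overlaps the held-out ground truth at Dice
≈ 0.97 (per-image scores are the record fields; `score` averages Dice over
the test set). `TongueSegmenter` follows the scikit-learn estimator
conventions (`get_params`/`set_params`, `fit`/`predict`/`score`, fitted
attributes with trailing underscores), so it composes with sklearn
model-selection tooling.

A command-line interface wraps the same functionality:

```sh
tonguenet synth --n 300 --domain A --seed 0 --out data/a
tonguenet train data/a/manifest.tsv --checkpoint model.npz --config cfg.yaml
tonguenet eval model.npz data/a/manifest.tsv --table scores.csv
tonguenet predict model.npz data/a/A0000.png pred.png
tonguenet crossval data/a/manifest.tsv --k 5
```

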