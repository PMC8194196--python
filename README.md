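# maskcxr

Weakly-supervised multi-label classification of thoracic disease in chest
radiographs, built around two ideas: a **multi-scale spatial attention gate**
on the input image, and **segmentation-guided feature weighting** — zeroing
backbone features outside the lung and heart, where thoracic pathology lies,
instead of fusing global and local feature branches.

The package is aimed at researchers studying weak supervision and
anatomy-constrained learning for radiograph screening. Everything runs
end-to-end on a single CPU using a built-in phantom generator that emulates
the structure of chest-radiograph datasets (images, lung/heart masks,
pipe-separated multi-label manifests, lesion bounding boxes), so no external
data download is needed.

## The model

For an image `X` with label vector `Y ∈ {0,1}^c` (all-zero = "No Finding"):

1. An attention gate `A = σ(conv_7(pool_ch[X, conv_5(X), conv_9(X)]))` of
   shape `1×H×W` multiplies the image element-wise (`pool_ch` = per-pixel
   channel max and mean of each scale branch).
2. A convolutional backbone maps the gated image to the *global attention
   map* `F_g ∈ R^{c_feat×h×w}`.
3. A U-Net trained with dice loss,
   `dice = 2|M_gt ∩ M_prob| / (|M_gt| + |M_prob|)`,
   segments left lung, right lung and heart; the merged binary mask `M_g`
   (union of the three) is adaptively average-pooled to `1×h×w` and
   re-binarised.
4. Feature weighting: `F_l = F_g ⊗ M_g` — features outside the anatomy are
   exactly zero.
5. Channel-wise average pooling and a fully connected sigmoid head give
   per-class probabilities `Ŷ`, trained with
   `BCE(Y, Ŷ) = −(1/c) Σ_i [y_i log ŷ_i + (1−y_i) log(1−ŷ_i)]`.
6. Class activation maps (head-weighted channel sums of `F_l`, rectified,
   upsampled) are thresholded at 0.2 of their maximum to produce one
   predicted lesion box per class, scored by IoU.

The neural networks are implemented in a compact numpy layer library with
manual backpropagation (`maskcxr.nn`), including an FFT path for the
large-kernel attention convolutions. See `docs/methods.md` for design
decisions and study protocols.

## Worked example

```python
import numpy as np
from maskcxr import (PhantomConfig, generate_phantom, split_phantom,
                     SegTrainConfig, train_segmenter, ClsTrainConfig,
                     train_classifier, predict_proba, evaluate_classifier)

cfg = PhantomConfig(image_size=64, n_samples=200, n_classes=4,
                    label_prior=0.5, distractor_rate=0.8, seed=0)
samples = generate_phantom(cfg)
train, val, test = split_phantom(samples, 0.85, 0.15, seed=0)

seg, _ = train_segmenter(train[:60], val[:12],
                         SegTrainConfig(epochs=8, base_width=8, depth=3, seed=0))
model, _ = train_classifier(train, val, seg,
                            ClsTrainConfig(epochs=15, lr=3e-3, seed=0))

y_true = np.stack([s.labels for s in test])
print(evaluate_classifier(y_true, predict_proba(model, test), cfg.class_names))
```

Output (4 phantom classes, 30 held-out images):

```text
           class   auroc  threshold
0   Cardiomegaly  1.0000   0.590362
1   Infiltration  0.7857   0.257883
2         Nodule  0.9152   0.502881
3  Consolidation  0.4933   0.659035
4        Average  0.7986        NaN
```

Cardiomegaly is separable from heart geometry alone, so it saturates
immediately; the harder lesion classes need far more than the 144 training
images used here (the package's reference ablation study trains on
1400-phantom datasets, where the weighted model reaches macro AUROC ≈ 0.88
and exceeds the unweighted ablation by ≈ 0.06–0.10). The `threshold` column
is the per-class ROC operating point (Youden's J). The same pipeline is
available from the shell:

```bash
maskcxr run --seed 0 --out runs/demo        # full pipeline
maskcxr generate --seed 1 --out data/ph     # just the dataset
```

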