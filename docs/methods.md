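# Methods

## Model

`maskcxr` implements a weakly-supervised framework for multi-label
classification of thoracic disease in chest radiographs. For an image `X`
with a c-dimensional binary label vector `Y` (all-zero = "No Finding"), the
pipeline is

1. **Multi-scale attention gate.** Three image-like branches — the image
   itself plus one learned 3→3 convolution per scale kernel (defaults 5 and
   9) — are each reduced to their per-pixel channel maximum and mean. The six
   pooled planes are fused by a single 6→1 convolution (kernel 7) and passed
   through a sigmoid, giving a gate `A ∈ (0,1)^{1×H×W}` that multiplies the
   image element-wise before the backbone. All attention convolutions use
   stride 1 with zero same-padding: the gate must match the image resolution
   exactly for the element-wise product, which rules out strided variants.
   Whether the three branches should be pooled then jointly fused (done here,
   mirroring the spatial-attention block this design improves upon) or fused
   per branch and summed is a genuinely open design point; joint fusion lets
   the gate weigh scales against each other per pixel.
2. **Backbone.** The gated image feeds a convolutional backbone whose last
   feature map is the *global attention map* `F_g ∈ R^{c_feat×h×w}`. Two
   backbones are provided: a 121-layer densely connected network
   (`c_feat = 1024`, spatial reduction 32; randomly initialised — no
   pretrained weights ship with the package) and a tiny 3-stage strided CNN
   (3→24→48→32 channels, reduction 8, receptive field 15 px) used for all
   desk-scale training. The tiny backbone makes the mask-invariance
   properties directly testable because its receptive field is known.
   The tiny backbone and the attention convolutions use **reflect padding**:
   zero borders would give edge receptive fields an absolute-position
   signature, letting a globally pooled classifier infer "inside the chest"
   from border artefacts. With reflection the classifier is
   translation-invariant and anatomical position enters the model only
   through the explicit segmentation mask — which is the framework's whole
   premise. (The U-Net keeps zero padding: a segmenter legitimately uses
   absolute position.)
3. **Segmentation and feature weighting.** A U-Net trained with soft dice
   loss predicts left-lung, right-lung and heart foreground probabilities;
   thresholding at 0.5 and taking the pixel-wise union gives the merged
   anatomy mask `M_g`. `M_g` is resized to the feature grid by adaptive
   average pooling and re-binarised with a `> 0` rule (any anatomy overlap
   keeps the cell — chosen so small structures such as nodule-bearing cells
   survive; the threshold is configurable). The *local attention map* is
   `F_l = F_g ⊗ M` — element-wise multiplication, so features outside the
   anatomy are exactly zero.
4. **Head.** Channel-wise spatial average pooling of `F_l`, a fully
   connected layer, and a per-class sigmoid give independent disease
   probabilities `Ŷ`. Training minimises the per-class-averaged binary
   cross-entropy `BCE(Y, Ŷ) = -(1/c) Σ_i [y_i log ŷ_i + (1-y_i) log(1-ŷ_i)]`.
5. **Weak localization.** A class activation map for class k is the
   `F`-channel sum weighted by the head's k-th weight row, rectified at zero
   and bilinearly upsampled to image size. Binarising at 0.2 of the map's
   maximum and taking the largest 4-connected component yields one predicted
   box per image and class, scored by IoU against ground-truth boxes.

### Resolved ambiguities

* The local map is produced by **multiplication** (`⊗`, "logical AND",
  zeroing), not by the element-wise *summation* mentioned once in passing in
  descriptions of such frameworks: summation would not zero non-anatomy
  features, contradicting the zeroing contract.
* The dice expression is the dice *coefficient*; the training objective is
  `1 − dice` (minimising the coefficient itself would drive overlap to
  zero). Multi-structure training uses the unweighted mean over the three
  structures.
* Spatial average pooling divides by the full `h·w`. A masked-mean variant
  (divide by the count of kept cells) is available behind the
  `masked_mean` config flag for study, but is off by default since the
  head is described as a plain average-pooling layer.
* Operating thresholds per class are chosen by maximising Youden's J
  (tpr − fpr) on the ROC curve, ties broken toward higher specificity; the
  source material only says thresholds come "according to the ROC curve".
* When an image carries several ground-truth boxes of one class, the best
  (maximum) IoU counts; one predicted box is emitted per image/class.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| `attention.scale_kernels` | (5, 9) | odd; branch convolutions are 3→3 with bias |
| `attention.fusion_kernel` | 7 | 6→1 fusion convolution |
| dice smoothing `ε` | 1.0 | added to numerator and denominator; defines dice = 1 on two empty masks |
| mask binarisation | 0.5 (pixel), > 0 (feature grid) | both configurable |
| CAM threshold | 0.2 × max | relative, so extraction is scale-invariant |
| U-Net | depth 4, base width 64 | desk tests use depth 3, width 8 |
| optimiser | Adam, lr 1e-3, weight decay 1e-4 | classifier defaults; desk studies use lr 3e-3, batch 32 |
| BCE clip | 1e-7 | probabilities clipped away from {0,1} before logs |

## Phantom generator

Real chest radiographs and their annotations are large external resources;
the package instead generates *phantoms* that preserve exactly the structure
the method relies on:

* **anatomy** — two vertically elongated lung ellipses and a heart ellipse
  at canonical frontal-view positions with ±10 % jitter, distinct mean
  intensities, additive Gaussian noise;
* **pathology confined to anatomy** — each class maps to a lesion family
  (bright disc, diffuse haze, bright wedge, enlarged-and-brightened heart)
  rendered ≥ 80 % inside the merged mask, with tight boxes recorded and
  `labels[k] = 1` iff a class-k lesion was inserted. The three lung families
  occupy distinct size scales and non-overlapping additive-intensity bands
  (haze < wedge < disc), so phantom classes are separable by construction;
* **out-of-anatomy structure**, the reason feature weighting has something
  to suppress. Two kinds are rendered, both with zero pixel overlap with the
  merged mask. First, dark lung-intensity *air pockets* (bowel gas or
  axillary air analogues) host *distractor* lesions drawn from the same
  shape families as true lesions, so a distractor is locally
  indistinguishable from pathology and only anatomical position separates
  them. Second, *clutter* — 8–14 random ellipses and bars whose intensities
  span the lesion bands (shoulders, bowel, implants, film markers) — gives
  every image label-independent activity in the same feature channels a
  lesion excites. A classifier pooling over the whole image accumulates this
  activity; the mask-weighted classifier never sees it. This mirrors the
  premise that pathology cues drown in global features because of normal
  regions, and it is what makes the weighting ablation informative.

Rendering quantises to 8-bit before the float conversion, and all
randomness flows from per-sample generators derived from (seed, index), so
identical configs are byte-identical.

Default study conditions: per-class label prior 0.5 and distractor rate 0.8
in the ablation (one distractor per image with probability 0.8), noise sd
0.03 of full scale. The validation split is the fraction `val_frac` *of the
train split* (the usual 10 %-of-train rule); with 100 samples and fractions
0.9/0.1 the split is 81/9/10 (`n_test = round(n·(1−train_frac))`, then
`n_val = round(n_train·val_frac)`). Stratification uses the label
combination, falling back to an unstratified split with a warning when
groups are too small.

What phantoms do **not** model: rib/clavicle structure, projection physics,
intensity calibration differences, label noise, patient-level correlation
(so "no patient overlap" reduces to no image-id overlap). Passing the
phantom studies shows the pipeline's mechanics work — mask weighting
suppresses out-of-anatomy signal, CAM finds in-anatomy lesions — not that
benchmark-scale radiograph performance is reproduced.

## Desk-scale studies

Sized for a single CPU; all seeded and reported as the median over 3 seeds.

* **Segmentation**: 3 datasets of 50 phantoms at 64×64; tiny U-Net (depth 3,
  width 8), dice loss, Adam lr 5e-3, batch 4, 16 epochs, best epoch by
  validation dice loss; held-out mean dice over the three structures.
* **Feature-weighting ablation**: 1400 phantoms at 64×64, 4 classes, label
  prior 0.5, distractor rate 0.8; frozen segmenter trained on a subset of
  the training phantoms; weighted and unweighted classifiers share data,
  seeds, attention and hyperparameters (tiny backbone, Adam lr 3e-3, batch
  32, 15 epochs, best epoch by validation macro AUROC); held-out macro
  AUROC. Batch 32 keeps the batch-norm statistics stable; the attention
  fusion bias starts at +2 so the gate opens near pass-through.
* **Localization**: CAM → box on the trained weighted model's held-out
  split, per-class mean IoU vs. a fixed central box covering 25 % of the
  image. The central box is a *blind* baseline for focal lung lesions; for
  cardiomegaly it is nearly an oracle (the heart is a central organ), so the
  heart class is compared in the overall mean only.

## Numerical notes

* The neural-network core is a small numpy layer library (im2col
  convolutions, batch normalisation, pooling, manual backprop, Adam). Every
  layer's backward pass is verified against central-difference gradients.
* Stride-1 convolutions with kernels ≥ 5 (the attention-scale kernels) run
  through an FFT path (convolution theorem via `rfft2`), exact to float
  round-off and several times faster than im2col at these sizes; gradients
  for both weights and inputs use the same transform.
* Parameters are float32; reductions and the dice/BCE arithmetic are
  float64. All computation is deterministic on a given platform; datasets
  are additionally byte-identical across platforms because rendering is
  quantised before the float conversion.
* Bilinear upsampling (CAM heatmaps and mask-support checks) uses the same
  interpolation for both, so "CAM is zero outside the upsampled mask
  support" holds exactly, not approximately.

## Known limitations

* The dense 121-layer backbone is provided architecture-faithful but
  randomly initialised; desk-scale training uses the tiny backbone. Nothing
  here reproduces benchmark-scale AUROCs — the bundled published per-class
  tables exist to pin the aggregation arithmetic, not to be re-derived.
* The unweighted ablation's AUROC on phantoms varies noticeably across
  seeds (the global model sometimes partially compensates for distractors);
  the ablation is therefore reported as a median over seeds.
* CAM boxes are single-component; multi-lesion images are scored by the
  best-matching ground-truth box only.
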