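# Methods

## Problem

Diabetic retinopathy (DR) produces four pixel-annotatable lesion types in
color fundus photographs: microaneurysms (MA, small circular dark-red
dots), hemorrhages (HE, larger irregular dark-red blobs), hard exudates
(bright yellow, sharp-edged) and soft exudates (cotton-wool spots: pale,
fuzzy-edged). `funduseg` segments all four classes with a single
convolutional network and scores the result with a component-overlap
metric suited to small lesions.

## Size normalization

Fundus images arrive at arbitrary sizes with black frames. Normalization
(1) crops the tightest box whose maximum channel intensity exceeds a
threshold (default 10/255; the black frame of real fundus images is not
exactly zero), (2) pads the short side with black to a square, split
evenly with the odd pixel to bottom/right, and (3) resizes to
1024 x 1024. A further resize to 512 x 512 produces the network input.
Images are resampled bilinearly; masks use nearest-neighbor and are
re-binarized, which prevents label bleeding at lesion boundaries. Every
step is stored in a `PreprocessRecord` (JSON-serializable) so predicted
masks can be mapped back to original coordinates; the round trip loses
only resampling detail (IoU >= 0.95 for blobs of >= 5 px radius).
Normalization is idempotent up to resampling tolerance.

## Augmentation

Training sets are expanded up to fivefold. Each synthetic sample applies
a random *subset* of: horizontal flip, vertical flip, per-axis scaling,
translation, rotation — never deterministically all of them. Magnitudes
default to scale in [0.9, 1.1] per axis, translation in +-10% of the
image side, rotation in +-15 degrees; these are deliberately
conservative (lesions must stay inside the field of view) and are
exposed in `AugmentConfig`. Identical parameters are applied to image
(bilinear) and masks (nearest), out-of-bounds regions are filled with
black, and the expansion is deterministic per seed with originals always
included.

## Network

The segmentation network is an encoder/dual-attention/decoder design:

* **Encoder.** A 3x3 conv-BN-ReLU stem, then a *single* 2x2 max-pool
  (Map1). All further downsampling uses stride-2 residual bottleneck
  blocks — repeated pooling discards exactly the few-pixel structures
  (MAs) the task cares about. Each stage holds one stride-2 conv block
  (projection shortcut: conv-BN) and one identity block (identity
  shortcut); both run two 3x3 conv-BN-ReLU stages at an internal width of
  `out_channels / bottleneck_ratio` (default ratio 4) before a 3x3
  expansion, all kernels 3x3. Channels double per stage from
  `base_channels` (default 64): Map1..Map4 at 1/2, 1/4, 1/8, 1/16
  resolution.
* **Dual attention.** The two deepest maps (stages 3 and 4) pass through
  position attention (softmax-normalized N x N affinity over spatial
  positions, N = H'W') and channel attention (C x C affinity between
  flattened feature maps) in parallel; each adds its re-weighted features
  through a learnable scale initialised to zero, and the two branch
  outputs are summed, so the whole module starts as `2x` the input and
  learns how much context to mix in. Config validation rejects attention
  on maps larger than 64 x 64 because the spatial affinity grows as N^2.
* **Dilated block.** Three sequential 3x3 dilated convs at rates
  (1, 2, 5) at the deepest level — pairwise-coprime-ish rates avoid the
  gridding artifact and give a 17 x 17 stacked receptive field
  (r_out = r_in + 2d per layer) without further downsampling.
* **Decoder.** U-net-style: bilinear 2x upsample + 3x3 conv (chosen over
  transposed convolution to avoid checkerboard artifacts), concatenation
  with the same-level encoder map, channel dropout (default rate 0.5)
  after each concatenation, and a fusing conv-BN-ReLU. The head is a 3x3
  conv to 4 channels with a per-pixel sigmoid: one multi-label network
  rather than four binary ones, since lesion classes can legitimately
  co-occur and even overlap.

Open design points resolved here: the second encoder map is built by the
same conv-block/identity-block stage pattern as the deeper ones, and
attention is applied before the dilated block at the deepest stage.

### The tensor backend

The package ships its own compact reverse-mode autodiff engine and layer
library on numpy (`funduseg.nn`): conv via nine per-tap BLAS products,
batch-norm with train/eval statistics, a single 2x2 max-pool, separable
bilinear upsampling with an exact adjoint, channel dropout, and Adam.
Gradients of every layer and of the composed network are verified against
central finite differences in the test suite. The engine is sized for the
CPU-scale problems this package targets; it is not a general deep-learning
framework.

## Training protocol

Batch size 2, Adam at learning rate 1e-4, dropout 0.5, and the loss
`BCE + (1 - Dice)` with equal weights (the Dice term is epsilon-smoothed
so empty masks are defined, and averaged over classes). The monitored
indicator is the training loss; any decrease counts as improvement (no
minimum delta). After 5 epochs without improvement the learning rate is
multiplied by 0.1; after 15 epochs without improvement training stops and
the best-loss weights are restored. Both rules are pure state machines
over the loss sequence and are tested as such. Datasets are split
train:test = 2:1 at the image level (|train| = round(2n/3)), disjoint and
deterministic per seed; `max_epochs` defaults to 300, with early stopping
expected to end training first. An optional validation fraction exists
but defaults to 0 (the protocol monitors training loss).

The overfit capacity test (4 synthetic 128 x 128 images, base 16
channels) disables dropout and uses learning rate 2e-3 with relaxed
patience, as is conventional when checking that an architecture can
memorise a tiny dataset; with the production schedule the plateau rule
stops training before full memorisation, which is its job.

## Evaluation

Pixel-exact confusion counts underestimate performance on small
components, so scoring uses component-level overlap. With detected
components D_1..D_N (union D) and true components G_1..G_M (union G) and
threshold sigma (default 0.2, strict inequality):

* TP: D∩G, plus all of any D_i with |D_i∩G|/|D_i| > sigma, plus all of
  any G_j with |G_j∩D|/|G_j| > sigma;
* FP: D_i disjoint from G, plus D_i\G at ratio <= sigma;
* FN: G_j disjoint from D, plus G_j\D at ratio <= sigma;
* TN: the rest.

At sigma = 0 this degenerates to touch-matching (any detection touching
truth is fully credited). A pixel satisfying a TP rule is TP regardless
of other rules; in practice the rule sets are disjoint, and the
implementation is verified against a literal set-based oracle (with an
independent BFS flood fill) on hundreds of random mask pairs at
sigma in {0, 0.2, 0.5, 1}. Components use 8-connectivity by default
(configurable, recorded in reports). From the counts: sensitivity,
specificity, precision, accuracy and F1; zero denominators return 0 and
are flagged. ROC/AUC and precision-recall/AUPR are computed on raw pixel
probabilities pooled over the test set (micro-average); the curves come
from scikit-learn with trapezoidal areas. Lesion counting is
per-class connected-component counting on the binarized predictions.

## Synthetic data

The generator renders a bright circular field of view (radius 0.48 of
the short side) on a black frame, a reddish-orange background with
low-frequency shading, dark curvilinear vessel-like strokes (so the
HE-versus-vessel confusion mode exists in training data), and the four
lesion classes with their clinical morphology. Per-class pixel budgets
default to the composition of public DR segmentation data — MA 0.10%,
HE 1.03%, hard exudate 0.90%, soft exudate 0.38% of image area — divided
over a drawn lesion count (MA 3-8, HE 2-5, hard 2-6, soft 1-3).
Placement is rejection-sampled: lesions stay inside the field of view
and, by default, are dilated-disjoint across and within classes, so mask
component counts equal the number of lesions placed. Soft exudates are
Gaussian-feathered in the *image only*; the mask keeps the sharp
pre-blur support, as annotators outline cotton-wool spots. Everything is
deterministic per seed.

What the generator does **not** emulate: optic disc and macula, vessel
branching topology, camera vignetting and color variation between
devices, compression artifacts, and the extreme class imbalance and
ambiguity of real annotations. Tests passing on synthetic data therefore
demonstrate that the pipeline's mechanics and contracts are correct, not
that the network reaches clinical performance; the latter requires
training on real datasets at full resolution on a GPU.

## Problem sizes in the shipped checks

The test suite and the reproduction script run entirely on CPU: the
metric oracle uses 200 random 48 x 48 mask pairs; the capacity check
memorises 4 images at 128 x 128 with base 16 channels; the end-to-end
demo trains on 8 synthetic 64 x 64 images (base 8 channels, 30 epochs),
a deliberately small configuration chosen so a complete run stays in the
minutes range while exercising every stage.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full 512 x 512
  training at base 64 channels is possible but slow — the package is a
  faithful, testable implementation of the method, not a production
  trainer.
* Spatial attention memory grows as (H'W')^2; config validation caps it
  at 64 x 64 maps.
* Per-stage channel counts and augmentation magnitudes are package
  defaults where the method description leaves them open; they are all
  exposed in configs.
* ROC/PR are pixel-level; a component-level curve variant is not
  implemented.
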