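# Methods

## Problem setting

A quadrat (a square red frame with a 50 cm inner opening) is placed in a
rice field and photographed from above, so every image covers the same
ground area.  The task is to count the grain-bearing ears (panicles) in
each image.  Ears are dense, elongated, mutually occluding, and shot under
variable illumination, which makes bounding-box annotation expensive and
box-based detection unreliable.  The package therefore uses *point
supervision*: each ear is annotated by a single pixel, and the model is a
fully-convolutional segmentation network trained with a
localization-counting (LC) loss.  At inference the network's per-pixel
softmax is thresholded by argmax into a binary ear mask, and the number of
connected foreground components ("blobs") is the predicted count — one
blob per ear.

## The localization-counting loss

Let `S` be the per-pixel two-class softmax output (channel 0 background,
channel 1 ear) and `T` the set of annotated pixels.  The loss is the sum of
four non-negative terms:

* **Image-level** `L_I`: with `C_e` the set of classes present (background
  always; ear iff `T` is non-empty) and `C_¬e` the absent classes,
  `L_I = −(1/|C_e|) Σ_{c∈C_e} log max_i S_ic − (1/|C_¬e|) Σ_{c∈C_¬e} log(1 − max_i S_ic)`.
  Somewhere in the image each present class must be predicted confidently;
  absent classes nowhere.
* **Point-level** `L_P = −Σ_{i∈T} log S_{i,ear}` — every annotated pixel
  must be classified as ear; unlabeled pixels are ignored by this term.
* **Split** `L_S = Σ_{i∈E} α_i (−log S_{i,bg})`, where `E` is the set of
  watershed ridge pixels inside blobs that contain ≥ 2 annotation points
  and `α_i` is the number of points in pixel *i*'s blob.  A blob straddling
  several ears is carved apart by pushing its internal ridges to
  background.  An alternative formulation (the mean ear-side probability
  over `E`) is available behind `printed_variant`.
* **False-positive** `L_F = −Σ_{i∈B_fp} log S_{i,bg}` over all pixels of
  blobs containing no annotation point.

A perfect prediction — exactly one confident blob per point and confident
background elsewhere — has zero loss, and each term's gradient with respect
to `S` is analytic once the combinatorial structure (blob labels, ridge
set, per-class argmax pixels) is frozen at its current value; that is how
the training gradient is computed, with log arguments clamped at 1e-12.
By default the split and false-positive terms are unnormalized sums; a
`normalize` switch divides each by its pixel-set size.

### The geodesic-midline watershed

Standard priority-flood watershed lines depend on queue tie-breaking,
which makes them irreproducible by an independent implementation.  The
split term instead uses a deterministic variant.  Within a multi-point
blob, the cost of entering a pixel is `1 + λ(1 − S_ear)` (λ =
`topography_weight`, default 1), path cost is the sum over an 8-connected
path, and every pixel joins the *basin* of its cheapest seed (ties to the
lowest seed index).  Wherever two basins touch, the pixel of the touching
pair whose best/second-best cost margin is smaller joins the ridge set
(both on an exact tie); seed pixels never do.  This rule is
order-independent, reduces to the equidistant midline on uniform maps,
yields a generically one-pixel-wide ridge, and separates every pair of
adjacent basins by construction (for any cross-basin adjacency, one pixel
of the pair has the minimal margin).

Blob connectivity is 8-connected by default (configurable to 4).  Note
that under 8-connectivity a one-pixel ridge does not disconnect a blob at
inference — counting overlapping ears separately relies on the trained
network shrinking its blobs around the points, which the split and
false-positive terms jointly encourage.

## Network and training

Three backbones share the contract image → same-size two-channel logits:

* `tiny` — 4 conv layers (16/32/32 channels, one stride-2 stage, bilinear
  ×2 decoder, 1×1 head), ≈14k parameters.  This is the desk-scale model all
  training tests use.
* `vgg16-fcn` — the 13-conv VGG-16 trunk, 1×1 score head, bilinear ×32.
* `resnet50-fcn` — the ResNet-50 bottleneck trunk with batch norm, same
  FCN head.

All layers (convolution via im2col, batch norm, ReLU, max pooling,
bilinear upsampling, residual blocks) are implemented on float32 numpy
arrays with hand-derived backward passes, verified against scipy
correlation oracles and finite differences.  Initialization is seeded He;
two builds with the same seed are bit-identical.

Training follows the published recipe as defaults: SGD, batch size 1,
momentum 0.9, weight decay 5e-4, learning rate 1e-5, 180 epochs, fixed
rate.  That learning rate presumes a pretrained deep trunk; from-scratch
runs on the tiny model use 1e-4.  Two numerical safeguards were needed for
stable from-scratch training: global gradient-norm clipping
(`max_grad_norm`, 20 in the tests — the point-level gradient `1/S` at a
badly mispredicted annotated pixel is otherwise unbounded and can fling
the model into an all-background local minimum), and an Adam optimizer as
an alternative (`optimizer="adam"`).  Inputs are normalized by per-channel
mean/sd computed on the training set.  Images whose sides are not
divisible by the backbone stride are edge-padded on the bottom/right and
the logits cropped back.  Probability ties (exactly 0.5) at inference go
to background.  An optional minimum-blob-size filter exists but defaults
to off.

`LCFCNCounter` packages all of this as a scikit-learn estimator
(`fit(images, point_lists)` / `predict → counts` / `score = −MAE`), so it
composes with sklearn model selection.

## Synthetic field scenes

The real quadrat dataset is not publicly deposited, so the generator
emulates its structure with exact ground truth: a green canopy background
textured with broad leaf strokes; ears as elongated ellipses (defaults at
96×96: length 10–18 px, width 3–5 px, random orientation) with speckled
grain texture, brighter and yellower than the canopy; 5–25 ears per image
by default (configurable law: fixed, uniform, or Poisson); an
`overlap_fraction` (default 0.3) controlling how often an ear is placed
touching another, with disjoint placements otherwise kept at least one
pixel apart; a per-image illumination multiplier (0.75–1.25); additive
Gaussian noise (sd 8 on the 8-bit scale); an optional red frame whose
inner-edge corner coordinates the renderer reports as ground truth; and
one annotation point per ear at the ellipse centre jittered by ≤ 20 % of
the minor axis.  Three presets mirror the acquisition-quality tiers:
A (clear: noise 4), B (noisy: noise 18, light 0.7–1.3), C (red-shifted
cast).  Per-image seeds are spawned from a master seed; rendering is
bit-deterministic.

What the generator does **not** model: perspective foreshortening, 3-D
canopy geometry, specular highlights, motion blur, growth-stage variation,
and real panicle morphology.  Tests passing on these scenes therefore
demonstrate that the implementation is correct and that the method behaves
as designed under controlled density/light/noise — not that the specific
accuracy numbers transfer to real field imagery.

## Preprocessing

Frame detection follows the ray-casting construction: from points offset
around the image centre, rays march outward in the four cardinal
directions until they meet red (HSV hue within 0.06 of 0°/360°, saturation
≥ 0.35, value ≥ 0.2), a hit being confirmed only when most of a short run
behind it is also red (this rejects isolated reddish canopy pixels).  A
least-squares line through each side's hits (a fan of five rays per side
spanning ±20 % of the extent; two rays as in the original construction are
geometrically sufficient but amplify rasterization jitter when
extrapolating to the corners) intersects into four sub-pixel corners,
validated for convexity.  On 50 synthetic frames (axis-aligned and rotated
up to ±15°) recovered corners stay within 2 px of the renderer's truth.
Rectification maps the corner quadrilateral to a full output raster by
projective warp; annotation points ride the same homography.

Resizing scales points with the raster and deduplicates rounding
collisions with a warning.  Augmentation is a horizontal flip (an
involution) and a 90° counter-clockwise rotation — both exact raster
bijections, so per-image counts are preserved; `{flip}` doubles a dataset
and `{flip, rotation}` triples it (1100 → 2200 → 3300).  The rotation
angle is a design choice: 90° keeps annotation transport exact.

## Classical baseline

The seven-step traditional counter: HSI intensity `I = (R+G+B)/3`; Otsu
(or fixed) binarization; two area-filter passes against dirt/noise;
erosion-then-dilation with a disk to suppress thin ears and isolate broad
leaves; XOR of the denoised mask with that leaf image to recover the ears
(intersected with the denoised mask so an over-dilated leaf rim cannot
resurrect); a final minimum-area pass; connected-component count.  The
erosion radius must exceed the ear half-width and stay below the leaf
half-width.  On clean scenes with thin ears the pipeline is exact; under
the noisy variable-light preset its fixed thresholds fragment and it
degrades sharply, while the trained counter holds up — the qualitative
ordering that motivates the learned method.  The comparison suite in the
tests (25 images, counts 3–10, thin ears, noise 18, light 0.7–1.3) is
chosen to probe exactly that regime; under clean conditions both methods
saturate and the comparison is uninformative.

## Evaluation metrics

MAE, RMSE, nRMSE = 100·RMSE/(y_max − y_min) using the evaluated set's true
counts, and Acc_rate = 100·mean(1 − |h−y|/y).  The accuracy is implemented
as a mean (the printed running-sum form cannot yield a percentage);
images with y = 0 are excluded from the accuracy mean and counted in the
report; a degenerate true-count range makes nRMSE NaN rather than failing
the report.  `MAE ≤ RMSE` always holds, and
`nRMSE · range / 100` reproduces RMSE to 1e-9 by construction.

## Problem sizes in the test suite

The parameter-recovery study trains the tiny backbone on 80 synthetic
64×64 scenes (counts uniform 3–12, no overlap) for 100 epochs and
evaluates 20 held-out scenes; it reaches held-out MAE well under 1.5 and
beats the constant-mean-count predictor by an order of magnitude.  The
augmentation check uses an 1100-image 96×96 stand-in.  The
baseline-vs-learned comparison trains on 40 noisy 96×96 scenes for 60
epochs.  These sizes keep a full run of suite plus acceptance script to a
few CPU-minutes while leaving every qualitative conclusion intact.

## Known limitations

* The deep backbones are forward-verified but not exercised by training
  tests; from-scratch ResNet-50 on CPU is out of scope, and pretrained
  weights are only an optional local-file hook.
* The counter resolves overlapping ears only as far as blob shrinkage
  separates them; heavily fused clumps still merge (see the connectivity
  note above).
* Synthetic-scene realism is deliberately bounded; see above for what the
  generator omits.
* The accuracy metric is undefined for images with zero true ears and is
  reported over the remaining images only.
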