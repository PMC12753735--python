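# Methods

This note documents the models and procedures smearkit implements, the
parameters that matter, the synthetic data the tests run on, and the
numerical and design choices made where the design was genuinely open.

## Pipeline model

The package implements a segmentation-first analysis of stained
peripheral blood smears.  The working assumption is that classifying a
blood cell is much easier once it has been isolated: a binary
foreground mask removes background and debris, an instance-separation
step splits touching cells, and the classifier then sees one
background-zeroed cell per input.  The stages are independent library
modules; the pipeline orchestration and CLI are thin layers over them.

### Preprocessing

* **Resize** — separable bilinear interpolation with half-pixel-centred
  source coordinates (each output sample is the convex combination
  `(1-a)·I[x1] + a·I[x2]` along each axis).  The half-pixel convention
  was chosen because it is symmetric and standard; the worked example in
  the test suite (`[0, 255] → [0, 127.5, 255]`) is derived under it.
  Convexity guarantees the output never leaves the input intensity
  range.
* **Rescaling** — division by 255, with the array dtype acting as the
  scale flag (integer = byte scale, float = unit scale).  A float input
  already inside [0, 1] is rejected rather than silently divided again.
* **CLAHE** — contrast-limited adaptive histogram equalization via
  scikit-image.  `clip_limit` uses the OpenCV-style scale (default 2.0,
  mapped internally as `clip/256`), tile grid 8×8.  Neither value is
  prescribed by the method; they are the widely used defaults and are
  exposed in config.  CLAHE is applied to the luma channel of a YCbCr
  decomposition by default (per-RGB-channel mode available) to avoid
  hue shifts.  A zero-dynamic-range image is returned unchanged — there
  is no contrast to redistribute — which also makes the operator
  idempotent on constants.
* **Augmentation** — seven operators sampled uniformly from closed
  ranges: rotation [−20°, 20°], width/height shift [−0.05, 0.05] of the
  frame, shear [0, 0.05], zoom factors 1 + [0, 0.05] per axis,
  horizontal flip with probability ½, and clamp-to-edge
  nearest-neighbour fill.  They are composed as one affine matrix about
  the image centre in the order rotation → shear → zoom → shift, flip
  last; the source material lists the operators without an order, so an
  order had to be fixed and documented.  A vertical flip exists behind a
  config flag, default off, since it is not part of the core operator
  set.  Augmentation is applied to training folds only.

### U-Net segmentation

Standard encoder–decoder with skip connections: four blocks of two 3×3
same-padded ReLU convolutions and 2×2 max pooling (filters
64→128→256→512), a 1024-filter bottleneck, a mirrored decoder with 2×
nearest-neighbour upsampling and channel concatenation, and a 1×1
sigmoid head.  Same padding and parameter-free upsampling are forced by
the reference layer table (constant spatial dims within a block; zero
parameters in upsampling rows).  The declarative `ModelSpec` reproduces
that table row for row from closed-form arithmetic
(`kh·kw·c_in·c_out + c_out` per convolution) and is audited against the
actual weight array sizes.

Training policy: He-normal initialisation, Adam (lr 10⁻³, β₁ 0.9,
β₂ 0.999, ε 10⁻⁷), binary cross-entropy, batch 16, early stopping on
validation loss (patience 10, best-weight restore), ReduceLROnPlateau
(factor 0.5, patience 5, floor 10⁻⁵), L2 kernel penalty 10⁻⁴
(implemented as the `2·λ·W` gradient term, matching a `λ·Σw²` penalty).
Validation loss is the monitored quantity for both callbacks; the
monitor is not named upstream, so this choice is recorded here.  Two
rejected ablations — a Dice term in the loss and GELU activations —
remain available behind config flags, default off.

The networks run on a NumPy training stack written for this package:
im2col convolutions (`sliding_window_view` + BLAS `tensordot`),
transposed-convolution input gradients, pooling with argmax routing,
inverted dropout, and the Adam/callback machinery above.  Gradients are
verified against central finite differences in the test suite.

### Marker-controlled watershed

The probability map is thresholded at τ = 0.5 and cleaned by one 3×3
opening and closing (iteration count 1 by default, the stated range is
1–2), with a single hole-filling pass.  The distance transform is the
exact Euclidean transform (`scipy.ndimage.distance_transform_edt`); the
mask-size-5 chamfer variant named upstream is an approximation to it and
the exact transform is used since OpenCV is not a dependency.

Markers: distance peaks with a 7×7 minimum-separation footprint
(dense-overlap preset: 9×9), kept where the distance exceeds
`dt_threshold_frac` of the distance maximum (default 0.325, the
midpoint of the stated 0.30–0.35 band; dense preset 0.25).  Two
implementation choices matter and are deliberate:

* **Per-component normalization.**  "Fraction of the maximum" is
  normalized per connected component of the mask, not globally —
  otherwise a platelet (radius ~4 px) next to a monocyte (radius
  ~15 px) would never pass the threshold and its region would be lost.
  Global normalization is available via `per_component_norm=False`.
* **Peak-detection smoothing.**  The rasterized distance transform of a
  disc union carries spurious ridge maxima that survive the 7×7
  footprint and over-segment cells.  Peaks are therefore detected on a
  lightly smoothed copy (Gaussian σ = 1 px, `peak_smooth_sigma`); the
  flooding itself uses the raw map.  On 200 constructed overlapping
  disc pairs this step raises the correct two-way split rate from
  ~90% to ~97%.

Sure background is the complement of the mask dilated 3 iterations; the
zone between markers and sure background is the unknown region.  Seeds
are labelled by 8-connectivity and grown two dilation steps inside the
thresholded zone so markers are small regions rather than single
pixels.  Flooding is scikit-image's compact watershed (compactness
0.001) on the negated distance map, confined to the mask; a
plain-Python Dijkstra priority flood in the test suite reproduces its
label partition exactly on small grids (ties are settled by queue entry
age in both).  The tie-break "by gradient magnitude" mentioned upstream
is not implemented; entry-age tie-breaking is what the flooding
algorithm defines, and the oracle equivalence pins the exact behaviour.

Post-filters (applied to the final regions, after splitting): area
< 80 px or > 6000 px, circularity 4πA/P² < 0.40, and border contact
(bounding box touching any image edge).  The perimeter estimator is
scikit-image's boundary-weighted estimator, under which a rasterized
disc of radius ≥ 10 px measures circularity ≈ 0.91–0.96 — safely inside
[0.9, 1.0], which is the calibration requirement for the circularity
gate to behave as intended.  Each removed region carries explicit
reason codes.  Kept regions are cropped at their bounding box,
background-zeroed (bitwise multiplication with the instance mask),
centred on a square canvas and resized to the classifier ingress size.

### Lightweight CNN classifier

Four 3×3 valid convolutions (32→64→128→256) each followed by 2×2
pooling, dropout after pools 2–4 (rate 0.25) and before the output
(0.5), flatten → dense 256 → softmax over 9 classes: 653,129 trainable
parameters.  The 64×64×3 ingress is forced analytically by the
reference table (64 → 62 under valid 3×3; the ladder ends at 2×2×256 →
flatten 1024).  Dropout rates, optimizer and loss are not stated
upstream; the defaults here are 0.25/0.5 and the same Adam policy as
the U-Net with categorical cross-entropy, all exposed in config.

Cross-validation is stratified 5-fold: the test folds partition the
data with per-class proportions preserved within one sample, and the
remainder of each fold is split train:validation 75:25.  The upstream
fold sizes (6057/2019/2048 of 10,124) are internally inconsistent with
n/k = 2024.8; exact partitioning is implemented instead (test folds of
2024–2025 at that n) and the train:val ratio matches the printed
6057:2019.  Per-fold seeds are `seed + fold_index`.  Fold hygiene
(disjointness, full coverage) is validated before training and
augmented variants never cross split boundaries.

### Evaluation

Accuracy, precision, recall and F1 from confusion counts, with
zero-denominator metrics reported as undefined (never coerced to 0);
multiclass headline numbers are micro accuracy (trace/total) plus
macro-averaged one-vs-rest precision/recall/F1 — the averaging scheme
is not named upstream, macro is this package's documented choice.  IoU
and Dice on binary masks define empty-vs-empty as 1.0 and satisfy
Dice = 2·IoU/(1+IoU) to 10⁻¹²; ROC/AUC is one-vs-rest trapezoidal with
pooled micro and unweighted macro averages, checked against
Mann-Whitney pair counting.  Fold aggregation reports the unweighted
mean and population standard deviation (ddof 0), formatted to two
decimals.

### Grad-CAM

Channel weights are the spatially averaged gradients of the target
class's pre-softmax logit with respect to a convolutional layer's
activations (default: the last convolution — the layer is not named
upstream); the heatmap is the rectified weighted activation sum,
max-normalized and bilinearly upsampled to the input size.
Max-normalization makes the map invariant to positive rescaling of the
logit; an all-zero gradient returns an all-zero map with a warning
rather than an error.

## Synthetic data: what it emulates and what it does not

The generator renders round-ish cells of nine classes on a pale
background: per-class radius ranges (3–16 px), body colours, nucleus
morphologies (none / round / multi-lobed / kidney / band) and a
granularity texture term, plus frame-level nuisances — partial overlap
between cells (a placed fraction of cells relaxes the centre-distance
constraint against exactly one partner), a linear illumination gradient
(default ±7.5%), and additive Gaussian noise (default σ = 4 on the byte
scale).  Ground truth is exact: the instance map records the visible
extent of each cell (later cells occlude earlier ones; occlusion
geometry guarantees each remainder stays 8-connected) and noise is
applied after compositing.

The class morphologies are fixture defaults chosen to be mutually
distinguishable.  They are **not** calibrated to real hematology: real
smears have far more texture, staining variability, debris and
morphology overlap between classes (monocyte vs. immature granulocyte,
for instance).  Passing the desk-scale tests therefore demonstrates
that the pipeline machinery — training dynamics, marker selection,
splitting, fold bookkeeping, metric arithmetic — is correct, not that
the headline accuracies would transfer to clinical data.  The published
full-dataset figures (97.10% classification accuracy, 98.23%/95.97%/
97.92% segmentation accuracy/IoU/Dice) require the original annotated
microscopy dataset and GPU-scale training and are out of scope here;
the tests assert the property-based substitutes instead (reduced U-Net
IoU ≥ 0.85, watershed pair-split rate ≥ 95%, classifier hold-out
accuracy ≥ 90%).

Default generator conditions used by the desk-scale experiments: 200
frames of 128×128 px with one cell per class and overlap fraction 0.2
for segmentation; a balanced 100-per-class 64×64 ROI fixture for
classification.  These sizes were chosen as the smallest at which the
trained behaviour is stable; the acceptance script reports each
measured quantity together with the n it used.

## Numerical choices and degenerate inputs

* float32 throughout the network stack; BCE/CCE clip probabilities at
  10⁻⁷.  Softmax/sigmoid heads fuse the activation derivative into the
  loss gradient (`p − t`), the standard numerically stable form.
* Max pooling on odd dimensions crops the trailing row/column (the
  reference shape ladder, 31 → 14, does the same); pooling gradient ties
  route to the first argmax.
* The convergence exits (`stop_iou`, `stop_accuracy`) stop training
  once a monitored validation metric reaches a level, keeping the
  current weights; early stopping proper restores best-epoch weights.
* Empty mask → zero markers is a defined, non-error outcome; flooding
  with no foreground markers returns the mask as one region and logs
  the degenerate case.
* Watershed-line pixels do not arise (the flooding is run without line
  emission); if the backend ever emits unlabeled mask pixels they would
  surface in the oracle-equivalence test.
* A 1-px region has an ill-defined perimeter; it is floored at 1.0 so
  circularity stays finite (such regions are removed by the area gate
  anyway).

## Known limitations

* No pretrained weights; everything trains from scratch on synthetic or
  user-supplied data.
* The NumPy stack is single-process and CPU-bound; it is sized for the
  desk-scale experiments, not for 256×256 full-width training runs.
* The synthetic generator does not model stain variation, debris,
  out-of-focus blur or pathological morphologies; see above for what
  that implies about test evidence.
* Counting-based diagnosis, multi-class semantic segmentation and
  transfer-learning baselines are out of scope.
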