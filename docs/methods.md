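# Methods

## The recognition problem

An intraoperative hyperspectral camera records an H × W × B hypercube: a full
relative-absorption spectrum (B = 100 equally spaced bands, 500–1000 nm) at
every pixel of a surgical field. The task is per-pixel classification into seven
classes — artery, fat, metal, muscle, nerve, skin, vein (codes 1..7, 0 =
unlabeled) — from a sub-volume of the cube centered on the pixel: a 5 × 5
spatial window over all 100 bands. A model emits one score per class and the
pixel takes the argmax (ties break toward the lowest class code). Ground truth
is sparse: an annotator labels only pixels whose class is certain, and training
and evaluation use annotated pixels exclusively.

Nerves are the clinically critical and technically hardest class: they are the
thinnest structures in the field (a pixel or two wide at this camera's
640 × 476 resolution) and their spectra closely resemble muscle and fat.

## Models

**3-D CNN.** Six three-dimensional convolutional hidden layers followed by one
fully connected hidden layer and a 7-neuron linear output. Convolutions stride
along the spectral axis (100 → 50 → 25 → 13) while valid 3 × 3 spatial kernels
shrink the window (5 → 3 → 1); channel widths are 8, 8, 21, 21, 21, 40, the
hidden layer has 44 units. Every hidden layer is ReLU. At the default
(window 5, 100 bands, 7 classes) configuration the network has exactly 32,628
trainable parameters — small enough to train well on a cohort of a few hundred
thousand sub-volumes without augmentation, drop-out or transfer learning.

Training minimizes class-weighted softmax cross-entropy with Adam at learning
rate 0.001. Weights are inversely proportional to per-class training counts
(normalized to sum to K = 7; any positive rescaling is loss-equivalent up to
the learning rate). The loss uses the weighted-mean convention
`Σ w_y · nll / Σ w_y`, so its scale does not depend on a batch's class mix.
Epochs, batch size, initialization and stopping are free choices here:
fixed-epoch stopping (default 12 epochs), batch 256 by default (the tests use
32–64, which gives more optimizer steps per epoch on desk-scale cohorts),
uniform fan-in initialization `U(±1/√fan_in)`, all driven by one seed so
training is bit-reproducible.

The network is implemented directly in numpy (im2col convolutions, hand-derived
backward passes, Adam); the model is small enough that one CPU matmul per layer
per batch is entirely adequate, and the backward pass is verified against
finite differences in the test suite.

**RBF-SVM.** scikit-learn's `SVC` at its defaults: RBF kernel, C = 1,
`gamma="scale"`, one-vs-one fitting with one-vs-rest decision values used as
the per-class scores for ROC analysis. ("Degree" is a polynomial-kernel notion
and does not apply to an RBF kernel; it is ignored.) The SVM consumes a
100-dimensional feature vector per pixel — one value per wavelength — taken as
the **center pixel's spectrum** of the sub-volume. A spatial mean over the
window was considered and rejected: for structures thinner than the window
(nerves), pooling replaces the minority spectrum by its neighborhood's, and the
class becomes unrecoverable even on noise-free data. Features are band
auto-scaled (per-band mean 0 / variance 1) with a scaler fitted on the training
fold only and stored inside the model, so inference cannot bypass it.

**Preprocessing provenance.** SNV (per-curve standardization to mean 0, SD 1)
is an optional ablation for both models. A dataset records whether SNV was
applied, and a model refuses inputs whose declared normalization differs from
its training normalization; provenance is enforced, not trusted.

## Normalizations: SNV vs band auto-scaling

SNV standardizes each *curve across bands*, removing exactly the multiplicative
gain / additive offset family produced by illumination geometry; it needs no
training data and is idempotent. Band auto-scaling standardizes each *band
across training curves*; it equalizes band influence for the kernel distance
and is a fitted, fold-local transform. A constant spectrum has no SNV
normalization and raises an error identifying the pixel — degenerate inputs are
never epsilon-fudged, because the generator cannot produce them and silence
would hide bugs.

## Evaluation

Leave-one-patient-out cross-validation: with n subjects, fold i trains on all
subjects except i and tests on subject i; each subject is held out exactly
once. All fitted preprocessing (band scaler) and the class weights are
functions of the training fold only; fold structure is asserted in tests.

Metrics per fold and pooled:

* **Confusion matrices**, row-normalized so each supported row sums to 1; the
  diagonal equals per-class sensitivity. Zero-support rows are flagged (NaN),
  never divided.
* **One-vs-all sensitivity, specificity and Dice** (DSC = 2TP/(2TP+FP+FN), the
  F1 score, equal to the harmonic mean of precision and sensitivity). With zero
  class support a metric is reported missing (NaN), not zero, and such folds
  are excluded from that class's across-fold mean; macro averages are
  unweighted means over classes with defined values.
* **ROC curves** per class, one-vs-all, pooling test-pixel scores over all
  folds (per-fold averaging of curves is the other option; pooling matches
  scoring every test pixel once). AUC is trapezoidal and equals the
  probability that a random positive outscores a random negative, ties ½ —
  asserted against a brute-force pairwise oracle in the tests.
* **Across-fold dispersion** is reported both as SD and as standard error
  (SD/√n folds).
* **Model comparisons** use a two-tailed paired t-test across folds (pairing by
  held-out subject), α = 0.05, stars at p < 0.05 and p < 0.01, p-values to four
  decimals, no multiple-testing correction. Zero difference variance is flagged
  degenerate, with no p reported.

## The synthetic cohort generator

The surgical acquisitions behind this pipeline are not publicly deposited, so
the generator produces cohorts with the *statistical structure* that the
pipeline actually exercises. What it emulates:

* **Geometry** (default 64 × 64; the camera's full 640 × 476 is supported):
  skin background, a fat margin, a muscle block, artery and vein as jittered
  sinusoidal tubes (width 4 px), the nerve as the thinnest curvilinear
  structure (width 1 px) running between the vessels, and a metal retractor
  bar. Annotation covers the eroded core of each region, subsampled (fraction
  0.25, floor 40 px — thin structures are annotated along their length — cap
  400 px), reproducing both conservative annotation and severe imbalance.
* **Spectra**: class mean curves are sums of a few Gaussian bumps on
  500–1000 nm, constrained only by ordinal relations — muscle/nerve/fat are the
  most similar classes, vein and skin the most dissimilar tissues, metal has a
  flat high profile. A sampled curve is
  `gain · (mean + subject_shift + smooth_deviation) + offset + noise`:
  lognormal gain (SD 0.08) and additive offset (SD 0.05) form exactly the
  family SNV cancels; the smooth deviation (scale 0.02) and the per-subject
  shift (scale 0.022) are band-correlated draws on a Gaussian-bump basis; noise
  (SD 0.015) is independent per band. Metal adds specular spikes (probability
  0.35, plateau 2.5–4× tissue level), giving it by far the largest variance.
* **Two dials.** The *separability* dial (`zero_variability()`) zeroes every
  stochastic scale so classes emit exactly their mean curves; any sound
  pipeline must then recover every class almost perfectly under LOPOCV, which
  is the pipeline's smoke test. The *confusability* dial
  (`nerve_muscle_similarity`, default 0.6) blends the nerve mean toward the
  muscle mean. The variability defaults were chosen once so that the
  qualitative clinical picture is reproduced at desk scale: nerve is the
  lowest-sensitivity class for every model and the CNN retains a clear nerve
  advantage over the SVM, driven by its weighted loss and spatial context.

What it does **not** emulate: light transport, scattering physics or any real
tissue chromophore; motion/breathing artifacts; camera noise models; RGB
rendering. Passing tests therefore demonstrate that the pipeline's machinery —
data handling, fold hygiene, training, metrics — behaves correctly and that the
qualitative difficulty ordering is reproduced under the stated statistical
structure; they say nothing quantitative about performance on real surgical
data, whose headline numbers are out of reach without the original
acquisitions.

Determinism: a cohort is a pure function of (configuration, seed); per-subject
streams are spawned from one seed sequence, so subjects are independent but
reproducible, and the whole pipeline (simulate → train → evaluate) writes
byte-identical metrics for identical configuration and seed.

## Numerical and design notes

* Coordinates are 0-based (row, col), row-major, band axis last. Class codes
  are alphabetical: artery=1 … vein=7, fixing confusion-matrix order.
* Cubes are stored as minimal ENVI pairs (lowercase-key text header + raw
  little-endian float32, BSQ interleave); round-trips are bit-exact. Masks are
  8-bit indexed PNGs with a JSON code→name sidecar.
* Sub-volume extraction is total over the image: near borders, out-of-image
  positions are filled by edge replication; interior patches reproduce the raw
  cube block exactly. (Annotations are interior in practice, so padding rarely
  fires, but the operation must not have holes.)
* Desk scale: tests run cohorts of 3–8 subjects at 48–64 px scenes with a few
  hundred annotated pixels per subject, chosen so the full suite (including two
  LOPOCV studies) completes on one CPU in minutes while preserving the
  imbalance and confusability structure. These sizes are package test
  conditions, not claims about the original study's scale.

## Known limitations

* The CNN is trained for a fixed epoch budget; no early stopping or validation
  split (faithful to a small, fixed training recipe, but the loss trajectory is
  logged for inspection).
* The SVM's one-vs-rest decision values are comparable across classes only in
  the usual heuristic sense; ROC analysis inherits that caveat.
* The generator's class geometry is stylized (bands, tubes, bars); spatial
  context learned by the CNN on synthetic scenes will not transfer to real
  anatomy, and is not meant to.
* Full-resolution (640 × 476) cohorts are supported but slow on one CPU; the
  pipeline is written for clarity and desk-scale verification, not throughput.
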