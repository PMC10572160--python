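# Methods

## The calibration surface

Storage day *z* is modelled on the poly31 basis {x³, x²y, x², xy, x,
y, 1} in MDA (*x*, nmol/mgprot) and SH (*y*, μmol/gprot) — degree 3
in the lipid-oxidation marker, degree 1 in the thiol marker. The
canonical fit uses the eight packaged batch-mean triples (days 0–14,
4 °C) and reaches R² = 0.9948.

Numerical choices:

* The least-squares problem is solved through an SVD (`lstsq`), not
  the normal equations: on raw concentrations the 8×7 design has
  condition number ≈ 2·10⁷, and squaring it would halve the usable
  precision. A normal-equations solve is still used as an
  *independent oracle* in the tests, on well-conditioned synthetic
  sets.
* Optional z-scoring of the predictors (`center_scale=True`) changes
  only the coefficient parametrization, never the fitted surface:
  any affine map of x and y separately spans the same 7-dimensional
  function space. The tests assert this invariance to 1e-6.
* A historically published coefficient vector for this surface ships
  as a documentary constant. Applied to raw concentrations it does
  not reproduce the predictions published alongside it — it was
  evidently expressed in an unstated internal coordinate system —
  so prediction always uses the refit. By the function-space argument
  above, *no* least-squares fit on these eight means can reproduce
  every published prediction: the level-4 median pair (10.20, 66.37)
  lies far outside the calibration hull (MDA ≤ 7.24, SH ≥ 98.17),
  where a near-interpolating cubic is hypersensitive to rounding in
  the printed means. The refit gives 7.61 days there versus the
  published 8.78; the level-2 and level-3 pairs agree to ≈ 0.03 and
  ≈ 0.13 days.
* Predictions are unclamped. Extrapolating level pairs legitimately
  produce negative or > 14-day values (the freshest SH median with a
  level-2 MDA median evaluates below zero); evaluation outside the
  calibration bounding box logs an INFO notice.
* Fitting requires at least 7 points (one per basis term); with
  exactly 7 in general position the fit interpolates (R² = 1).
  Rank-deficient designs are rejected with the collinear columns
  named (via pivoted QR).

## Level binning

For each indicator the assay values are sorted — MDA ascending, SH
descending, so level 1 is always freshest — and cut into four groups
whose sizes differ by at most one (remainder to the earliest groups).
Each group's median is the class value. Boundaries are midpoints
between adjacent sorted values; a value equal to a boundary goes to
the lower level, and out-of-range values clamp to levels 1/4. Ties at
group edges are broken by stable sort position so balance survives
duplicated values. The canonical median table (MDA 3.30/5.15/6.25/
10.20; SH 163.98/119.19/106.42/66.37) ships as a frozen fixture and
is what the fusion pipeline uses in paper mode; dataset mode refits
schemes to the data at hand.

## Synthetic data: what it emulates, and what it does not

The generator stands in for an unavailable 1120-image laboratory
dataset (8 batches × 140 images). Per-image indicator values are
drawn independently, Gaussian around the batch means with 8%
coefficient of variation (truncated positive). The within-batch CV is
an assumption — only batch means are published — and the
independence of the MDA and SH draws is likewise synthetic
convenience, not biology.

Rendering maps each indicator to a spoilage score in [0, 1] by
inverting the batch-mean-versus-day curve (piecewise linear, extended
two days past each end so near-range values do not saturate; score =
(day + 2)/18). The day-equivalent scale matters for SH, whose raw
means crowd into 98–105 μmol/gprot over days 8–14: an affine score
would compress three level boundaries into a sliver. Appearance
channels are split between the indicators so each grading task is
separately decodable from pixels:

* MDA score → meat hue (green → brown) and body fullness;
* SH score → brightness, specular gloss count/size, mucus
  cloudiness (luminance-preserving desaturation) and Gaussian blur;
* plus seeded per-image geometric jitter, low-frequency tissue
  texture, a pale adductor-muscle landmark, and sensor noise.

Passing tests on this data show that the pipeline's machinery —
labelling, training, evaluation, fusion — works and that the graders
can learn a 4-level photographic signature; they say nothing about
accuracy on real oyster photographs, whose appearance-to-chemistry
coupling is far noisier than the generator's deterministic schedules.
The generator's built-in contract (asserted in tests) is that a
two-feature classifier on mean hue and luminance exceeds 80% 4-level
accuracy, i.e. the CNN task is learnable at desk scale by
construction.

## Graders and the training recipe

The reference architecture is the AlexNet series layout (5 conv,
3 max-pool, 3 FC stages, 227×227×3 input, 4-way softmax), built here
with non-overlapping pooling (geometry 56-28-14-7). The reference
recipe mirrors the classical fine-tuning settings: Adam, initial
learning rate 1e-5, drop factor 0.1 every 10 epochs, minibatch 64,
15 epochs. Those are the `ClassifierConfig` defaults.

Training at that scale presumes a pretrained backbone and a GPU;
this package trains **from scratch** on synthetic data, so the
test-scale configuration (`ClassifierConfig.reduced()`) uses a
width-reduced variant of the same family on 64×64 inputs with Adam at
2e-3, drop factor 0.3 every 2 epochs, minibatch 8, 5 epochs — a
fine-tuning learning rate of 1e-5 simply cannot move He-initialized
weights in 5 epochs. Inputs are standardized by the fixed affine
(x − 0.35)/0.25 (typical image mean/scale), matched to the He
initialization. Under these conditions both graders reach ≈ 0.94–0.98
held-out accuracy (the weakest per-level recall, SH level 3, sits
around 0.86–0.91: that level's boundaries fall where batches overlap
most). Training is seed-deterministic on a given machine; the engine
is float32 numpy, single-threaded BLAS-friendly.

No dropout or augmentation is used: the synthetic task does not need
regularization at 5 epochs, and omitting them keeps runs exactly
reproducible.

## Evaluation arithmetic

Confusion matrices are actual-by-predicted counts; per-level
precision, recall, specificity (TN/(TN+FP)) and F1 follow the
standard one-vs-rest definitions, with NaN (never 0) on empty
denominators. Overall accuracy = trace/total, identically the
support-weighted mean recall. `recompose_overall_accuracy` recovers
diagonal counts by rounding recall × support — useful for
re-deriving an overall accuracy from a published per-level table.
Display rounding is two decimals. Note that published specificity
values for this kind of table do not always match TN/(TN+FP) on the
reconstructable counts; the standard formula is used regardless.

## Interpretability

Deep dream maximizes one class unit of the final FC layer by gradient
ascent from seeded low-contrast noise, with mean-normalized gradient
steps, light Gaussian smoothing every 8 steps, and clipping to the
valid pixel range; the objective trace is recorded and must rise over
smoothed windows (not necessarily stepwise). The strongest-activation
map takes the last convolutional layer's pre-ReLU response (so
negative activation is visible as dark), selects the channel with the
largest maximum (ties to the lower index), min-max normalizes and
bilinearly upscales to the input size. Both are qualitative tools;
no regularization gallery is attempted.

## Fusion

`predict_freshness` composes level → class median → surface, exactly
and unclamped, so every image maps to one of 16 possible output
triples. Paper mode uses the frozen median table (required to
reproduce the published prediction table); dataset mode uses medians
refit to a manifest. Batch prediction skips unreadable rows with a
warning and is byte-deterministic for fixed inputs. Wall time is
logged per prediction but never asserted — throughput claims are
hardware-bound.

## Problem sizes used by the test suite

The session fixtures build the default 1120-image dataset at 64 px
(seed 1) and train one reduced-scale grader per task (seed 0,
5 epochs); all other tests run on small derived inputs. These sizes
were chosen so the whole suite runs in minutes on a single CPU while
still exercising the full pipeline end to end.
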