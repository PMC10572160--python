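# oysterfresh

Non-destructive freshness grading of Pacific oysters (*Crassostrea
gigas*) from photographs of the shucked meat.

Freshness of refrigerated oyster meat is conventionally assessed by
destructive biochemical assays: malondialdehyde (MDA, nmol/mgprot)
accumulates with lipid oxidation and total sulfhydryl content (SH,
μmol/gprot) falls as muscle proteins oxidize. `oysterfresh`
implements a two-tier image-based alternative:

1. **Tier 1 — two parallel 4-level CNN graders.** An AlexNet-family
   series network (5 convolutional, 3 max-pooling, 3 fully connected
   stages, 227×227×3 input) per indicator classifies a photograph
   into one of four freshness levels. Levels come from the *data
   balance* rule: sort all assay values (MDA ascending, SH
   descending), split into four equal-count groups, and take each
   group's median as its class value.
2. **Tier 2 — a poly31 calibration surface.** Storage day *z* is a
   bivariate polynomial in MDA (*x*) and SH (*y*),

   z = c₁x³ + c₂x²y + c₃x² + c₄xy + c₅x + c₆y + c₇,

   least-squares fit to eight batch-mean calibration triples (storage
   days 0–14 at 4 °C, shipped with the package; R² = 0.995). The
   levels predicted by tier 1 map to their class-median (MDA, SH)
   pair, and the surface evaluated there yields the predicted storage
   day.

Because the real assay imagery is not public, the package includes a
first-class synthetic data module that renders oyster-on-half-shell
images whose appearance drifts with spoilage (green/glossy/full →
dark/dry/blurred with surface mucus), so the full pipeline is
trainable and testable on one CPU. The CNN engine (conv/pool/dense
layers with hand-written backprop and Adam) is part of the package,
which also makes input-gradient visualizations (deep dream,
strongest-activation maps) straightforward.

## Worked example

```python
from oysterfresh import fit_surface, load_calibration

surface = fit_surface(load_calibration())
print(f"R^2 = {surface.r_squared:.4f}")
for mda, sh in [(5.15, 119.19), (6.25, 106.42), (10.20, 66.37)]:
    print(mda, sh, round(surface.predict(mda, sh), 2))
```

prints

```
R^2 = 0.9948
5.15 119.19 4.74
6.25 106.42 7.97
10.2 66.37 7.61
```

— the goodness of fit of the calibration surface, then the predicted
storage day at the level-2, level-3 and level-4 median (MDA, SH)
pairs: meat graded level 2 on both indicators is about 5 days old,
level 3 about 8 days. The level-4 input lies far outside the
calibration range, so its cubic extrapolation should be read
qualitatively ("old"), not literally.

The `examples/` directory holds one short script per capability:
surface fitting, level binning, dataset generation, grader training
and evaluation, two-tier prediction, and feature visualization. A
thin CLI wraps the same functions:

```sh
oysterfresh generate data/ --seed 1 --image-size 64
oysterfresh train data/manifest.csv --task mda --out mda_grader
oysterfresh evaluate data/manifest.csv --model mda_grader
oysterfresh predict data/manifest.csv --mda-model mda_grader --sh-model sh_grader
```

## Layout

```
src/oysterfresh/
  surface.py     poly31 calibration surface (fit, predict, serialize)
  binning.py     balanced 4-level labelling and the median table
  synthetic.py   synthetic oyster imagery + dataset manifest
  nn.py          minimal CNN engine (conv/pool/dense, Adam, backprop)
  classifier.py  grader configs, training loop, inference, checkpoints
  metrics.py     confusion matrix and derived metrics
  interpret.py   deep dream and strongest-activation maps
  pipeline.py    two-tier fusion: image -> levels -> medians -> day
  cli.py         command-line front end
```

See `docs/methods.md` for the model details, generator assumptions
and numerical choices.
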