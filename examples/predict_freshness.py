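"""Two-tier freshness prediction on a handful of images.

Both graders classify each image into a 4-level class; the class
medians feed the fitted surface, which returns the predicted storage
day.  Only 16 distinct output triples exist (4 x 4 level pairs).
"""

from pathlib import Path

from oysterfresh import (
    BatchSpec,
    ClassifierConfig,
    build_dataset,
    default_batches,
    fit_surface,
    load_calibration,
    train,
)
from oysterfresh.pipeline import batch_predict

out = Path("scratch/example_predict")
manifest = build_dataset(out, seed=1, image_size=64)
surface = fit_surface(load_calibration())

mda_model = train(ClassifierConfig.reduced(seed=0), manifest, "MDA")
sh_model = train(ClassifierConfig.reduced(seed=0), manifest, "SH")

sample = manifest[manifest["split"] == "test"].groupby("day").head(1)
table = batch_predict(mda_model, sh_model, surface, sample)
print(table[["mda", "sh", "predicted_day", "actual_day"]].to_string(index=False))
# Predicted days are unclamped: level pairs far outside the
# calibration range (e.g. the freshest SH median with a mid MDA
# median) extrapolate the cubic and can print negative days.
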