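"""Generate a small synthetic oyster image dataset.

Renders procedurally drawn oyster-on-half-shell images whose
appearance drifts with storage (green/glossy/full -> dark/dry/
blurred), labels them by balanced quantile binning of the per-image
MDA/SH values, and writes images plus a manifest CSV.
"""

from pathlib import Path

from oysterfresh import BatchSpec, build_dataset, default_batches

out = Path("scratch/example_dataset")
specs = [
    BatchSpec(day=b.day, mean_mda=b.mean_mda, mean_sh=b.mean_sh, n_images=10)
    for b in default_batches()
]
manifest = build_dataset(out, specs=specs, seed=0, image_size=64, labeled_count=None)

print(f"wrote {len(manifest)} images under {out}")
print(manifest.groupby("day")[["mda", "sh"]].mean().round(2))
print("\nsplit counts:", manifest["split"].value_counts().to_dict())
print("MDA level counts:", manifest["mda_level"].value_counts().sort_index().to_dict())
# Batch-mean MDA rises and SH falls with storage day, mirroring the
# calibration data the batches are parameterized by.
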