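"""Train the two 4-level graders and print their test metrics.

Uses the compact 64-px architecture and the reduced from-scratch
recipe (2e-3 Adam, 5 epochs).  A few minutes on one CPU.
"""

from pathlib import Path

from oysterfresh import ClassifierConfig, build_dataset, train
from oysterfresh.metrics import confusion_from_predictions, metrics_from_confusion
from oysterfresh.synthetic import load_images

out = Path("scratch/example_training")
manifest = build_dataset(out, seed=1, image_size=64)
test = manifest[manifest["split"] == "test"]
test_images = load_images(test)

for task, col in (("MDA", "mda_level"), ("SH", "sh_level")):
    model = train(ClassifierConfig.reduced(seed=0), manifest, task)
    predicted = model.predict_levels(test_images)
    cm = confusion_from_predictions(test[col].to_numpy(int), predicted)
    report = metrics_from_confusion(cm)
    print(f"\n=== {task} grader ===")
    print(cm.to_text())
    print(report.to_frame().to_string(index=False))
# Rows are actual levels, columns predicted; precision/recall/
# specificity/F1 are one-vs-rest per level, accuracy = trace/total.
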