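"""Interpretability visualizations for a trained grader.

Writes (a) a grid of deep-dream images, one per freshness level —
gradient ascent on each class unit of the final fully connected
layer — and (b) an input|activation montage showing the strongest
channel of the last convolutional layer for one test image.
"""

from pathlib import Path

import numpy as np
from PIL import Image

from oysterfresh import ClassifierConfig, build_dataset, deep_dream, train
from oysterfresh.interpret import montage, save_dream_grid, strongest_activation

out = Path("scratch/example_interpret")
out.mkdir(parents=True, exist_ok=True)
manifest = build_dataset(out / "data", seed=1, image_size=64)
model = train(ClassifierConfig.reduced(seed=0), manifest, "MDA")

dreams = [deep_dream(model, level, iterations=48, seed=0) for level in (1, 2, 3, 4)]
save_dream_grid(dreams, out / "dreams.png")
for d in dreams:
    gain = d.objective_trace[-1] - d.objective_trace[0]
    print(f"level {d.class_index}: activation rose by {gain:.2f} over "
          f"{d.iterations} iterations")

test = manifest[manifest["split"] == "test"].iloc[0]
with Image.open(test["path"]) as img:
    arr = np.asarray(img.convert("RGB"))
amap = strongest_activation(model, arr)
montage(arr, amap, out / "activation.png")
print(f"strongest channel: {amap.channel_index}; montage and dream grid in {out}")
# Bright regions of the activation map mark where the model looks;
# on synthetic oysters this is typically the meat body and its rim.
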