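"""Shared fixtures: one synthetic dataset and one trained grader pair.

The dataset and the two trained classifiers are expensive (minutes),
so they are built once per session and shared by every test that
needs them.  All randomness is seeded: dataset seed 1, model seed 0.
"""

from __future__ import annotations

import pytest

from oysterfresh import ClassifierConfig, build_dataset, fit_surface, load_calibration, train
from oysterfresh.synthetic import load_images

DATASET_SEED = 1
MODEL_SEED = 0


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset at 64 px: manifest plus image arrays."""
    root = tmp_path_factory.mktemp("oysters")
    manifest = build_dataset(root, seed=DATASET_SEED, image_size=64)
    splits = {}
    for name in ("train", "validation", "test"):
        part = manifest[manifest["split"] == name]
        splits[name] = (part, load_images(part))
    return {"manifest": manifest, "root": root, "splits": splits}


@pytest.fixture(scope="session")
def trained_models(dataset):
    """One reduced-scale grader per task, trained on the session dataset."""
    manifest = dataset["manifest"]
    tr, xtr = dataset["splits"]["train"]
    va, xva = dataset["splits"]["validation"]
    models = {}
    for task in ("MDA", "SH"):
        models[task] = train(
            ClassifierConfig.reduced(seed=MODEL_SEED),
            manifest,
            task,
            images=xtr,
            validation_images=xva,
        )
    return models


@pytest.fixture(scope="session")
def surface_model():
    return fit_surface(load_calibration())
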