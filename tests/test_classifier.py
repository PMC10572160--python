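"""CNN graders: architecture, resizing, training loop, inference."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from oysterfresh.classifier import (
    ClassifierConfig,
    ClassifierError,
    TrainedClassifier,
    build_network,
    resize_input,
    train,
)
from oysterfresh.nn import Conv2D, Dense, MaxPool2D


def test_config_validation():
    with pytest.raises(ClassifierError):
        ClassifierConfig(max_epochs=0)
    with pytest.raises(ClassifierError):
        ClassifierConfig(initial_learning_rate=-1e-5)
    with pytest.raises(ClassifierError):
        ClassifierConfig(transfer_init=True)  # no pretrained backbone here


def test_reference_recipe_defaults():
    cfg = ClassifierConfig()
    assert cfg.image_size == 227
    assert cfg.initial_learning_rate == 1e-5
    assert cfg.lr_drop_factor == 0.1
    assert cfg.lr_drop_period == 10
    assert cfg.minibatch_size == 64
    assert cfg.max_epochs == 15


@pytest.mark.parametrize("architecture, size", [("alexnet", 227), ("compact", 64)])
def test_network_family_layout(architecture, size):
    """Both variants: 5 conv, 3 pool, 3 FC stages, 4-way output."""
    net = build_network(ClassifierConfig(architecture=architecture, image_size=size))
    assert sum(isinstance(l, Conv2D) for l in net.layers) == 5
    assert sum(isinstance(l, MaxPool2D) for l in net.layers) == 3
    assert sum(isinstance(l, Dense) for l in net.layers) == 3
    x = np.zeros((1, 3, size, size), dtype=np.float32)
    assert net.forward(x).shape == (1, 4)


def test_resize_input_contract():
    tall = np.zeros((4032, 3024, 3), dtype=np.uint8)
    assert resize_input(tall, 227).shape == (227, 227, 3)
    small = np.random.default_rng(0).integers(0, 255, (227, 227, 3), dtype=np.uint8)
    assert np.array_equal(resize_input(small, 227), small)  # identity
    with pytest.raises(ClassifierError):
        resize_input(np.zeros((64, 64), dtype=np.uint8))  # grayscale array
    with pytest.raises(ClassifierError):
        resize_input(Image.new("L", (64, 64)))  # grayscale PIL


def _mini_manifest(dataset, n_per_level=10):
    manifest = dataset["manifest"]
    tr = manifest[manifest["split"] == "train"]
    picks = pd.concat(
        [tr[tr["mda_level"] == lev].head(n_per_level) for lev in (1, 2, 3, 4)]
    )
    return picks.assign(split="train")


def test_train_input_validation(dataset):
    cfg = ClassifierConfig.reduced(seed=0, max_epochs=1)
    with pytest.raises(ClassifierError):
        train(cfg, pd.DataFrame(columns=["split", "mda_level", "path"]), "MDA")
    mini = _mini_manifest(dataset)
    missing = mini[mini["mda_level"] != 2]  # drop one class entirely
    with pytest.raises(ClassifierError):
        train(cfg, missing, "MDA")
    with pytest.raises(ClassifierError):
        train(cfg, mini, "TVBN")


def test_training_is_seed_deterministic(dataset):
    mini = _mini_manifest(dataset)
    cfg = ClassifierConfig.reduced(seed=5, max_epochs=1)
    a = train(cfg, mini, "MDA")
    b = train(cfg, mini, "MDA")
    assert a.weights_hash() == b.weights_hash()
    assert np.array_equal(
        a.history[["loss", "accuracy"]], b.history[["loss", "accuracy"]]
    )


def test_learning_rate_schedule_recorded(dataset):
    mini = _mini_manifest(dataset, n_per_level=4)
    cfg = ClassifierConfig(
        architecture="compact", image_size=64, initial_learning_rate=1e-3,
        lr_drop_factor=0.1, lr_drop_period=1, minibatch_size=8,
        max_epochs=3, seed=0,
    )
    model = train(cfg, mini, "MDA")
    lr_by_epoch = model.history.groupby("epoch")["learning_rate"].first()
    assert np.allclose(lr_by_epoch.to_numpy(), [1e-3, 1e-4, 1e-5])


def test_probabilities_normalized(trained_models, dataset):
    _, xte = dataset["splits"]["test"]
    probs = trained_models["MDA"].predict_proba(xte[:16])
    assert probs.shape == (16, 4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_prediction_batch_invariance(trained_models, dataset):
    """One image alone predicts identically to the same image in a batch."""
    _, xte = dataset["splits"]["test"]
    model = trained_models["SH"]
    batch_probs = model.predict_proba(xte[:8])
    for i in range(8):
        solo = model.predict_proba(xte[i : i + 1])[0]
        assert np.allclose(solo, batch_probs[i], atol=1e-5)


def test_predict_level_argmax_and_tie_rule(trained_models):
    model = trained_models["MDA"]

    class Stub(TrainedClassifier):
        def __init__(self, inner, probs):
            super().__init__(task=inner.task, config=inner.config, net=inner.net)
            self._probs = np.asarray(probs, dtype=float)

        def predict_proba(self, images):
            return self._probs[None]

    level, probs = Stub(model, [0.7, 0.1, 0.1, 0.1]).predict_level(
        np.zeros((64, 64, 3), np.uint8)
    )
    assert level == 1
    level, _ = Stub(model, [0.25, 0.25, 0.25, 0.25]).predict_level(
        np.zeros((64, 64, 3), np.uint8)
    )
    assert level == 1  # ties break toward the fresher level


def test_validation_accuracy_reaches_090(trained_models):
    """Learnability of the synthetic task at reduced scale."""
    for task in ("MDA", "SH"):
        hist = trained_models[task].history
        final_val = hist["val_accuracy"].dropna().iloc[-1]
        assert final_val >= 0.90, f"{task} final validation accuracy {final_val}"


def test_per_class_recall_on_held_out_split(trained_models, dataset):
    from oysterfresh.metrics import confusion_from_predictions, metrics_from_confusion

    for task, col in (("MDA", "mda_level"), ("SH", "sh_level")):
        te, xte = dataset["splits"]["test"]
        predicted = trained_models[task].predict_levels(xte)
        report = metrics_from_confusion(
            confusion_from_predictions(te[col].to_numpy(int), predicted)
        )
        assert np.all(report.recall >= 0.85), f"{task} recalls {report.recall}"


def test_checkpoint_roundtrip(trained_models, dataset, tmp_path):
    _, xte = dataset["splits"]["test"]
    model = trained_models["MDA"]
    model.save(tmp_path / "grader")
    clone = TrainedClassifier.load(tmp_path / "grader")
    assert clone.task == "MDA"
    assert clone.weights_hash() == model.weights_hash()
    assert np.allclose(
        clone.predict_proba(xte[:4]), model.predict_proba(xte[:4]), atol=1e-7
    )
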