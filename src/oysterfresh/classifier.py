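"""Four-level freshness graders: AlexNet-family CNN classifiers.

Two independent classifiers are trained on oyster-meat photographs,
one per biochemical indicator: a grader of MDA level (lipid
oxidation) and a grader of SH level (protein thiol loss), each a
4-way image classifier.  The reference architecture is the AlexNet
series layout — five convolutional stages, three max-pooling stages
and three fully connected stages on a 227x227x3 input.  A
width-reduced variant of the same layout ("compact", 64x64 input)
trains in minutes on a single CPU and is what the test-scale recipes
use.

Training recipe (reference scale): Adam, initial learning rate 1e-5,
learning-rate drop factor 0.1 every 10 epochs, minibatch 64, max 15
epochs.  The compact from-scratch variant defaults to a larger
initial rate (2e-3) because the tiny fine-tuning rate is suited to a
pretrained backbone, not random initialization.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

from .nn import (
    Adam,
    Conv2D,
    Dense,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)

Task = Literal["MDA", "SH"]

N_CLASSES = 4


class ClassifierError(ValueError):
    """Invalid input to the classifier routines."""


@dataclass
class ClassifierConfig:
    """Hyperparameters of one grader.

    Defaults mirror the reference recipe at full 227x227 scale;
    :meth:`reduced` returns the compact test-scale configuration.
    """

    architecture: Literal["alexnet", "compact"] = "alexnet"
    image_size: int = 227
    initial_learning_rate: float = 1e-5
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    minibatch_size: int = 64
    max_epochs: int = 15
    seed: int = 0
    transfer_init: bool = False

    def __post_init__(self) -> None:
        positive = {
            "image_size": self.image_size,
            "initial_learning_rate": self.initial_learning_rate,
            "lr_drop_factor": self.lr_drop_factor,
            "lr_drop_period": self.lr_drop_period,
            "minibatch_size": self.minibatch_size,
            "max_epochs": self.max_epochs,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ClassifierError(f"{name} must be positive, got {value}")
        if self.transfer_init:
            raise ClassifierError(
                "transfer_init requires an external pretrained backbone; "
                "this build trains from scratch"
            )

    @classmethod
    def reduced(cls, seed: int = 0, max_epochs: int = 5) -> "ClassifierConfig":
        """Compact 64x64 configuration for CPU-scale runs."""
        return cls(
            architecture="compact",
            image_size=64,
            initial_learning_rate=2e-3,
            lr_drop_factor=0.3,
            lr_drop_period=2,
            minibatch_size=8,
            max_epochs=max_epochs,
            seed=seed,
        )


def build_network(config: ClassifierConfig) -> Sequential:
    """Instantiate the series network for a configuration.

    Both variants follow the same layout family: 5 conv stages,
    3 max-pool stages, 3 fully connected stages, 4-way output.
    """
    rng = np.random.default_rng(config.seed)
    if config.architecture == "alexnet":
        # AlexNet layout with non-overlapping pooling (the engine pools
        # with size == stride), so the spatial geometry is 56-28-14-7
        # rather than the original 55-27-13-6.
        if config.image_size != 227:
            raise ClassifierError("the alexnet variant requires 227x227 input")
        return Sequential([
            Conv2D(3, 96, 11, stride=4, padding=2, rng=rng), ReLU(),   # 56
            MaxPool2D(2),                                              # 28
            Conv2D(96, 256, 5, padding=2, rng=rng), ReLU(),
            MaxPool2D(2),                                              # 14
            Conv2D(256, 384, 3, padding=1, rng=rng), ReLU(),
            Conv2D(384, 384, 3, padding=1, rng=rng), ReLU(),
            Conv2D(384, 256, 3, padding=1, rng=rng), ReLU(),
            MaxPool2D(2),                                              # 7
            Flatten(),
            Dense(256 * 7 * 7, 4096, rng=rng), ReLU(),
            Dense(4096, 4096, rng=rng), ReLU(),
            Dense(4096, N_CLASSES, rng=rng),
        ])
    if config.architecture == "compact":
        if config.image_size % 16 != 0:
            raise ClassifierError("compact variant needs image_size divisible by 16")
        s = config.image_size
        f = (s // 16) * (s // 16) * 48
        return Sequential([
            Conv2D(3, 16, 5, stride=2, padding=2, rng=rng), ReLU(),   # s/2
            MaxPool2D(2),                                             # s/4
            Conv2D(16, 32, 3, padding=1, rng=rng), ReLU(),
            MaxPool2D(2),                                             # s/8
            Conv2D(32, 32, 3, padding=1, rng=rng), ReLU(),
            Conv2D(32, 48, 3, padding=1, rng=rng), ReLU(),
            Conv2D(48, 48, 3, padding=1, rng=rng), ReLU(),
            MaxPool2D(2),                                             # s/16
            Flatten(),
            Dense(f, 128, rng=rng), ReLU(),
            Dense(128, 64, rng=rng), ReLU(),
            Dense(64, N_CLASSES, rng=rng),
        ])
    raise ClassifierError(f"unknown architecture {config.architecture!r}")


def last_conv_index(net: Sequential) -> int:
    """Index of the last convolutional layer in the stack."""
    idx = [i for i, lay in enumerate(net.layers) if isinstance(lay, Conv2D)]
    if not idx:
        raise ClassifierError("network has no convolutional layer")
    return idx[-1]


def resize_input(image, size: int = 227) -> np.ndarray:
    """Resize an RGB image to the network input size.

    Accepts a PIL image or an (H, W, 3) uint8/float array; returns a
    (size, size, 3) uint8 array.  Bilinear interpolation, deterministic.
    An already-conforming image is returned with identical pixels.
    """
    if isinstance(image, np.ndarray):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ClassifierError(
                f"expected an RGB (H, W, 3) image, got shape {image.shape}"
            )
        if image.dtype != np.uint8:
            image = np.clip(np.asarray(image, dtype=float) * 255, 0, 255).astype(
                np.uint8
            )
        pil = Image.fromarray(image, mode="RGB")
    elif isinstance(image, Image.Image):
        if image.mode != "RGB":
            raise ClassifierError(f"expected an RGB image, got mode {image.mode!r}")
        pil = image
    else:
        raise ClassifierError(f"unsupported image type {type(image)!r}")
    if pil.size != (size, size):
        pil = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(pil, dtype=np.uint8)


def _to_batch(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8/float -> standardized float32 NCHW batch.

    Fixed affine (x - 0.35) / 0.25 brings typical oyster photographs
    to roughly zero mean, unit variance — matched to the He
    initialization of the first layer.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.max() > 1.5:
        x = x / 255.0
    return (np.ascontiguousarray(x.transpose(0, 3, 1, 2)) - 0.35) / 0.25


@dataclass
class TrainedClassifier:
    """A trained grader: network weights plus training provenance."""

    task: Task
    config: ClassifierConfig
    net: Sequential
    class_order: tuple[int, ...] = (1, 2, 3, 4)
    history: pd.DataFrame | None = None

    # -- inference -----------------------------------------------------

    def predict_proba(self, images) -> np.ndarray:
        """(N, 4) class probabilities; rows sum to 1."""
        x = _to_batch(images)
        if x.shape[2] != self.config.image_size:
            raise ClassifierError(
                f"expected {self.config.image_size}px input, got {x.shape[2]}"
            )
        return softmax(self.net.forward(x).astype(np.float64))

    def predict_level(self, image) -> tuple[int, np.ndarray]:
        """(level 1..4, probability vector) for a single image.

        Argmax of the probabilities; ties break toward the lower level.
        """
        probs = self.predict_proba(np.asarray(image)[None] if np.asarray(image).ndim == 3 else image)
        p = probs[0]
        return int(self.class_order[int(np.argmax(p))]), p

    def predict_levels(self, images) -> np.ndarray:
        probs = self.predict_proba(images)
        return np.asarray(self.class_order)[np.argmax(probs, axis=1)]

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.net.state_arrays()):
            h.update(self.net.state_arrays()[key].tobytes())
        return h.hexdigest()

    # -- serialization -------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) and a JSON sidecar next to it."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_arrays())
        sidecar = {
            "task": self.task,
            "class_order": list(self.class_order),
            "config": asdict(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        if self.history is not None:
            self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = ClassifierConfig(**sidecar["config"])
        net = build_network(config)
        with np.load(path.with_suffix(".npz")) as arrays:
            net.load_state(dict(arrays))
        history = None
        hist_path = path.with_suffix(".history.csv")
        if hist_path.exists():
            history = pd.read_csv(hist_path)
        return cls(
            task=sidecar["task"],
            config=config,
            net=net,
            class_order=tuple(sidecar["class_order"]),
            history=history,
        )


def _load_manifest_images(manifest: pd.DataFrame, size: int) -> np.ndarray:
    out = np.empty((len(manifest), size, size, 3), dtype=np.uint8)
    for i, path in enumerate(manifest["path"]):
        with Image.open(path) as img:
            out[i] = resize_input(img.convert("RGB"), size)
    return out


def train(
    config: ClassifierConfig,
    manifest: pd.DataFrame,
    task: Task,
    images: np.ndarray | None = None,
    validation_images: np.ndarray | None = None,
) -> TrainedClassifier:
    """Train one grader on the train split of a dataset manifest.

    The manifest must carry ``split`` and ``{mda,sh}_level`` columns (as
    written by the synthetic dataset builder).  ``images`` may supply
    the pixel data directly (aligned with the train split rows, in
    manifest order) to skip file I/O; otherwise images are read from
    ``manifest['path']``.

    Learning rate decays by ``lr_drop_factor`` every ``lr_drop_period``
    epochs; history records per-iteration minibatch loss/accuracy and
    per-epoch validation accuracy.
    """
    if task not in ("MDA", "SH"):
        raise ClassifierError(f"task must be 'MDA' or 'SH', got {task!r}")
    if len(manifest) == 0:
        raise ClassifierError("empty manifest")
    col = "mda_level" if task == "MDA" else "sh_level"
    tr = manifest[manifest["split"] == "train"]
    va = manifest[manifest["split"] == "validation"]
    if len(tr) == 0:
        raise ClassifierError("manifest has no train split")
    present = set(tr[col].astype(int))
    if present != {1, 2, 3, 4}:
        raise ClassifierError(
            f"train split must contain all 4 levels for task {task}; got {sorted(present)}"
        )

    if images is None:
        x_tr = _load_manifest_images(tr, config.image_size)
    else:
        x_tr = images
        if len(x_tr) != len(tr):
            raise ClassifierError("images must align with the train split rows")
    y_tr = tr[col].to_numpy(dtype=int) - 1
    if len(va) > 0:
        x_va = (
            _load_manifest_images(va, config.image_size)
            if validation_images is None
            else validation_images
        )
        y_va = va[col].to_numpy(dtype=int) - 1
    else:
        x_va = y_va = None

    net = build_network(config)
    optimizer = Adam(net.params(), lr=config.initial_learning_rate)
    rng = np.random.default_rng(config.seed)
    xb_all = _to_batch(x_tr)

    records = []
    iteration = 0
    for epoch in range(1, config.max_epochs + 1):
        optimizer.lr = config.initial_learning_rate * config.lr_drop_factor ** (
            (epoch - 1) // config.lr_drop_period
        )
        order = rng.permutation(len(y_tr))
        for start in range(0, len(order), config.minibatch_size):
            idx = order[start : start + config.minibatch_size]
            xb, yb = xb_all[idx], y_tr[idx]
            logits = net.forward(xb)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            net.backward(dlogits)
            optimizer.step()
            iteration += 1
            records.append(
                {
                    "iteration": iteration,
                    "epoch": epoch,
                    "loss": loss,
                    "accuracy": float((np.argmax(logits, axis=1) == yb).mean()),
                    "learning_rate": optimizer.lr,
                    "val_accuracy": np.nan,
                }
            )
        if x_va is not None:
            clf = TrainedClassifier(task=task, config=config, net=net)
            val_acc = float((clf.predict_levels(x_va) - 1 == y_va).mean())
            records[-1]["val_accuracy"] = val_acc

    return TrainedClassifier(
        task=task,
        config=config,
        net=net,
        history=pd.DataFrame.from_records(records),
    )
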