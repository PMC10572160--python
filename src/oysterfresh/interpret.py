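"""Model interpretability: activation maximization and activation maps.

Two classic visualizations of what a trained grader has learned:

* **Deep dream / activation maximization** — gradient ascent on the
  input image to maximize one class unit of the final fully connected
  layer, starting from seeded noise.  The resulting image caricatures
  the features the model associates with that freshness level.
* **Strongest activation map** — forward an image to the last
  convolutional layer, pick the channel with the largest activation,
  min-max normalize its spatial response to [0, 1] and upscale to the
  input size.  Dark pixels mark negative activation, bright pixels
  positive; bright regions are what the model keys on.

Regularization of the dream is deliberately minimal (mean-normalized
gradient steps plus occasional Gaussian smoothing); the goal is a
faithful, reproducible ascent, not gallery-quality art.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

from .classifier import N_CLASSES, TrainedClassifier, last_conv_index


class InterpretError(ValueError):
    """Invalid input to the visualization routines."""


@dataclass(frozen=True)
class DreamResult:
    """Outcome of activation maximization for one class unit."""

    class_index: int  # level 1..4
    image: np.ndarray  # (S, S, 3) float in [0, 1]
    iterations: int
    objective_trace: np.ndarray  # activation value per iteration (len = iters + 1)


@dataclass(frozen=True)
class ActivationMap:
    """Strongest-channel response of the last conv layer for one image."""

    channel_index: int
    map: np.ndarray  # (S, S) float in [0, 1]


def _check_model(model: TrainedClassifier) -> None:
    if not isinstance(model, TrainedClassifier):
        raise InterpretError("a TrainedClassifier is required")


def deep_dream(
    model: TrainedClassifier,
    class_index: int,
    iterations: int = 48,
    step_size: float = 0.02,
    seed: int = 0,
    smooth_every: int = 8,
    smooth_sigma: float = 0.5,
) -> DreamResult:
    """Gradient-ascent image maximizing one output unit.

    ``class_index`` is the freshness level 1..4.  Starts from low-
    contrast seeded noise around mid-gray; each step moves the image
    along the normalized input gradient of the class logit, with light
    Gaussian smoothing every ``smooth_every`` steps.  ``iterations=0``
    returns the initial noise unchanged.  Deterministic under ``seed``.
    """
    _check_model(model)
    if not 1 <= class_index <= N_CLASSES:
        raise InterpretError(f"class_index must be 1..{N_CLASSES}, got {class_index}")
    if iterations < 0:
        raise InterpretError("iterations must be >= 0")
    size = model.config.image_size
    rng = np.random.default_rng(seed)
    # network input units: pixel = unit * 0.25 + 0.35 (see _to_batch)
    x = rng.normal(0.0, 0.2, (1, 3, size, size)).astype(np.float32)
    unit = class_index - 1

    def objective(xa: np.ndarray) -> float:
        return float(model.net.forward(xa)[0, unit])

    trace = [objective(x)]
    for it in range(iterations):
        logits = model.net.forward(x)
        grad_out = np.zeros_like(logits)
        grad_out[0, unit] = 1.0
        gx = model.net.backward(grad_out)
        gx = gx / (np.abs(gx).mean() + 1e-8)
        x = x + step_size * gx.astype(np.float32)
        if smooth_every and (it + 1) % smooth_every == 0:
            x = gaussian_filter(x, sigma=(0, 0, smooth_sigma, smooth_sigma))
        x = np.clip(x, -1.4, 2.6)  # the [0, 1] pixel range in input units
        trace.append(objective(x))

    img = np.transpose(x[0] * 0.25 + 0.35, (1, 2, 0))
    return DreamResult(
        class_index=class_index,
        image=np.clip(img, 0, 1),
        iterations=iterations,
        objective_trace=np.asarray(trace),
    )


def strongest_activation(
    model: TrainedClassifier, image, layer_index: int | None = None
) -> ActivationMap:
    """Strongest-channel activation map of the last conv layer.

    The channel whose maximum activation is largest is selected (ties
    break toward the lower channel index); its raw response map —
    pre-ReLU, so negative activation is visible — is min-max
    normalized to [0, 1] and bilinearly upscaled to the input size.
    """
    _check_model(model)
    from .classifier import _to_batch

    x = _to_batch(np.asarray(image))
    if x.shape[0] != 1:
        raise InterpretError("strongest_activation takes a single image")
    if layer_index is None:
        layer_index = last_conv_index(model.net)
    else:
        from .nn import Conv2D

        if not 0 <= layer_index < len(model.net.layers) or not isinstance(
            model.net.layers[layer_index], Conv2D
        ):
            raise InterpretError(f"layer {layer_index} is not a convolutional layer")
    acts = model.net.forward_to(x, layer_index)[0]  # (C, h, w)
    channel = int(np.argmax(acts.max(axis=(1, 2))))
    raw = acts[channel].astype(np.float64)
    lo, hi = raw.min(), raw.max()
    norm = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    size = model.config.image_size
    scale = size / norm.shape[0]
    up = zoom(norm, scale, order=1)[:size, :size]
    return ActivationMap(channel_index=channel, map=np.clip(up, 0.0, 1.0))


def montage(image, amap: ActivationMap, path=None) -> np.ndarray:
    """Side-by-side (input | activation map) panel; optionally saved."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = (np.clip(img, 0, 1) * 255).astype(np.uint8)
    gray = (amap.map * 255).astype(np.uint8)
    panel = np.concatenate([img, np.stack([gray] * 3, axis=2)], axis=1)
    if path is not None:
        Image.fromarray(panel).save(path)
    return panel


def save_dream_grid(dreams: list[DreamResult], path) -> None:
    """Write the four class dreams side by side as one PNG."""
    imgs = [(np.clip(d.image, 0, 1) * 255).astype(np.uint8) for d in dreams]
    Image.fromarray(np.concatenate(imgs, axis=1)).save(path)
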