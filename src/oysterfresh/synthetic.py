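"""Synthetic oyster-meat imagery with storage-drifted appearance.

Half-shell oysters refrigerated for 0–14 days drift in appearance:
fresh meat is greenish, glossy and full-bodied; stale meat is darker,
drier, mucus-clouded and blurred in tissue structure.  This module
emulates that drift so the image graders and the fusion pipeline are
testable end to end: eight storage-day batches, per-image MDA/SH
values scattered around the batch means, and a procedurally rendered
oyster blob whose appearance channels follow the indicators.

Appearance encoding (synthetic convention, not biological truth):

* meat hue ramps green → brown and body fullness shrinks with the
  image's **MDA** score;
* brightness drops, specular gloss spots shrink/disappear, mucus
  cloudiness rises and blur increases with the image's **SH** score
  (SH falls as spoilage advances, so a high score means low SH).

Because each indicator drives its own channels, each 4-level grading
task is decodable from pixels, which is what makes desk-scale
training meaningful.  Renders are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .binning import build_level_scheme
from .surface import load_calibration

#: Calibration mean curves used by the score maps.  Indicator value ->
#: equivalent storage day (piecewise linear, extended 2 days past each
#: end by the edge slopes so values just outside the calibration range
#: do not saturate) -> score = (day + 2) / 18 in [0, 1].
_SCORE_DAYS = np.arange(-2.0, 17.0, 2.0)


def _extend(means: np.ndarray) -> np.ndarray:
    lo = means[0] - (means[1] - means[0])
    hi = means[-1] + (means[-1] - means[-2])
    return np.concatenate([[lo], means, [hi]])


_SCORE_MDA_MEANS = _extend(
    np.array([4.44, 4.84, 5.01, 5.99, 6.18, 6.74, 6.81, 7.24])
)
_SCORE_SH_MEANS = _extend(
    np.array([150.43, 134.09, 124.89, 112.16, 104.87, 103.25, 101.67, 98.17])
)

CAMERAS = ("iPhone XS Max", "iPhone 7 Plus", "Oppo R11", "Redmi Note 9 pro")

MANIFEST_COLUMNS = (
    "path", "day", "mda", "sh", "mda_level", "sh_level", "split", "camera",
)


class SyntheticError(ValueError):
    """Invalid input to the synthetic-data routines."""


@dataclass(frozen=True)
class BatchSpec:
    """One storage-day batch: day, batch-mean indicators, image count."""

    day: float
    mean_mda: float
    mean_sh: float
    n_images: int = 140

    def __post_init__(self) -> None:
        if self.mean_mda <= 0 or self.mean_sh <= 0:
            raise SyntheticError("batch means must be positive")
        if self.n_images < 1:
            raise SyntheticError("n_images must be >= 1")


def default_batches(n_images: int = 140) -> list[BatchSpec]:
    """Eight batches at days 0..14 with the packaged calibration means."""
    cal = load_calibration()
    return [
        BatchSpec(day=p.day, mean_mda=p.mda, mean_sh=p.sh, n_images=n_images)
        for p in cal.points
    ]


@dataclass(frozen=True)
class AppearanceParams:
    """Rendering schedule endpoints, fresh (score 0) → stale (score 1)."""

    fresh_color: tuple[float, float, float] = (0.29, 0.50, 0.31)
    stale_color: tuple[float, float, float] = (0.46, 0.28, 0.19)
    brightness_range: tuple[float, float] = (1.10, 0.45)
    gloss_count_range: tuple[int, int] = (7, 0)
    gloss_size_range: tuple[float, float] = (0.045, 0.02)  # fraction of size
    blur_sigma_range: tuple[float, float] = (0.4, 2.2)     # px at 64; scales
    fullness_range: tuple[float, float] = (1.0, 0.72)
    mucus_alpha_range: tuple[float, float] = (0.0, 0.40)
    noise_level: float = 0.008
    jitter: float = 0.03  # relative geometric jitter per image


def mda_score(mda) -> np.ndarray | float:
    """Spoilage score in [0, 1]: equivalent storage day / 14.

    Monotone piecewise-linear inversion of the calibration MDA-vs-day
    mean curve, clipped at the endpoints.  Indexing appearance by the
    equivalent day spreads the levels evenly even where the raw means
    crowd together.
    """
    d = np.interp(np.asarray(mda, dtype=float), _SCORE_MDA_MEANS, _SCORE_DAYS)
    return np.clip((d + 2.0) / 18.0, 0.0, 1.0)


def sh_score(sh) -> np.ndarray | float:
    """Spoilage score in [0, 1] from SH (falls as spoilage advances)."""
    d = np.interp(-np.asarray(sh, dtype=float), -_SCORE_SH_MEANS, _SCORE_DAYS)
    return np.clip((d + 2.0) / 18.0, 0.0, 1.0)


def sample_indicators(
    batch: BatchSpec, n: int, seed: int, cv: float = 0.08
) -> np.ndarray:
    """Draw n per-image (mda, sh) pairs for one batch.

    Gaussian around the batch means with coefficient of variation
    ``cv`` (default 8%), truncated positive by redrawing.  ``cv = 0``
    returns the exact means.  Reproducible under ``seed``.
    """
    if n < 1:
        raise SyntheticError(f"n must be >= 1, got {n}")
    if cv < 0:
        raise SyntheticError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.array([batch.mean_mda, batch.mean_sh])
    out = rng.normal(means, cv * means, size=(n, 2))
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        redraw = rng.normal(means, cv * means, size=(n, 2))
        out = np.where(bad, redraw, out)
    out[out <= 0] = means[None, :].repeat(n, axis=0)[out <= 0]  # pathological cv
    return out


def _lerp(a, b, t):
    return np.asarray(a) + (np.asarray(b) - np.asarray(a)) * t


def render_image(
    day: float | None,
    appearance: AppearanceParams = AppearanceParams(),
    size: int = 227,
    seed: int = 0,
    s_mda: float | None = None,
    s_sh: float | None = None,
) -> np.ndarray:
    """Render one synthetic oyster-on-half-shell image.

    Returns a (size, size, 3) uint8 RGB array.  Appearance follows the
    two spoilage scores in [0, 1]; if they are not given they default
    to ``day / 14`` (the nominal schedule).  Identical arguments give
    pixel-identical output.
    """
    if size < 64:
        raise SyntheticError(f"size must be >= 64, got {size}")
    if s_mda is None or s_sh is None:
        if day is None:
            raise SyntheticError("either day or both scores are required")
        s = float(np.clip(day / 14.0, 0.0, 1.0))
        s_mda = s if s_mda is None else s_mda
        s_sh = s if s_sh is None else s_sh
    s_mda = float(np.clip(s_mda, 0.0, 1.0))
    s_sh = float(np.clip(s_sh, 0.0, 1.0))
    rng = np.random.default_rng(seed)
    ap = appearance
    jit = ap.jitter

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size  # [0,1]

    # half shell: pale blue-gray elliptical dish on a dark table
    img = np.full((size, size, 3), 0.18, dtype=np.float32)
    cx, cy = 0.5 + rng.uniform(-jit, jit) * 0.4, 0.5 + rng.uniform(-jit, jit) * 0.4
    shell_a, shell_b = 0.47, 0.40
    r_shell = ((xx - cx) / shell_a) ** 2 + ((yy - cy) / shell_b) ** 2
    shell_color = np.array([0.58, 0.60, 0.62], dtype=np.float32)
    grad = (1.0 - 0.35 * r_shell)[..., None].astype(np.float32)
    img = np.where((r_shell <= 1.0)[..., None], shell_color * grad, img)

    # meat: ellipse shrinking with spoilage (fullness from both scores)
    fullness = _lerp(*ap.fullness_range, 0.5 * (s_mda + s_sh))
    a = 0.38 * fullness * (1 + rng.uniform(-jit, jit))
    b = 0.30 * fullness * (1 + rng.uniform(-jit, jit))
    theta = rng.uniform(-0.35, 0.35)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    r_meat = (xr / a) ** 2 + (yr / b) ** 2
    meat_mask = r_meat <= 1.0

    color = _lerp(ap.fresh_color, ap.stale_color, s_mda).astype(np.float32)
    brightness = float(_lerp(*ap.brightness_range, s_sh))
    meat = color[None, None, :] * brightness

    # low-frequency tissue texture
    tex = gaussian_filter(
        rng.normal(0, 1, (size, size)).astype(np.float32), sigma=size / 16
    )
    tex /= max(np.abs(tex).max(), 1e-6)
    meat = meat * (1 + 0.08 * tex)[..., None]

    # mucus cloudiness: desaturate toward same-luminance gray, so the
    # brightness schedule is not confounded
    mucus = float(_lerp(*ap.mucus_alpha_range, s_sh))
    gray = meat.mean(axis=2, keepdims=True)
    meat = (1 - mucus) * meat + mucus * gray

    img = np.where(meat_mask[..., None], meat, img)

    # specular gloss spots, fading with spoilage
    n_gloss = int(round(_lerp(*ap.gloss_count_range, s_sh)))
    gsize = float(_lerp(*ap.gloss_size_range, s_sh)) * size
    for _ in range(max(n_gloss, 0)):
        gx = cx + rng.uniform(-0.6, 0.6) * a
        gy = cy + rng.uniform(-0.6, 0.6) * b
        d2 = ((xx - gx) ** 2 + (yy - gy) ** 2) * size**2
        spot = np.exp(-d2 / (2 * gsize**2)).astype(np.float32)
        img += (0.55 * spot * meat_mask)[..., None]

    # adductor muscle: small pale oval, a consistent landmark
    mx, my = cx + 0.45 * a, cy
    r_mus = (((xx - mx) / (0.22 * a)) ** 2 + ((yy - my) / (0.28 * b)) ** 2)
    muscle = np.exp(-r_mus).astype(np.float32) * meat_mask
    img = img * (1 - 0.5 * muscle[..., None]) + 0.5 * muscle[..., None] * np.array(
        [0.78, 0.76, 0.70], dtype=np.float32
    )

    # blur (tissue definition lost with storage) and sensor noise
    sigma = float(_lerp(*ap.blur_sigma_range, s_sh)) * size / 64.0
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    if ap.noise_level > 0:
        img = img + rng.normal(0, ap.noise_level, img.shape).astype(np.float32)

    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def build_dataset(
    out_dir: str | Path,
    specs: Sequence[BatchSpec] | None = None,
    split_fractions: tuple[float, float, float] = (0.4, 0.1, 0.5),
    seed: int = 0,
    image_size: int = 227,
    labeled_count: int | None = 1044,
    cv: float = 0.08,
    appearance: AppearanceParams = AppearanceParams(),
) -> pd.DataFrame:
    """Generate the full labeled image dataset and its manifest.

    Renders every image of every batch, assigns 4-level labels by
    balanced quantile binning of the pooled per-image indicator values,
    randomly selects ``labeled_count`` images (default 1044 of the
    1120) and splits them train/validation/test by ``split_fractions``
    (default 40/10/50, largest-remainder rounding); the remainder get
    split ``"unused"``.  Writes PNGs plus ``manifest.csv`` into
    ``out_dir`` and returns the manifest frame.
    """
    if specs is None:
        specs = default_batches()
    if len(specs) == 0:
        raise SyntheticError("no batches given")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise SyntheticError("split_fractions must be 3 non-negatives summing to 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    for b, spec in enumerate(specs):
        pairs = sample_indicators(spec, spec.n_images, seed=int(rng.integers(2**31)), cv=cv)
        for i, (mda, sh) in enumerate(pairs):
            rows.append({"batch": b, "day": spec.day, "mda": mda, "sh": sh})
    df = pd.DataFrame(rows)

    mda_scheme = build_level_scheme(df["mda"].to_numpy(), "MDA")
    sh_scheme = build_level_scheme(df["sh"].to_numpy(), "SH")
    from .binning import level_of  # local import avoids a cycle at module load

    df["mda_level"] = level_of(mda_scheme, df["mda"].to_numpy())
    df["sh_level"] = level_of(sh_scheme, df["sh"].to_numpy())

    n = len(df)
    labeled = n if labeled_count is None else min(labeled_count, n)
    perm = rng.permutation(n)
    chosen = perm[:labeled]
    counts = np.floor(fr * labeled).astype(int)
    for k in np.argsort(-(fr * labeled - counts))[: labeled - counts.sum()]:
        counts[k] += 1
    split = np.full(n, "unused", dtype=object)
    split[chosen[: counts[0]]] = "train"
    split[chosen[counts[0] : counts[0] + counts[1]]] = "validation"
    split[chosen[counts[0] + counts[1] :]] = "test"
    df["split"] = split
    df["camera"] = rng.choice(CAMERAS, size=n)

    paths = []
    for i, row in df.iterrows():
        img = render_image(
            day=row["day"],
            appearance=appearance,
            size=image_size,
            seed=int(rng.integers(2**31)),
            s_mda=float(mda_score(row["mda"])),
            s_sh=float(sh_score(row["sh"])),
        )
        path = out_dir / "images" / f"oyster_d{int(row['day']):02d}_{i:04d}.png"
        Image.fromarray(img).save(path)
        paths.append(str(path))
    df["path"] = paths
    manifest = df[list(MANIFEST_COLUMNS)].copy()
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_images(manifest: pd.DataFrame, size: int | None = None) -> np.ndarray:
    """Read manifest images into an (N, S, S, 3) uint8 array."""
    from .classifier import resize_input

    first = np.asarray(Image.open(manifest["path"].iloc[0]).convert("RGB"))
    size = size or first.shape[0]
    out = np.empty((len(manifest), size, size, 3), dtype=np.uint8)
    for i, path in enumerate(manifest["path"]):
        with Image.open(path) as img:
            out[i] = resize_input(img.convert("RGB"), size)
    return out
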