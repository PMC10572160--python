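"""Synthetic dataset generator: indicators, rendering, manifest contract."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from oysterfresh.synthetic import (
    AppearanceParams,
    BatchSpec,
    SyntheticError,
    build_dataset,
    default_batches,
    load_images,
    mda_score,
    render_image,
    sample_indicators,
    sh_score,
)


def luminance(img):
    x = img.astype(float) / 255.0
    return (0.299 * x[..., 0] + 0.587 * x[..., 1] + 0.114 * x[..., 2]).mean()


def test_default_batches_follow_calibration():
    batches = default_batches()
    assert len(batches) == 8
    assert [b.day for b in batches] == [0, 2, 4, 6, 8, 10, 12, 14]
    assert all(b.n_images == 140 for b in batches)
    means = [b.mean_mda for b in batches]
    assert means == sorted(means)


def test_sample_indicators_statistics():
    batch = BatchSpec(day=0, mean_mda=4.44, mean_sh=150.43)
    pairs = sample_indicators(batch, 10_000, seed=1)
    assert pairs.shape == (10_000, 2)
    assert np.all(pairs > 0)
    assert pairs[:, 0].mean() == pytest.approx(4.44, rel=0.02)
    assert pairs[:, 1].mean() == pytest.approx(150.43, rel=0.02)


def test_sample_indicators_degenerate_and_deterministic():
    batch = BatchSpec(day=6, mean_mda=5.99, mean_sh=112.16)
    exact = sample_indicators(batch, 5, seed=3, cv=0.0)
    assert np.allclose(exact, [[5.99, 112.16]] * 5)
    a = sample_indicators(batch, 50, seed=9)
    b = sample_indicators(batch, 50, seed=9)
    assert np.array_equal(a, b)
    with pytest.raises(SyntheticError):
        sample_indicators(batch, 0, seed=1)


def test_scores_are_monotone_day_equivalents():
    m = mda_score(np.array([4.44, 5.99, 7.24]))
    assert np.all(np.diff(m) > 0)
    s = sh_score(np.array([150.43, 112.16, 98.17]))
    assert np.all(np.diff(s) > 0)  # spoilage score rises as SH falls
    assert mda_score(2.0) == 0.0 and mda_score(12.0) == 1.0  # clipped tails


def test_render_shape_and_size_contract():
    img = render_image(day=4, size=64, seed=0)
    assert img.shape == (64, 64, 3) and img.dtype == np.uint8
    big = render_image(day=4, size=96, seed=0)
    assert big.shape == (96, 96, 3)
    with pytest.raises(SyntheticError):
        render_image(day=4, size=32, seed=0)


def test_render_deterministic_under_seed():
    ap = AppearanceParams()
    a = render_image(day=8, appearance=ap, size=64, seed=5)
    b = render_image(day=8, appearance=ap, size=64, seed=5)
    assert np.array_equal(a, b)
    # noise- and blur-free renders are also pixel-identical
    quiet = AppearanceParams(noise_level=0.0, blur_sigma_range=(0.0, 0.0))
    c = render_image(day=8, appearance=quiet, size=64, seed=5)
    d = render_image(day=8, appearance=quiet, size=64, seed=5)
    assert np.array_equal(c, d)


def test_fresh_renders_brighter_than_stale():
    fresh = np.mean([luminance(render_image(0, size=64, seed=s)) for s in range(50)])
    stale = np.mean([luminance(render_image(14, size=64, seed=s)) for s in range(50)])
    assert fresh > stale + 0.05


def test_small_dataset_build_contract(tmp_path):
    specs = [
        BatchSpec(day=b.day, mean_mda=b.mean_mda, mean_sh=b.mean_sh, n_images=6)
        for b in default_batches()
    ]
    manifest = build_dataset(
        tmp_path, specs=specs, seed=4, image_size=64, labeled_count=40
    )
    assert len(manifest) == 48
    assert list(manifest.columns) == [
        "path", "day", "mda", "sh", "mda_level", "sh_level", "split", "camera",
    ]
    # every manifest row points at a real image
    for p in manifest["path"]:
        assert Path(p).exists()
    counts = manifest["split"].value_counts()
    assert counts.get("unused", 0) == 8
    assert counts["train"] + counts["validation"] + counts["test"] == 40
    # labels balanced by construction of the quartile split
    for col in ("mda_level", "sh_level"):
        sizes = manifest[col].value_counts()
        assert sizes.max() - sizes.min() <= 1
    # persisted manifest matches the returned frame
    on_disk = pd.read_csv(tmp_path / "manifest.csv")
    assert np.array_equal(on_disk["mda_level"], manifest["mda_level"])


def test_all_train_split(tmp_path):
    specs = [BatchSpec(day=0, mean_mda=4.44, mean_sh=150.43, n_images=8)]
    manifest = build_dataset(
        tmp_path, specs=specs, split_fractions=(1, 0, 0), seed=0,
        image_size=64, labeled_count=None,
    )
    assert (manifest["split"] == "train").all()


def test_build_dataset_input_validation(tmp_path):
    with pytest.raises(SyntheticError):
        build_dataset(tmp_path, specs=[], seed=0)
    with pytest.raises(SyntheticError):
        build_dataset(tmp_path, split_fractions=(0.5, 0.2, 0.2), seed=0)


def test_default_dataset_shape_and_splits(dataset):
    manifest = dataset["manifest"]
    assert len(manifest) == 1120
    assert manifest.groupby("day").size().eq(140).all()
    counts = manifest["split"].value_counts()
    # 1044 labeled at 40/10/50
    assert abs(counts["train"] - 419) <= 4
    assert abs(counts["validation"] - 103) <= 4
    assert abs(counts["test"] - 522) <= 4


def test_trivial_classifier_separability(dataset):
    """Mean hue-proxy + luminance alone must grade both tasks > 80%."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    manifest = dataset["manifest"]
    x = load_images(manifest).astype(float) / 255.0
    lum = (0.299 * x[..., 0] + 0.587 * x[..., 1] + 0.114 * x[..., 2]).mean(axis=(1, 2))
    green_red = (x[..., 1] - x[..., 0]).mean(axis=(1, 2))
    feats = np.column_stack([green_red, lum])
    tr = (manifest["split"] == "train").to_numpy()
    te = (manifest["split"] == "test").to_numpy()
    for col in ("mda_level", "sh_level"):
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=5000))
        clf.fit(feats[tr], manifest[col][tr])
        assert clf.score(feats[te], manifest[col][te]) > 0.80
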