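"""Two-tier freshness prediction: parallel graders feeding the surface.

Tier 1 runs the two 4-level image graders (MDA and SH) on an oyster
photograph; tier 2 maps each predicted level to its class-median
indicator value and evaluates the MDA-SH-day polynomial surface at
that pair.  The output is the triple (MDA content, SH content,
predicted storage day).  Because levels are discrete, the whole
image-to-output map factors through at most 16 (MDA level, SH level)
pairs.

"Paper mode" (default) maps levels through the frozen canonical
median table; "dataset mode" uses schemes fitted to a dataset's own
values.  Predicted days are reported unclamped — extrapolating level
pairs can yield negative or >14-day values.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .binning import PAPER_MEDIANS, LevelScheme, median_of_level
from .classifier import TrainedClassifier, resize_input
from .surface import SurfaceModel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the fusion pipeline failed; the stage is named."""


@dataclass(frozen=True)
class FreshnessPrediction:
    """Prediction triple for one image, plus the levels behind it."""

    mda_level: int
    sh_level: int
    mda: float  # nmol/mgprot (level median)
    sh: float  # umol/gprot (level median)
    predicted_day: float  # unclamped; may be negative
    elapsed_s: float = 0.0


def _medians(
    level: int,
    indicator: str,
    schemes: dict[str, LevelScheme] | None,
) -> float:
    if schemes is None:
        return median_of_level(PAPER_MEDIANS, level, indicator)
    return median_of_level(schemes[indicator], level)


def predict_freshness(
    mda_model: TrainedClassifier,
    sh_model: TrainedClassifier,
    surface: SurfaceModel,
    image,
    schemes: dict[str, LevelScheme] | None = None,
) -> FreshnessPrediction:
    """Level -> median -> surface composition for one image.

    ``schemes`` switches from the frozen median table (None, paper
    mode) to dataset-fitted schemes keyed ``{"MDA": ..., "SH": ...}``.
    """
    t0 = time.perf_counter()
    try:
        img = resize_input(image, mda_model.config.image_size)
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc
    try:
        mda_level, _ = mda_model.predict_level(img)
        sh_level, _ = sh_model.predict_level(img)
    except Exception as exc:
        raise PipelineError(f"stage classify: {exc}") from exc
    try:
        mda = _medians(mda_level, "MDA", schemes)
        sh = _medians(sh_level, "SH", schemes)
    except Exception as exc:
        raise PipelineError(f"stage level-median: {exc}") from exc
    try:
        day = float(surface.predict(mda, sh))
    except Exception as exc:
        raise PipelineError(f"stage surface: {exc}") from exc
    return FreshnessPrediction(
        mda_level=mda_level,
        sh_level=sh_level,
        mda=mda,
        sh=sh,
        predicted_day=day,
        elapsed_s=time.perf_counter() - t0,
    )


def batch_predict(
    mda_model: TrainedClassifier,
    sh_model: TrainedClassifier,
    surface: SurfaceModel,
    manifest: pd.DataFrame,
    schemes: dict[str, LevelScheme] | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """One prediction row per manifest image.

    Output columns: image, mda_level, sh_level, mda, sh, predicted_day
    and, when the manifest carries it, actual_day.  Unreadable rows are
    skipped with a logged warning.  Deterministic: identical inputs
    give an identical table.
    """
    rows = []
    has_day = "day" in manifest.columns
    for _, rec in manifest.iterrows():
        try:
            with Image.open(rec["path"]) as img:
                pred = predict_freshness(
                    mda_model, sh_model, surface, img.convert("RGB"), schemes
                )
        except (PipelineError, OSError) as exc:
            logger.warning("skipping %s: %s", rec.get("path"), exc)
            continue
        row = {
            "image": rec["path"],
            "mda_level": pred.mda_level,
            "sh_level": pred.sh_level,
            "mda": pred.mda,
            "sh": pred.sh,
            "predicted_day": round(pred.predicted_day, 2),
        }
        if has_day:
            row["actual_day"] = rec["day"]
        rows.append(row)
    if not rows:
        logger.warning("no readable images in manifest; returning empty table")
    columns = ["image", "mda_level", "sh_level", "mda", "sh", "predicted_day"] + (
        ["actual_day"] if has_day else []
    )
    table = pd.DataFrame(rows, columns=columns)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def reachable_predictions(surface: SurfaceModel) -> pd.DataFrame:
    """The 16 level-pair triples the pipeline can ever emit (paper mode)."""
    rows = []
    for ml in range(1, 5):
        for sl in range(1, 5):
            mda = median_of_level(PAPER_MEDIANS, ml, "MDA")
            sh = median_of_level(PAPER_MEDIANS, sl, "SH")
            rows.append(
                {
                    "mda_level": ml,
                    "sh_level": sl,
                    "mda": mda,
                    "sh": sh,
                    "predicted_day": round(float(surface.predict(mda, sh)), 2),
                }
            )
    return pd.DataFrame(rows)
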