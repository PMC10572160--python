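"""MDA-SH-storage-day polynomial surface.

Storage time of refrigerated oyster meat is modelled as a bivariate
polynomial in two spoilage indicators: malondialdehyde content
(MDA, ``x``, nmol/mgprot, rises with lipid oxidation) and total
sulfhydryl content (SH, ``y``, umol/gprot, falls with protein
oxidation).  The surface is the seven-term "poly31" family — degree 3
in MDA, degree 1 in SH:

    z = c0*x^3 + c1*x^2*y + c2*x^2 + c3*x*y + c4*x + c5*y + c6

fit by least squares to per-batch mean (MDA, SH, day) calibration
triples.  The canonical calibration set (eight batches, storage days
0..14 at 4 degrees C) ships with the package; see
:func:`load_calibration`.

A historically published coefficient vector for this surface is kept
as the documentary constant :data:`PUBLISHED_COEFFICIENTS`.  Applied
to raw concentrations it does not reproduce the predictions published
alongside it (it was evidently expressed in an unstated internal
coordinate system), so it is never used for prediction here; the
canonical model is always a refit.  Because any affine change of the
predictor coordinates spans the same seven-dimensional function
space, the refit surface is the unique least-squares surface for this
basis regardless of such scaling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Names of the poly31 basis terms, in coefficient order.
TERM_NAMES: tuple[str, ...] = ("x^3", "x^2*y", "x^2", "x*y", "x", "y", "1")

N_TERMS = len(TERM_NAMES)

#: Documentary fixture: the coefficient vector as originally published
#: (order matches TERM_NAMES). Kept for reference only — see module
#: docstring; never used for prediction.
PUBLISHED_COEFFICIENTS: tuple[float, ...] = (
    -1.779, -0.8836, 43.52, 0.9794, -319.3, -2.968, 769.8,
)

#: R-squared reported for the published fit.
PUBLISHED_R_SQUARED = 0.9946


class SurfaceError(ValueError):
    """Invalid input to the surface-fitting routines."""


class UnderdeterminedFitError(SurfaceError):
    """Fewer calibration points than basis terms."""


class RankDeficientError(SurfaceError):
    """Design matrix is rank deficient (collinear basis columns)."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One (MDA, SH, storage-day) calibration triple.

    Parameters
    ----------
    mda : float
        Malondialdehyde content, nmol/mgprot.  Must be positive.
    sh : float
        Total sulfhydryl content, umol/gprot.  Must be positive.
    day : float
        Storage time in days.  Must be non-negative.
    """

    mda: float
    sh: float
    day: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mda) and self.mda > 0):
            raise SurfaceError(f"mda must be finite and > 0, got {self.mda!r}")
        if not (math.isfinite(self.sh) and self.sh > 0):
            raise SurfaceError(f"sh must be finite and > 0, got {self.sh!r}")
        if not (math.isfinite(self.day) and self.day >= 0):
            raise SurfaceError(f"day must be finite and >= 0, got {self.day!r}")


@dataclass(frozen=True)
class CalibrationSet:
    """Ordered collection of calibration points."""

    points: tuple[CalibrationPoint, ...]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise SurfaceError("calibration set is empty")
        seen = {}
        for p in self.points:
            key = (p.mda, p.sh)
            if key in seen:
                raise SurfaceError(f"duplicate (mda, sh) pair {key}")
            seen[key] = p

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_arrays(
        cls,
        mda: Sequence[float],
        sh: Sequence[float],
        day: Sequence[float],
    ) -> "CalibrationSet":
        if not (len(mda) == len(sh) == len(day)):
            raise SurfaceError("mda, sh, day must have equal length")
        return cls(tuple(CalibrationPoint(m, s, d) for m, s, d in zip(mda, sh, day)))

    @property
    def mda(self) -> np.ndarray:
        return np.array([p.mda for p in self.points], dtype=float)

    @property
    def sh(self) -> np.ndarray:
        return np.array([p.sh for p in self.points], dtype=float)

    @property
    def day(self) -> np.ndarray:
        return np.array([p.day for p in self.points], dtype=float)


def load_calibration() -> CalibrationSet:
    """Load the packaged eight-batch calibration data.

    Batch-mean MDA and SH of oyster meat stored on the half shell at
    4 degrees C for 0, 2, ..., 14 days.
    """
    with resources.files("oysterfresh.data").joinpath(
        "calibration_batches.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return CalibrationSet.from_arrays(
        df["mda_nmol_per_mgprot"], df["sh_umol_per_gprot"], df["day"]
    )


def build_design_matrix(
    mda: np.ndarray | Sequence[float] | CalibrationSet,
    sh: np.ndarray | Sequence[float] | None = None,
) -> np.ndarray:
    """Evaluate the poly31 basis at each point.

    Accepts either a :class:`CalibrationSet` or two equal-length arrays.
    Returns an ``(n, 7)`` matrix with columns ``[x^3, x^2*y, x^2, x*y,
    x, y, 1]`` in that order.
    """
    if isinstance(mda, CalibrationSet):
        x, y = mda.mda, mda.sh
    else:
        x = np.atleast_1d(np.asarray(mda, dtype=float))
        y = np.atleast_1d(np.asarray(sh, dtype=float))
    if x.size == 0:
        raise SurfaceError("no points to build a design matrix from")
    if x.shape != y.shape:
        raise SurfaceError("mda and sh arrays must have equal shape")
    return np.column_stack(
        [x**3, x**2 * y, x**2, x * y, x, y, np.ones_like(x)]
    )


@dataclass
class SurfaceModel:
    """Fitted poly31 surface.

    Attributes
    ----------
    coefficients : ndarray, shape (7,)
        Multipliers of the basis terms in :data:`TERM_NAMES` order.
    r_squared : float
        1 - SSE/SST on the fitting data, SST about the mean of z.
    centering : ((mx, sx), (my, sy))
        Affine transform applied to each predictor before building
        monomials; identity ``((0, 1), (0, 1))`` by default.  Fits in a
        centered coordinate system represent the *same* surface (the
        centered basis spans the same function space); the transform is
        stored so prediction is exact either way.
    fit_bounds : ((mda_min, mda_max), (sh_min, sh_max)) or None
        Bounding box of the calibration predictors, used to notice
        extrapolation at predict time.
    """

    coefficients: np.ndarray
    r_squared: float
    centering: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 1.0),
        (0.0, 1.0),
    )
    fit_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (N_TERMS,):
            raise SurfaceError(
                f"expected {N_TERMS} coefficients, got {self.coefficients.shape}"
            )
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise SurfaceError(f"r_squared outside [0, 1]: {self.r_squared}")

    # -- prediction ----------------------------------------------------

    def predict(self, mda, sh):
        """Predicted storage day at (MDA, SH).

        Scalar in, scalar out; array in, array out.  The raw polynomial
        value is returned — it may be negative or exceed the calibration
        range, and no clamping is applied.  Evaluation outside the
        calibration bounding box is legitimate but logged at INFO level.
        """
        x = np.asarray(mda, dtype=float)
        y = np.asarray(sh, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise SurfaceError("mda and sh must be finite")
        if self.fit_bounds is not None:
            (x0, x1), (y0, y1) = self.fit_bounds
            if np.any(x < x0) or np.any(x > x1) or np.any(y < y0) or np.any(y > y1):
                logger.info(
                    "evaluating surface outside calibration range "
                    "mda=[%.4g, %.4g], sh=[%.4g, %.4g]", x0, x1, y0, y1,
                )
        (mx, sx), (my, sy) = self.centering
        xh = (x - mx) / sx
        yh = (y - my) / sy
        scalar = xh.ndim == 0
        design = build_design_matrix(np.atleast_1d(xh), np.atleast_1d(yh))
        z = design @ self.coefficients
        return float(z[0]) if scalar else z

    __call__ = predict

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "poly31",
                "terms": list(TERM_NAMES),
                "coefficients": self.coefficients.tolist(),
                "r_squared": self.r_squared,
                "centering": [list(self.centering[0]), list(self.centering[1])],
                "fit_bounds": None
                if self.fit_bounds is None
                else [list(self.fit_bounds[0]), list(self.fit_bounds[1])],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SurfaceModel":
        doc = json.loads(text)
        bounds = doc.get("fit_bounds")
        return cls(
            coefficients=np.array(doc["coefficients"], dtype=float),
            r_squared=float(doc["r_squared"]),
            centering=(
                tuple(doc["centering"][0]),
                tuple(doc["centering"][1]),
            ),
            fit_bounds=None
            if bounds is None
            else (tuple(bounds[0]), tuple(bounds[1])),
        )


def _name_collinear_columns(design: np.ndarray) -> list[str]:
    """Identify basis columns past the numerical rank via pivoted QR."""
    from scipy.linalg import qr

    _, _, piv = qr(design, pivoting=True)
    rank = np.linalg.matrix_rank(design)
    return [TERM_NAMES[j] for j in sorted(piv[rank:])]


def fit_surface(points: CalibrationSet, center_scale: bool = False) -> SurfaceModel:
    """Least-squares fit of the poly31 surface to calibration triples.

    Solved through numpy's SVD-based ``lstsq`` rather than the normal
    equations: on raw concentrations the design matrix is ill
    conditioned (x^3 vs 1 spans several orders of magnitude) and an
    orthogonal decomposition is numerically stable.

    Parameters
    ----------
    points : CalibrationSet
        At least 7 triples (one per basis term).
    center_scale : bool
        If True, z-score each predictor before building the monomials.
        The fitted *surface* is identical either way (same function
        space); only the coefficient parametrization changes.
    """
    n = len(points)
    if n < N_TERMS:
        raise UnderdeterminedFitError(
            f"need at least {N_TERMS} points for a {N_TERMS}-term fit, got {n}"
        )
    x, y, z = points.mda, points.sh, points.day
    if center_scale:
        mx, sx = float(x.mean()), float(x.std(ddof=1))
        my, sy = float(y.mean()), float(y.std(ddof=1))
        if sx == 0 or sy == 0:
            raise SurfaceError("cannot scale a constant predictor")
        centering = ((mx, sx), (my, sy))
    else:
        centering = ((0.0, 1.0), (0.0, 1.0))
    (mx, sx), (my, sy) = centering
    design = build_design_matrix((x - mx) / sx, (y - my) / sy)
    rank = np.linalg.matrix_rank(design)
    if rank < N_TERMS:
        bad = _name_collinear_columns(design)
        raise RankDeficientError(
            f"design matrix rank {rank} < {N_TERMS}; collinear columns: {bad}"
        )
    coef, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
    fitted = design @ coef
    sse = float(np.sum((z - fitted) ** 2))
    sst = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return SurfaceModel(
        coefficients=coef,
        r_squared=min(max(r2, 0.0), 1.0),
        centering=centering,
        fit_bounds=(
            (float(x.min()), float(x.max())),
            (float(y.min()), float(y.max())),
        ),
    )


def evaluate_surface(model: SurfaceModel, mda, sh):
    """Functional alias for :meth:`SurfaceModel.predict`."""
    return model.predict(mda, sh)
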