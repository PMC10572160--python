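"""Four-level freshness labelling by balanced quantile groups.

Indicator measurements (MDA or SH) are sorted — MDA ascending, SH
descending, so that level 1 is always the freshest — and split into
four groups of equal count ("data balance": group sizes differ by at
most one).  Each group's median becomes the class-representative
value used to label images and, downstream, to feed the day-predicting
surface.

The canonical level medians obtained from the original 280-sample
assay campaign ship as the read-only fixture :data:`PAPER_MEDIANS`;
schemes built from data are used for synthetic inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Indicator = Literal["MDA", "SH"]

#: Frozen level-median table: level 1 (freshest) .. level 4.
#: MDA in nmol/mgprot (ascending), SH in umol/gprot (descending).
PAPER_MEDIANS: dict[str, tuple[float, float, float, float]] = {
    "MDA": (3.30, 5.15, 6.25, 10.20),
    "SH": (163.98, 119.19, 106.42, 66.37),
}

N_LEVELS = 4


class BinningError(ValueError):
    """Invalid input to the level-binning routines."""


class DegenerateSchemeError(BinningError):
    """All input values identical — no four-level split exists."""


def _check_indicator(indicator: str) -> Indicator:
    if indicator not in ("MDA", "SH"):
        raise BinningError(f"indicator must be 'MDA' or 'SH', got {indicator!r}")
    return indicator  # type: ignore[return-value]


@dataclass(frozen=True)
class LevelScheme:
    """Quartile-group labelling scheme for one indicator.

    ``boundaries`` are the three cut values between consecutive groups
    on the *sorted* axis; for MDA (ascending) a value belongs to the
    lowest level whose boundary it does not exceed, for SH (descending)
    the comparison is reversed.  Values equal to a boundary go to the
    lower level index; values beyond the observed range clamp to the
    extreme levels.
    """

    indicator: Indicator
    sort_order: Literal["ascending", "descending"]
    boundaries: tuple[float, float, float]
    medians: tuple[float, float, float, float]
    group_sizes: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        med = np.asarray(self.medians)
        if self.sort_order == "ascending":
            ok = bool(np.all(np.diff(med) > 0))
        else:
            ok = bool(np.all(np.diff(med) < 0))
        if not ok:
            raise DegenerateSchemeError(
                f"medians {self.medians} are not strictly monotone for "
                f"{self.sort_order} sort order"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "indicator": self.indicator,
                "sort_order": self.sort_order,
                "boundaries": list(self.boundaries),
                "medians": list(self.medians),
                "group_sizes": list(self.group_sizes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LevelScheme":
        d = json.loads(text)
        return cls(
            indicator=d["indicator"],
            sort_order=d["sort_order"],
            boundaries=tuple(d["boundaries"]),
            medians=tuple(d["medians"]),
            group_sizes=tuple(d["group_sizes"]),
        )


def _group_slices(n: int) -> list[tuple[int, int]]:
    # Remainder goes to the earliest groups: sizes ceil(n/4) first.
    base, rem = divmod(n, N_LEVELS)
    sizes = [base + (1 if k < rem else 0) for k in range(N_LEVELS)]
    out, start = [], 0
    for s in sizes:
        out.append((start, start + s))
        start += s
    return out


def build_level_scheme(
    values: Sequence[float] | np.ndarray, indicator: Indicator
) -> LevelScheme:
    """Split sorted indicator values into 4 balanced groups.

    MDA values are sorted ascending and SH values descending, so level
    1 is the freshest group either way (lowest MDA / highest SH).  Ties
    at group boundaries are broken by stable sort position, keeping the
    group counts balanced even with duplicated values.
    """
    _check_indicator(indicator)
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < N_LEVELS:
        raise BinningError(f"need at least {N_LEVELS} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise BinningError("values must be finite")
    if np.unique(v).size < 2:
        raise DegenerateSchemeError("all values identical; no level split exists")
    ascending = indicator == "MDA"
    order = np.sort(v, kind="stable")
    if not ascending:
        order = order[::-1]
    slices = _group_slices(v.size)
    medians = tuple(float(np.median(order[a:b])) for a, b in slices)
    # Boundary between group k and k+1: midpoint of the adjacent values.
    boundaries = tuple(
        float((order[b - 1] + order[b]) / 2.0) for _, b in slices[:-1]
    )
    return LevelScheme(
        indicator=indicator,
        sort_order="ascending" if ascending else "descending",
        boundaries=boundaries,  # type: ignore[arg-type]
        medians=medians,  # type: ignore[arg-type]
        group_sizes=tuple(b - a for a, b in slices),  # type: ignore[arg-type]
    )


def level_of(scheme: LevelScheme, value) -> int | np.ndarray:
    """Level index 1..4 for a measurement (scalar or array).

    Boundary-equal values go to the lower level index; values beyond
    the observed range clamp to level 1 or 4.
    """
    v = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(v)):
        raise BinningError("value must be finite")
    b = np.asarray(scheme.boundaries)
    if scheme.sort_order == "ascending":
        # level = 1 + #{boundaries strictly below v}; boundary-equal
        # values therefore land in the lower level.
        lev = 1 + np.searchsorted(b, v, side="left")
    else:
        # descending axis: level = 1 + #{boundaries strictly above v}.
        bd = b[::-1]  # ascending order for searchsorted
        lev = 1 + (bd.size - np.searchsorted(bd, v, side="right"))
    lev = np.clip(lev, 1, N_LEVELS)
    return int(lev) if np.isscalar(value) or np.ndim(value) == 0 else lev


def median_of_level(
    scheme_or_fixture: LevelScheme | dict | None,
    level: int,
    indicator: Indicator | None = None,
) -> float:
    """Class-representative (median) value for a level.

    Accepts a fitted :class:`LevelScheme`, the :data:`PAPER_MEDIANS`
    fixture dict (then ``indicator`` is required), or ``None`` as a
    shorthand for the fixture.
    """
    if not (isinstance(level, (int, np.integer)) and 1 <= level <= N_LEVELS):
        raise BinningError(f"level must be an integer in 1..{N_LEVELS}, got {level!r}")
    if isinstance(scheme_or_fixture, LevelScheme):
        return scheme_or_fixture.medians[level - 1]
    table = PAPER_MEDIANS if scheme_or_fixture is None else scheme_or_fixture
    if indicator is None:
        raise BinningError("indicator is required with a median table")
    _check_indicator(indicator)
    return float(table[indicator][level - 1])
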