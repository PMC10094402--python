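"""Mast-cell histomorphometry statistics.

Mast cells in toluidine-blue-stained sections of the rat upper-lip dermis
are counted in the first three high representative fields (HRF; 400x,
0.95 mm^2) of a section and averaged.  A cell with three or more granules
outside the cell body counts as degranulated (that classification happens
upstream at the microscope; this module ingests already-classified
counts).  Degranulation inhibition by a pretreatment is

    I% = 100 * (control_degranulated - treated_degranulated) / control_degranulated

and the degranulation-pain relationship is assessed with Pearson's r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

HRF_AREA_MM2 = 0.95
N_FIELDS = 3
TIME_POINTS = ("5 min", "25 min", "24 h")


@dataclass(frozen=True)
class MastCellField:
    """Counts in one high representative field."""

    total: int
    degranulated: int
    field_area: float = HRF_AREA_MM2

    def __post_init__(self) -> None:
        if self.total < 0 or self.degranulated < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.degranulated > self.total:
            raise ValidationError(
                f"degranulated count {self.degranulated} exceeds total {self.total}"
            )
        if self.field_area <= 0:
            raise ValidationError("field area must be positive")


@dataclass(frozen=True)
class MastCellSample:
    """Per-rat averaged counts over the first three HRFs at one time point."""

    rat_id: str
    group_label: str
    time_point: str
    fields: tuple[MastCellField, ...]

    def __post_init__(self) -> None:
        if len(self.fields) != N_FIELDS:
            raise ValidationError(
                f"rat {self.rat_id!r}: expected {N_FIELDS} fields, got {len(self.fields)}"
            )
        if self.time_point not in TIME_POINTS and self.time_point != "naive":
            raise ValidationError(
                f"unknown time point {self.time_point!r}; expected one of {TIME_POINTS} or 'naive'"
            )

    @property
    def mean_total(self) -> float:
        return average_fields(self)[0]

    @property
    def mean_degranulated(self) -> float:
        return average_fields(self)[1]


def average_fields(sample: MastCellSample) -> tuple[float, float]:
    """Arithmetic mean (unrounded) of total and degranulated counts over
    the sample's three fields."""
    totals = [f.total for f in sample.fields]
    degran = [f.degranulated for f in sample.fields]
    return float(np.mean(totals)), float(np.mean(degran))


def degranulation_inhibition(
    control_degranulated: float, treated_degranulated: float
) -> float:
    """Percent inhibition I% of mast-cell degranulation by a pretreatment;
    negative when the treatment increases degranulation."""
    if control_degranulated == 0:
        raise UndefinedStatisticError("I% undefined: control degranulated count is zero")
    return 100.0 * (control_degranulated - treated_degranulated) / control_degranulated


def correlate_degranulation_pain(
    degranulated: Sequence[float], pain_s: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between per-rat degranulated counts and phase
    pain times; two-sided p from the t transform with n-2 df.

    With the study's n = 6, |r| must exceed ~0.811 for p < 0.05.
    """
    x = np.asarray(degranulated, dtype=float)
    y = np.asarray(pain_s, dtype=float)
    if len(x) != len(y):
        raise ValidationError("paired observations required")
    if len(x) < 3:
        raise ValidationError(f"need >= 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: a variable has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pair_by_rat_id(
    degran_by_rat: dict[str, float], pain_by_rat: dict[str, float]
) -> tuple[list[float], list[float], list[str]]:
    """Match histology and behavior cohorts by rat id; unmatched rats are
    dropped (returned for logging).  Positional pairing across separate
    cohorts is the caller's alternative."""
    shared = sorted(set(degran_by_rat) & set(pain_by_rat))
    unmatched = sorted(set(degran_by_rat) ^ set(pain_by_rat))
    return [degran_by_rat[r] for r in shared], [pain_by_rat[r] for r in shared], unmatched


def pearson_significance_threshold(n: int, alpha: float = 0.05) -> float:
    """|r| above which the two-sided Pearson p-value drops below alpha at
    sample size n (t transform, n-2 df)."""
    if n < 3:
        raise ValidationError("n must be >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / math.sqrt(t**2 + (n - 2)))
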