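"""Behavioral data model for the orofacial formalin test.

A rat's nociceptive response (face rubbing/scratching after a formalin
injection into the upper lip) is scored as the time in seconds spent on
pain-related behavior in fifteen consecutive 3-minute bins (45 min total).
Bins 1-3 form phase 1 (0-9 min, acute nociceptive pain from direct
nociceptor activation); bins 4-15 form phase 2 (9-45 min, inflammatory
pain with central sensitization).

Antinociceptive activity of a treatment is expressed per rat as

    AA% = 100 * (control_rubbing_time - post_drug_rubbing_time) / control_rubbing_time

where the control rubbing time is the mean phase total of the concurrent
vehicle (0.9% NaCl + formalin) group.  Percent inhibition of one drug's
effect by a co-administered adjuvant is

    %I = 100 - 100 * (AA% with adjuvant) / (AA% without adjuvant)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import UndefinedStatisticError, ValidationError

N_BINS = 15
BIN_SECONDS = 180.0  # 3-minute bins
PHASE1_SLICE = slice(0, 3)   # bins 1-3, 0-9 min
PHASE2_SLICE = slice(3, 15)  # bins 4-15, 9-45 min

Phase = Literal[1, 2]


@dataclass(frozen=True)
class RubbingRecord:
    """One rat's 15-bin face-rubbing time course with treatment metadata.

    Parameters
    ----------
    rat_id : str
        Unique animal identifier.
    group_label : str
        Treatment group label (e.g. ``"CG5+MS5"``).
    cg_dose : float
        Cromoglycate dose in mg/kg (>= 0).
    ms_dose : float
        Magnesium sulfate dose in mg/kg (>= 0).
    bins : tuple of float
        Fifteen rubbing durations in seconds; bin k covers
        [3(k-1), 3k) minutes and cannot exceed 180 s.
    """

    rat_id: str
    group_label: str
    cg_dose: float
    ms_dose: float
    bins: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bins) != N_BINS:
            raise ValidationError(
                f"rat {self.rat_id!r}: expected {N_BINS} bins, got {len(self.bins)}"
            )
        for k, b in enumerate(self.bins, start=1):
            if not math.isfinite(b) or b < 0.0 or b > BIN_SECONDS:
                raise ValidationError(
                    f"rat {self.rat_id!r}: bin {k} duration {b!r} outside [0, {BIN_SECONDS:g}] s"
                )
        for name, dose in (("cg_dose", self.cg_dose), ("ms_dose", self.ms_dose)):
            if not math.isfinite(dose) or dose < 0.0:
                raise ValidationError(
                    f"rat {self.rat_id!r}: {name} must be a non-negative finite number, got {dose!r}"
                )

    @property
    def total_s(self) -> float:
        return float(sum(self.bins))


@dataclass(frozen=True)
class PhaseSummary:
    """Per-rat phase totals and (optionally) antinociceptive activity."""

    rat_id: str
    phase1_s: float
    phase2_s: float
    aa_phase1_pct: float | None = None
    aa_phase2_pct: float | None = None

    def phase_total(self, phase: Phase) -> float:
        return self.phase1_s if phase == 1 else self.phase2_s

    def aa_pct(self, phase: Phase) -> float | None:
        return self.aa_phase1_pct if phase == 1 else self.aa_phase2_pct


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD of a phase total over the rats of one group."""

    group_label: str
    phase: Phase
    n: int
    mean_s: float
    sd_s: float


def phase_totals(record: RubbingRecord) -> PhaseSummary:
    """Sum the 15-bin time course into phase-1 (bins 1-3) and phase-2
    (bins 4-15) totals.  AA fields are left unset."""
    bins = np.asarray(record.bins, dtype=float)
    return PhaseSummary(
        rat_id=record.rat_id,
        phase1_s=float(bins[PHASE1_SLICE].sum()),
        phase2_s=float(bins[PHASE2_SLICE].sum()),
    )


def antinociceptive_activity(control_s: float, post_drug_s: float) -> float:
    """Antinociceptive activity AA% of a treatment against the vehicle control.

    ``100 * (control_s - post_drug_s) / control_s``: 100 for complete
    suppression, 0 for no effect, negative for a pro-nociceptive response.
    """
    if control_s == 0:
        raise UndefinedStatisticError("AA% undefined: control rubbing time is zero")
    if control_s < 0 or post_drug_s < 0:
        raise ValidationError("rubbing times must be non-negative")
    return 100.0 * (control_s - post_drug_s) / control_s


def percent_inhibition(aa_with_mg: float, aa_without_mg: float) -> float:
    """Percent inhibition %I of a drug's antinociceptive effect by an adjuvant.

    ``100 - 100 * aa_with_mg / aa_without_mg``; values above 100 (the
    combination reverses the effect) are returned unclamped.
    """
    if aa_without_mg == 0:
        raise UndefinedStatisticError("%I undefined: AA% without adjuvant is zero")
    return 100.0 - 100.0 * aa_with_mg / aa_without_mg


def summarize_group(
    summaries: Sequence[PhaseSummary], phase: Phase, group_label: str = ""
) -> GroupSummary:
    """Mean and sample SD (n-1 denominator; 0 for a singleton) of one
    group's phase totals."""
    if len(summaries) == 0:
        raise ValidationError("cannot summarize an empty group")
    values = np.array([s.phase_total(phase) for s in summaries], dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return GroupSummary(
        group_label=group_label,
        phase=phase,
        n=len(values),
        mean_s=float(values.mean()),
        sd_s=sd,
    )


def attach_aa(
    summaries: Iterable[PhaseSummary],
    control_mean_phase1_s: float,
    control_mean_phase2_s: float,
) -> list[PhaseSummary]:
    """Fill the AA% fields of per-rat summaries using the vehicle group's
    mean phase totals as the control rubbing times."""
    out = []
    for s in summaries:
        out.append(
            replace(
                s,
                aa_phase1_pct=antinociceptive_activity(control_mean_phase1_s, s.phase1_s),
                aa_phase2_pct=antinociceptive_activity(control_mean_phase2_s, s.phase2_s),
            )
        )
    return out


def phase_summaries_with_aa(
    records: Sequence[RubbingRecord],
) -> dict[str, list[PhaseSummary]]:
    """Phase totals plus per-rat AA% for a full study table.

    The vehicle control group is identified as the rats with both doses
    zero; its mean phase totals are the AA% denominators for every rat
    (including the controls themselves, whose AA% then scatters around 0).

    Returns a mapping of group label -> per-rat summaries with AA filled.
    """
    controls = [r for r in records if r.cg_dose == 0 and r.ms_dose == 0]
    if not controls:
        raise ValidationError("no vehicle control group (cg_dose == ms_dose == 0) in table")
    ctrl_totals = [phase_totals(r) for r in controls]
    c1 = float(np.mean([s.phase1_s for s in ctrl_totals]))
    c2 = float(np.mean([s.phase2_s for s in ctrl_totals]))
    grouped: dict[str, list[PhaseSummary]] = {}
    for r in records:
        s = attach_aa([phase_totals(r)], c1, c2)[0]
        grouped.setdefault(r.group_label, []).append(s)
    return grouped
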