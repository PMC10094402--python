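"""Synthetic per-rat study generator.

Emulates the statistical structure of an orofacial formalin interaction
study so every pipeline stage is testable without animal data:

* a biphasic face-rubbing template (phase-1 burst in bins 1-2, a quiet
  bin 3, a phase-2 plateau over bins 4-15) for the formalin + vehicle
  control rat;
* a dose-dependent Emax-type drug (cromoglycate): per-phase hyperbolic
  effect ``Emax * D^h / (D^h + ED50^h)``, phase 2 reaching full efficacy
  (Emax 100%, ED50 7 mg/kg), phase 1 submaximal (Emax 55%, ED50
  2.35 mg/kg);
* a dose-independent low-efficacy adjuvant (magnesium sulfate): a flat
  ~40% effect in phase 2, negligible in phase 1, at any tested dose;
* an interaction mode that leaves cromoglycate potency untouched (null),
  multiplies it (potentiate) or divides it (inhibit) when magnesium is
  co-administered;
* Poisson/binomial mast-cell fields calibrated to ~212 total and ~3
  degranulated cells per high representative field in naive dermis, a
  formalin degranulation surge, and magnesium inhibition of ~23%/40% at
  the 5/25 min time points only.

Noise is multiplicative lognormal on bin durations (rubbing times are
nonnegative and right-skewed), parameterized by a coefficient of
variation; an additive-normal mode exists for ANOVA calibration work.
Every draw is keyed by (seed, doses, group, rat index) through a
counter-style ``SeedSequence``, so adding a group never perturbs another
group's rats and regeneration is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BIN_SECONDS, N_BINS, RubbingRecord
from .errors import ValidationError
from .histomorphometry import MastCellField, MastCellSample

DEFAULT_CONTROL_COURSE = (55.0, 40.0, 8.0) + (30.0,) * 12  # ~103 s phase 1, 360 s phase 2


@dataclass(frozen=True)
class CGCurve:
    """Hyperbolic (Emax-type) cromoglycate effect per phase."""

    emax_phase1: float = 55.0
    emax_phase2: float = 100.0
    ed50_phase1: float = 2.35
    ed50_phase2: float = 7.0
    hill: float = 1.0

    def effect(self, dose: float, phase: int) -> float:
        if dose <= 0:
            return 0.0
        emax = self.emax_phase1 if phase == 1 else self.emax_phase2
        ed50 = self.ed50_phase1 if phase == 1 else self.ed50_phase2
        dh = dose**self.hill
        return emax * dh / (dh + ed50**self.hill)


@dataclass(frozen=True)
class MSEffect:
    """Dose-independent magnesium sulfate effect per phase (any dose > 0)."""

    phase1: float = 10.0
    phase2: float = 40.0

    def effect(self, dose: float, phase: int) -> float:
        if dose <= 0:
            return 0.0
        return self.phase1 if phase == 1 else self.phase2


@dataclass(frozen=True)
class MastCellConfig:
    """Calibration of the Poisson/binomial mast-cell field model."""

    naive_total: float = 212.0
    naive_degran: float = 3.0
    formalin_degran_multiplier: float = 8.0
    degran_multiplier_24h: float = 5.0
    vehicle_degran_multiplier_5min: float = 2.0
    formalin_total_reduction: dict[str, float] = field(
        default_factory=lambda: {"5 min": 0.15, "25 min": 0.25, "24 h": 0.439}
    )
    vehicle_total_reduction_5min: float = 0.10
    ms_extra_total_reduction_5min: float = 0.10
    ms_inhibition_5min: float = 0.23
    ms_inhibition_25min: float = 0.40
    ms_inhibition_24h: float = 0.0

    def inhibition(self, time_point: str) -> float:
        return {
            "5 min": self.ms_inhibition_5min,
            "25 min": self.ms_inhibition_25min,
            "24 h": self.ms_inhibition_24h,
        }[time_point]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: one seed fixes the entire output stream."""

    seed: int = 0
    n_per_group: int = 6
    control_course: tuple[float, ...] = DEFAULT_CONTROL_COURSE
    noise_cv: float = 0.15
    noise_model: str = "lognormal"  # or "normal" (additive, for ANOVA calibration)
    cg_curve: CGCurve = field(default_factory=CGCurve)
    ms_effect: MSEffect = field(default_factory=MSEffect)
    interaction_mode: str = "null"  # null | potentiate | inhibit
    interaction_magnitude: float = 0.0
    mastcell: MastCellConfig = field(default_factory=MastCellConfig)

    def __post_init__(self) -> None:
        if len(self.control_course) != N_BINS:
            raise ValidationError(f"control_course needs {N_BINS} bins")
        if any(b < 0 or b > BIN_SECONDS for b in self.control_course):
            raise ValidationError(f"control_course bins must lie in [0, {BIN_SECONDS:g}]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.noise_model not in ("lognormal", "normal"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.interaction_mode not in ("null", "potentiate", "inhibit"):
            raise ValidationError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.cg_curve.ed50_phase1 <= 0 or self.cg_curve.ed50_phase2 <= 0:
            raise ValidationError("ED50s must be > 0")
        for pct in (
            self.cg_curve.emax_phase1,
            self.cg_curve.emax_phase2,
            self.ms_effect.phase1,
            self.ms_effect.phase2,
        ):
            if not (-100.0 <= pct <= 100.0):
                raise ValidationError(f"effect percent {pct!r} outside [-100, 100]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "control_course" in d:
            d["control_course"] = tuple(d["control_course"])
        if isinstance(d.get("cg_curve"), dict):
            d["cg_curve"] = CGCurve(**d["cg_curve"])
        if isinstance(d.get("ms_effect"), dict):
            d["ms_effect"] = MSEffect(**d["ms_effect"])
        if isinstance(d.get("mastcell"), dict):
            d["mastcell"] = MastCellConfig(**d["mastcell"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _rat_rng(config: ScenarioConfig, stream: str, group_label: str, rat_index: int) -> np.random.Generator:
    """Independent, reproducible stream per (seed, stream, group, rat)."""
    key = zlib.crc32(f"{stream}|{group_label}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key, rat_index]))


def combined_effect(config: ScenarioConfig, cg_dose: float, ms_dose: float, phase: int) -> float:
    """Deterministic combined AA% of the two drugs for one phase.

    The interaction mode rescales cromoglycate's effective dose when
    magnesium is present: ``inhibit`` divides it by (1 + magnitude)
    (potency loss, rightward shift), ``potentiate`` multiplies it.  The
    magnesium term is additive and dose-independent.  Clamped to
    [-100, 100].
    """
    d_eff = cg_dose
    if ms_dose > 0 and cg_dose > 0:
        if config.interaction_mode == "inhibit":
            d_eff = cg_dose / (1.0 + config.interaction_magnitude)
        elif config.interaction_mode == "potentiate":
            d_eff = cg_dose * (1.0 + config.interaction_magnitude)
    total = config.cg_curve.effect(d_eff, phase) + config.ms_effect.effect(ms_dose, phase)
    return float(np.clip(total, -100.0, 100.0))


def group_label_for(cg_dose: float, ms_dose: float) -> str:
    if cg_dose == 0 and ms_dose == 0:
        return "vehicle"
    parts = []
    if cg_dose > 0:
        parts.append(f"CG{cg_dose:g}")
    if ms_dose > 0:
        parts.append(f"MS{ms_dose:g}")
    return "+".join(parts)


def simulate_rubbing_course(
    config: ScenarioConfig, cg_dose: float, ms_dose: float, rat_index: int
) -> RubbingRecord:
    """One rat's 15-bin time course: the control template scaled per phase
    by (1 - combined effect/100), with per-bin noise, truncated to
    [0, 180] s."""
    label = group_label_for(cg_dose, ms_dose)
    rng = _rat_rng(config, "behavior", label, rat_index)
    scale1 = 1.0 - combined_effect(config, cg_dose, ms_dose, 1) / 100.0
    scale2 = 1.0 - combined_effect(config, cg_dose, ms_dose, 2) / 100.0
    template = np.asarray(config.control_course, dtype=float)
    means = template * np.array([scale1] * 3 + [scale2] * 12)
    cv = config.noise_cv
    if cv == 0:
        bins = means
    elif config.noise_model == "lognormal":
        sigma = np.sqrt(np.log1p(cv**2))
        mu = -(sigma**2) / 2.0  # unit-mean lognormal factor
        bins = means * rng.lognormal(mean=mu, sigma=sigma, size=N_BINS)
    else:
        bins = means + rng.normal(0.0, cv * template, size=N_BINS)
    bins = np.clip(bins, 0.0, BIN_SECONDS)
    return RubbingRecord(
        rat_id=f"{label}-r{rat_index}",
        group_label=label,
        cg_dose=cg_dose,
        ms_dose=ms_dose,
        bins=tuple(float(b) for b in bins),
    )


def simulate_group(
    config: ScenarioConfig, cg_dose: float, ms_dose: float
) -> list[RubbingRecord]:
    return [
        simulate_rubbing_course(config, cg_dose, ms_dose, i)
        for i in range(config.n_per_group)
    ]


def simulate_dose_response_experiment(
    config: ScenarioConfig,
    doses: Sequence[float],
    fixed_ms_dose: float = 0.0,
    ms_alone_doses: Sequence[float] = (),
) -> list[RubbingRecord]:
    """Full study layout: vehicle controls, cromoglycate-alone groups at
    each dose, combination groups at one fixed magnesium dose (when
    nonzero), optional magnesium-alone groups."""
    if len(doses) < 3:
        raise ValidationError(f"need >= 3 cromoglycate doses, got {len(doses)}")
    records = list(simulate_group(config, 0.0, 0.0))
    for d in doses:
        records.extend(simulate_group(config, d, 0.0))
    if fixed_ms_dose > 0:
        for d in doses:
            records.extend(simulate_group(config, d, fixed_ms_dose))
    for m in ms_alone_doses:
        records.extend(simulate_group(config, 0.0, m))
    return records


# -- mast cells ----------------------------------------------------------

MASTCELL_GROUPS = ("naive", "vehicle", "formalin", "formalin+ms")


def _mastcell_means(config: ScenarioConfig, group: str, time_point: str) -> tuple[float, float]:
    mc = config.mastcell
    total = mc.naive_total
    degran = mc.naive_degran
    if group == "naive":
        return total, degran
    if group == "vehicle":
        if time_point == "5 min":
            total *= 1.0 - mc.vehicle_total_reduction_5min
            degran *= mc.vehicle_degran_multiplier_5min
        return total, degran
    if group in ("formalin", "formalin+ms"):
        total *= 1.0 - mc.formalin_total_reduction[time_point]
        mult = mc.degran_multiplier_24h if time_point == "24 h" else mc.formalin_degran_multiplier
        degran *= mult
        if group == "formalin+ms":
            degran *= 1.0 - mc.inhibition(time_point)
            if time_point == "5 min":
                total *= 1.0 - mc.ms_extra_total_reduction_5min
        return total, degran
    raise ValidationError(f"unknown mast-cell group {group!r}; expected one of {MASTCELL_GROUPS}")


def simulate_mastcell_sample(
    config: ScenarioConfig, group: str, time_point: str, rat_index: int
) -> MastCellSample:
    """Three Poisson HRF totals around the group/time mean with binomial
    degranulated counts; degranulated <= total by construction."""
    mean_total, mean_degran = _mastcell_means(config, group, time_point)
    rng = _rat_rng(config, "mastcell", f"{group}@{time_point}", rat_index)
    fields = []
    p = min(mean_degran / mean_total, 1.0) if mean_total > 0 else 0.0
    for _ in range(3):
        total = int(rng.poisson(mean_total))
        degran = int(rng.binomial(total, p)) if total > 0 else 0
        fields.append(MastCellField(total=total, degranulated=degran))
    return MastCellSample(
        rat_id=f"{group}@{time_point}-r{rat_index}",
        group_label=group,
        time_point=time_point if group != "naive" else "naive",
        fields=tuple(fields),
    )


def simulate_mastcell_cohort(
    config: ScenarioConfig,
    groups: Sequence[str] = ("vehicle", "formalin", "formalin+ms"),
    time_points: Sequence[str] = ("5 min", "25 min", "24 h"),
) -> list[MastCellSample]:
    """Naive rats plus every (group, time point) cell at n_per_group."""
    samples = [
        simulate_mastcell_sample(config, "naive", "5 min", i)
        for i in range(config.n_per_group)
    ]
    for g in groups:
        for tp in time_points:
            samples.extend(
                simulate_mastcell_sample(config, g, tp, i) for i in range(config.n_per_group)
            )
    return samples


def behavior_frame(records: Sequence[RubbingRecord]) -> pd.DataFrame:
    """Long study table in the behavior CSV schema."""
    rows = []
    for r in records:
        row = {
            "rat_id": r.rat_id,
            "group": r.group_label,
            "cg_dose_mgkg": r.cg_dose,
            "ms_dose_mgkg": r.ms_dose,
        }
        row.update({f"bin{k + 1:02d}": r.bins[k] for k in range(N_BINS)})
        rows.append(row)
    return pd.DataFrame(rows)


def histology_frame(samples: Sequence[MastCellSample]) -> pd.DataFrame:
    """Long histology table in the histology CSV schema."""
    rows = []
    for s in samples:
        for i, f in enumerate(s.fields, start=1):
            rows.append(
                {
                    "rat_id": s.rat_id,
                    "group": s.group_label,
                    "time_point": s.time_point,
                    "field_index": i,
                    "total_cells": f.total,
                    "degranulated_cells": f.degranulated,
                }
            )
    return pd.DataFrame(rows)
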