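"""CSV schemas and validated ingestion.

Behavior table, one row per rat:
    rat_id, group, cg_dose_mgkg, ms_dose_mgkg, bin01..bin15  (seconds)

Histology table, one row per counted field (three per rat):
    rat_id, group, time_point, field_index, total_cells, degranulated_cells
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .behavior import N_BINS, RubbingRecord
from .errors import ValidationError
from .histomorphometry import MastCellField, MastCellSample

BIN_COLUMNS = [f"bin{k:02d}" for k in range(1, N_BINS + 1)]
BEHAVIOR_COLUMNS = ["rat_id", "group", "cg_dose_mgkg", "ms_dose_mgkg", *BIN_COLUMNS]
HISTOLOGY_COLUMNS = [
    "rat_id",
    "group",
    "time_point",
    "field_index",
    "total_cells",
    "degranulated_cells",
]


@dataclass
class ValidationReport:
    """Itemized schema/invariant findings; errors are fatal, warnings not."""

    path: str
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_columns(df: pd.DataFrame, expected: Sequence[str], report: ValidationReport) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        report.errors.append(f"missing columns: {missing}")
    if extra:
        report.errors.append(f"unexpected columns: {extra}")


def validate_behavior_csv(path: str | Path) -> ValidationReport:
    report = ValidationReport(path=str(path))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file
        report.errors.append(f"cannot read: {exc}")
        return report
    _check_columns(df, BEHAVIOR_COLUMNS, report)
    if report.errors:
        return report
    if df["rat_id"].duplicated().any():
        dupes = df.loc[df["rat_id"].duplicated(), "rat_id"].tolist()
        report.errors.append(f"duplicate rat_id values: {dupes}")
    for idx, row in df.iterrows():
        try:
            _record_from_row(row)
        except ValidationError as exc:
            report.errors.append(f"row {idx}: {exc}")
    return report


def validate_histology_csv(path: str | Path) -> ValidationReport:
    report = ValidationReport(path=str(path))
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        report.errors.append(f"cannot read: {exc}")
        return report
    _check_columns(df, HISTOLOGY_COLUMNS, report)
    if report.errors:
        return report
    for idx, row in df.iterrows():
        if row["degranulated_cells"] > row["total_cells"]:
            report.errors.append(
                f"row {idx}: degranulated ({row['degranulated_cells']}) > total ({row['total_cells']})"
            )
        if row["field_index"] not in (1, 2, 3):
            report.errors.append(f"row {idx}: field_index {row['field_index']} not in 1-3")
    counts = df.groupby("rat_id")["field_index"].count()
    for rat, c in counts.items():
        if c != 3:
            report.errors.append(f"rat {rat!r}: {c} fields, expected 3")
    return report


def _record_from_row(row: pd.Series) -> RubbingRecord:
    return RubbingRecord(
        rat_id=str(row["rat_id"]),
        group_label=str(row["group"]),
        cg_dose=float(row["cg_dose_mgkg"]),
        ms_dose=float(row["ms_dose_mgkg"]),
        bins=tuple(float(row[c]) for c in BIN_COLUMNS),
    )


def read_behavior_csv(path: str | Path) -> list[RubbingRecord]:
    report = validate_behavior_csv(path)
    if not report.ok:
        raise ValidationError("; ".join(report.errors))
    df = pd.read_csv(path)
    return [_record_from_row(row) for _, row in df.iterrows()]


def read_histology_csv(path: str | Path) -> list[MastCellSample]:
    report = validate_histology_csv(path)
    if not report.ok:
        raise ValidationError("; ".join(report.errors))
    df = pd.read_csv(path)
    samples = []
    for (rat, group, tp), sub in df.groupby(["rat_id", "group", "time_point"], sort=False):
        sub = sub.sort_values("field_index")
        fields = tuple(
            MastCellField(int(r["total_cells"]), int(r["degranulated_cells"]))
            for _, r in sub.iterrows()
        )
        samples.append(
            MastCellSample(rat_id=str(rat), group_label=str(group), time_point=str(tp), fields=fields)
        )
    return samples


def write_behavior_csv(records: Sequence[RubbingRecord], path: str | Path) -> None:
    from .synthetic import behavior_frame

    behavior_frame(records).to_csv(path, index=False)


def write_histology_csv(samples: Sequence[MastCellSample], path: str | Path) -> None:
    from .synthetic import histology_frame

    histology_frame(samples).to_csv(path, index=False)
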