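"""Study orchestration: ingestion -> behavior statistics -> dose-response
-> interaction -> histomorphometry -> inference, with a reproducible
manifest.

Every number in the emitted report is produced by an operation in one of
the domain modules; this layer only sequences them and serializes the
results.  Rerunning with the same config, seed and inputs reproduces a
byte-identical report bundle (the manifest records content hashes; its
timestamp lives only in the manifest itself, outside the hashed
artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior import RubbingRecord, phase_summaries_with_aa, summarize_group
from .errors import NocistatError
from .histomorphometry import (
    MastCellSample,
    average_fields,
    correlate_degranulation_pain,
    degranulation_inhibition,
)
from .inference import tukey_hsd, two_way_rm_anova
from .interaction import FixedDoseReport, fixed_dose_analysis
from .synthetic import (
    ScenarioConfig,
    behavior_frame,
    histology_frame,
    simulate_dose_response_experiment,
    simulate_mastcell_cohort,
)

log = logging.getLogger("nocistat")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_section_interaction(rep: FixedDoseReport) -> dict:
    c = rep.comparison
    return {
        "phase": rep.phase,
        "fixed_ms_dose_mgkg": rep.fixed_ms_dose,
        "alone_max_effect_pct": rep.alone_max_effect_pct,
        "alone_fit": {
            "slope": rep.alone_fit.slope,
            "intercept": rep.alone_fit.intercept,
            "ed50_mgkg": rep.alone_fit.ed50,
            "emax_pct": rep.alone_fit.emax,
            "method": rep.alone_fit.method_tag,
        },
        "combo_fit": {
            "slope": rep.combo_fit.slope,
            "intercept": rep.combo_fit.intercept,
            "ed50_mgkg": rep.combo_fit.ed50,
            "method": rep.combo_fit.method_tag,
        },
        "parallelism": {"F": c.parallelism_F, "p": c.parallelism_p},
        "potency": {
            "ratio": c.ratio,
            "cl_low": c.cl_low,
            "cl_high": c.cl_high,
            "significant": c.significant,
            "direction_note": "ratio > 1: combination needs more cromoglycate "
            "for equal effect (rightward shift, antagonism direction)",
        },
        "verdict": c.verdict,
        "verdict_significant": c.verdict_significant,
        "shift_direction": c.shift_direction,
        "ed50_combination_mgkg": rep.ed50_combination,
        "percent_inhibition_by_dose": {f"{d:g}": v for d, v in rep.per_dose_inhibition.items()},
        "notes": rep.notes,
    }


def analyze_behavior(records: Sequence[RubbingRecord]) -> dict:
    """Phase group summaries, per-rat AA%, split-plot ANOVA over phases,
    and Tukey HSD on phase-2 totals."""
    grouped = phase_summaries_with_aa(records)
    group_rows = []
    for label, summaries in sorted(grouped.items()):
        for phase in (1, 2):
            gs = summarize_group(summaries, phase, label)
            aa = [s.aa_pct(phase) for s in summaries]
            group_rows.append(
                {
                    "group": label,
                    "phase": phase,
                    "n": gs.n,
                    "mean_s": gs.mean_s,
                    "sd_s": gs.sd_s,
                    "mean_aa_pct": float(np.mean(aa)),
                    "sd_aa_pct": float(np.std(aa, ddof=1)) if len(aa) > 1 else 0.0,
                }
            )

    long_rows = []
    for label, summaries in grouped.items():
        for s in summaries:
            for phase in (1, 2):
                long_rows.append(
                    {"rat": s.rat_id, "treatment": label, "phase": f"phase{phase}",
                     "value": s.phase_total(phase)}
                )
    long_df = pd.DataFrame(long_rows)
    anova = two_way_rm_anova(long_df, dv="value", between="treatment",
                             within="phase", subject="rat")
    phase2_groups = {
        label: [s.phase2_s for s in summaries] for label, summaries in sorted(grouped.items())
    }
    tukey = tukey_hsd(phase2_groups)
    return {
        "group_table": group_rows,
        "anova": [dataclasses.asdict(a) for a in anova],
        "tukey_phase2": [dataclasses.asdict(t) for t in tukey],
    }


def analyze_mastcells(samples: Sequence[MastCellSample]) -> dict:
    """Per-group/time mean counts plus I% of degranulation by magnesium
    pretreatment (formalin+ms vs formalin, per time point)."""
    rows = []
    for s in samples:
        mt, md = average_fields(s)
        rows.append(
            {"rat_id": s.rat_id, "group": s.group_label, "time_point": s.time_point,
             "mean_total": mt, "mean_degranulated": md}
        )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["group", "time_point"], sort=True)[["mean_total", "mean_degranulated"]]
        .agg(["mean", "std", "count"])
    )
    inhibition = {}
    for tp in ("5 min", "25 min", "24 h"):
        ctrl = df[(df.group == "formalin") & (df.time_point == tp)]["mean_degranulated"]
        trt = df[(df.group == "formalin+ms") & (df.time_point == tp)]["mean_degranulated"]
        if len(ctrl) and len(trt) and ctrl.mean() > 0:
            inhibition[tp] = degranulation_inhibition(float(ctrl.mean()), float(trt.mean()))
    flat_summary = {
        f"{g}|{tp}": {
            "mean_total": float(sub["mean_total"].mean()),
            "sd_total": float(sub["mean_total"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "mean_degranulated": float(sub["mean_degranulated"].mean()),
            "sd_degranulated": float(sub["mean_degranulated"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "n": int(len(sub)),
        }
        for (g, tp), sub in df.groupby(["group", "time_point"], sort=True)
    }
    return {"per_rat": rows, "summary": flat_summary, "degranulation_inhibition_pct": inhibition}


def correlate_cohorts(
    samples: Sequence[MastCellSample],
    records: Sequence[RubbingRecord],
    histology_group: str,
    behavior_group: str,
    time_point: str,
    phase: int,
) -> dict:
    """Pearson correlation between degranulation and phase pain.

    The two cohorts are separate animals, so rats are paired by position
    within their group (sorted ids) unless ids actually match.
    """
    degran = sorted(
        (s.rat_id, average_fields(s)[1])
        for s in samples
        if s.group_label == histology_group and s.time_point == time_point
    )
    from .behavior import phase_totals

    pain = sorted(
        (r.rat_id, phase_totals(r).phase_total(phase))
        for r in records
        if r.group_label == behavior_group
    )
    n = min(len(degran), len(pain))
    if n < 3:
        raise NocistatError("fewer than 3 pairable rats for the correlation")
    r, p = correlate_degranulation_pain([d for _, d in degran[:n]], [y for _, y in pain[:n]])
    return {"r": r, "p": p, "n": n, "time_point": time_point, "phase": phase}


def run_study(
    config: ScenarioConfig,
    out_dir: str | Path,
    phases: Sequence[int] = (1, 2),
    alpha: float = 0.05,
    behavior_records: Sequence[RubbingRecord] | None = None,
    histology_samples: Sequence[MastCellSample] | None = None,
) -> dict:
    """Run the full study analysis and write the report bundle.

    With no explicit inputs the default synthetic study is generated:
    phase-matched cromoglycate dose sets (1, 5, 10 mg/kg for phase 1;
    1, 10, 30 mg/kg for phase 2) with magnesium 5 or 15 mg/kg fixed in
    the combination arm, plus the mast-cell cohort.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": alpha,
        "config": config.to_dict(),
    }

    phase_doses = {1: (1.0, 5.0, 10.0), 2: (1.0, 10.0, 30.0)}
    phase_ms = {1: 5.0, 2: 15.0}

    for phase in phases:
        if behavior_records is None:
            records = simulate_dose_response_experiment(
                config, phase_doses[phase], fixed_ms_dose=phase_ms[phase],
                ms_alone_doses=(phase_ms[phase],),
            )
        else:
            records = list(behavior_records)
        bpath = out / f"behavior_phase{phase}.csv"
        behavior_frame(records).to_csv(bpath, index=False)
        artifacts.append(bpath)

        section = analyze_behavior(records)
        try:
            rep = fixed_dose_analysis(records, phase, fixed_ms_dose=phase_ms[phase], alpha=alpha)
            section["interaction"] = report_section_interaction(rep)
        except NocistatError as exc:
            log.warning("phase %d interaction analysis unavailable: %s", phase, exc)
            section["interaction"] = {"error": str(exc)}
        report[f"phase{phase}"] = section

    if histology_samples is None:
        histology_samples = simulate_mastcell_cohort(config)
    hpath = out / "histology.csv"
    histology_frame(histology_samples).to_csv(hpath, index=False)
    artifacts.append(hpath)
    report["mastcells"] = analyze_mastcells(histology_samples)

    # degranulation-pain correlations across the two cohorts
    try:
        records2 = (
            list(behavior_records)
            if behavior_records is not None
            else simulate_dose_response_experiment(
                config, phase_doses[2], fixed_ms_dose=15.0, ms_alone_doses=(15.0,)
            )
        )
        pain_group = "MS15" if any(r.group_label == "MS15" for r in records2) else "vehicle"
        report["correlations"] = {
            "degran5min_vs_phase1": correlate_cohorts(
                histology_samples, records2, "formalin+ms", pain_group, "5 min", 1
            ),
            "degran25min_vs_phase2": correlate_cohorts(
                histology_samples, records2, "formalin+ms", pain_group, "25 min", 2
            ),
        }
    except NocistatError as exc:
        report["correlations"] = {"error": str(exc)}

    rpath = out / "report.json"
    rpath.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    artifacts.append(rpath)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
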