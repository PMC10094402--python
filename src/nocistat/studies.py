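"""Simulation studies over the pipeline: parameter recovery, interval
coverage, type-I calibration, and the closure of the default scenario.

These are the repeatable numerical experiments the analysis scripts and
the acceptance checks run.  Every experiment takes a seed and derives one
independent generator stream per replicate, so results are reproducible
and replicates never share draws.

Problem sizes default to the study's own scale (6 rats per group, 3 dose
groups per arm) with replicate counts chosen to keep Monte-Carlo error on
rates below about one percentage point.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .behavior import phase_summaries_with_aa
from .dose_response import DoseEffectPoint, fit_log_dose_line
from .errors import NocistatError
from .histomorphometry import average_fields, degranulation_inhibition
from .inference import two_way_rm_anova
from .interaction import fixed_dose_analysis, relative_potency
from .synthetic import (
    MSEffect,
    ScenarioConfig,
    simulate_dose_response_experiment,
    simulate_mastcell_sample,
)

PHASE2_DOSES = (1.0, 10.0, 30.0)
PHASE1_DOSES = (1.0, 5.0, 10.0)


def _alone_points(records, phase) -> list[DoseEffectPoint]:
    grouped = phase_summaries_with_aa(records)
    by_rat = {r.rat_id: r for r in records}
    pts = []
    for summaries in grouped.values():
        for s in summaries:
            rec = by_rat[s.rat_id]
            if rec.cg_dose > 0 and rec.ms_dose == 0 and s.aa_pct(phase) > 0:
                pts.append(DoseEffectPoint(rec.cg_dose, min(s.aa_pct(phase), 100.0)))
    return pts


def ed50_recovery_experiment(
    seed: int, n_sim: int = 200, true_ed50: float = 7.0, n_per_group: int = 6
) -> dict:
    """Recover the phase-2 ED50 from per-rat AA% by the direct log-dose
    line, n_sim independent simulated studies; reports the median
    absolute relative error against the injected truth."""
    errs = []
    for i in range(n_sim):
        cfg = ScenarioConfig(seed=seed * 100_000 + i, n_per_group=n_per_group)
        recs = simulate_dose_response_experiment(cfg, PHASE2_DOSES)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_log_dose_line(_alone_points(recs, 2))
        errs.append(abs(fit.ed50 - true_ed50) / true_ed50)
    return {
        "median_abs_rel_err": float(np.median(errs)),
        "true_ed50": true_ed50,
        "n_sim": n_sim,
    }


def _linear_arm(rng, doses, slope, intercept, sd, reps=6):
    d = np.repeat(doses, reps)
    e = intercept + slope * np.log10(d) + rng.normal(0.0, sd, d.size)
    return fit_log_dose_line([DoseEffectPoint(di, min(ei, 100.0)) for di, ei in zip(d, e)])


def fieller_coverage_experiment(
    seed: int,
    n_rep: int = 1000,
    true_ratio: float = 2.0,
    slope: float = 40.0,
    noise_sd: float = 6.0,
    doses: Sequence[float] = (1.0, 4.0, 16.0),
) -> dict:
    """Empirical coverage of the 95% Fieller CL for a known potency shift.

    The data-generating model is the parallel-line model itself (common
    slope, arm B displaced by log10(true_ratio), normal errors), so the
    nominal level is the benchmark.  Unbounded intervals (g >= 1) cover by
    convention.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1E11E]))
    shift = slope * np.log10(true_ratio)
    covered = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_rep):
            a = _linear_arm(rng, doses, slope, 10.0, noise_sd)
            b = _linear_arm(rng, doses, slope, 10.0 - shift, noise_sd)
            comp = relative_potency(a, b, parallelism_alpha=0.0)
            if comp.cl_low <= true_ratio <= comp.cl_high:
                covered += 1
    return {"coverage": covered / n_rep, "n_rep": n_rep, "true_ratio": true_ratio}


def parallelism_type1_experiment(
    seed: int,
    n_rep: int = 1000,
    slope: float = 40.0,
    noise_sd: float = 6.0,
    doses: Sequence[float] = (1.0, 4.0, 16.0),
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the parallelism F-test when both arms share the
    same true slope (normal errors): should sit at the nominal alpha."""
    from .interaction import test_parallelism

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7A11]))
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_rep):
            a = _linear_arm(rng, doses, slope, 10.0, noise_sd)
            b = _linear_arm(rng, doses, slope, 5.0, noise_sd)
            _, p, _ = test_parallelism(a, b)
            rejections += p < alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def anova_type1_experiment(
    seed: int,
    n_rep: int = 1000,
    n_groups: int = 3,
    n_subjects: int = 6,
    n_within: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the split-plot treatment effect under the global
    null (all observations iid normal)."""
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA404A]))
    template = pd.DataFrame(
        {
            "rat": [f"g{g}s{s}" for g in range(n_groups) for s in range(n_subjects)
                    for _ in range(n_within)],
            "treatment": [f"g{g}" for g in range(n_groups) for _ in range(n_subjects * n_within)],
            "time": [f"t{t}" for _ in range(n_groups * n_subjects) for t in range(n_within)],
        }
    )
    rejections = 0
    for _ in range(n_rep):
        template["value"] = rng.normal(size=len(template))
        res = {r.effect_name: r for r in two_way_rm_anova(template)}
        rejections += res["treatment"].p < alpha
    return {"rejection_rate": rejections / n_rep, "n_rep": n_rep, "alpha": alpha}


def verdict_experiment(
    seed: int,
    interaction_mode: str = "null",
    magnitude: float = 0.0,
    n_runs: int = 100,
    n_per_group: int = 6,
    phase: int = 2,
    doses: Sequence[float] = PHASE2_DOSES,
    fixed_ms_dose: float = 15.0,
) -> dict:
    """Distribution of interaction verdicts over repeated simulated
    studies with a truly inert adjuvant (no additive magnesium effect),
    under the requested interaction mode."""
    counts: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_runs):
            cfg = ScenarioConfig(
                seed=seed * 100_000 + i,
                n_per_group=n_per_group,
                ms_effect=MSEffect(0.0, 0.0),
                interaction_mode=interaction_mode,
                interaction_magnitude=magnitude,
            )
            recs = simulate_dose_response_experiment(cfg, doses, fixed_ms_dose=fixed_ms_dose)
            try:
                rep = fixed_dose_analysis(recs, phase, fixed_ms_dose=fixed_ms_dose)
                verdict = rep.comparison.verdict
            except NocistatError:
                verdict = "error"
            counts[verdict] = counts.get(verdict, 0) + 1
    return {k: v / n_runs for k, v in counts.items()} | {"n_runs": n_runs}


def calibration_closure(seed: int, n_cohorts: int = 10) -> dict:
    """Summary pattern of the default scenario: cromoglycate dose-dependent
    with phase-2 efficacy above phase-1, magnesium ~40% and
    dose-independent in phase 2, degranulation inhibited at 5/25 min but
    not 24 h."""
    cfg = ScenarioConfig(seed=seed)
    recs1 = simulate_dose_response_experiment(
        cfg, (1.0, 5.0, 10.0, 30.0), ms_alone_doses=(5.0, 15.0)
    )
    grouped1 = phase_summaries_with_aa(recs1)

    def group_mean_aa(grouped, label, phase):
        return float(np.mean([s.aa_pct(phase) for s in grouped[label]]))

    cg_phase1 = {d: group_mean_aa(grouped1, f"CG{d:g}", 1) for d in (1.0, 5.0, 10.0, 30.0)}
    cg_phase2 = {d: group_mean_aa(grouped1, f"CG{d:g}", 2) for d in (1.0, 5.0, 10.0, 30.0)}
    ms_phase2 = {d: group_mean_aa(grouped1, f"MS{d:g}", 2) for d in (5.0, 15.0)}

    inhibition: dict[str, list[float]] = {"5 min": [], "25 min": [], "24 h": []}
    for c in range(n_cohorts):
        ccfg = ScenarioConfig(seed=seed + 1000 * (c + 1))
        for tp in inhibition:
            f = np.mean(
                [average_fields(simulate_mastcell_sample(ccfg, "formalin", tp, i))[1]
                 for i in range(ccfg.n_per_group)]
            )
            fm = np.mean(
                [average_fields(simulate_mastcell_sample(ccfg, "formalin+ms", tp, i))[1]
                 for i in range(ccfg.n_per_group)]
            )
            inhibition[tp].append(degranulation_inhibition(float(f), float(fm)))

    return {
        "cg_phase1_max_aa_pct": max(cg_phase1.values()),
        "cg_phase2_max_aa_pct": max(cg_phase2.values()),
        "cg_phase1_by_dose": cg_phase1,
        "cg_phase2_by_dose": cg_phase2,
        "ms_phase2_aa_pct": ms_phase2,
        "degran_inhibition_pct": {tp: float(np.mean(v)) for tp, v in inhibition.items()},
    }
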