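#!/usr/bin/env python
"""Dose-response fits and ED50 estimation for the drugs given alone.

Cromoglycate: log-dose regression per phase; in phase 1, where the drug
tops out below ~60% antinociception, the maximal effect is first
estimated from the double-reciprocal (1/E vs 1/D) plot and the ED50 is
the half-saturation dose.  Magnesium sulfate has no ED50 (its effect is
dose-independent); its flat phase-2 effect is summarized instead.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np

from nocistat.behavior import phase_summaries_with_aa
from nocistat.dose_response import DoseEffectPoint, ed50_submaximal, fit_log_dose_line
from nocistat.io import read_behavior_csv


def alone_points(recs, phase):
    grouped = phase_summaries_with_aa(recs)
    by_rat = {r.rat_id: r for r in recs}
    pts = []
    for summaries in grouped.values():
        for s in summaries:
            r = by_rat[s.rat_id]
            if r.cg_dose > 0 and r.ms_dose == 0 and s.aa_pct(phase) > 0:
                pts.append(DoseEffectPoint(r.cg_dose, min(s.aa_pct(phase), 100.0)))
    return pts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/dose_response.json"))
    args = ap.parse_args()

    recs = read_behavior_csv(args.data_dir / "behavior_alone_full_range.csv")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for phase in (1, 2):
            pts = alone_points(recs, phase)
            max_mean = max(
                float(np.mean([p.effect for p in pts if p.dose == d]))
                for d in {p.dose for p in pts}
            )
            if max_mean < 60.0:
                fit = ed50_submaximal(pts)
                route = "double-reciprocal (submaximal efficacy)"
            else:
                fit = fit_log_dose_line(pts)
                route = "direct log-dose line"
            out[f"phase{phase}"] = {
                "ed50_mgkg": fit.ed50,
                "emax_pct": fit.emax,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "method": fit.method_tag,
                "n_points": fit.n_points,
            }
            print(f"phase {phase}: ED50 = {fit.ed50:.2f} mg/kg via {route}"
                  + (f", Emax = {fit.emax:.1f}%" if fit.emax else ""))

        grouped = phase_summaries_with_aa(recs)
        ms = {
            d: float(np.mean([s.aa_phase2_pct for s in grouped[f"MS{d:g}"]]))
            for d in (5.0, 15.0)
        }
    out["ms_phase2_aa_pct"] = ms
    print(f"magnesium phase-2 AA%: {ms[5.0]:.1f}% at 5 mg/kg, {ms[15.0]:.1f}% at 15 mg/kg "
          "(dose-independent)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
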