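#!/usr/bin/env python
"""Mast-cell histomorphometry and the degranulation-pain correlation.

Averages each rat's three high representative fields, summarizes total
and degranulated counts per group and time point, computes magnesium's
degranulation inhibition I% against the formalin group, and correlates
per-rat degranulation with phase pain times across cohorts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from nocistat.errors import NocistatError
from nocistat.io import read_behavior_csv, read_histology_csv
from nocistat.pipeline import analyze_mastcells, correlate_cohorts


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/mastcells.json"))
    args = ap.parse_args()

    samples = read_histology_csv(args.data_dir / "histology.csv")
    res = analyze_mastcells(samples)
    pd.DataFrame(res["per_rat"]).to_csv(args.out.parent / "mastcell_per_rat.csv", index=False)

    naive = res["summary"].get("naive|naive")
    if naive:
        print(f"naive dermis: {naive['mean_total']:.0f} +/- {naive['sd_total']:.0f} total, "
              f"{naive['mean_degranulated']:.1f} degranulated cells/HRF")
    for tp, v in res["degranulation_inhibition_pct"].items():
        print(f"degranulation inhibition by magnesium at {tp}: {v:.1f}%")

    correlations = {}
    try:
        recs = read_behavior_csv(args.data_dir / "behavior_phase2.csv")
        for name, (tp, phase) in {
            "degran5min_vs_phase1_pain": ("5 min", 1),
            "degran25min_vs_phase2_pain": ("25 min", 2),
        }.items():
            c = correlate_cohorts(samples, recs, "formalin+ms", "MS15", tp, phase)
            correlations[name] = c
            sig = "significant" if c["p"] < 0.05 else "not significant"
            print(f"{name}: r = {c['r']:.3f}, p = {c['p']:.3f} ({sig}, n = {c['n']})")
    except (NocistatError, FileNotFoundError) as exc:
        correlations = {"error": str(exc)}

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {"summary": res["summary"],
         "degranulation_inhibition_pct": res["degranulation_inhibition_pct"],
         "correlations": correlations},
        indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
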