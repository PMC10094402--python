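#!/usr/bin/env python
"""Phase-wise behavioral scoring and group inference.

Reads the simulated behavior tables, sums each rat's time course into
phase-1 (0-9 min) and phase-2 (9-45 min) totals, computes per-rat AA%
against the vehicle group mean, and runs the split-plot ANOVA
(treatment between, phase within) with Tukey HSD on phase-2 totals.
Writes group summary and inference tables under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nocistat.io import read_behavior_csv
from nocistat.pipeline import analyze_behavior


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for phase in (1, 2):
        recs = read_behavior_csv(args.data_dir / f"behavior_phase{phase}.csv")
        res = analyze_behavior(recs)
        groups = pd.DataFrame(res["group_table"])
        groups.to_csv(args.out_dir / f"group_summary_phase{phase}.csv", index=False)
        pd.DataFrame(res["anova"]).to_csv(args.out_dir / f"anova_phase{phase}.csv", index=False)
        pd.DataFrame(res["tukey_phase2"]).to_csv(
            args.out_dir / f"tukey_phase{phase}.csv", index=False
        )
        sub = groups[groups.phase == phase].sort_values("mean_aa_pct")
        print(f"\n== study layout {phase}: group mean AA% in phase {phase} ==")
        for _, row in sub.iterrows():
            print(f"  {row['group']:>10}: {row['mean_aa_pct']:6.1f}% "
                  f"(rubbing {row['mean_s']:.0f} +/- {row['sd_s']:.0f} s)")
        treat = [a for a in res["anova"] if a["effect_name"] == "treatment"][0]
        print(f"  treatment effect: F = {treat['F']:.1f}, p = {treat['p']:.2e}")


if __name__ == "__main__":
    main()
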