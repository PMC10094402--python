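#!/usr/bin/env python
"""Generate the synthetic study tables.

Emits the per-rat behavioral CSVs for both phase layouts (phase 1:
cromoglycate 1/5/10 mg/kg with magnesium 5 mg/kg fixed; phase 2:
1/10/30 mg/kg with magnesium 15 mg/kg fixed, plus an extended alone
curve up to 30 mg/kg) and the mast-cell histology cohort, all under
results/data/.
"""

import argparse
from pathlib import Path

from nocistat.io import write_behavior_csv, write_histology_csv
from nocistat.synthetic import (
    ScenarioConfig,
    simulate_dose_response_experiment,
    simulate_mastcell_cohort,
)

LAYOUTS = {1: ((1.0, 5.0, 10.0), 5.0), 2: ((1.0, 10.0, 30.0), 15.0)}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cfg = ScenarioConfig(seed=args.seed)
    for phase, (doses, ms) in LAYOUTS.items():
        recs = simulate_dose_response_experiment(
            cfg, doses, fixed_ms_dose=ms, ms_alone_doses=(ms,)
        )
        path = out / f"behavior_phase{phase}.csv"
        write_behavior_csv(recs, path)
        print(f"phase {phase}: {len(recs)} rats -> {path}")

    extended = simulate_dose_response_experiment(
        cfg, (1.0, 5.0, 10.0, 30.0), ms_alone_doses=(5.0, 15.0)
    )
    write_behavior_csv(extended, out / "behavior_alone_full_range.csv")
    print(f"alone full range: {len(extended)} rats -> {out / 'behavior_alone_full_range.csv'}")

    samples = simulate_mastcell_cohort(cfg)
    write_histology_csv(samples, out / "histology.csv")
    print(f"histology: {len(samples)} rats -> {out / 'histology.csv'}")


if __name__ == "__main__":
    main()
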