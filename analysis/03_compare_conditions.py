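#!/usr/bin/env python
"""Collate condition comparisons and ground-truth recovery across plates.

Produces two tables:

* results/condition_summary.csv — per plate and readout: group mean ± SD,
  compact letters, ANOVA p; the treated row's direction vs control.
* results/recovery.csv — per-well fitted (c, d) against the generator's
  ground truth with relative errors, plus a printed median summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microclot import io as mio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"
RESULTS = ROOT / "results"


def main() -> None:
    summaries = []
    recovery_rows = []
    for plate_dir in sorted(p for p in SCRATCH.iterdir() if p.is_dir()):
        name = plate_dir.name
        res = RESULTS / "plates" / name
        comparison = pd.read_csv(res / "comparison.csv")
        comparison.insert(0, "plate", name)
        summaries.append(comparison)

        truth = mio.read_truth(plate_dir / "truth.json")
        fits = pd.read_csv(res / "fits.csv")
        for rec in fits.itertuples():
            gt = truth.get(rec.well_id)
            if gt is None or rec.status not in ("ok", "censored"):
                continue
            degrading = gt["degrading"]
            recovery_rows.append({
                "plate": name, "well_id": rec.well_id, "condition": rec.condition,
                "c_true": gt["c_true"] if degrading else np.nan,
                "c_fit": rec.c,
                "c_rel_err": (abs(rec.c - gt["c_true"]) / gt["c_true"]
                              if degrading and np.isfinite(rec.c) else np.nan),
                "d_true": gt["d_true"] if degrading else np.nan,
                "d_fit": rec.d,
                "d_rel_err": (abs(rec.d - gt["d_true"]) / gt["d_true"]
                              if degrading and np.isfinite(rec.d) else np.nan),
            })

    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(RESULTS / "condition_summary.csv", index=False)
    recovery = pd.DataFrame(recovery_rows)
    recovery.to_csv(RESULTS / "recovery.csv", index=False)

    print("condition comparison (fibrinolysis time):")
    time_rows = summary[summary["readout"] == "fibrinolysis_time_h"]
    for rec in time_rows.itertuples():
        print(f"  {rec.plate:13s} {rec.condition:13s} "
              f"{rec.mean:7.1f} ± {rec.sd:4.1f} h   letter {rec.letter}")
    print(f"\nrecovery over {recovery['c_rel_err'].notna().sum()} degrading wells: "
          f"median |c| rel err {recovery['c_rel_err'].median():.3f}, "
          f"median |d| rel err {recovery['d_rel_err'].median():.3f}")


if __name__ == "__main__":
    main()
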