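#!/usr/bin/env python
"""Run the full mask -> trace -> fit -> stats pipeline on each simulated plate.

Reads the plate directories written by 01_simulate_plates.py and writes
per-plate traces.csv, fits.csv, comparison.csv, pairwise.csv and
manifest.json under results/plates/<scenario>/.
"""

from pathlib import Path

import pandas as pd

from microclot import PlateExperiment, run_analysis

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"
RESULTS = ROOT / "results" / "plates"


def main() -> None:
    plates = sorted(p for p in SCRATCH.iterdir() if p.is_dir())
    if not plates:
        raise SystemExit("no plates under scratch/plates; run 01_simulate_plates.py first")
    for plate in plates:
        out = RESULTS / plate.name
        experiment = PlateExperiment.from_dir(plate)
        paths = run_analysis(experiment, out)
        fits = pd.read_csv(paths["fits"])
        n_ok = (fits["status"] == "ok").sum()
        n_cens = (fits["status"] == "censored").sum()
        print(f"{plate.name}: {len(fits)} wells analyzed "
              f"({n_ok} ok, {n_cens} censored) -> {out}")


if __name__ == "__main__":
    main()
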