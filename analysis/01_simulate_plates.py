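#!/usr/bin/env python
"""Simulate the four condition-comparison plates used by the downstream analyses.

Each plate has a shared untreated control row (c = 72 h, d = 105%) and one
treated row of 8 replicate wells:

* acellular      — non-degrading wells (no cells, trace stays flat)
* inhibitor      — PAI-1-like: fibrinolysis slowed (c 72 -> 120 h), full lysis
* inflammatory   — LPS/baricitinib-like: slowed and capped (c 120 h, d 70%)
* statin         — rosuvastatin-like: accelerated (c 36 h), full lysis

Image stacks are large and binary, so they land under scratch/plates/;
later scripts read them back like any real plate directory.
"""

from pathlib import Path

from microclot import run_simulation

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "plates"

RENDER = {
    "image_size": [128, 128],
    "clot_radius": 40,
    "frame_interval_h": 4.0,
    "duration_h": 168.0,
    "noise_sigma": 200.0,
    "speck_count": 4,
    "vignette_gain": 0.05,
}

SCENARIOS = {
    "acellular": {"control": {"c": 72.0, "d": 105.0},
                  "acellular": {"degrading": False}},
    "inhibitor": {"control": {"c": 72.0, "d": 105.0},
                  "inhibitor": {"c": 120.0, "d": 105.0}},
    "inflammatory": {"control": {"c": 72.0, "d": 105.0},
                     "inflammatory": {"c": 120.0, "d": 70.0}},
    "statin": {"control": {"c": 72.0, "d": 105.0},
               "statin": {"c": 36.0, "d": 105.0}},
}


def main() -> None:
    for i, (name, conditions) in enumerate(SCENARIOS.items()):
        out = SCRATCH / name
        config = {
            "seed": 1000 + i,
            "n_replicates": 8,
            "jitter_frac": 0.05,
            "conditions": conditions,
            "render": dict(RENDER),
        }
        run_simulation(config, out)
        print(f"{name}: 2 conditions x 8 wells -> {out}")


if __name__ == "__main__":
    main()
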