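# microclot

Quantification of fibrin micro-clot dissolution from brightfield time-lapse
imaging.

Endothelial cells drive fibrinolysis: they secrete tissue-type plasminogen
activator (tPA), which converts plasminogen to plasmin, the enzyme that
degrades fibrin — and plasminogen activator inhibitor-1 (PAI-1), which
opposes it. A micro-clot dissolution assay probes this balance by printing
a microliter-scale fibrin clot over an endothelial monolayer in a well
plate and imaging each well hourly for up to 7 days while the cells lyse
the clot. This package turns those image sequences into per-well kinetic
readouts and condition-level statistics, and ships a seeded synthetic-data
generator so the whole pipeline is testable without any imaging data.

## The pipeline

1. **Masking** — the clot is segmented from the *first* frame only:
   binarize and invert (Otsu by default, so the dark clot becomes the
   foreground), morphological closing, hole filling, opening, and largest
   connected component. The frame-1 mask is applied unchanged to all later
   frames.
2. **Intensity trace** — per frame *i*, the average pixel intensity

   APIᵢ = 100 × mean(frameᵢ inside mask) / mean(frameᵢ outside mask)

   The ratio cancels global brightness drift; the trace rises as the dark
   clot lyses and can exceed 100% in late frames because the optics
   brighten the image center.
3. **Kinetics** — each trace is fit to a 4-parameter logistic curve

   y(t) = d + (a − d) / (1 + (t/c)^b)

   chosen so that y(c) = (a + d)/2 exactly: **c** is the *fibrinolysis
   time* (time to 50% degradation) and **d** the *amount of fibrinolysis*
   (the upper asymptote). Flat traces (acellular wells) are classified
   non-degrading; wells that never reach 50% within the recording are
   censored at the final time, not dropped silently.
4. **Statistics** — per condition: mean ± SD, one-way ANOVA, Tukey HSD on
   all pairs (α = 0.05), and a compact letter display — conditions not
   connected by the same letter differ significantly.

The `microclot.synthetic` module generates ground-truth-bearing inputs at
three fidelities (bare 4PL traces, rendered image stacks, whole plates with
condition effects and between-well jitter) and includes a mechanistic
surface-erosion model of dissolution time versus clot volume.

## Worked example

```python
import numpy as np
from microclot import (CONTROL_TRUTH, RenderConfig, render_stack,
                       generate_mask, extract_trace, fit_4pl)

cfg = RenderConfig(image_size=(128, 128), clot_radius=40,
                   frame_interval_h=4.0, duration_h=168.0, seed=7)
stack, truth = render_stack(CONTROL_TRUTH, cfg)   # c_true=72 h, d_true=105%
mask = generate_mask(stack.frames[0])
fit = fit_4pl(extract_trace(stack, mask))
print(f"c = {fit.c:.1f} h, d = {fit.d:.1f} %")
```

prints

```
c = 72.0 h, d = 105.0 %
```

i.e. the well reached 50% degradation at 72.0 h and plateaued at 105% of
background — the generator's ground truth, recovered through the full
mask → trace → fit pipeline.

At plate level, the numbered drivers under `analysis/` simulate and analyze
four two-condition plates (8 replicate wells each: a PAI-1-like inhibitor,
an LPS-like flattened profile, a statin-like accelerator, and an acellular
control), e.g.:

```
$ python analysis/01_simulate_plates.py && python analysis/02_analyze_plates.py
$ python analysis/03_compare_conditions.py
condition comparison (fibrinolysis time):
  inflammatory  control          72.6 ±  3.5 h   letter b
  inflammatory  inflammatory    121.1 ±  5.0 h   letter a
  inhibitor     control          72.7 ±  3.7 h   letter b
  inhibitor     inhibitor       117.5 ±  4.7 h   letter a
  statin        control          71.0 ±  5.1 h   letter a
  statin        statin           36.3 ±  1.6 h   letter b

recovery over 56 degrading wells: median |c| rel err 0.005, median |d| rel err 0.028
```

Distinct letters within a plate mean the Tukey-adjusted pairwise p-value is
below 0.05. `analysis/04_volume_dependence.py` sweeps the erosion model
over clot volumes 0.5–8 µL and verifies the dissolution time is strictly
increasing and accelerating in volume, matching the cube-root closed form
when plasminogen depletion is switched off.

A command-line interface mirrors the library:

```
microclot simulate config.yaml --out plate/     # render a synthetic plate
microclot mask plate/wells/A01.tif --out m.tif  # frame-1 segmentation
microclot analyze plate/ --out results/         # traces, fits, comparison
microclot recover plate/truth.json results/fits.csv --out recovery.csv
```

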