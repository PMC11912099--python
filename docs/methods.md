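# Methods

## Assay model

A fibrin micro-clot printed over an endothelial monolayer appears in
brightfield as a roughly circular region darker than the surrounding well.
As endothelial tPA converts plasminogen to plasmin, the clot lyses and its
footprint brightens toward (and past) the background level. The pipeline
quantifies this with one statistic and one curve:

* **Average pixel intensity (API).** For each frame *i*, with the clot mask
  M segmented from frame 1 only,
  `API_i = 100 · mean(frame_i[M]) / mean(frame_i[~M])`.
  The background is the full complement of the mask — no annulus or border
  exclusion. Dividing by the per-frame background mean cancels
  multiplicative illumination drift exactly (the statistic is invariant to
  a global gain) but not additive offsets; this is a documented property of
  the ratio-of-means definition, not a defect of the implementation.

* **4PL degradation profile.** `y(t) = d + (a − d)/(1 + (t/c)^b)` with
  lower asymptote `a` (% of background), steepness `b` (dimensionless),
  inflection time `c` (hours) and upper asymptote `d` (% of background).
  This parameterization satisfies `y(c) = (a + d)/2` identically, which
  makes `c` the time of 50% degradation by construction and `d` the final
  amount of fibrinolysis. Alternative sigmoid families (Gompertz,
  exponential saturation) are deliberately out of scope: the two readouts
  are defined *as* 4PL parameters.

## Masking

Five steps on frame 1: Otsu threshold + inversion (dark foreground),
closing (disc, radius 3 px), hole filling (4-connected background),
opening (disc, radius 5 px), largest 8-connected component with a
deterministic tie-break (first pixel in row-major scan order). Defaults:

| parameter          | default | rationale |
|--------------------|---------|-----------|
| threshold_method   | otsu    | parameter-free, affine-invariant; a fixed threshold is available for instruments with calibrated intensity |
| closing_radius     | 3 px    | bridges pixel noise inside the clot at the default render scale without welding specks to the clot |
| opening_radius     | 5 px    | removes debris/specks of radius < 5 px; clots are hundreds of px across, so the 1-px boundary erosion is negligible |
| connectivity       | 8       | isotropic objects; 4 available |
| min_mask_fraction  | 0.005   | a clot below 0.5% of the image area is a segmentation failure, not a clot |
| max_mask_fraction  | 0.6     | thresholding a clot-free noisy frame merges, after closing, into one blob covering most of the image; a "clot" that leaves no background also breaks the API ratio. Raised as a degenerate-threshold error |

The radii were chosen once against the synthetic fixtures (median IoU
≥ 0.98 at noise up to 5% of clot contrast) and are exposed in `MaskParams`
for real data with different pixel scales. The granulometry property (mask
area non-increasing in opening radius) holds up to a sub-0.1% tolerance:
quantized disc structuring elements are not perfectly nested.

## Kinetic fitting

Nonlinear least squares (`scipy.optimize.curve_fit`, trust-region with
bounds `a, d ∈ [0, 300]`, `b ∈ (0, 50]`, `c ∈ (0, 10·t_max]`).
Initialization: `a₀` = first value, `d₀` = last value, `c₀` = first
midpoint crossing (fallback: mid-time), `b₀` = 4. On failure, up to 5
seeded jittered restarts; a fit that still fails is flagged
`converged=False` and its readouts raise rather than return garbage.

* **Non-degrading classifier:** a trace whose 95th−5th percentile spread is
  below `range_epsilon = 5` percentage points is reported flat (acellular
  wells): no `c`, amount = trace mean. Five points sits well above the
  per-frame noise of the statistic (pixel noise averages out over the mask)
  and well below any real transition (≥ 10 points in all study conditions).
* **Censoring:** wells whose fitted `c` exceeds the recording end are
  reported as censored at the final time and excluded from the
  fibrinolysis-time ANOVA (their amount still enters the amount ANOVA).
  This keeps hypo-fibrinolytic conditions from biasing group means with
  extrapolated times.
* At least 8 time points are required; hourly sampling over days gives
  ~169, so this only rejects degenerate inputs.

## Statistics

Mean ± sample SD (n−1); one-way fixed-effects ANOVA; Tukey HSD via the
studentized range with pooled within-group variance
(`scipy.stats.tukey_hsd`, Tukey–Kramer for unequal n — the study designs
are balanced at n = 8). Compact letter display by insert-and-absorb: start
with one letter column holding all groups, split a column on each
significant pair it contains, absorb subset columns, order columns by group
mean. The construction guarantees "share a letter ⇔ not significant"; the
test suite checks it against a brute-force minimal clique-cover oracle for
up to five groups. Readouts are compared untransformed; `alpha` defaults
to 0.05.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:
control kinetics a = 40%, b = 4, c = 72 h, d = 105%; hourly frames over
168 h; 8 replicate wells per condition; between-well jitter 5%
(multiplicative lognormal on c so it stays positive, additive Gaussian on
d); trace noise σ = 2 percentage points. Condition effects shift (c, d):
an inhibitor like PAI-1 raises c and leaves d; an inflammatory stimulus
like LPS (or high-dose baricitinib) raises c *and* caps d near 70%
(residual fibrin); a statin-like accelerator lowers c only; acellular
wells are non-degrading.

**Rendering.** Frame 1 is a dark disc (plus optional dark specks as
distractors) on a uniform 16-bit-scale background (level 30000). The disc
interior follows the kinetic trace so that the API computed on the true
disc reproduces the trace exactly in the noiseless case — the rendering is
calibrated to the statistic, which is what makes closed-loop recovery
tests meaningful. The background drifts multiplicatively at `drift_rate`
per hour; additive Gaussian pixel noise is truncated to [0, 65535]; and a
Gaussian radial vignette (σ = 0.35·min(H, W)) ramps in with *degradation
progress* — the completed fraction of the 4PL transition — peaking at
`vignette_gain` in the final frame. Tying the vignette to progress rather
than wall time is the simplest mechanism that yields a >100% plateau only
after lysis and exactly zero brightening in frame 1. `clot_contrast`
(default 0.5) sets the frame-1 darkening for single-frame segmentation
fixtures and the speck darkness; in stack rendering the trace itself fixes
the disc intensity.

What the renderer does *not* emulate: cells, texture inside the clot or
background, irregular clot outlines, flow, fluorescence, frame-to-frame
registration error, or saturation. Passing recovery tests therefore shows
the algorithm chain is correct and well-conditioned under realistic noise,
drift and optics — not that segmentation will survive arbitrary real-world
artifacts; the mask parameters are the knobs to revisit on real data. The
vignette also biases the fitted plateau slightly above the ground-truth
`d` on rendered plates (≈2–3% at gain 0.05), exactly as it does in the
real assay.

**Volume→radius mapping.** Rendered clots use a fixed pixel radius per
config; no physical µL→px calibration is implied.  Time zero is the first
frame.

## Surface-erosion model

A mechanistic stand-in for the observed superlinear growth of fibrinolysis
time with clot volume: plasmin acts at the clot surface, and the
plasminogen supply per well is finite while cell number and serum are
fixed. With volume V (µL), pool P (arbitrary units, P(0) = p0):

    dV/dt = −k_surf · V^g · (P/p0)
    dP/dt = −α · k_surf · V^g · (P/p0)

with geometry exponent g = 2/3 (surface ∝ V^(2/3) for a shrinking
sphere-like body). Dissolution is the first time V ≤ 0.01·V(0); runs that
never reach it within the horizon are censored (returned as infinity).
Integration uses `scipy.integrate.solve_ivp` with a terminal event
(rtol 1e-9). With α = 0 and g = 2/3 the model collapses to the closed form
`t = 3(V0^{1/3} − (0.01·V0)^{1/3})/k_surf`, used as an exact oracle.

Defaults: k_surf = 0.033 (1 µL dissolves in ≈72 h without depletion, the
control fibrinolysis time), p0 = 1, α = 0.1. Because P is conserved along
V (dP = α·dV), α·0.99·V0 ≥ p0 makes dissolution impossible: the pool runs
out first. α = 0.1 consumes ~80% of the pool at the largest study volume
(8 µL), the strongest depletion for which the whole 0.5–8 µL sweep still
dissolves — times are then strictly increasing with positive second
differences across the sweep. The 8 µL clot needs ≈395 h, so volume sweeps
use an extended horizon; the 168 h default horizon reflects the assay's
7-day recording and censors such clots, as the real assay would. These
equations are this package's model of the surface-action hypothesis, not a
measured mechanism.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (`numpy.random.default_rng`;
plate wells derive child seeds via `SeedSequence([seed, condition,
replicate])`), and run manifests deliberately omit wall-clock timestamps,
so identical config + seed reproduce byte-identical CSVs, TIFFs and
manifests. The test suite and analysis drivers render at reduced geometry
(96–512 px images, 2–6 h frame intervals) — the pipeline is
scale-invariant by construction (Otsu + ratio statistic), and the reduced
sizes keep the closed-loop studies quick while preserving every property
under test at its stated tolerance.

## Known limitations

* Single clot per well; multi-clot or fragmented clots violate the
  largest-component step.
* The background definition (full mask complement) includes well walls if
  present in the field of view; real Incucyte exports may need cropping.
* No mixed-effects structure across plates; each plate is analyzed
  independently.
* Censored fibrinolysis times are excluded from ANOVA rather than modeled
  (no survival-style analysis).
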