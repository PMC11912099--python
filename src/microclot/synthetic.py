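"""Seeded synthetic data with known ground truth, at three fidelities.

No imaging data ships with this package, so everything the pipeline
consumes can be generated here:

* bare intensity traces drawn from a known 4PL truth (:func:`simulate_trace`),
* rendered brightfield-like image stacks of a lysing clot
  (:func:`render_stack`, :func:`render_frame`),
* whole simulated plates with condition effects and between-well
  variability (:func:`simulate_plate`),

plus a mechanistic surface-erosion kinetics model
(:func:`erosion_dissolution_time`) that reproduces the qualitative
dependence of fibrinolysis time on clot volume: lysis proceeds at the clot
surface and draws on a finite plasminogen pool, so time-to-dissolution
grows superlinearly with printed volume.

Rendering model
---------------
Frame 1 shows a dark disc (the clot) on a uniform background, optionally
with small dark distractor specks.  Over time the disc interior brightens
so that the average-pixel-intensity statistic computed on the true disc
reproduces the kinetic trace; the background drifts slowly; and a radially
symmetric center-brightening (vignette) ramps in with degradation
progress, peaking in the final frame — this is what pushes the statistic
above 100% after complete lysis.  Pixel values live on a 16-bit scale with
additive Gaussian noise truncated to the valid range.  All randomness is
driven by explicit seeds; identical seeds give bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, InvalidInputError
from .intensity import IntensityTrace
from .kinetics import logistic4

__all__ = [
    "KineticsTruth",
    "RenderConfig",
    "ErosionModelParams",
    "GroundTruth",
    "FrameStack",
    "CONTROL_TRUTH",
    "simulate_trace",
    "render_frame",
    "render_stack",
    "simulate_plate",
    "erosion_dissolution_time",
    "volume_sweep",
]

_U16_MAX = 65535.0


@dataclass(frozen=True)
class KineticsTruth:
    """Ground-truth 4PL kinetics of one well.

    ``degrading=False`` emulates the acellular condition: the trace stays
    flat at ``a_true`` and the other parameters are ignored.
    """

    a_true: float
    b_true: float
    c_true: float
    d_true: float
    degrading: bool = True

    def __post_init__(self) -> None:
        vals = (self.a_true, self.b_true, self.c_true, self.d_true)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("kinetic parameters must be finite")
        if self.b_true <= 0 or self.c_true <= 0:
            raise InvalidInputError("b_true and c_true must be positive")
        if self.degrading and self.d_true < self.a_true:
            raise InvalidInputError("d_true must be >= a_true for a degrading well")

    def curve(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        if not self.degrading:
            return np.full(t.shape, self.a_true)
        return logistic4(t, self.a_true, self.b_true, self.c_true, self.d_true)


#: Untreated-well kinetics used as the default condition: baseline 40% of
#: background, 50% lysis at 72 h, plateau slightly above background.
CONTROL_TRUTH = KineticsTruth(a_true=40.0, b_true=4.0, c_true=72.0, d_true=105.0)


@dataclass(frozen=True)
class RenderConfig:
    """Geometry, optics and noise of the rendered well.

    clot_contrast is the fractional darkening of the clot (and of the
    distractor specks) relative to background in frame 1; stack rendering
    derives the disc intensity from the kinetic trace instead, so there it
    only sets speck darkness.  vignette_gain is the peak fractional
    center-brightening reached in the final frame of a fully degraded well.
    drift_rate is the fractional background change per hour.
    """

    image_size: tuple[int, int] = (512, 512)
    clot_center: tuple[int, int] | None = None  # (row, col); None = image center
    clot_radius: float = 150.0
    background_level: float = 30000.0
    clot_contrast: float = 0.5
    vignette_gain: float = 0.0
    drift_rate: float = 0.0
    noise_sigma: float = 0.0
    speck_count: int = 0
    speck_radius: float = 4.0
    frame_interval_h: float = 1.0
    duration_h: float = 168.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        r, c = self.center
        if not (r - self.clot_radius >= 0 and r + self.clot_radius < h
                and c - self.clot_radius >= 0 and c + self.clot_radius < w):
            raise InvalidInputError("clot disc must lie fully inside the image")
        if self.frame_interval_h <= 0:
            raise InvalidInputError("frame_interval_h must be positive")
        if self.duration_h < 2 * self.frame_interval_h:
            raise InvalidInputError("duration_h must cover at least two frame intervals")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be non-negative")
        if not 0 <= self.clot_contrast <= 1:
            raise InvalidInputError("clot_contrast must lie in [0, 1]")
        if self.vignette_gain < 0:
            raise InvalidInputError("vignette_gain must be non-negative")

    @property
    def center(self) -> tuple[float, float]:
        if self.clot_center is not None:
            return (float(self.clot_center[0]), float(self.clot_center[1]))
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    @property
    def times_h(self) -> np.ndarray:
        n = int(np.floor(self.duration_h / self.frame_interval_h)) + 1
        return np.arange(n) * self.frame_interval_h

    def disc_mask(self) -> np.ndarray:
        h, w = self.image_size
        rr, cc = np.ogrid[:h, :w]
        r0, c0 = self.center
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.clot_radius ** 2


@dataclass(frozen=True)
class ErosionModelParams:
    """Surface-erosion kinetics of clot dissolution.

    The clot loses volume at a rate proportional to its exposed surface
    (A ~ V^geometry_exponent) and to the fraction of the plasminogen pool
    still available; lysing fibrin consumes plasminogen:

        dV/dt = -k_surf * V^g * (P / p0)
        dP/dt = -alpha * k_surf * V^g * (P / p0)

    With alpha = 0 and g = 2/3 this reduces to the cube-root law of a
    shrinking sphere; alpha > 0 depletes the pool and makes dissolution
    time grow superlinearly with initial volume.
    """

    volume_uL: float = 1.0
    k_surf: float = 0.033
    p0: float = 1.0
    alpha: float = 0.1
    geometry_exponent: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.volume_uL <= 0 or self.k_surf <= 0 or self.p0 <= 0:
            raise InvalidInputError("volume_uL, k_surf and p0 must be positive")
        if self.alpha < 0 or self.geometry_exponent <= 0:
            raise InvalidInputError("alpha must be >= 0 and geometry_exponent > 0")


@dataclass
class GroundTruth:
    """Everything used to render one well: kinetics, geometry, condition."""

    truth: KineticsTruth
    mask: np.ndarray
    config: RenderConfig
    condition: str | None = None

    def to_record(self) -> dict:
        """JSON-serialisable sidecar record (geometry instead of the raw mask)."""
        return {
            "condition": self.condition,
            "a_true": self.truth.a_true,
            "b_true": self.truth.b_true,
            "c_true": self.truth.c_true,
            "d_true": self.truth.d_true,
            "degrading": self.truth.degrading,
            "clot_center": list(self.config.center),
            "clot_radius": self.config.clot_radius,
            "image_size": list(self.config.image_size),
            "seed": self.config.seed,
        }


@dataclass
class FrameStack:
    """One well's ordered grayscale frames with acquisition times (hours)."""

    well_id: str
    times_h: np.ndarray
    frames: np.ndarray  # (T, H, W), float64 on a 16-bit scale

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times_h.size:
            raise InvalidInputError("frames must be (T, H, W) with one time per frame")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("times must be strictly increasing")


def simulate_trace(
    truth: KineticsTruth,
    times_h,
    noise_sigma: float = 0.0,
    seed: int = 0,
    well_id: str = "sim",
) -> IntensityTrace:
    """Draw an intensity trace from the 4PL truth plus seeded Gaussian noise.

    Noise is expressed in percentage points of the statistic.
    """
    times = np.asarray(times_h, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be a strictly increasing 1-D array")
    if noise_sigma < 0:
        raise InvalidInputError("noise_sigma must be non-negative")
    values = truth.curve(times)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return IntensityTrace.from_values(times, values, well_id=well_id)


def _speck_centers(cfg: RenderConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Rejection-sample speck centers outside the clot and inside the image."""
    h, w = cfg.image_size
    r0, c0 = cfg.center
    centers: list[tuple[float, float]] = []
    margin = cfg.speck_radius + 1
    attempts = 0
    while len(centers) < cfg.speck_count and attempts < 1000 * max(cfg.speck_count, 1):
        attempts += 1
        rr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        if (rr - r0) ** 2 + (cc - c0) ** 2 > (cfg.clot_radius + cfg.speck_radius + 2) ** 2:
            centers.append((rr, cc))
    return centers


def _paint_discs(base: np.ndarray, centers, radius: float, value_scale: float) -> None:
    h, w = base.shape
    rr, cc = np.ogrid[:h, :w]
    for (r0, c0) in centers:
        m = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        base[m] *= value_scale


def render_frame(cfg: RenderConfig, rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Render a single frame-1-style image: dark disc + specks + noise.

    Returns (frame, true_disc_mask).  Used for segmentation fixtures; the
    disc darkening is ``clot_contrast`` of the background level.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    frame = np.full((h, w), cfg.background_level, dtype=float)
    disc = cfg.disc_mask()
    frame[disc] = cfg.background_level * (1.0 - cfg.clot_contrast)
    specks = _speck_centers(cfg, rng)
    _paint_discs(frame, specks, cfg.speck_radius, 1.0 - cfg.clot_contrast)
    if cfg.noise_sigma > 0:
        frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
    return np.clip(frame, 0.0, _U16_MAX), disc


def _vignette_profile(cfg: RenderConfig) -> np.ndarray:
    """Radial brightening profile, 1 at the image center, falling off outward."""
    h, w = cfg.image_size
    rr, cc = np.ogrid[:h, :w]
    r0, c0 = ((h - 1) / 2.0, (w - 1) / 2.0)
    sigma = 0.35 * min(h, w)
    return np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))


def render_stack(truth: KineticsTruth, cfg: RenderConfig,
                 well_id: str = "well", condition: str | None = None) -> tuple[FrameStack, GroundTruth]:
    """Render a full time-lapse of a lysing (or inert) clot.

    The disc interior follows the kinetic trace so that the average-pixel-
    intensity statistic computed on the true disc reproduces the trace
    (exactly in the noiseless, vignette-free, speck-free case; within noise
    otherwise).  The vignette ramps with degradation progress — the
    fraction of the 4PL transition completed — so frame 1 is never
    brightened, and a fully lysed well ends above 100%.
    """
    times = cfg.times_h
    y = truth.curve(times)
    if truth.degrading and truth.d_true > truth.a_true:
        progress = np.clip((y - truth.a_true) / (truth.d_true - truth.a_true), 0.0, 1.0)
    else:
        progress = np.zeros_like(y)

    rng = np.random.default_rng(cfg.seed)
    disc = cfg.disc_mask()
    specks = _speck_centers(cfg, rng)
    vignette = _vignette_profile(cfg)
    h, w = cfg.image_size

    frames = np.empty((times.size, h, w), dtype=float)
    for i, t in enumerate(times):
        bg = cfg.background_level * max(1.0 + cfg.drift_rate * t, 1e-3)
        frame = np.full((h, w), bg, dtype=float)
        frame[disc] = bg * y[i] / 100.0
        _paint_discs(frame, specks, cfg.speck_radius, 1.0 - cfg.clot_contrast)
        if cfg.vignette_gain > 0 and progress[i] > 0:
            frame = frame * (1.0 + cfg.vignette_gain * progress[i] * vignette)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        frames[i] = np.clip(frame, 0.0, _U16_MAX)

    stack = FrameStack(well_id=well_id, times_h=times, frames=frames)
    gt = GroundTruth(truth=truth, mask=disc, config=cfg, condition=condition)
    return stack, gt


def _well_id(condition_index: int, replicate: int) -> str:
    return f"{chr(ord('A') + condition_index)}{replicate + 1:02d}"


def simulate_plate(
    conditions: Mapping[str, KineticsTruth],
    n_replicates: int,
    cfg: RenderConfig,
    seed: int,
    jitter_frac: float = 0.05,
) -> tuple[dict[str, FrameStack], dict[str, GroundTruth], pd.DataFrame]:
    """Simulate a plate: one row of replicate wells per condition.

    Between-well variability is multiplicative lognormal on c_true (keeps
    it positive) and additive Gaussian on d_true, both scaled by
    ``jitter_frac``.  Returns (stacks, truths, plate map) keyed by well id.
    """
    if n_replicates < 2:
        raise InvalidInputError("need at least 2 replicates per condition")
    if not conditions:
        raise ConfigurationError("no conditions supplied")
    for name, truth in conditions.items():
        if not isinstance(truth, KineticsTruth):
            raise ConfigurationError(f"condition {name!r} has no kinetics entry")

    root = np.random.SeedSequence(seed)
    stacks: dict[str, FrameStack] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    for ci, (name, base) in enumerate(conditions.items()):
        for rep in range(n_replicates):
            ss = np.random.SeedSequence([seed, ci, rep])
            rng = np.random.default_rng(ss)
            if base.degrading and jitter_frac > 0:
                c_w = base.c_true * float(np.exp(rng.normal(0.0, jitter_frac)))
                d_w = base.d_true + float(rng.normal(0.0, jitter_frac * base.d_true))
                d_w = max(d_w, base.a_true)
                truth = replace(base, c_true=c_w, d_true=d_w)
            else:
                truth = base
            wid = _well_id(ci, rep)
            well_seed = int(ss.generate_state(1)[0] % (2**31))
            well_cfg = replace(cfg, seed=well_seed)
            stack, gt = render_stack(truth, well_cfg, well_id=wid, condition=name)
            stacks[wid] = stack
            truths[wid] = gt
            rows.append({"well_id": wid, "condition": name, "replicate": rep + 1})
    platemap = pd.DataFrame(rows)
    return stacks, truths, platemap


# --------------------------------------------------------------------------
# Mechanistic surface-erosion model


def erosion_dissolution_time(params: ErosionModelParams, horizon_h: float = 168.0) -> float:
    """First time the clot volume falls to 1% of its initial value.

    Integrates the surface-erosion ODE system; returns the dissolution time
    in hours, or ``math.inf`` as the censored marker if the threshold is
    not reached within ``horizon_h`` (e.g. the plasminogen pool runs out).
    """
    if horizon_h <= 0:
        raise InvalidInputError("horizon_h must be positive")
    v0 = params.volume_uL
    threshold = 0.01 * v0
    g = params.geometry_exponent

    def rhs(t, state):
        v, p = state
        v = max(v, 0.0)
        p = max(p, 0.0)
        rate = params.k_surf * v ** g * (p / params.p0)
        return [-rate, -params.alpha * rate]

    def dissolved(t, state):
        return state[0] - threshold

    dissolved.terminal = True
    dissolved.direction = -1

    sol = solve_ivp(
        rhs, (0.0, horizon_h), [v0, params.p0],
        events=dissolved, rtol=1e-9, atol=1e-12 * v0, max_step=horizon_h / 50,
    )
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return float("inf")


def volume_sweep(volumes_uL, params: ErosionModelParams, horizon_h: float = 168.0) -> pd.DataFrame:
    """Dissolution time across initial volumes, with the shared params."""
    rows = []
    for v in volumes_uL:
        p = replace(params, volume_uL=float(v))
        t = erosion_dissolution_time(p, horizon_h)
        rows.append({"volume_uL": float(v), "dissolution_time_h": t,
                     "censored": not np.isfinite(t)})
    return pd.DataFrame(rows)
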