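"""Four-parameter logistic (4PL) fitting of degradation time courses.

The intensity trace of a lysing clot is sigmoidal: it starts at the dark
baseline of the intact fibrin, rises as plasmin erodes the clot, and
plateaus once lysis stops.  We fit

    y(t) = d + (a - d) / (1 + (t / c)^b)

where ``a`` is the lower asymptote (baseline intensity, % of background),
``b`` the steepness, ``c`` the inflection time and ``d`` the upper
asymptote.  Under this parameterization y(c) = (a + d) / 2 exactly, so

* ``c`` is literally the time at which 50% of the degradation has occurred
  (the *fibrinolysis time*), and
* ``d`` is the final *amount of fibrinolysis*.

Traces with essentially no dynamic range (acellular wells: the clot never
lyses) are classified as non-degrading before any fitting; for those wells
the fibrinolysis time is censored and the amount is the trace mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidInputError, UnusableFitError
from .intensity import IntensityTrace

__all__ = [
    "LogisticFit",
    "FibrinolysisTime",
    "logistic4",
    "fit_4pl",
    "fibrinolysis_time",
    "fibrinolysis_amount",
    "RANGE_EPSILON",
]

#: Dynamic range (95th - 5th percentile of the trace, percentage points)
#: below which a trace is classified as non-degrading.
RANGE_EPSILON = 5.0

_B_BOUNDS = (1e-3, 50.0)
_AD_BOUNDS = (0.0, 300.0)


def logistic4(t, a, b, c, d):
    """Evaluate the 4PL curve y(t) = d + (a - d) / (1 + (t/c)^b)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.power(t / c, b, where=t > 0, out=np.zeros_like(t))
    return d + (a - d) / (1.0 + ratio)


@dataclass
class LogisticFit:
    """Fitted 4PL parameters plus diagnostics for one well.

    ``degrading=False`` means the trace was classified as flat (no lysis);
    then ``a`` and ``d`` both hold the trace mean, ``b``/``c`` are NaN and
    the fibrinolysis time is censored.  ``censored=True`` means the 50%
    transition was not reached within the recording (c > t_max or no lysis).
    """

    a: float
    b: float
    c: float
    d: float
    rss: float
    converged: bool
    degrading: bool
    censored: bool
    t_max: float
    n_points: int

    def predict(self, t):
        if not self.degrading:
            return np.full(np.shape(np.asarray(t, dtype=float)), self.a)
        return logistic4(t, self.a, self.b, self.c, self.d)


class FibrinolysisTime(NamedTuple):
    """Fibrinolysis-time readout; ``censored`` means '> hours' (never reached 50%)."""

    hours: float
    censored: bool


def _coerce(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, IntensityTrace):
        return trace.times_h, trace.api_percent
    times, values = trace
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def _initial_guess(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    a0 = float(values[0])
    d0 = float(values[-1])
    mid = 0.5 * (a0 + d0)
    # first crossing of the midpoint, in the direction of the transition
    if d0 >= a0:
        above = np.nonzero(values >= mid)[0]
    else:
        above = np.nonzero(values <= mid)[0]
    crossing = above[above > 0]
    c0 = float(times[crossing[0]]) if crossing.size else float(0.5 * (times[0] + times[-1]))
    if c0 <= 0:
        c0 = float(0.5 * (times[0] + times[-1]))
    return np.array([a0, 4.0, c0, d0])


def fit_4pl(
    trace,
    range_epsilon: float = RANGE_EPSILON,
    max_restarts: int = 5,
) -> LogisticFit:
    """Least-squares 4PL fit of an intensity trace.

    Parameters
    ----------
    trace : IntensityTrace or (times, values)
        Degradation time course; at least 8 points spanning > 0 hours.
    range_epsilon : float
        Dynamic-range threshold (percentage points) for the non-degrading
        classifier; traces whose 95th-5th percentile spread falls below it
        are reported flat without fitting.
    max_restarts : int
        Bounded multi-start: number of jittered re-initialisations tried
        after a failed optimisation before giving up (converged=False).

    Bounds: b in (0, 50], c in (0, 10*t_max], a and d in [0, 300].
    """
    times, values = _coerce(trace)
    if times.size != values.size:
        raise InvalidInputError("times and values must have equal length")
    if times.size < 8:
        raise InvalidInputError(f"need at least 8 time points, got {times.size}")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    t_max = float(times[-1])
    if t_max - float(times[0]) <= 0:
        raise InvalidInputError("trace must span a positive time interval")
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
        raise InvalidInputError("times and values must be finite")

    dyn = float(np.percentile(values, 95) - np.percentile(values, 5))
    if dyn < range_epsilon:
        mean = float(values.mean())
        rss = float(np.sum((values - mean) ** 2))
        return LogisticFit(
            a=mean, b=float("nan"), c=float("nan"), d=mean,
            rss=rss, converged=True, degrading=False, censored=True,
            t_max=t_max, n_points=int(times.size),
        )

    lower = np.array([_AD_BOUNDS[0], _B_BOUNDS[0], _B_BOUNDS[0], _AD_BOUNDS[0]])
    upper = np.array([_AD_BOUNDS[1], _B_BOUNDS[1], 10.0 * t_max, _AD_BOUNDS[1]])
    p0 = np.clip(_initial_guess(times, values), lower + 1e-9, upper - 1e-9)

    best = None
    rng = np.random.default_rng(20240501)
    guess = p0
    for _ in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(
                logistic4, times, values, p0=guess,
                bounds=(lower, upper), maxfev=20000,
            )
            rss = float(np.sum((values - logistic4(times, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
            break
        except RuntimeError:
            jitter = rng.normal(1.0, 0.2, size=4)
            guess = np.clip(p0 * np.abs(jitter), lower + 1e-9, upper - 1e-9)
    if best is None:
        return LogisticFit(
            a=float("nan"), b=float("nan"), c=float("nan"), d=float("nan"),
            rss=float("inf"), converged=False, degrading=True, censored=False,
            t_max=t_max, n_points=int(times.size),
        )
    (a, b, c, d), rss = best
    return LogisticFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        rss=rss, converged=True, degrading=True, censored=bool(c > t_max),
        t_max=t_max, n_points=int(times.size),
    )


def fibrinolysis_time(fit: LogisticFit) -> FibrinolysisTime:
    """Time to 50% degradation, censored at the recording end when never reached."""
    if not fit.converged:
        raise UnusableFitError("fit did not converge; fibrinolysis time unavailable")
    if not fit.degrading or fit.censored:
        return FibrinolysisTime(hours=fit.t_max, censored=True)
    return FibrinolysisTime(hours=fit.c, censored=False)


def fibrinolysis_amount(fit: LogisticFit) -> float:
    """Final amount of fibrinolysis: the upper asymptote ``d``.

    Non-degrading wells report the trace mean (no lysis occurred, so the
    'final amount' equals the baseline); the flat fit stores that mean in
    both ``a`` and ``d``.
    """
    if not fit.converged:
        raise UnusableFitError("fit did not converge; fibrinolysis amount unavailable")
    return fit.d
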