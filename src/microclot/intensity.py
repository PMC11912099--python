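"""Average-pixel-intensity statistic of the initial fibrin region.

The degradation readout of the assay is the mean intensity of the frame-1
fibrin mask, expressed as a percentage of the mean intensity of everything
outside the mask, computed per frame:

    API_i = 100 * mean(frame_i over mask) / mean(frame_i over ~mask)

The per-frame ratio cancels slow global changes in illumination, so the
trace reflects clot lysis rather than lamp drift.  Because the brightfield
optics brighten the image center in late frames, the statistic can exceed
100% once the clot has fully dissolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidFrameError, InvalidInputError

__all__ = ["IntensityTrace", "average_pixel_intensity", "extract_trace"]


@dataclass
class IntensityTrace:
    """Per-frame degradation time course of one well.

    Attributes
    ----------
    well_id : str
        Identifier of the well the trace belongs to.
    times_h : ndarray
        Acquisition times in hours, strictly increasing.
    api_percent : ndarray
        Average pixel intensity per frame (% of background).
    fibrin_mean : ndarray
        Raw mean intensity inside the frame-1 fibrin mask, per frame.
    background_mean : ndarray
        Raw mean intensity outside the mask, per frame; strictly positive.
    """

    well_id: str
    times_h: np.ndarray
    api_percent: np.ndarray
    fibrin_mean: np.ndarray
    background_mean: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.api_percent = np.asarray(self.api_percent, dtype=float)
        self.fibrin_mean = np.asarray(self.fibrin_mean, dtype=float)
        self.background_mean = np.asarray(self.background_mean, dtype=float)
        n = self.times_h.size
        if not (self.api_percent.size == self.fibrin_mean.size == self.background_mean.size == n):
            raise InvalidInputError("trace arrays must have equal length")
        if n == 0:
            raise InvalidInputError("trace must contain at least one frame")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidInputError("acquisition times must be strictly increasing")
        if np.any(self.background_mean <= 0):
            raise InvalidInputError("background mean must be positive in every frame")

    def __len__(self) -> int:
        return int(self.times_h.size)

    @classmethod
    def from_values(cls, times_h, api_percent, well_id: str = "sim") -> "IntensityTrace":
        """Build a trace directly from API values (background normalised to 100)."""
        api = np.asarray(api_percent, dtype=float)
        return cls(
            well_id=well_id,
            times_h=np.asarray(times_h, dtype=float),
            api_percent=api,
            fibrin_mean=api.copy(),
            background_mean=np.full(api.shape, 100.0),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame table (well_id, time_h, fibrin_mean, background_mean, api_percent)."""
        return pd.DataFrame(
            {
                "well_id": self.well_id,
                "time_h": self.times_h,
                "fibrin_mean": self.fibrin_mean,
                "background_mean": self.background_mean,
                "api_percent": self.api_percent,
            }
        )


def _mask_array(mask) -> np.ndarray:
    # accept either a bare boolean array or a FibrinMask-like object
    arr = getattr(mask, "mask", mask)
    return np.asarray(arr, dtype=bool)


def average_pixel_intensity(frame: np.ndarray, mask) -> float:
    """Mean intensity inside ``mask`` as a percentage of the mean outside it.

    The background is the full complement of the mask within the frame.

    Raises
    ------
    InvalidInputError
        If the mask is empty, covers the whole frame, or shapes differ.
    InvalidFrameError
        If the background mean is not strictly positive.
    """
    frame = np.asarray(frame, dtype=float)
    m = _mask_array(mask)
    if m.shape != frame.shape:
        raise InvalidInputError(f"mask shape {m.shape} does not match frame shape {frame.shape}")
    n_in = int(m.sum())
    if n_in == 0:
        raise InvalidInputError("mask is empty")
    if n_in == m.size:
        raise InvalidInputError("mask covers the entire frame; no background remains")
    fibrin = float(frame[m].mean())
    background = float(frame[~m].mean())
    if background <= 0:
        raise InvalidFrameError(f"background mean is {background}; cannot normalise")
    return 100.0 * fibrin / background


def extract_trace(stack, mask, well_id: str | None = None) -> IntensityTrace:
    """Apply :func:`average_pixel_intensity` to every frame of a stack.

    ``stack`` is any object with ``frames`` (T, H, W) and ``times_h`` arrays
    (e.g. :class:`microclot.synthetic.FrameStack`).  A failure in any single
    frame raises an error naming the frame index; frames are never skipped
    silently, because the kinetic fit assumes the recorded time grid.
    """
    m = _mask_array(mask)
    frames = np.asarray(stack.frames, dtype=float)
    times = np.asarray(stack.times_h, dtype=float)
    if frames.ndim != 3:
        raise InvalidInputError("stack.frames must be a (T, H, W) array")
    if frames.shape[0] != times.size:
        raise InvalidInputError("number of frames does not match number of time points")

    api = np.empty(times.size)
    fibrin = np.empty(times.size)
    background = np.empty(times.size)
    for i in range(times.size):
        try:
            frame = frames[i]
            fibrin[i] = frame[m].mean()
            background[i] = frame[~m].mean()
            api[i] = average_pixel_intensity(frame, m)
        except (InvalidFrameError, InvalidInputError) as exc:
            raise InvalidFrameError(f"frame {i}: {exc}") from exc
    return IntensityTrace(
        well_id=well_id or getattr(stack, "well_id", "well"),
        times_h=times,
        api_percent=api,
        fibrin_mean=fibrin,
        background_mean=background,
    )
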