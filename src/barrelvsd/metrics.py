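"""ROI time courses and temporal response metrics.

Extracts the per-animal numbers used for group comparison: the peak ΔF/F
amplitude and its latency, the extrema of the first difference of the
peak-normalized trace (rise and decay speed, per 10 ms frame at 100 Hz),
and the post-peak time to half-peak with linear interpolation between
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Union

import numpy as np

from .core import AcquisitionGeometry, MissingDataError, ParameterError
from .roi import BarrelROI

__all__ = [
    "TimeCourse",
    "ResponseMetrics",
    "roi_timecourse",
    "peak_response",
    "normalize_timecourse",
    "derivative_extrema",
    "time_to_half_peak",
    "response_metrics",
]


@dataclass(frozen=True)
class TimeCourse:
    """ΔF/F trace with its time axis in ms (relative to stimulus onset for
    evoked data, to trial start otherwise)."""

    values: np.ndarray
    times_ms: np.ndarray
    n_pixels_averaged: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times_ms", np.asarray(self.times_ms, dtype=float))
        if self.values.shape != self.times_ms.shape or self.values.ndim != 1:
            raise ParameterError("values and times_ms must be matching 1-D vectors")
        if self.times_ms.size >= 2 and not np.all(np.diff(self.times_ms) > 0):
            raise ParameterError("time axis must be strictly increasing")

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass(frozen=True)
class ResponseMetrics:
    peak_amplitude: float
    time_to_peak_ms: float
    max_derivative: float       # of the peak-normalized trace, per frame
    min_derivative: float
    time_to_half_peak_ms: Optional[float]


def roi_timecourse(
    mean_movie: np.ndarray,
    roi: Union[BarrelROI, Iterable[tuple[int, int]]],
    geometry: AcquisitionGeometry,
    label: str = "",
) -> TimeCourse:
    """Per-frame mean ΔF/F over the ROI pixels, missing-aware.

    Works on a trial-averaged 3-D movie ``(frame, row, col)``.  The same
    pooling rule serves barrel and ring ROIs.  Raises if every ROI pixel is
    vessel-masked.
    """
    pixels = sorted(roi.pixels) if isinstance(roi, BarrelROI) else sorted(roi)
    if not pixels:
        raise MissingDataError("empty ROI")
    movie = np.asarray(mean_movie, dtype=float)
    rows, cols = zip(*pixels)
    traces = movie[:, list(rows), list(cols)]
    defined = np.isfinite(traces)
    if not defined.any():
        raise MissingDataError("all ROI pixels are vessel-masked")
    with np.errstate(invalid="ignore"):
        values = np.nanmean(traces, axis=1)
    relative = geometry.stim_onset_frame is not None
    return TimeCourse(
        values=values,
        times_ms=geometry.frame_times_ms(relative_to_stim=relative),
        n_pixels_averaged=len(pixels),
        label=label,
    )


def peak_response(
    tc: TimeCourse,
    search_window_ms: Optional[tuple[float, float]] = None,
    interpolate: bool = False,
) -> tuple[float, float]:
    """Maximum of the trace and its time.

    The search window defaults to the full post-stimulus extent
    (``t >= 0``).  Ties go to the earliest time.  With ``interpolate=True``
    a parabola through the peak sample and its neighbors refines the peak
    time below the frame duration (used for ring-latency analysis, where
    latency steps are smaller than one frame).
    """
    t, v = tc.times_ms, tc.values
    if search_window_ms is None:
        sel = t >= 0
    else:
        lo, hi = search_window_ms
        if lo < 0:
            raise ParameterError("search window must be wholly post-stimulus")
        sel = (t >= lo) & (t <= hi)
    if not np.any(sel):
        raise ParameterError("empty peak-search window")
    idx = np.flatnonzero(sel)
    k = idx[int(np.argmax(v[idx]))]  # argmax returns the first maximum: earliest tie
    peak, t_peak = float(v[k]), float(t[k])
    if interpolate and 0 < k < len(v) - 1:
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # strictly concave triple
            t_peak += 0.5 * (y0 - y2) / denom * tc.dt_ms
    return peak, t_peak


def normalize_timecourse(tc: TimeCourse) -> TimeCourse:
    """Divide by the peak amplitude so the post-stimulus maximum is 1."""
    peak, _ = peak_response(tc)
    if peak <= 0:
        raise ParameterError(f"cannot normalize a trace with nonpositive peak ({peak})")
    return replace(tc, values=tc.values / peak)


def derivative_extrema(norm_tc: TimeCourse) -> tuple[float, float]:
    """Extrema of the forward first difference of a peak-normalized trace.

    Units are normalized amplitude per frame (×0.1 to convert to per ms at
    100 Hz).  The maximum is taken over the rising extent (differences
    ending at or before the peak), the minimum over the descending extent
    (differences starting at or after the peak).  No smoothing is applied.
    """
    v = norm_tc.values
    if v.size < 2:
        raise ParameterError("trace must have at least 2 frames")
    if not np.isclose(np.nanmax(v), 1.0):
        raise ParameterError("trace must be peak-normalized (max = 1)")
    d = np.diff(v)
    k_peak = int(np.nanargmax(v))
    rising = d[:k_peak] if k_peak > 0 else d
    falling = d[k_peak:] if k_peak < d.size else d  # trace ends at peak: whole trace
    return float(np.nanmax(rising)), float(np.nanmin(falling))


def time_to_half_peak(tc: TimeCourse) -> float:
    """Time of the first post-peak crossing of half the peak amplitude,
    linearly interpolated between the bracketing frames.

    Raises :class:`MissingDataError` if the trace never falls below
    half-peak within the recording (reported, never silently clipped).
    """
    peak, t_peak = peak_response(tc)
    half = 0.5 * peak
    t, v = tc.times_ms, tc.values
    k_peak = int(np.flatnonzero(t == t_peak)[0])
    for k in range(k_peak, v.size - 1):
        if v[k] >= half and v[k + 1] < half:
            frac = (v[k] - half) / (v[k] - v[k + 1])
            return float(t[k] + frac * (t[k + 1] - t[k]))
        if v[k + 1] == half:
            return float(t[k + 1])
    raise MissingDataError("trace never falls below half-peak within the recording")


def response_metrics(tc: TimeCourse) -> ResponseMetrics:
    """All temporal metrics of one evoked ROI trace."""
    peak, t_peak = peak_response(tc)
    dmax, dmin = derivative_extrema(normalize_timecourse(tc))
    try:
        t_half = time_to_half_peak(tc)
    except MissingDataError:
        t_half = None
    return ResponseMetrics(peak, t_peak, dmax, dmin, t_half)
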