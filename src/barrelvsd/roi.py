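"""Barrel-column ROI detection from the early evoked response.

The activated barrel center is the peak pixel of the trial-averaged ΔF/F
frame 20 ms after stimulus onset (the early response is still confined to
one barrel column at that time).  The ROI is the set of pixels whose early
response exceeds a high fraction of the center value — 0.775 by default,
the midpoint of the customary 75–80% band — restricted to the connected
component containing the center so that disjoint noise pixels cannot join.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AcquisitionGeometry, MissingDataError, ParameterError

__all__ = ["BarrelROI", "find_center", "define_roi"]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class BarrelROI:
    """Pixel set of one activated barrel column."""

    pixels: frozenset  # of (row, col)
    center: tuple[int, int]
    threshold_fraction: float
    reference_time_ms: float

    def __post_init__(self) -> None:
        if self.center not in self.pixels:
            raise ParameterError("ROI center must belong to the ROI")
        if not self.pixels:
            raise ParameterError("ROI must contain at least one pixel")

    @property
    def size(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        m[list(rows), list(cols)] = True
        return m

    def sorted_pixels(self) -> list[tuple[int, int]]:
        return sorted(self.pixels)


def _early_frame(
    mean_movie: np.ndarray, geometry: AcquisitionGeometry, early_time_ms: float
) -> np.ndarray:
    frame = np.asarray(mean_movie)[geometry.ms_to_frame(early_time_ms)]
    if np.all(~np.isfinite(frame)):
        raise MissingDataError("early frame is entirely missing")
    return frame


def find_center(
    mean_movie: np.ndarray,
    geometry: AcquisitionGeometry,
    early_time_ms: float = 20.0,
) -> tuple[int, int]:
    """Argmax pixel of the early post-stimulus frame over non-vessel pixels.

    Ties are broken toward the smallest row, then the smallest column.
    Raises if all defined values are equal (no distinct peak).
    """
    frame = _early_frame(mean_movie, geometry, early_time_ms)
    finite = np.isfinite(frame)
    vals = frame[finite]
    if np.all(vals == vals[0]) and vals.size > 1:
        raise MissingDataError("early frame has no distinct peak (all values equal)")
    peak = np.nanmax(frame)
    rows, cols = np.nonzero(frame == peak)
    # np.nonzero is already row-major ordered => first entry is the tie-break winner
    return int(rows[0]), int(cols[0])


def define_roi(
    mean_movie: np.ndarray,
    geometry: AcquisitionGeometry,
    early_time_ms: float = 20.0,
    threshold_fraction: float = 0.775,
    connectivity: int = 8,
    center: tuple[int, int] | None = None,
) -> BarrelROI:
    """Threshold the early frame at a fraction of the center value and keep
    the connected component containing the center.

    ``threshold_fraction`` in (0, 1]; 8-connectivity by default
    (4 available).  Vessel (NaN) pixels never qualify.  The ROI is invariant
    to any strictly increasing pointwise transform of the early frame, and
    raising the threshold can only shrink it.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ParameterError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 4 or 8")
    frame = _early_frame(mean_movie, geometry, early_time_ms)
    if center is None:
        center = find_center(mean_movie, geometry, early_time_ms)
    if not np.isfinite(frame[center]):
        raise MissingDataError(f"ROI center {center} is a vessel pixel")
    with np.errstate(invalid="ignore"):
        qualifies = frame >= threshold_fraction * frame[center]
    qualifies &= np.isfinite(frame)
    labels, _ = ndimage.label(qualifies, structure=_STRUCTURES[connectivity])
    component = labels == labels[center]
    pixels = frozenset((int(r), int(c)) for r, c in zip(*np.nonzero(component)))
    return BarrelROI(
        pixels=pixels,
        center=(int(center[0]), int(center[1])),
        threshold_fraction=threshold_fraction,
        reference_time_ms=early_time_ms,
    )
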