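"""Core containers for trial-structured widefield fluorescence data.

The package works on movies shaped ``(trial, frame, row, col)``.  Raw camera
movies are held in :class:`FluorescenceMovie`; after normalization and
artifact correction they become :class:`DffMovie`, whose values are relative
fluorescence changes (ΔF/F) with blood-vessel pixels flagged missing (NaN).

Time convention: frame ``k`` starts at ``k * 1000 / frame_rate`` ms from
trial start.  For stimulated trials, ``t = 0`` is the start of the frame at
``stim_onset_frame``, so the time of frame ``k`` relative to the stimulus is
``(k - stim_onset_frame) * dt_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "FluorescenceMovie",
    "DffMovie",
    "GeometryError",
    "ParameterError",
    "ConditionError",
    "MissingDataError",
    "PipelineOrderError",
    "CONDITIONS",
]

CONDITIONS = ("evoked", "blank", "spontaneous")


class GeometryError(ValueError):
    """Movie dimensions or acquisition geometry are invalid or inconsistent."""


class ParameterError(ValueError):
    """A physical or algorithmic parameter is outside its valid range."""


class ConditionError(ValueError):
    """An operation was applied to a trial condition it does not support."""


class MissingDataError(ValueError):
    """Required data (trials, pixels, blanks, ...) is absent or fully masked."""


class PipelineOrderError(RuntimeError):
    """A stage was invoked out of the fixed preprocessing order."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera geometry and timing of one recording.

    Parameters
    ----------
    n_rows, n_cols:
        Image size in pixels.
    pixel_size_um:
        Cortical extent covered by one pixel side, in micrometers.
    frame_rate_hz:
        Acquisition rate in Hz.
    n_frames:
        Frames per trial.
    stim_onset_frame:
        Index of the frame at which the stimulus is delivered, or ``None``
        for unstimulated (spontaneous) recordings.  At least three
        pre-stimulus frames are required so a 30 ms baseline exists.
    """

    n_rows: int = 100
    n_cols: int = 100
    pixel_size_um: float = 50.0
    frame_rate_hz: float = 100.0
    n_frames: int = 40
    stim_onset_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_frames < 1:
            raise GeometryError(
                f"grid/frame counts must be >= 1, got "
                f"({self.n_rows}, {self.n_cols}, {self.n_frames})"
            )
        if self.pixel_size_um <= 0:
            raise GeometryError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_rate_hz <= 0:
            raise GeometryError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if self.stim_onset_frame is not None:
            if not (1 <= self.stim_onset_frame <= self.n_frames - 1):
                raise GeometryError(
                    f"stim_onset_frame {self.stim_onset_frame} outside "
                    f"[1, {self.n_frames - 1}]"
                )
            if self.stim_onset_frame < 3:
                raise GeometryError(
                    "need >= 3 pre-stimulus frames for the 30 ms baseline, "
                    f"got stim_onset_frame={self.stim_onset_frame}"
                )

    @property
    def dt_ms(self) -> float:
        """Frame duration in milliseconds."""
        return 1000.0 / self.frame_rate_hz

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def frame_times_ms(self, relative_to_stim: bool = False) -> np.ndarray:
        """Frame start times in ms, optionally relative to stimulus onset."""
        t = np.arange(self.n_frames, dtype=float) * self.dt_ms
        if relative_to_stim:
            if self.stim_onset_frame is None:
                raise ConditionError("geometry has no stim_onset_frame")
            t -= self.stim_onset_frame * self.dt_ms
        return t

    def ms_to_frame(self, ms_after_stim: float) -> int:
        """Frame index for a time given in ms after stimulus onset."""
        if self.stim_onset_frame is None:
            raise ConditionError("geometry has no stim_onset_frame")
        k = self.stim_onset_frame + int(round(ms_after_stim / self.dt_ms))
        if not (0 <= k < self.n_frames):
            raise ParameterError(
                f"{ms_after_stim} ms after stimulus maps to frame {k}, "
                f"outside [0, {self.n_frames})"
            )
        return k

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def _check_movie_data(data: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 4:
        raise GeometryError(f"movie data must be 4-D (trial, frame, row, col), got {data.ndim}-D")
    if data.shape[1:] != (geometry.n_frames, geometry.n_rows, geometry.n_cols):
        raise GeometryError(
            f"data shape {data.shape[1:]} inconsistent with geometry "
            f"({geometry.n_frames}, {geometry.n_rows}, {geometry.n_cols})"
        )
    return data


@dataclass
class FluorescenceMovie:
    """Raw trial-structured fluorescence, in camera counts.

    ``data`` has shape ``(n_trials, n_frames, n_rows, n_cols)``; values must
    be finite and non-negative.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    condition: str = "evoked"
    group: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.data = _check_movie_data(self.data, self.geometry)
        if self.condition not in CONDITIONS:
            raise ConditionError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ParameterError("raw fluorescence must be finite and >= 0")
        if self.condition == "evoked" and self.geometry.stim_onset_frame is None:
            raise ConditionError("evoked movie requires a stim_onset_frame")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class DffMovie:
    """ΔF/F movie (dimensionless relative fluorescence change).

    Vessel pixels, once flagged, are NaN in every frame of every trial;
    every downstream mean excludes them.  ``provenance`` records the
    processing applied so the fixed pipeline order can be asserted.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    condition: str = "evoked"
    group: str = ""
    animal_id: str = ""
    vessel_mask: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = _check_movie_data(data, self.geometry)
        if self.vessel_mask is not None:
            self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
            if self.vessel_mask.shape != self.geometry.shape:
                raise GeometryError("vessel_mask shape does not match geometry")
        ok = self.data[:, :, ~self.vessel_mask] if self.vessel_mask is not None else self.data
        if not np.all(np.isfinite(ok)):
            raise ParameterError("non-vessel ΔF/F values must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def with_vessels_masked(self, mask: np.ndarray) -> "DffMovie":
        """Return a copy with ``mask`` pixels set missing (NaN) everywhere.

        Missingness is monotone: an already-masked pixel stays masked.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.geometry.shape:
            raise GeometryError("vessel mask shape does not match geometry")
        combined = mask if self.vessel_mask is None else (mask | self.vessel_mask)
        data = self.data.copy()
        data[:, :, combined] = np.nan
        prov = dict(self.provenance)
        prov["vessels_masked"] = True
        return replace(self, data=data, vessel_mask=combined, provenance=prov)
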