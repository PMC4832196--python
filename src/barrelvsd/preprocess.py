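"""Raw-fluorescence → ΔF/F preprocessing with artifact correction.

The fixed pipeline order is: ΔF/F normalization → blank subtraction →
vessel exclusion → analysis.  Display smoothing is terminal-only and never
feeds a quantitative operation.

ΔF/F is defined as ``F / F0 - 1`` where ``F0`` is the per-pixel mean over a
baseline window (the 30 ms — three frames at 100 Hz — immediately before
stimulus onset for evoked trials, or the first three frames for blank and
spontaneous trials).  Under a multiplicative artifact model this definition
makes blank subtraction cancel heart-beat and photobleaching artifacts to
first order.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionGeometry,
    DffMovie,
    FluorescenceMovie,
    GeometryError,
    MissingDataError,
    ParameterError,
    PipelineOrderError,
)

__all__ = [
    "compute_dff",
    "subtract_blank",
    "detect_vessels",
    "average_trials",
    "smooth_for_display",
    "VesselMask",
]


class VesselMask:
    """Boolean vessel mask with the detection parameters that produced it."""

    def __init__(self, mask: np.ndarray, highpass_sigma: float, threshold_k: float):
        self.mask = np.asarray(mask, dtype=bool)
        self.highpass_sigma = float(highpass_sigma)
        self.threshold_k = float(threshold_k)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _baseline_slice(geometry: AcquisitionGeometry, condition: str, n: int) -> slice:
    if n < 1:
        raise ParameterError(f"baseline_n_frames must be >= 1, got {n}")
    if condition == "evoked":
        onset = geometry.stim_onset_frame
        if onset is None:
            raise ParameterError("evoked movie lacks stim_onset_frame")
        if onset - n < 0:
            raise ParameterError(
                f"baseline of {n} frames does not fit before stimulus frame {onset}"
            )
        return slice(onset - n, onset)
    if n > geometry.n_frames:
        raise ParameterError("baseline window longer than the trial")
    return slice(0, n)


def compute_dff(
    movie: FluorescenceMovie,
    baseline_n_frames: int = 3,
    vessel_mask: Optional[np.ndarray] = None,
) -> DffMovie:
    """Per-pixel normalization by pre-stimulation activity.

    ``dff(t) = F(t) / mean(F over baseline frames) - 1`` for each trial and
    pixel.  The default three-frame baseline is 30 ms at 100 Hz.  A zero or
    negative baseline mean at a non-vessel pixel is an error (the pixel is
    named); vessel pixels, if a mask is supplied, are set missing.
    """
    sl = _baseline_slice(movie.geometry, movie.condition, baseline_n_frames)
    f0 = movie.data[:, sl].mean(axis=1, keepdims=True)
    bad = f0[:, 0] <= 0
    if vessel_mask is not None:
        bad &= ~np.asarray(vessel_mask, dtype=bool)[None]
    if np.any(bad):
        trial, row, col = (int(i[0]) for i in np.nonzero(bad))
        raise ParameterError(
            f"degenerate baseline (mean <= 0) at non-vessel pixel "
            f"({row}, {col}) in trial {trial}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = movie.data / f0 - 1.0
    vm = None
    if vessel_mask is not None:
        vm = np.asarray(vessel_mask, dtype=bool)
        dff[:, :, vm] = np.nan
    return DffMovie(
        dff,
        movie.geometry,
        movie.condition,
        movie.group,
        movie.animal_id,
        vessel_mask=vm,
        provenance={
            "baseline_frames": [sl.start, sl.stop],
            "blank_subtracted": False,
            "vessels_masked": vm is not None,
        },
    )


def subtract_blank(
    evoked: DffMovie, blanks: Union[DffMovie, Sequence[DffMovie]]
) -> DffMovie:
    """Remove heart-beat and photobleaching trends by subtracting the
    average blank-trial ΔF/F (frame-by-frame) from every trial."""
    if isinstance(blanks, DffMovie):
        blank_list = [blanks]
    else:
        blank_list = list(blanks)
    if not blank_list:
        raise MissingDataError("blank subtraction requested but no blank trials given")
    if evoked.provenance.get("vessels_masked"):
        raise PipelineOrderError(
            "blank subtraction must precede vessel exclusion"
        )
    stack = []
    for b in blank_list:
        if (b.geometry.n_frames, *b.geometry.shape) != (
            evoked.geometry.n_frames,
            *evoked.geometry.shape,
        ):
            raise GeometryError("blank and evoked movies differ in shape")
        stack.append(b.data)
    all_blanks = np.concatenate(stack, axis=0)
    blank_mean = all_blanks.mean(axis=0)
    return DffMovie(
        evoked.data - blank_mean[None],
        evoked.geometry,
        evoked.condition,
        evoked.group,
        evoked.animal_id,
        vessel_mask=evoked.vessel_mask,
        provenance={**evoked.provenance, "blank_subtracted": True,
                    "n_blank_trials": int(all_blanks.shape[0])},
    )


def detect_vessels(
    blank_frame_average: np.ndarray,
    highpass_sigma: float = 2.0,
    threshold_k: float = 3.0,
) -> VesselMask:
    """Find dark curvilinear blood vessels in a blank-condition frame.

    The frame is high-pass filtered by subtracting a spatial Gaussian blur
    (σ = 2 px by default); pixels whose absolute residual exceeds
    ``threshold_k`` times a robust residual scale (1.4826 × median absolute
    deviation) are flagged.  The threshold rule itself is this package's
    choice; MAD is used for robustness to the vessels' own outliers.
    """
    frame = np.asarray(blank_frame_average, dtype=float)
    if frame.ndim != 2:
        raise GeometryError("blank_frame_average must be 2-D")
    if not np.all(np.isfinite(frame)):
        raise ParameterError("vessel detection input must be finite")
    if highpass_sigma <= 0:
        raise ParameterError("highpass_sigma must be > 0")
    residual = frame - ndimage.gaussian_filter(frame, sigma=highpass_sigma)
    mad = np.median(np.abs(residual - np.median(residual)))
    scale = 1.4826 * mad
    # absolute floor keeps float dust on (near-)constant frames unflagged
    floor = 1e-9 * max(1.0, float(np.abs(frame).max()))
    mask = np.abs(residual) > max(threshold_k * scale, floor)
    return VesselMask(mask, highpass_sigma, threshold_k)


def average_trials(movie: DffMovie) -> np.ndarray:
    """Per-pixel mean over trials, ignoring missing (vessel) entries.

    Returns a 3-D array ``(frame, row, col)``; pixels missing in all trials
    stay NaN.
    """
    if movie.n_trials < 1:
        raise MissingDataError("cannot average zero trials")
    with np.errstate(invalid="ignore"):
        return np.nanmean(movie.data, axis=0)


def smooth_for_display(map_2d: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Missing-aware Gaussian blur for visualization only.

    Vessel (NaN) pixels are excluded from the kernel sum (normalized
    convolution) and stay NaN in the output.  σ = 0 is the identity.  This
    function is terminal: nothing quantitative may consume its output.
    """
    field = np.asarray(map_2d, dtype=float)
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return field.copy()
    missing = ~np.isfinite(field)
    filled = np.where(missing, 0.0, field)
    weight = np.where(missing, 0.0, 1.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma)
    den = ndimage.gaussian_filter(weight, sigma=sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[missing] = np.nan
    return out
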