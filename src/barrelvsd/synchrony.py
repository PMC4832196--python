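"""Seed-pixel spatial correlation maps, neighborhood synchrony and
spatial-shuffle nulls.

All correlations are zero-lag Pearson coefficients computed in short
sliding windows (80 ms: a center frame ±4 frames at 100 Hz) on *residual*
movies — single trials minus the trial-averaged response — so that
stimulus-locked structure is removed and only internally generated
covariability remains.

For each seed pixel in the barrel ROI, the correlation with every pixel in
a square patch (51 × 51 px, ±1.25 mm by default) is averaged over trials
and window positions; the per-seed maps are aligned on the seed and
averaged, giving the mean cross-correlation of ROI pixels with their
surroundings.  The scalar "neighborhood synchrony" is the mean map value
within 200 μm of the seed (the seed cell itself, r = 1 by definition, is
excluded).  The significance reference is a spatial-shuffle null: pixel
positions are freshly permuted within every frame of every trial,
destroying spatial structure while preserving each frame's value
distribution.

An unaligned whole-field variant (per-pixel mean correlation with the ROI
seeds, maps averaged without seed alignment) is also provided.

Zero-variance windows are undefined: they produce missing values that are
counted, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .core import (
    AcquisitionGeometry,
    DffMovie,
    MissingDataError,
    ParameterError,
)
from .roi import BarrelROI

__all__ = [
    "ResidualMovie",
    "CorrelationMap",
    "make_residuals",
    "sliding_window_correlation",
    "seed_correlation_map",
    "average_aligned_maps",
    "unaligned_field_map",
    "neighborhood_synchrony",
    "aligned_roi_synchrony",
    "shuffle_null",
    "synchrony_timecourse",
]

#: Default analysis-window lengths (ms) per condition.
DEFAULT_WINDOW_MS = {"spontaneous": 2500.0, "evoked": 150.0, "blank": 2500.0}

DEFAULT_HALF_WIDTH_PX = 25          # 51 x 51 patch = +-1.25 mm at 50 um/px
DEFAULT_WINDOW_HALFWIDTH_FRAMES = 4  # +-40 ms at 100 Hz -> 9-frame window
DEFAULT_RADIUS_UM = 200.0


@dataclass
class ResidualMovie:
    """Single-trial ΔF/F residuals after subtracting the trial average.

    ``data`` has shape (trial, frame, row, col) restricted to the analysis
    window; the per-pixel mean over trials is zero by construction.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    condition: str
    window_frames: tuple[int, int]
    vessel_mask: Optional[np.ndarray] = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class CorrelationMap:
    """Grid of mean Pearson r with its provenance.

    For seed-aligned maps, ``values[half_width, half_width]`` is the seed
    cell: flagged excluded (NaN) because its self-correlation is 1 by
    definition.  ``counts`` holds the number of (trial × window × seed)
    samples behind every cell.
    """

    values: np.ndarray
    counts: np.ndarray
    half_width_px: Optional[int]     # None for unaligned full-field maps
    seed: Optional[tuple[int, int]]  # None for averaged/unaligned maps
    window_halfwidth_frames: int
    n_undefined_windows: int = 0

    @property
    def aligned(self) -> bool:
        return self.half_width_px is not None

    @property
    def center_index(self) -> tuple[int, int]:
        if not self.aligned:
            raise ParameterError("full-field map has no aligned center cell")
        return (self.half_width_px, self.half_width_px)


def make_residuals(
    trials: DffMovie,
    window_frames: Optional[tuple[int, int]] = None,
) -> ResidualMovie:
    """Subtract the trial-averaged response from every single trial.

    ``window_frames`` is a half-open frame interval; by default it covers
    2500 ms from trial start for spontaneous/blank trials and 150 ms from
    stimulus onset for evoked trials (clipped to the recording).  Requires
    at least two trials.  Adding any trial-invariant spatiotemporal pattern
    to all trials leaves the residuals (hence all correlations) unchanged.
    """
    if trials.n_trials < 2:
        raise MissingDataError("residualization requires >= 2 trials")
    g = trials.geometry
    if window_frames is None:
        n = int(round(DEFAULT_WINDOW_MS[trials.condition] / g.dt_ms))
        start = g.stim_onset_frame if trials.condition == "evoked" else 0
        window_frames = (start, min(start + n, g.n_frames))
    lo, hi = window_frames
    if not (0 <= lo < hi <= g.n_frames):
        raise ParameterError(f"window {window_frames} outside [0, {g.n_frames}]")
    data = trials.data[:, lo:hi]
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
    else:
        data = data.copy()  # preserve single precision for large studies
    data -= data.mean(axis=0, keepdims=True, dtype=np.float64).astype(data.dtype)
    return ResidualMovie(
        data=data,
        geometry=g,
        condition=trials.condition,
        window_frames=(lo, hi),
        vessel_mask=trials.vessel_mask,
    )


# ---------------------------------------------------------------------------
# windowed Pearson machinery
# ---------------------------------------------------------------------------

def _rolling_mean(x: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Mean over every full window along ``axis`` (valid positions only)."""
    c = np.cumsum(x, axis=axis, dtype=np.float64)
    c = np.insert(c, 0, 0.0, axis=axis)
    lead = [slice(None)] * x.ndim
    lag = [slice(None)] * x.ndim
    lead[axis] = slice(window, None)
    lag[axis] = slice(0, -window)
    return (c[tuple(lead)] - c[tuple(lag)]) / window


def _windowed_corr_with_seed(
    patch: np.ndarray, seed_series: np.ndarray, halfwidth: int
) -> np.ndarray:
    """Sliding-window Pearson r between a seed series and every pixel series.

    ``patch``: (n_trials, T, ...pixels...); ``seed_series``: (n_trials, T).
    Returns r with shape (n_trials, T - 2*halfwidth, ...pixels...); windows
    with zero variance on either side are NaN.
    """
    if halfwidth < 1:
        raise ParameterError("window_halfwidth_frames must be >= 1")
    w = 2 * halfwidth + 1
    if patch.shape[1] < w:
        raise ParameterError(
            f"analysis window of {patch.shape[1]} frames shorter than the "
            f"{w}-frame correlation window"
        )
    extra = patch.ndim - 2
    s = seed_series.reshape(seed_series.shape + (1,) * extra)
    m_x = _rolling_mean(patch, w, 1)
    m_xx = _rolling_mean(patch * patch, w, 1)
    m_s = _rolling_mean(s, w, 1)
    m_ss = _rolling_mean(s * s, w, 1)
    m_sx = _rolling_mean(patch * s, w, 1)
    cov = m_sx - m_s * m_x
    var_x = np.maximum(m_xx - m_x * m_x, 0.0)
    var_s = np.maximum(m_ss - m_s * m_s, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_s * var_x)
    tol = 1e-15
    r[np.broadcast_to(var_s <= tol, r.shape)] = np.nan
    r[var_x <= tol] = np.nan
    return np.clip(r, -1.0, 1.0)


def _check_seed(residuals: ResidualMovie, seed: tuple[int, int]) -> tuple[int, int]:
    r0, c0 = seed
    if not residuals.geometry.contains(r0, c0):
        raise ParameterError(f"seed {seed} outside the grid")
    if residuals.vessel_mask is not None and residuals.vessel_mask[r0, c0]:
        raise ParameterError(f"seed {seed} lies on a vessel")
    if not np.all(np.isfinite(residuals.data[:, :, r0, c0])):
        raise ParameterError(f"seed {seed} has missing samples")
    return int(r0), int(c0)


def sliding_window_correlation(
    residuals: ResidualMovie,
    seed: tuple[int, int],
    target: tuple[int, int],
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
) -> np.ndarray:
    """r(t) between two pixels: per-trial windowed Pearson r at every valid
    center frame, then the plain mean over trials (windows with undefined r
    are excluded from the mean; an all-undefined center frame stays NaN)."""
    r0, c0 = _check_seed(residuals, seed)
    r1, c1 = _check_seed(residuals, target)
    r = _windowed_corr_with_seed(
        residuals.data[:, :, r1, c1][..., None],
        residuals.data[:, :, r0, c0],
        window_halfwidth_frames,
    )[..., 0]
    with np.errstate(invalid="ignore"):
        return np.nanmean(r, axis=0)


def seed_correlation_map(
    residuals: ResidualMovie,
    seed: tuple[int, int],
    half_width_px: int = DEFAULT_HALF_WIDTH_PX,
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
) -> CorrelationMap:
    """Seed-centered patch of mean windowed correlations.

    Every cell is the mean over trials and all valid window centers of the
    sliding-window r between the seed and the cell's pixel.  Cells outside
    the imaged frame or on vessels are missing.  The center cell (the seed
    itself) is excluded (NaN) from the map and from any scalar summary.
    """
    r0, c0 = _check_seed(residuals, seed)
    g = residuals.geometry
    size = 2 * half_width_px + 1
    values = np.full((size, size), np.nan)
    counts = np.zeros((size, size), dtype=np.int64)

    rlo, rhi = max(0, r0 - half_width_px), min(g.n_rows, r0 + half_width_px + 1)
    clo, chi = max(0, c0 - half_width_px), min(g.n_cols, c0 + half_width_px + 1)
    patch = residuals.data[:, :, rlo:rhi, clo:chi]
    r = _windowed_corr_with_seed(
        patch, residuals.data[:, :, r0, c0], window_halfwidth_frames
    )
    defined = np.isfinite(r)
    n_undef = int(r.size - defined.sum())
    n = defined.sum(axis=(0, 1))
    total = np.where(defined, r, 0.0).sum(axis=(0, 1))
    mean_r = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    orow = slice(rlo - r0 + half_width_px, rhi - r0 + half_width_px)
    ocol = slice(clo - c0 + half_width_px, chi - c0 + half_width_px)
    values[orow, ocol] = mean_r
    counts[orow, ocol] = n
    values[half_width_px, half_width_px] = np.nan  # seed cell: r = 1 by definition
    counts[half_width_px, half_width_px] = 0
    if residuals.vessel_mask is not None:
        vm = np.zeros((size, size), dtype=bool)
        vm[orow, ocol] = residuals.vessel_mask[rlo:rhi, clo:chi]
        values[vm] = np.nan
        counts[vm] = 0
    return CorrelationMap(
        values=values,
        counts=counts,
        half_width_px=half_width_px,
        seed=(r0, c0),
        window_halfwidth_frames=window_halfwidth_frames,
        n_undefined_windows=n_undef,
    )


def average_aligned_maps(maps: Iterable[CorrelationMap]) -> CorrelationMap:
    """Cell-wise missing-aware mean of seed-aligned maps (count-weighted
    across seeds so every underlying sample has equal weight)."""
    maps = list(maps)
    if not maps:
        raise MissingDataError("no maps to average")
    hw = maps[0].half_width_px
    whw = maps[0].window_halfwidth_frames
    if any(m.half_width_px != hw for m in maps):
        raise ParameterError("maps have mismatched half widths")
    total = np.zeros_like(maps[0].values)
    counts = np.zeros_like(maps[0].counts)
    for m in maps:
        good = np.isfinite(m.values) & (m.counts > 0)
        total[good] += m.values[good] * m.counts[good]
        counts += np.where(good, m.counts, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return CorrelationMap(
        values=values,
        counts=counts,
        half_width_px=hw,
        seed=None,
        window_halfwidth_frames=whw,
        n_undefined_windows=sum(m.n_undefined_windows for m in maps),
    )


def _roi_pixels(roi) -> list[tuple[int, int]]:
    if isinstance(roi, BarrelROI):
        return roi.sorted_pixels()
    pixels = sorted(tuple(p) for p in roi)
    if not pixels:
        raise MissingDataError("empty seed ROI")
    return pixels


def unaligned_field_map(
    residuals: ResidualMovie,
    roi,
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
    target_mask: Optional[np.ndarray] = None,
) -> CorrelationMap:
    """Whole-field map: every pixel's mean correlation with the ROI seeds,
    averaged without aligning on the seed (per-pixel, count-weighted).

    ``target_mask`` restricts the computation to a subset of target pixels
    (the rest stay missing); useful when only a neighborhood summary of the
    map is needed."""
    pixels = _roi_pixels(roi)
    g = residuals.geometry
    total = np.zeros(g.shape)
    counts = np.zeros(g.shape, dtype=np.int64)
    n_undef = 0
    if target_mask is not None:
        target_mask = np.asarray(target_mask, dtype=bool)
        flat_idx = np.flatnonzero(target_mask.ravel())
        flat_data = residuals.data.reshape(*residuals.data.shape[:2], -1)[:, :, flat_idx]
    for seed in pixels:
        r0, c0 = _check_seed(residuals, seed)
        seed_series = residuals.data[:, :, r0, c0]
        if target_mask is None:
            r = _windowed_corr_with_seed(
                residuals.data, seed_series, window_halfwidth_frames
            )
            r[:, :, r0, c0] = np.nan  # self-correlation: excluded
            defined = np.isfinite(r)
            n_undef += int(r.size - defined.sum())
            total += np.where(defined, r, 0.0).sum(axis=(0, 1))
            counts += defined.sum(axis=(0, 1))
        else:
            r = _windowed_corr_with_seed(flat_data, seed_series, window_halfwidth_frames)
            self_pos = np.searchsorted(flat_idx, r0 * g.n_cols + c0)
            if self_pos < flat_idx.size and flat_idx[self_pos] == r0 * g.n_cols + c0:
                r[:, :, self_pos] = np.nan
            defined = np.isfinite(r)
            n_undef += int(r.size - defined.sum())
            total.ravel()[flat_idx] += np.where(defined, r, 0.0).sum(axis=(0, 1))
            counts.ravel()[flat_idx] += defined.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    if residuals.vessel_mask is not None:
        values[residuals.vessel_mask] = np.nan
        counts[residuals.vessel_mask] = 0
    return CorrelationMap(
        values=values,
        counts=counts,
        half_width_px=None,
        seed=None,
        window_halfwidth_frames=window_halfwidth_frames,
        n_undefined_windows=n_undef,
    )


def neighborhood_synchrony(
    corr_map: CorrelationMap,
    pixel_size_um: float,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> float:
    """Mean r over the defined cells within ``radius_um`` of the seed cell
    (count-weighted; Euclidean offsets 0 < d <= radius; the seed cell is
    excluded).  The radius in pixels is floor(radius_um / pixel_size)."""
    if not corr_map.aligned:
        raise ParameterError("neighborhood synchrony requires a seed-aligned map")
    if radius_um <= 0:
        raise ParameterError("radius_um must be > 0")
    radius_px = int(np.floor(radius_um / pixel_size_um))
    hw = corr_map.half_width_px
    offs = np.arange(-hw, hw + 1)
    d = np.hypot(offs[:, None], offs[None, :])
    sel = (d > 0) & (d <= radius_px)
    sel &= np.isfinite(corr_map.values) & (corr_map.counts > 0)
    if not sel.any():
        raise MissingDataError("no defined cells within the neighborhood radius")
    weights = corr_map.counts[sel].astype(float)
    return float(np.sum(corr_map.values[sel] * weights) / weights.sum())


def aligned_roi_synchrony(
    residuals: ResidualMovie,
    roi,
    half_width_px: int = DEFAULT_HALF_WIDTH_PX,
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
    radius_um: float = DEFAULT_RADIUS_UM,
    return_map: bool = False,
):
    """Full aligned pipeline: per-seed maps -> aligned average -> scalar.

    Seeds that fall on vessels are skipped (reported via the map's counts).
    Returns the synchrony scalar, or ``(scalar, map)`` with
    ``return_map=True``.
    """
    pixels = _roi_pixels(roi)
    vm = residuals.vessel_mask
    maps = []
    for seed in pixels:
        if vm is not None and vm[seed]:
            continue
        maps.append(
            seed_correlation_map(residuals, seed, half_width_px, window_halfwidth_frames)
        )
    if not maps:
        raise MissingDataError("every seed pixel is vessel-masked")
    mean_map = average_aligned_maps(maps)
    value = neighborhood_synchrony(
        mean_map, residuals.geometry.pixel_size_um, radius_um
    )
    return (value, mean_map) if return_map else value


def _shuffled_residuals(
    residuals: ResidualMovie, rng: np.random.Generator
) -> ResidualMovie:
    """Permute pixel positions independently within every frame of every
    trial.  Only non-vessel pixels are permuted among non-vessel positions,
    preserving the missing-data pattern."""
    n_tr, n_fr = residuals.n_trials, residuals.n_frames
    flat = residuals.data.reshape(n_tr, n_fr, -1)
    if residuals.vessel_mask is not None:
        good = ~residuals.vessel_mask.ravel()
        idx = np.flatnonzero(good)
    else:
        idx = np.arange(flat.shape[2])
    out = flat.copy()
    out[:, :, idx] = rng.permuted(flat[:, :, idx], axis=2)
    return ResidualMovie(
        data=out.reshape(residuals.data.shape),
        geometry=residuals.geometry,
        condition=residuals.condition,
        window_frames=residuals.window_frames,
        vessel_mask=residuals.vessel_mask,
    )


def shuffle_null(
    residuals: ResidualMovie,
    roi,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    half_width_px: Optional[int] = None,
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> np.ndarray:
    """Null distribution of neighborhood synchrony under spatial shuffling.

    Each iterate freshly permutes pixel positions within every frame of
    every trial, reruns the aligned-map pipeline over the ROI seeds and
    records the neighborhood-synchrony scalar.  ``half_width_px`` defaults
    to just covering the neighborhood radius (the scalar only reads cells
    within it, so a larger patch would change nothing).
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    if half_width_px is None:
        half_width_px = max(
            1, int(np.floor(radius_um / residuals.geometry.pixel_size_um))
        )
    rng = np.random.default_rng(rng_seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = _shuffled_residuals(residuals, rng)
        out[i] = aligned_roi_synchrony(
            shuffled, roi, half_width_px, window_halfwidth_frames, radius_um
        )
    return out


def synchrony_timecourse(
    residuals: ResidualMovie,
    roi,
    window_halfwidth_frames: int = DEFAULT_WINDOW_HALFWIDTH_FRAMES,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood synchrony resolved over window-center time.

    For every valid center frame (the first is ``window_halfwidth_frames``),
    the windowed r is averaged over trials, seeds and the in-radius
    neighborhood cells.  Returns ``(times_ms, r_of_t)`` with times relative
    to stimulus onset for evoked residuals and to trial start otherwise.
    """
    pixels = _roi_pixels(roi)
    g = residuals.geometry
    radius_px = int(np.floor(radius_um / g.pixel_size_um))
    hw = window_halfwidth_frames
    n_centers = residuals.n_frames - 2 * hw
    if n_centers < 1:
        raise ParameterError("analysis window shorter than one correlation window")
    total = np.zeros(n_centers)
    count = np.zeros(n_centers)
    offs = np.arange(-radius_px, radius_px + 1)
    dgrid = np.hypot(offs[:, None], offs[None, :])
    vm = residuals.vessel_mask
    for seed in pixels:
        if vm is not None and vm[seed]:
            continue
        r0, c0 = _check_seed(residuals, seed)
        rlo, rhi = max(0, r0 - radius_px), min(g.n_rows, r0 + radius_px + 1)
        clo, chi = max(0, c0 - radius_px), min(g.n_cols, c0 + radius_px + 1)
        patch = residuals.data[:, :, rlo:rhi, clo:chi]
        r = _windowed_corr_with_seed(
            patch, residuals.data[:, :, r0, c0], window_halfwidth_frames
        )
        dsub = dgrid[
            rlo - r0 + radius_px : rhi - r0 + radius_px,
            clo - c0 + radius_px : chi - c0 + radius_px,
        ]
        sel = (dsub > 0) & (dsub <= radius_px)
        if vm is not None:
            sel &= ~vm[rlo:rhi, clo:chi]
        rr = r[:, :, sel]
        defined = np.isfinite(rr)
        total += np.where(defined, rr, 0.0).sum(axis=(0, 2))
        count += defined.sum(axis=(0, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    lo, _ = residuals.window_frames
    centers = np.arange(hw, residuals.n_frames - hw) + lo
    t = centers * g.dt_ms
    if residuals.condition == "evoked" and g.stim_onset_frame is not None:
        t = t - g.stim_onset_frame * g.dt_ms
    return t, values


def field_map_neighborhood(
    corr_map: CorrelationMap,
    roi,
    pixel_size_um: float,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> float:
    """Neighborhood summary of an unaligned full-field map: the mean of the
    defined cells lying within ``radius_um`` of any ROI seed, with the seed
    cells themselves excluded (mirroring the aligned scalar)."""
    if corr_map.aligned:
        raise ParameterError("expected an unaligned full-field map")
    pixels = _roi_pixels(roi)
    radius_px = int(np.floor(radius_um / pixel_size_um))
    n_rows, n_cols = corr_map.values.shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    near = np.zeros((n_rows, n_cols), dtype=bool)
    for r0, c0 in pixels:
        near |= np.hypot(rows - r0, cols - c0) <= radius_px
    for r0, c0 in pixels:
        near[r0, c0] = False
    sel = near & np.isfinite(corr_map.values) & (corr_map.counts > 0)
    if not sel.any():
        raise MissingDataError("no defined cells near the ROI")
    w = corr_map.counts[sel].astype(float)
    return float(np.sum(corr_map.values[sel] * w) / w.sum())
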