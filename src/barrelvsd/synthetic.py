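"""Synthetic widefield VSD movie generator with known ground truth.

Generates raw fluorescence movies with the statistical structure the
analysis pipeline assumes: a radially propagating whisker-evoked response,
spatially correlated spontaneous fluctuations, a global heart-beat
sinusoid, exponential photobleaching, dark curvilinear blood vessels and
per-pixel shot noise.  The signal model is multiplicative,

    F(t, x, y) = F0(x, y) * (1 + R + S + H) * B(t) + eps,

so ΔF/F preprocessing recovers the injected components exactly in the
noise-free limit:

* ``R(t, x, y)`` — evoked response: a peak-normalized rise/decay
  double exponential in local time (delayed by ``d / propagation_speed``),
  attenuated with distance as ``exp(-d / lambda)`` where the damping
  length ``lambda`` grows slowly with local time (lateral spread into
  neighboring columns).
* ``S(t, x, y)`` — spontaneous fluctuation: spatially Gaussian-correlated,
  temporally AR(1) noise with marginal sd ``spont_amplitude``.
* ``H(t)`` — heart-beat sinusoid, spatially uniform, random phase per trial.
* ``B(t) = exp(-t / bleach_tau)`` — photobleaching shared by all pixels.
* ``eps`` — white shot noise with sd ``noise_sd * F0``.

Two default parameter sets emulate the study groups: a control-like set
("Ctrl") and a transgenic amyloid-model-like set ("Tg") with ~70% larger
evoked amplitude, faster lateral spread growth, slower rise kinetics and a
shorter spontaneous spatial correlation length.

Every generator output is a pure function of (geometry, params, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionGeometry,
    ConditionError,
    FluorescenceMovie,
    GeometryError,
    ParameterError,
)

__all__ = [
    "GenotypeParams",
    "TrialGroundTruth",
    "AnimalRecord",
    "Cohort",
    "ctrl_like_params",
    "tg_like_params",
    "default_evoked_geometry",
    "default_spontaneous_geometry",
    "generate_vessel_mask",
    "generate_evoked_trial",
    "generate_evoked_trials",
    "generate_spontaneous_trial",
    "generate_spontaneous_trials",
    "generate_blank_trial",
    "generate_blank_trials",
    "generate_cohort",
    "generate_f0_map",
    "evoked_response_field",
    "response_peak_time_ms",
    "sample_peak_estimates",
]

#: Fraction of the grid that vessel paths are allowed to cover at most.
MAX_VESSEL_FRACTION = 0.15
#: Vessel-free radius kept around the imaging center in cohort generation.
CLEAR_DISC_RADIUS_PX = 8

#: Resting fluorescence level (camera counts) and its depression on vessels.
F0_LEVEL = 1000.0
VESSEL_F0_FACTOR = 0.8
#: Multiplicative staining/illumination inhomogeneity of the resting light.
F0_TEXTURE_SD = 0.02
F0_TEXTURE_CORR_PX = 3.0


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters for one genotype group.

    Amplitudes are in ΔF/F units, lengths in μm, times in ms,
    frequencies in Hz.  ``spread_growth`` and ``propagation_speed`` are in
    μm/ms.  ``spont_temporal_ar`` is the AR(1) coefficient of the
    spontaneous field per frame.
    """

    label: str = "Ctrl"
    evoked_amplitude: float = 4.3e-3
    spread_sigma0: float = 650.0
    spread_growth: float = 0.5
    propagation_speed: float = 40.0
    rise_tau: float = 15.0
    decay_tau: float = 160.0
    spont_corr_length: float = 100.0
    spont_amplitude: float = 5.0e-4
    noise_sd: float = 5.0e-4
    heartbeat_freq: float = 9.0
    heartbeat_amp: float = 1.0e-4
    bleach_tau: float = 5.0e4
    spont_temporal_ar: float = 0.8

    def __post_init__(self) -> None:
        positive = (
            "evoked_amplitude spread_sigma0 spread_growth propagation_speed "
            "rise_tau decay_tau spont_corr_length spont_amplitude noise_sd "
            "heartbeat_freq heartbeat_amp bleach_tau"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.decay_tau <= self.rise_tau:
            raise ParameterError(
                f"decay_tau ({self.decay_tau}) must exceed rise_tau ({self.rise_tau})"
            )
        if not (0.0 <= self.spont_temporal_ar < 1.0):
            raise ParameterError("spont_temporal_ar must be in [0, 1)")

    def evolve(self, **changes) -> "GenotypeParams":
        return replace(self, **changes)


def ctrl_like_params() -> GenotypeParams:
    """Control-group-like defaults (see module docstring)."""
    return GenotypeParams()


def tg_like_params() -> GenotypeParams:
    """Transgenic-amyloid-model-like defaults: ~1.7x evoked amplitude,
    faster lateral spread growth, slower rise, shorter spontaneous
    correlation length than the control-like set."""
    return GenotypeParams(
        label="Tg",
        evoked_amplitude=7.3e-3,
        spread_growth=1.5,
        rise_tau=22.0,
        spont_corr_length=60.0,
    )


def default_evoked_geometry(n_rows: int = 100, n_cols: int = 100) -> AcquisitionGeometry:
    """100 Hz, 50 μm/px; 100 ms pre-stimulus and 300 ms post-stimulus."""
    return AcquisitionGeometry(
        n_rows=n_rows, n_cols=n_cols, n_frames=40, stim_onset_frame=10
    )


def default_spontaneous_geometry(n_rows: int = 100, n_cols: int = 100) -> AcquisitionGeometry:
    """100 Hz, 50 μm/px; 2500 ms of unstimulated recording."""
    return AcquisitionGeometry(n_rows=n_rows, n_cols=n_cols, n_frames=250)


@dataclass
class TrialGroundTruth:
    """What was injected into one generated trial."""

    condition: str
    seed: int
    evoked_amplitude: float = 0.0
    center: Optional[tuple[int, int]] = None
    spont_corr_length: float = 0.0
    heartbeat_phase: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["center"] is not None:
            d["center"] = list(d["center"])
        return d


# ---------------------------------------------------------------------------
# vessels
# ---------------------------------------------------------------------------

def generate_vessel_mask(
    geometry: AcquisitionGeometry, n_vessels: int, rng_seed: int
) -> np.ndarray:
    """Curvilinear blood-vessel mask from seeded random walks.

    Procedure (deterministic given the seed; each vessel consumes draws in
    this exact order from ``numpy.random.default_rng(rng_seed)``):

    1. start row, start col: two ``integers`` draws over the grid;
    2. initial heading: one ``uniform(0, 2*pi)`` draw;
    3. for each of ``n_rows + n_cols`` steps: one ``normal(0, 0.2)`` draw
       added to the heading, then the position advances one unit along it;
       the nearest pixel is marked, and for even-indexed vessels the pixel
       one column to the right as well (width 2); the walk stops when it
       leaves the grid.

    Marking stops once ``MAX_VESSEL_FRACTION`` of the grid is covered.
    """
    if n_vessels < 0:
        raise ParameterError(f"n_vessels must be >= 0, got {n_vessels}")
    mask = np.zeros(geometry.shape, dtype=bool)
    if n_vessels == 0:
        return mask
    rng = np.random.default_rng(rng_seed)
    max_pixels = int(MAX_VESSEL_FRACTION * mask.size)
    n_steps = geometry.n_rows + geometry.n_cols
    for vessel_idx in range(n_vessels):
        r = float(rng.integers(0, geometry.n_rows))
        c = float(rng.integers(0, geometry.n_cols))
        heading = rng.uniform(0.0, 2.0 * math.pi)
        wide = vessel_idx % 2 == 0
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.2)
            r += math.sin(heading)
            c += math.cos(heading)
            ri, ci = int(round(r)), int(round(c))
            if not geometry.contains(ri, ci):
                break
            if mask.sum() >= max_pixels:
                return mask
            mask[ri, ci] = True
            if wide and ci + 1 < geometry.n_cols:
                mask[ri, ci + 1] = True
    return mask


# ---------------------------------------------------------------------------
# evoked response field (closed form)
# ---------------------------------------------------------------------------

def _double_exp(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Rise/decay double exponential, peak-normalized to 1, zero for t <= 0."""
    t = np.maximum(np.asarray(t_ms, dtype=float), 0.0)
    g = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    t_star = response_peak_time_ms(rise_tau, decay_tau)
    g_max = math.exp(-t_star / decay_tau) - math.exp(-t_star / rise_tau)
    out = g / g_max
    out[np.asarray(t_ms) <= 0] = 0.0
    return out


def response_peak_time_ms(rise_tau: float, decay_tau: float) -> float:
    """Analytic argmax of the double exponential (local time after onset):
    ``t* = ln(decay/rise) * rise * decay / (decay - rise)``."""
    return math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)


def evoked_response_field(
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
    center: tuple[int, int],
) -> np.ndarray:
    """Noise-free evoked ΔF/F component ``R(t, x, y)``, shape (n_frames, rows, cols).

    At distance ``d`` (μm) from the wavefront center, the local time is
    ``tl = t - t_onset - d / propagation_speed``; the response is
    ``evoked_amplitude * g(tl) * exp(-d / lambda(tl))`` with the damping
    length ``lambda(tl) = spread_sigma0 + spread_growth * tl`` and ``g`` the
    peak-normalized double exponential (zero for ``tl <= 0``).  The
    exponential distance profile keeps the early response confined to the
    barrel column while still reaching the outer rings at later times, and
    propagation delay — not envelope growth — sets ring latencies.
    """
    if geometry.stim_onset_frame is None:
        raise ConditionError("evoked trial requires geometry with stim_onset_frame")
    r0, c0 = center
    if not geometry.contains(r0, c0):
        raise ParameterError(f"center {center} outside the {geometry.shape} grid")
    rows = np.arange(geometry.n_rows)[:, None]
    cols = np.arange(geometry.n_cols)[None, :]
    d_um = np.hypot(rows - r0, cols - c0) * geometry.pixel_size_um
    t_ms = geometry.frame_times_ms(relative_to_stim=True)[:, None, None]
    tl = t_ms - d_um[None] / params.propagation_speed
    lam = params.spread_sigma0 + params.spread_growth * np.maximum(tl, 0.0)
    damping = np.exp(-d_um[None] / lam)
    return params.evoked_amplitude * _double_exp(tl, params.rise_tau, params.decay_tau) * damping


# ---------------------------------------------------------------------------
# stochastic components
# ---------------------------------------------------------------------------

def _spont_fields(
    rng: np.random.Generator,
    n_trials: int,
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
) -> np.ndarray:
    """Spontaneous fluctuation S: spatially Gaussian-correlated (wrap-around
    boundary, so the field is stationary), AR(1) in time, marginal sd
    ``spont_amplitude``.  Shape (n_trials, n_frames, rows, cols), float64."""
    if params.spont_corr_length <= 0:
        raise ParameterError("spont_corr_length must be > 0")
    shape = (n_trials, geometry.n_frames, geometry.n_rows, geometry.n_cols)
    # single precision throughout: the field is noise, and the caller
    # upcasts before assembling the movie
    white = rng.standard_normal(shape, dtype=np.float32)
    sigma_px = params.spont_corr_length / geometry.pixel_size_um
    if sigma_px >= 0.3:
        smoothed = ndimage.gaussian_filter(
            white, sigma=(0, 0, sigma_px, sigma_px), mode="wrap"
        )
        sd = smoothed.std()
        if sd > 0:
            smoothed /= sd
    else:
        smoothed = white  # kernel narrower than a pixel: effectively white
    phi = np.float32(params.spont_temporal_ar)
    if phi > 0:
        out = np.empty_like(smoothed)
        out[:, 0] = smoothed[:, 0]
        scale = np.float32(math.sqrt(1.0 - float(phi) ** 2))
        for k in range(1, geometry.n_frames):
            out[:, k] = phi * out[:, k - 1] + scale * smoothed[:, k]
        smoothed = out
    return params.spont_amplitude * smoothed.astype(np.float64, copy=False)


def _heartbeat(
    geometry: AcquisitionGeometry, params: GenotypeParams, phases: np.ndarray
) -> np.ndarray:
    """Global heart-beat sinusoid per trial, shape (n_trials, n_frames)."""
    t_s = geometry.frame_times_ms()[None, :] / 1000.0
    return params.heartbeat_amp * np.sin(
        2.0 * math.pi * params.heartbeat_freq * t_s + phases[:, None]
    )


def _bleach(geometry: AcquisitionGeometry, params: GenotypeParams) -> np.ndarray:
    return np.exp(-geometry.frame_times_ms() / params.bleach_tau)


def generate_f0_map(
    geometry: AcquisitionGeometry,
    rng_seed: int,
    texture_sd: float = F0_TEXTURE_SD,
    texture_corr_px: float = F0_TEXTURE_CORR_PX,
) -> np.ndarray:
    """Resting-fluorescence map with smooth staining/illumination texture
    (multiplicative, sd ``texture_sd``, correlation length ``texture_corr_px``).
    The texture is static per animal; ΔF/F normalization removes it exactly,
    but it gives vessel detection a physical background scale."""
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(geometry.shape)
    tex = ndimage.gaussian_filter(white, texture_corr_px, mode="wrap")
    sd = tex.std()
    if sd > 0:
        tex /= sd
    return F0_LEVEL * (1.0 + texture_sd * tex)


def _f0_grid(
    geometry: AcquisitionGeometry,
    vessel_mask: Optional[np.ndarray],
    f0_map: Optional[np.ndarray] = None,
) -> np.ndarray:
    f0 = np.full(geometry.shape, F0_LEVEL) if f0_map is None else f0_map.copy()
    if vessel_mask is not None:
        f0[vessel_mask] *= VESSEL_F0_FACTOR
    return f0


def _assemble(
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
    rng: np.random.Generator,
    n_trials: int,
    response: Optional[np.ndarray],
    vessel_mask: Optional[np.ndarray],
    f0_map: Optional[np.ndarray] = None,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray]:
    """Build raw movies; returns (data, heartbeat_phases).

    Random draws are consumed in a fixed order (phases, spontaneous field,
    shot noise) so that blank and evoked trials generated from the same seed
    differ only where the evoked component is nonzero.  ``dtype=float32``
    halves memory traffic for large simulation studies.
    """
    phases = rng.uniform(0.0, 2.0 * math.pi, size=n_trials)
    signal = _spont_fields(rng, n_trials, geometry, params).astype(dtype, copy=False)
    signal += _heartbeat(geometry, params, phases)[:, :, None, None].astype(dtype)
    if response is not None:
        signal += response[None].astype(dtype, copy=False)
    f0 = _f0_grid(geometry, vessel_mask, f0_map).astype(dtype, copy=False)
    data = f0[None, None] * (1.0 + signal)
    data *= _bleach(geometry, params)[None, :, None, None].astype(dtype)
    data += rng.standard_normal(data.shape, dtype=np.float32) * (params.noise_sd * f0)
    np.maximum(data, 0.0, out=data)  # camera counts cannot go negative
    return data, phases


def generate_evoked_trials(
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
    center: tuple[int, int],
    rng_seed: int,
    n_trials: int = 1,
    vessel_mask: Optional[np.ndarray] = None,
    f0_map: Optional[np.ndarray] = None,
    group: str = "",
    animal_id: str = "",
    dtype=np.float64,
) -> tuple[FluorescenceMovie, list[TrialGroundTruth]]:
    """Whisker-evoked trials sharing one wavefront center."""
    response = evoked_response_field(geometry, params, center)
    rng = np.random.default_rng(rng_seed)
    data, phases = _assemble(
        geometry, params, rng, n_trials, response, vessel_mask, f0_map, dtype
    )
    movie = FluorescenceMovie(data, geometry, "evoked", group, animal_id)
    truth = [
        TrialGroundTruth(
            condition="evoked",
            seed=int(rng_seed),
            evoked_amplitude=params.evoked_amplitude,
            center=tuple(center),
            spont_corr_length=params.spont_corr_length,
            heartbeat_phase=float(phases[i]),
        )
        for i in range(n_trials)
    ]
    return movie, truth


def generate_evoked_trial(geometry, params, center, rng_seed, **kw):
    """Single evoked trial; see :func:`generate_evoked_trials`."""
    return generate_evoked_trials(geometry, params, center, rng_seed, n_trials=1, **kw)


def generate_spontaneous_trials(
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
    rng_seed: int,
    n_trials: int = 1,
    vessel_mask: Optional[np.ndarray] = None,
    f0_map: Optional[np.ndarray] = None,
    group: str = "",
    animal_id: str = "",
    dtype=np.float64,
) -> tuple[FluorescenceMovie, list[TrialGroundTruth]]:
    """Unstimulated trials: spontaneous field plus artifacts and noise."""
    rng = np.random.default_rng(rng_seed)
    data, phases = _assemble(
        geometry, params, rng, n_trials, None, vessel_mask, f0_map, dtype
    )
    movie = FluorescenceMovie(data, geometry, "spontaneous", group, animal_id)
    truth = [
        TrialGroundTruth(
            condition="spontaneous",
            seed=int(rng_seed),
            spont_corr_length=params.spont_corr_length,
            heartbeat_phase=float(phases[i]),
        )
        for i in range(n_trials)
    ]
    return movie, truth


def generate_spontaneous_trial(geometry, params, rng_seed, **kw):
    return generate_spontaneous_trials(geometry, params, rng_seed, n_trials=1, **kw)


def generate_blank_trials(
    geometry: AcquisitionGeometry,
    params: GenotypeParams,
    rng_seed: int,
    n_trials: int = 1,
    vessel_mask: Optional[np.ndarray] = None,
    f0_map: Optional[np.ndarray] = None,
    group: str = "",
    animal_id: str = "",
    dtype=np.float64,
) -> FluorescenceMovie:
    """Blank (no-stimulation) trials on the evoked timebase: identical to
    evoked generation with the response off, retaining heartbeat, bleaching,
    spontaneous fluctuation and shot noise."""
    rng = np.random.default_rng(rng_seed)
    data, _ = _assemble(geometry, params, rng, n_trials, None, vessel_mask, f0_map, dtype)
    return FluorescenceMovie(data, geometry, "blank", group, animal_id)


def generate_blank_trial(geometry, params, rng_seed, **kw):
    return generate_blank_trials(geometry, params, rng_seed, n_trials=1, **kw)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Parameters subject to multiplicative between-animal jitter.
JITTERED_PARAMS = (
    "evoked_amplitude",
    "spread_sigma0",
    "spread_growth",
    "rise_tau",
    "decay_tau",
    "spont_corr_length",
)


@dataclass
class AnimalRecord:
    """All generated data and ground truth for one animal."""

    animal_id: str
    group: str
    params: GenotypeParams
    center: tuple[int, int]
    vessel_mask: np.ndarray
    evoked: Optional[FluorescenceMovie]
    blank: Optional[FluorescenceMovie]
    spontaneous: Optional[FluorescenceMovie]
    trial_truth: list[TrialGroundTruth] = field(default_factory=list)
    seed: int = 0


@dataclass
class Cohort:
    """Two-group synthetic study."""

    animals: list[AnimalRecord]
    evoked_geometry: Optional[AcquisitionGeometry]
    spontaneous_geometry: Optional[AcquisitionGeometry]
    seed: int

    def group(self, label: str) -> list[AnimalRecord]:
        return [a for a in self.animals if a.group == label]

    def ground_truth_json(self) -> str:
        records = []
        for a in self.animals:
            records.append(
                {
                    "animal_id": a.animal_id,
                    "group": a.group,
                    "seed": a.seed,
                    "center": list(a.center),
                    "params": asdict(a.params),
                    "trials": [t.to_dict() for t in a.trial_truth],
                }
            )
        return json.dumps({"seed": self.seed, "animals": records}, indent=2)


def _jitter_params(
    params: GenotypeParams, rng: np.random.Generator, jitter_sd: float
) -> GenotypeParams:
    """Multiplicative log-normal jitter (median-preserving) on the
    amplitude/kinetics/spread parameters."""
    if jitter_sd <= 0:
        return params
    changes = {
        name: getattr(params, name) * math.exp(rng.normal(0.0, jitter_sd))
        for name in JITTERED_PARAMS
    }
    return params.evolve(**changes)


def generate_cohort(
    ctrl_params: Optional[GenotypeParams] = None,
    tg_params: Optional[GenotypeParams] = None,
    n_animals_per_group: tuple[int, int] = (8, 6),
    n_trials_per_condition: int = 20,
    rng_seed: int = 0,
    evoked_geometry: Optional[AcquisitionGeometry] = None,
    spontaneous_geometry: Optional[AcquisitionGeometry] = None,
    n_blank_trials: Optional[int] = None,
    n_spontaneous_trials: Optional[int] = None,
    jitter_sd: float = 0.1,
    n_vessels: int = 6,
    conditions: Sequence[str] = ("evoked", "blank", "spontaneous"),
    dtype=np.float64,
) -> Cohort:
    """Generate a full two-group study.

    Default sizes mirror the study design: 8 control and 6 transgenic
    animals, 20 trials per condition.  Blank/spontaneous trial counts
    default to ``n_trials_per_condition`` but can be reduced independently.
    Per-animal parameters get multiplicative log-normal jitter
    (sd ``jitter_sd``, default 10%).  Evoked-response centers sit near the
    middle of the grid with a ±2 px uniform scatter, off vessels.
    """
    if ctrl_params is None:
        ctrl_params = ctrl_like_params()
    if tg_params is None:
        tg_params = tg_like_params()
    n_ctrl, n_tg = n_animals_per_group
    if n_ctrl < 1 or n_tg < 1 or n_trials_per_condition < 1:
        raise ParameterError("animal and trial counts must be >= 1")
    if evoked_geometry is None and ("evoked" in conditions or "blank" in conditions):
        evoked_geometry = default_evoked_geometry()
    if spontaneous_geometry is None and "spontaneous" in conditions:
        spontaneous_geometry = default_spontaneous_geometry()
    if n_blank_trials is None:
        n_blank_trials = n_trials_per_condition
    if n_spontaneous_trials is None:
        n_spontaneous_trials = n_trials_per_condition

    geometry_for_mask = evoked_geometry or spontaneous_geometry
    ss = np.random.SeedSequence(rng_seed)
    animals: list[AnimalRecord] = []
    plan = [("Ctrl", ctrl_params, i) for i in range(n_ctrl)] + [
        ("Tg", tg_params, i) for i in range(n_tg)
    ]
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(plan))]
    for (group, base_params, idx), animal_seed in zip(plan, child_seeds):
        rng = np.random.default_rng(animal_seed)
        params = _jitter_params(base_params, rng, jitter_sd)
        g = geometry_for_mask
        f0_map = generate_f0_map(g, int(rng.integers(2**31)))
        # the imaging field is centered on the studied barrel column, which
        # the experimenter picks away from large vessels: keep a clear disc
        # around the grid center when drawing the vessel pattern
        rows = np.arange(g.n_rows)[:, None] - g.n_rows // 2
        cols = np.arange(g.n_cols)[None, :] - g.n_cols // 2
        disc_radius = min(CLEAR_DISC_RADIUS_PX, min(g.n_rows, g.n_cols) // 5)
        central_disc = np.hypot(rows, cols) <= disc_radius
        vessel_mask = None
        for _ in range(50):
            cand_mask = generate_vessel_mask(g, n_vessels, int(rng.integers(2**31)))
            if not np.any(cand_mask & central_disc):
                vessel_mask = cand_mask
                break
        if vessel_mask is None:
            raise GeometryError(
                "could not draw a vessel pattern clear of the imaging center"
            )
        center = (
            g.n_rows // 2 + int(rng.integers(-2, 3)),
            g.n_cols // 2 + int(rng.integers(-2, 3)),
        )

        animal_id = f"{group.lower()}{idx + 1:02d}"
        truth: list[TrialGroundTruth] = []
        evoked = blank = spont = None
        if "evoked" in conditions:
            evoked, t = generate_evoked_trials(
                evoked_geometry, params, center, int(rng.integers(2**31)),
                n_trials=n_trials_per_condition, vessel_mask=vessel_mask,
                f0_map=f0_map, group=group, animal_id=animal_id, dtype=dtype,
            )
            truth += t
        if "blank" in conditions:
            blank = generate_blank_trials(
                evoked_geometry, params, int(rng.integers(2**31)),
                n_trials=n_blank_trials, vessel_mask=vessel_mask,
                f0_map=f0_map, group=group, animal_id=animal_id, dtype=dtype,
            )
        if "spontaneous" in conditions:
            spont, t = generate_spontaneous_trials(
                spontaneous_geometry, params, int(rng.integers(2**31)),
                n_trials=n_spontaneous_trials, vessel_mask=vessel_mask,
                f0_map=f0_map, group=group, animal_id=animal_id, dtype=dtype,
            )
            truth += t
        animals.append(
            AnimalRecord(
                animal_id=animal_id, group=group, params=params, center=center,
                vessel_mask=vessel_mask, evoked=evoked, blank=blank,
                spontaneous=spont, trial_truth=truth, seed=animal_seed,
            )
        )
    return Cohort(animals, evoked_geometry, spontaneous_geometry, rng_seed)


# ---------------------------------------------------------------------------
# summary-level sampler (for large statistical-calibration simulations)
# ---------------------------------------------------------------------------

def sample_peak_estimates(
    params: GenotypeParams,
    n_animals: int,
    n_trials: int,
    rng: np.random.Generator,
    jitter_sd: float = 0.1,
    measurement_sd: Optional[float] = None,
    n_roi_pixels: int = 15,
) -> np.ndarray:
    """Per-animal peak-amplitude estimates drawn from the movie model's own
    statistical abstraction, without rendering movies.

    Each animal's true peak is ``evoked_amplitude`` times a log-normal
    jitter factor (sd ``jitter_sd``); its estimate adds the noise of a peak
    read off an ROI-averaged, trial-averaged trace:
    sd = sqrt(noise_sd^2 + spont_amplitude^2) / sqrt(n_roi_pixels * n_trials)
    (the spontaneous term is only partly reduced by ROI pooling, so this is
    mildly optimistic; adequate for calibration studies of the rank tests).
    """
    true_peaks = params.evoked_amplitude * np.exp(
        rng.normal(0.0, jitter_sd, size=n_animals)
    )
    if measurement_sd is None:
        measurement_sd = math.sqrt(
            params.noise_sd**2 + params.spont_amplitude**2
        ) / math.sqrt(n_roi_pixels * n_trials)
    return true_peaks + rng.normal(0.0, measurement_sd, size=n_animals)
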