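"""End-to-end orchestration: cohort → per-animal metrics → group statistics.

The per-animal stage order is fixed: ΔF/F normalization, blank
subtraction, vessel exclusion, trial averaging, barrel-ROI detection,
temporal metrics, ring spread analysis, residualization and synchrony.
Group statistics always operate on per-animal values.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import preprocess, rings, roi, stats, synchrony
from .config import PipelineConfig
from .core import DffMovie, MissingDataError
from .metrics import peak_response, response_metrics, roi_timecourse
from .synthetic import AnimalRecord, Cohort

log = logging.getLogger("barrelvsd")

__all__ = ["AnimalResult", "CohortResult", "analyze_animal", "analyze_cohort", "run_pipeline"]


@dataclass
class AnimalResult:
    """Per-animal summary values, one row of the group-comparison tables."""

    animal_id: str
    group: str
    center: tuple[int, int]
    roi_size: int
    n_vessel_pixels: int
    peak_amplitude: float
    time_to_peak_ms: float
    max_derivative: float
    min_derivative: float
    time_to_half_peak_ms: Optional[float]
    ring_latencies_ms: list = field(default_factory=list)
    ring_half_peak_ms: list = field(default_factory=list)
    profile: Optional[np.ndarray] = None
    spont_synchrony: Optional[float] = None
    spont_null_mean: Optional[float] = None
    spont_null: Optional[np.ndarray] = None
    evoked_synchrony: Optional[float] = None
    spont_map: Optional[np.ndarray] = None

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "group": self.group,
            "center_row": self.center[0],
            "center_col": self.center[1],
            "roi_size": self.roi_size,
            "n_vessel_pixels": self.n_vessel_pixels,
            "peak_amplitude": self.peak_amplitude,
            "time_to_peak_ms": self.time_to_peak_ms,
            "max_derivative": self.max_derivative,
            "min_derivative": self.min_derivative,
            "time_to_half_peak_ms": self.time_to_half_peak_ms,
            "spont_synchrony": self.spont_synchrony,
            "spont_null_mean": self.spont_null_mean,
            "evoked_synchrony": self.evoked_synchrony,
        }
        for i, v in enumerate(self.ring_latencies_ms):
            row[f"ring{i + 1}_latency_ms"] = v
        for i, v in enumerate(self.ring_half_peak_ms):
            row[f"ring{i + 1}_half_peak_ms"] = v
        return row


@dataclass
class CohortResult:
    animals: list
    comparisons: dict
    config: PipelineConfig

    def metrics_table(self) -> pd.DataFrame:
        return pd.DataFrame([a.to_row() for a in self.animals])

    def group_values(self, metric: str, group: str) -> np.ndarray:
        return np.array(
            [getattr(a, metric) for a in self.animals
             if a.group == group and getattr(a, metric) is not None]
        )

    def summary_json(self) -> str:
        payload = {
            "config_hash": self.config.content_hash(),
            "comparisons": {
                name: {
                    "test": c.test,
                    "method": c.method,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "a_mean": c.a_mean,
                    "a_sem": c.a_sem,
                    "b_mean": c.b_mean,
                    "b_sem": c.b_sem,
                    "stars": c.stars(),
                }
                for name, c in self.comparisons.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def preprocess_animal(animal: AnimalRecord, config: PipelineConfig):
    """ΔF/F → blank subtraction → vessel exclusion for one animal.

    Returns (evoked_dff_masked, spontaneous_dff_masked_or_None, vessel_mask).
    Vessels are detected on the trial/frame-averaged raw blank image.
    """
    if animal.evoked is None:
        raise MissingDataError(f"animal {animal.animal_id} has no evoked trials")
    if animal.blank is None:
        raise MissingDataError(
            f"animal {animal.animal_id} has no blank trials for blank subtraction"
        )
    g = animal.evoked.geometry
    n_base = config.baseline_n_frames(g.frame_rate_hz)
    blank_dff = preprocess.compute_dff(animal.blank, n_base)
    vessels = preprocess.detect_vessels(
        animal.blank.data.mean(axis=(0, 1)),
        config.vessel_highpass_sigma_px,
        config.vessel_threshold_k,
    )
    evoked_dff = preprocess.compute_dff(animal.evoked, n_base)
    evoked_dff = preprocess.subtract_blank(evoked_dff, blank_dff)
    evoked_dff = evoked_dff.with_vessels_masked(vessels.mask)
    spont_dff = None
    if animal.spontaneous is not None:
        sg = animal.spontaneous.geometry
        spont_dff = preprocess.compute_dff(
            animal.spontaneous, config.baseline_n_frames(sg.frame_rate_hz)
        )
        spont_dff = spont_dff.with_vessels_masked(vessels.mask)
    return evoked_dff, spont_dff, vessels.mask


def analyze_animal(
    animal: AnimalRecord,
    config: PipelineConfig,
    compute_synchrony: bool = True,
    compute_evoked_synchrony: bool = False,
    n_shuffles: Optional[int] = None,
    keep_maps: bool = False,
    compute_rings: bool = True,
) -> AnimalResult:
    """Full single-animal analysis; ``n_shuffles=0`` skips the null and
    ``compute_rings=False`` skips the spatial-spread stage."""
    evoked_dff, spont_dff, vessel_mask = preprocess_animal(animal, config)
    g = evoked_dff.geometry
    mean_movie = preprocess.average_trials(evoked_dff)
    center = roi.find_center(mean_movie, g, config.roi_early_time_ms)
    barrel = roi.define_roi(
        mean_movie, g, config.roi_early_time_ms,
        config.roi_threshold_fraction, config.roi_connectivity, center=center,
    )
    tc = roi_timecourse(mean_movie, barrel, g, label="barrel")
    m = response_metrics(tc)

    latencies, halves, profile_values = [], [], None
    if compute_rings:
        ring_set = rings.define_rings(
            center, g, config.ring_width_um, config.n_rings, vessel_mask
        )
        ring_tcs = rings.ring_timecourses(mean_movie, ring_set, g)
        for rtc in ring_tcs:
            if rtc is None:
                latencies.append(np.nan)
                halves.append(np.nan)
                continue
            latencies.append(peak_response(rtc, interpolate=True)[1])
            try:
                halves.append(_half_peak(rtc))
            except MissingDataError:
                halves.append(np.nan)
        profile_values = rings.spatial_profile(
            mean_movie, ring_set, g, config.profile_sample_times_ms,
            reference_time_ms=config.roi_early_time_ms,
        ).values

    result = AnimalResult(
        animal_id=animal.animal_id,
        group=animal.group,
        center=center,
        roi_size=barrel.size,
        n_vessel_pixels=int(vessel_mask.sum()),
        peak_amplitude=m.peak_amplitude,
        time_to_peak_ms=m.time_to_peak_ms,
        max_derivative=m.max_derivative,
        min_derivative=m.min_derivative,
        time_to_half_peak_ms=m.time_to_half_peak_ms,
        ring_latencies_ms=latencies,
        ring_half_peak_ms=halves,
        profile=profile_values,
    )

    if compute_synchrony and spont_dff is not None and spont_dff.n_trials >= 2:
        whw = config.window_halfwidth_frames(spont_dff.geometry.frame_rate_hz)
        n_window = int(round(
            config.spontaneous_window_ms / spont_dff.geometry.dt_ms
        ))
        residuals = synchrony.make_residuals(
            spont_dff, (0, min(n_window, spont_dff.geometry.n_frames))
        )
        # without map output only cells inside the neighborhood radius
        # contribute to the scalar, so a radius-sized patch suffices
        half_width = config.corr_map_half_width_px if keep_maps else max(
            1, int(config.synchrony_radius_um // spont_dff.geometry.pixel_size_um)
        )
        value, mean_map = synchrony.aligned_roi_synchrony(
            residuals, barrel, half_width, whw,
            config.synchrony_radius_um, return_map=True,
        )
        result.spont_synchrony = value
        if keep_maps:
            result.spont_map = mean_map.values
        n_sh = config.n_shuffles if n_shuffles is None else n_shuffles
        if n_sh > 0:
            null = synchrony.shuffle_null(
                residuals, barrel, n_sh, rng_seed=animal.seed,
                window_halfwidth_frames=whw, radius_um=config.synchrony_radius_um,
            )
            result.spont_null = null
            result.spont_null_mean = float(null.mean())

    if compute_evoked_synchrony:
        whw = config.window_halfwidth_frames(g.frame_rate_hz)
        n_window = int(round(config.evoked_window_ms / g.dt_ms))
        onset = g.stim_onset_frame
        residuals = synchrony.make_residuals(
            evoked_dff, (onset, min(onset + n_window, g.n_frames))
        )
        half_width = config.corr_map_half_width_px if keep_maps else max(
            1, int(config.synchrony_radius_um // g.pixel_size_um)
        )
        result.evoked_synchrony = synchrony.aligned_roi_synchrony(
            residuals, barrel, half_width, whw, config.synchrony_radius_um,
        )
    return result


def _half_peak(tc):
    from .metrics import time_to_half_peak

    return time_to_half_peak(tc)


def analyze_cohort(
    cohort: Cohort,
    config: Optional[PipelineConfig] = None,
    compute_synchrony: bool = True,
    compute_evoked_synchrony: bool = False,
    n_shuffles: Optional[int] = None,
    keep_maps: bool = False,
    compute_rings: bool = True,
) -> CohortResult:
    """Analyze every animal, then compare the groups animal-wise."""
    config = config or PipelineConfig()
    results = []
    for animal in cohort.animals:
        t0 = time.perf_counter()
        results.append(
            analyze_animal(
                animal, config, compute_synchrony, compute_evoked_synchrony,
                n_shuffles, keep_maps, compute_rings,
            )
        )
        log.info("analyzed %s in %.2f s", animal.animal_id, time.perf_counter() - t0)

    comparisons = {}
    groups = sorted({a.group for a in results})
    if len(groups) == 2:
        ga, gb = groups  # alphabetical: Ctrl before Tg
        for metric in (
            "peak_amplitude", "time_to_peak_ms", "max_derivative",
            "min_derivative", "spont_synchrony", "evoked_synchrony",
        ):
            a = [getattr(r, metric) for r in results
                 if r.group == ga and getattr(r, metric) is not None]
            b = [getattr(r, metric) for r in results
                 if r.group == gb and getattr(r, metric) is not None]
            if len(a) >= 2 and len(b) >= 2:
                comparisons[metric] = stats.rank_sum_test(
                    a, b, metric=metric, alpha=config.alpha
                )
        obs = [r.spont_synchrony for r in results
               if r.spont_synchrony is not None and r.spont_null_mean is not None]
        ref = [r.spont_null_mean for r in results
               if r.spont_synchrony is not None and r.spont_null_mean is not None]
        if len(obs) >= 2:
            comparisons["spont_synchrony_vs_shuffle"] = stats.signed_rank_test(
                obs, ref, metric="spont_synchrony_vs_shuffle", alpha=config.alpha
            )
    return CohortResult(results, comparisons, config)


def run_pipeline(
    out_dir: Path,
    cohort: Optional[Cohort] = None,
    config: Optional[PipelineConfig] = None,
    simulate_kwargs: Optional[dict] = None,
    write_maps: bool = True,
) -> CohortResult:
    """Simulate (if no cohort is given), analyze, and write a results bundle:
    metrics CSV, comparison JSON, config YAML and PNG maps, all stamped with
    the config hash."""
    from . import __version__
    from .io import save_map_png
    from .synthetic import generate_cohort

    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    if cohort is None:
        cohort = generate_cohort(rng_seed=config.seed, **(simulate_kwargs or {}))
    result = analyze_cohort(cohort, config, keep_maps=write_maps)
    table = result.metrics_table()
    table.insert(0, "config_hash", config.content_hash())
    table.to_csv(out_dir / "animal_metrics.csv", index=False)
    (out_dir / "group_comparisons.json").write_text(result.summary_json())
    config.to_yaml(out_dir / "config.yaml")
    (out_dir / "provenance.json").write_text(json.dumps({
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": cohort.seed,
        "n_animals": len(cohort.animals),
    }, indent=2))
    if write_maps:
        for a in result.animals:
            if a.spont_map is not None:
                save_map_png(
                    a.spont_map, out_dir / f"corr_map_{a.animal_id}.png",
                    title=f"{a.animal_id} spontaneous correlation",
                )
    return result
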