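"""Pipeline configuration with the study's standard constants as defaults.

Defaults: 30 ms ΔF/F baseline; vessel high-pass σ = 2 px with a robust-z
threshold of 3; barrel ROI from the 20 ms frame at 77.5% of the peak;
four 200 μm rings; spatial-profile samples at 20/50/80 ms; 80 ms
correlation window (center ± 40 ms); 200 μm synchrony radius; 100 spatial
shuffles; 2500 ms spontaneous and 150 ms evoked correlation intervals;
α = 0.05.  The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .core import ParameterError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # preprocessing
    baseline_ms: float = 30.0
    vessel_highpass_sigma_px: float = 2.0
    vessel_threshold_k: float = 3.0
    # barrel ROI
    roi_early_time_ms: float = 20.0
    roi_threshold_fraction: float = 0.775
    roi_connectivity: int = 8
    # rings
    ring_width_um: float = 200.0
    n_rings: int = 4
    profile_sample_times_ms: tuple[float, ...] = (20.0, 50.0, 80.0)
    # synchrony
    corr_window_ms: float = 80.0
    corr_map_half_width_px: int = 25
    synchrony_radius_um: float = 200.0
    n_shuffles: int = 100
    spontaneous_window_ms: float = 2500.0
    evoked_window_ms: float = 150.0
    # statistics
    alpha: float = 0.05
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.roi_threshold_fraction <= 1):
            raise ParameterError("roi_threshold_fraction must be in (0, 1]")
        if self.corr_window_ms <= 0 or self.synchrony_radius_um <= 0:
            raise ParameterError("window and radius must be positive")

    def baseline_n_frames(self, frame_rate_hz: float) -> int:
        return max(1, int(round(self.baseline_ms * frame_rate_hz / 1000.0)))

    def window_halfwidth_frames(self, frame_rate_hz: float) -> int:
        """Frames on each side of a window center: 80 ms at 100 Hz -> ±4
        (a 9-frame window honoring the ± 40 ms reading)."""
        return max(1, int(round(self.corr_window_ms * frame_rate_hz / 2000.0)))

    def evolve(self, **changes) -> "PipelineConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile_sample_times_ms"] = list(self.profile_sample_times_ms)
        return d

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "profile_sample_times_ms" in d:
            d["profile_sample_times_ms"] = tuple(d["profile_sample_times_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
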