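"""Versioned pipeline configuration with every protocol constant embedded.

The defaults reproduce the canonical analysis: 0.5 mV / 10 s detection
thresholds, 45-min inclusion rule, 20 control frames, 20x20 ROI, 1 % dT/T
threshold held for more than 9 frames, alpha 0.05 with BY-FDR adjustment
and the >= 50 % responder cut.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from ..lfp_events import DetectionParams

CONFIG_SCHEMA_VERSION = 1

__all__ = [
    "IOSParams",
    "StatsParams",
    "PipelineConfig",
    "validate_config",
    "config_hash",
]


@dataclass(frozen=True)
class IOSParams:
    threshold_pct: float = 1.0
    persistence_frames: int = 10  # "> 9 subsequent images"
    control_frames: int = 20
    roi_size: int = 20
    frame_rate_hz: float = 2.0
    onset_threshold_pct: float = 0.4


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    fdr_method: str = "fdr_by"
    responder_cutoff: float = 0.5
    k_events: int = 5  # last 3-5 events per phase


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    groups: tuple[str, ...] | None = None  # None -> every default arm
    n_slices: dict[str, int] = field(default_factory=dict)  # per-group override
    sampling_rate_hz: float = 500.0
    inclusion_limit_min: float = 45.0
    drift_cutoff_hz: float = 0.005
    ios_events_per_phase: int = 3
    detection: DetectionParams = field(default_factory=DetectionParams)
    ios: IOSParams = field(default_factory=IOSParams)
    stats: StatsParams = field(default_factory=StatsParams)
    schema_version: int = CONFIG_SCHEMA_VERSION

    def resolved_groups(self) -> tuple[str, ...]:
        if self.groups is None:
            from ..synthetic_data import default_group_specs

            return tuple(default_group_specs())
        return tuple(self.groups)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "detection" in data and isinstance(data["detection"], dict):
            det = dict(data["detection"])
            if "ripple_band" in det:
                det["ripple_band"] = tuple(det["ripple_band"])
            data["detection"] = DetectionParams(**det)
        if "ios" in data and isinstance(data["ios"], dict):
            data["ios"] = IOSParams(**data["ios"])
        if "stats" in data and isinstance(data["stats"], dict):
            data["stats"] = StatsParams(**data["stats"])
        if "groups" in data and data["groups"] is not None:
            data["groups"] = tuple(data["groups"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Every violated invariant, reported with its field path; [] when valid."""
    errors: list[str] = []
    if config.sampling_rate_hz <= 0:
        errors.append("sampling_rate_hz: must be positive")
    if config.inclusion_limit_min <= 0:
        errors.append("inclusion_limit_min: must be positive")
    det = config.detection
    if det.dc_threshold_mv <= 0:
        errors.append("detection.dc_threshold_mv: must be positive")
    if det.min_duration_s <= 0:
        errors.append("detection.min_duration_s: must be positive")
    lo, hi = det.ripple_band
    if not 0 < lo < hi:
        errors.append("detection.ripple_band: must satisfy 0 < low < high")
    if hi >= config.sampling_rate_hz / 2:
        errors.append("detection.ripple_band: upper edge at/above Nyquist")
    ios = config.ios
    if ios.threshold_pct <= 0:
        errors.append("ios.threshold_pct: must be positive")
    if ios.persistence_frames < 1:
        errors.append("ios.persistence_frames: must be >= 1")
    if ios.control_frames < 1:
        errors.append("ios.control_frames: must be >= 1")
    if ios.roi_size < 1:
        errors.append("ios.roi_size: must be >= 1")
    if ios.frame_rate_hz <= 0:
        errors.append("ios.frame_rate_hz: must be positive")
    st = config.stats
    if not 0 < st.alpha < 1:
        errors.append("stats.alpha: must lie in (0, 1)")
    if not 3 <= st.k_events <= 5:
        errors.append("stats.k_events: must lie in [3, 5]")
    if config.ios_events_per_phase < 1:
        errors.append("ios_events_per_phase: must be >= 1")
    if not config.resolved_groups():
        errors.append("groups: at least one group required")
    else:
        from ..synthetic_data import default_group_specs

        known = set(default_group_specs())
        for g in config.resolved_groups():
            if g not in known:
                errors.append(f"groups: unknown group {g!r}")
    for g, n in config.n_slices.items():
        if n < 1:
            errors.append(f"n_slices.{g}: must be >= 1")
    return errors
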