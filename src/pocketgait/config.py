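"""Run configuration for the analysis pipeline.

All tunable knobs of preprocessing and event detection live in one flat,
serialisable dataclass so that a run is fully reproducible from a config
file plus a seed.  Keys may be written either with underscores
(``filter_cutoff_hz``) or dotted (``filter.cutoff_hz``) in YAML/flag form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class RunConfig:
    # low-pass filter (zero-phase Butterworth)
    filter_order: int = 4
    filter_cutoff_hz: float = 3.0
    # orientation estimation
    orientation_mode: str = "auto"  # auto | provided | complementary
    orientation_tilt_cutoff_hz: float = 0.25
    # gravity: None -> estimate scalar g from the low-passed acceleration norm
    gravity_g: float | None = None
    # uniform resampling rate; None -> trial's nominal rate
    resample_fs: float | None = None
    # turn detection / removal
    turn_window_s: float = 4.0
    turn_yaw_threshold_deg: float = 120.0
    turn_margin_s: float = 0.5
    # gait-event detection
    events_min_prominence_factor: float = 0.3
    events_min_spacing_s: float = 0.35
    events_iqr_window_s: float = 4.0
    events_edge_trim_s: float = 0.5
    segment_min_len_s: float = 3.0
    # event-matching tolerance used only by evaluation/tests
    events_match_tolerance_s: float = 0.05

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.filter_cutoff_hz <= 0:
            raise ValueError("filter_cutoff_hz must be > 0")
        if self.orientation_mode not in ("auto", "provided", "complementary"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        """Build a config from a flat mapping; unknown keys are rejected."""
        known = cls.field_names()
        kwargs: dict[str, Any] = {}
        for key, value in mapping.items():
            name = key.replace(".", "_")
            if name not in known:
                raise KeyError(f"unknown config key: {key!r}")
            kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        return cls.from_mapping(data)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
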