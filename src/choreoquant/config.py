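"""Pipeline configuration.

All spatial quantities are in pixels and all times in minutes unless a field
name says otherwise.  The defaults correspond to slow growth in glucose
minimal medium imaged every 5 min at 0.065 um/px; for glycerol medium the
upper cycle-length filter is raised to 80 frames via a config file.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    #: minutes between consecutive movie frames
    frame_interval_min: float = 5.0
    #: physical pixel size of the camera at full magnification, um/px
    pixel_size_um: float = 0.065
    #: width of the mid-cell window used for ter-centralisation calls, px
    midcell_window_px: float = 4.8
    #: consecutive qualifying frames required for a centralisation call
    persistence_frames: int = 3
    #: relative nucleoid dip depth above which a frame counts as constricted
    constriction_threshold: float = 0.13
    #: percentile of newborn dip depths used when deriving the threshold
    constriction_percentile: float = 95.0
    #: cycles shorter than this number of frames are discarded
    min_cycle_frames: int = 10
    #: cycles longer than this number of frames are discarded
    max_cycle_frames: int = 60
    #: an ori duplication seen before this frame triggers mother backtracking
    early_lookback_frames: int = 4
    #: largest |channel offset| searched during registration, px
    offset_search_px: int = 4
    #: two foci closer than this count as colocalised, um
    coloc_dist_um: float = 0.2
    #: if True, frames with no detected focus do not break a persistence run
    #: (they simply do not count); default is the conservative rule where a
    #: missed focus interrupts the run
    skip_missed_frames: bool = False
    #: maximum displacement allowed when linking foci between frames, px.
    #: Must exceed the one-frame ter transit of ~0.3 L (10-12 px in these
    #: cells), otherwise the defining jump of the centralisation event would
    #: never be linked into a track.
    max_link_step_px: float = 15.0
    #: default kymograph binning
    n_age_bins: int = 50
    n_pos_bins: int = 60

    def __post_init__(self) -> None:
        positive = [
            "frame_interval_min", "pixel_size_um", "midcell_window_px",
            "constriction_threshold", "constriction_percentile",
            "min_cycle_frames", "max_cycle_frames", "early_lookback_frames",
            "offset_search_px", "coloc_dist_um", "max_link_step_px",
            "n_age_bins", "n_pos_bins",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.persistence_frames < 1:
            raise ConfigError("persistence_frames must be >= 1")
        if self.min_cycle_frames >= self.max_cycle_frames:
            raise ConfigError("min_cycle_frames must be < max_cycle_frames")

    @property
    def midcell_window_um(self) -> float:
        return self.midcell_window_px * self.pixel_size_um

    @property
    def persistence_min(self) -> float:
        return self.persistence_frames * self.frame_interval_min

    # -- serialisation -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
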