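"""Cycle-level filtering and growth fitting."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .model import CellCycle, ChoreoQuantError, Dataset

__all__ = ["filter_cycles", "fit_growth_rate", "fitted_lengths", "GrowthFit"]


def filter_cycles(ds: Dataset, config: PipelineConfig
                  ) -> tuple[Dataset, int]:
    """Discard cycles shorter/longer than the configured frame bounds.

    Both bounds are inclusive: a cycle of exactly ``min_cycle_frames`` or
    exactly ``max_cycle_frames`` frames is kept.  Idempotent.
    """
    kept = [c for c in ds
            if config.min_cycle_frames <= c.n_frames
            <= config.max_cycle_frames]
    return Dataset(kept), len(ds) - len(kept)


@dataclass(frozen=True)
class GrowthFit:
    rate_per_hour: float
    log_intercept: float
    residual_rms: float


def fit_growth_rate(cycle: CellCycle, config: PipelineConfig) -> GrowthFit:
    """Exponential growth rate from a log-linear least-squares fit of area.

    Fits ``log(area) = log(A0) + k t`` with ``t`` in hours and returns the
    per-hour rate ``k`` together with the RMS residual of the fit in log
    space.
    """
    if cycle.n_frames < 3:
        raise ChoreoQuantError(
            f"cycle {cycle.cell_id}: need >= 3 frames to fit growth")
    area = cycle.areas_px2
    if np.any(area <= 0):
        raise ChoreoQuantError(
            f"cycle {cycle.cell_id}: non-positive area")
    t_h = np.arange(cycle.n_frames) * config.frame_interval_min / 60.0
    slope, intercept = np.polyfit(t_h, np.log(area), 1)
    resid = np.log(area) - (slope * t_h + intercept)
    return GrowthFit(float(slope), float(intercept),
                     float(np.sqrt(np.mean(resid ** 2))))


def fitted_lengths(cycle: CellCycle) -> np.ndarray:
    """Exponential-fit cell length per frame.

    Population statistics normalise focus positions by this fitted length
    rather than the raw per-frame length, which damps segmentation noise
    ("exponentially increasing normalised length").
    """
    n = cycle.n_frames
    if n < 3:
        return cycle.lengths_px.astype(float)
    f = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(f, np.log(cycle.lengths_px), 1)
    return np.exp(intercept + slope * f)
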