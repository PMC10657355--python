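"""Population-level summaries: kymographs, demographs, event-synchronised
kymographs, step-wise velocity curves, nucleoid-signal kymographs with
mass contours, and event-timing statistics.

Kymographs pool foci from many cycles by cell age (0 birth, 1 division)
and position relative to the exponentially increasing fitted cell length,
``r = (x - L_hat/2) / L_hat``; each age column is normalised by the number
of cell cycles observed at that age, so a column value is "foci per cell"
at that age and position.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .cycles import fitted_lengths
from .model import ChoreoQuantError, Dataset

__all__ = ["PositionHistogram", "position_kymograph", "demograph",
           "synchronized_kymograph", "stepwise_velocity", "hu_kymograph",
           "contour_level", "timing_summary", "TimingSummary"]


@dataclass
class PositionHistogram:
    """Position-frequency matrix (position bins x columns).

    ``matrix[:, c] * n_cycles_per_column[c]`` recovers the raw focus
    counts of column ``c`` (mass conservation).  Columns are age bins,
    length bins or event-relative frames depending on ``kind``.
    """

    matrix: np.ndarray
    position_edges: np.ndarray
    column_edges: np.ndarray
    n_cycles_per_column: np.ndarray
    kind: str = "kymograph"
    channel: str | None = None

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        centres_c = (self.column_edges[:-1] + self.column_edges[1:]) / 2 \
            if len(self.column_edges) == self.n_columns + 1 \
            else self.column_edges
        centres_p = (self.position_edges[:-1] + self.position_edges[1:]) / 2
        return pd.DataFrame(self.matrix, index=centres_p, columns=centres_c)


def _gather(ds: Dataset, channel: str, config: PipelineConfig):
    """Per-focus (age, r, cycle index) plus per-frame (age, cycle) arrays."""
    ages_foci, rs, ages_frames = [], [], []
    for c in ds:
        track = c.foci.get(channel)
        lhat = fitted_lengths(c)
        ages = c.ages()
        ages_frames.append(ages)
        if track is None or len(track) == 0:
            continue
        l_at = lhat[track.frames]
        r = (track.x_px - l_at / 2.0) / l_at
        rs.append(np.clip(r, -0.5, 0.5))
        ages_foci.append(ages[track.frames])
    if not rs:
        raise ChoreoQuantError(f"channel {channel!r} absent from dataset")
    return (np.concatenate(ages_foci), np.concatenate(rs),
            np.concatenate(ages_frames))


def position_kymograph(ds: Dataset, channel: str,
                       n_age_bins: int | None = None,
                       n_pos_bins: int | None = None,
                       config: PipelineConfig | None = None
                       ) -> PositionHistogram:
    """Population kymograph of focus positions versus cell age."""
    config = config or PipelineConfig()
    n_age_bins = n_age_bins or config.n_age_bins
    n_pos_bins = n_pos_bins or config.n_pos_bins
    age_f, r, age_all = _gather(ds, channel, config)
    age_edges = np.linspace(0.0, 1.0, n_age_bins + 1)
    pos_edges = np.linspace(-0.5, 0.5, n_pos_bins + 1)
    counts, _, _ = np.histogram2d(r, age_f, bins=[pos_edges, age_edges])
    denom, _ = np.histogram(age_all, bins=age_edges)
    matrix = np.divide(counts, denom[None, :],
                       out=np.zeros_like(counts),
                       where=denom[None, :] > 0)
    return PositionHistogram(matrix, pos_edges, age_edges,
                             denom.astype(float), "kymograph", channel)


def demograph(ds: Dataset, channel: str, length_bins: int = 40,
              n_pos_bins: int | None = None,
              config: PipelineConfig | None = None) -> PositionHistogram:
    """Like the kymograph but with columns indexed by current cell length
    (um); positions are signed mid-cell coordinates in um."""
    config = config or PipelineConfig()
    n_pos_bins = n_pos_bins or config.n_pos_bins
    px = config.pixel_size_um
    lengths_f, us, lengths_all = [], [], []
    for c in ds:
        lengths_all.append(c.lengths_px * px)
        track = c.foci.get(channel)
        if track is None or len(track) == 0:
            continue
        l_at = c.lengths_px[track.frames]
        us.append((track.x_px - l_at / 2.0) * px)
        lengths_f.append(l_at * px)
    if not us:
        raise ChoreoQuantError(f"channel {channel!r} absent from dataset")
    lengths_f = np.concatenate(lengths_f)
    us = np.concatenate(us)
    lengths_all = np.concatenate(lengths_all)
    len_edges = np.linspace(lengths_all.min(), lengths_all.max() + 1e-9,
                            length_bins + 1)
    max_u = np.abs(us).max() + 1e-9
    pos_edges = np.linspace(-max_u, max_u, n_pos_bins + 1)
    counts, _, _ = np.histogram2d(us, lengths_f, bins=[pos_edges, len_edges])
    denom, _ = np.histogram(lengths_all, bins=len_edges)
    matrix = np.divide(counts, denom[None, :],
                       out=np.zeros_like(counts),
                       where=denom[None, :] > 0)
    return PositionHistogram(matrix, pos_edges, len_edges,
                             denom.astype(float), "demograph", channel)


def synchronized_kymograph(ds: Dataset, channel: str,
                           events: Mapping[str, int | float],
                           window_frames: int,
                           n_pos_bins: int | None = None,
                           config: PipelineConfig | None = None
                           ) -> PositionHistogram:
    """Kymograph with columns indexed by ``frame - t_event``.

    ``events`` maps cell_id to the synchronisation frame; cycles without
    an entry (or with a NaN) are excluded.
    """
    config = config or PipelineConfig()
    n_pos_bins = n_pos_bins or config.n_pos_bins
    w = int(window_frames)
    rel_edges = np.arange(-w, w + 2) - 0.5
    pos_edges = np.linspace(-0.5, 0.5, n_pos_bins + 1)
    counts = np.zeros((n_pos_bins, 2 * w + 1))
    denom = np.zeros(2 * w + 1)
    seen = False
    for c in ds:
        t_ev = events.get(c.cell_id)
        if t_ev is None or (isinstance(t_ev, float) and np.isnan(t_ev)):
            continue
        t_ev = int(t_ev)
        seen = True
        rel_all = np.arange(c.n_frames) - t_ev
        inside = (rel_all >= -w) & (rel_all <= w)
        denom_idx = rel_all[inside] + w
        np.add.at(denom, denom_idx, 1)
        track = c.foci.get(channel)
        if track is None or len(track) == 0:
            continue
        rel = track.frames - t_ev
        keep = (rel >= -w) & (rel <= w)
        if not keep.any():
            continue
        lhat = fitted_lengths(c)
        l_at = lhat[track.frames[keep]]
        r = np.clip((track.x_px[keep] - l_at / 2.0) / l_at, -0.5, 0.5)
        h, _, _ = np.histogram2d(r, rel[keep],
                                 bins=[pos_edges, rel_edges])
        counts += h
    if not seen:
        raise ChoreoQuantError("no cycle carries the synchronising event")
    matrix = np.divide(counts, denom[None, :],
                       out=np.zeros_like(counts),
                       where=denom[None, :] > 0)
    return PositionHistogram(matrix, pos_edges, np.arange(-w, w + 1),
                             denom, "synchronized", channel)


# ---------------------------------------------------------------------------
# focus tracking and velocities
# ---------------------------------------------------------------------------

def _link_frame_pair(x1, i1, x2, i2, max_step):
    """Nearest-neighbour assignment between consecutive-frame foci.

    Global minimum-total-distance assignment limited to ``max_step``;
    equal-distance alternatives are broken in favour of brighter pairs.
    """
    if len(x1) == 0 or len(x2) == 0:
        return []
    cost = np.abs(x1[:, None] - x2[None, :])
    tie = -1e-9 * (i1[:, None] + i2[None, :])
    big = max_step * 1e6
    masked = np.where(cost <= max_step, cost + tie, big)
    rows, cols = linear_sum_assignment(masked)
    return [(a, b) for a, b in zip(rows, cols)
            if cost[a, b] <= max_step]


def stepwise_velocity(ds: Dataset, channel: str,
                      events: Mapping[str, int | float],
                      mode: str = "toward_old_pole",
                      window_frames: int = 10,
                      config: PipelineConfig | None = None
                      ) -> pd.DataFrame:
    """Mean step-wise focus velocity binned by event-relative frame.

    Foci are linked between consecutive frames by nearest-neighbour
    assignment (maximum step ``config.max_link_step_px``).  Each linked
    step from frame ``f`` to ``f+1`` contributes a velocity in um/min,
    signed positive toward the old pole (``mode="toward_old_pole"``) or
    toward whichever pole the focus was nearer at frame ``f``
    (``mode="toward_nearest_pole"``), assigned to relative frame
    ``(f + 1) - t_event``.  Returns mean, standard error (pooled over
    steps) and step count per relative frame.
    """
    if mode not in ("toward_old_pole", "toward_nearest_pole"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or PipelineConfig()
    w = int(window_frames)
    dt = config.frame_interval_min
    px = config.pixel_size_um
    sums = np.zeros(2 * w + 1)
    sq = np.zeros(2 * w + 1)
    n = np.zeros(2 * w + 1, dtype=int)
    for c in ds:
        t_ev = events.get(c.cell_id)
        if t_ev is None or (isinstance(t_ev, float) and np.isnan(t_ev)):
            continue
        t_ev = int(t_ev)
        track = c.foci.get(channel)
        if track is None or len(track) == 0:
            continue
        lhat = fitted_lengths(c)
        xs = track.by_frame(c.n_frames)
        intens = [track.intensity[track.frames == f]
                  for f in range(c.n_frames)]
        for f in range(c.n_frames - 1):
            rel = (f + 1) - t_ev
            if rel < -w or rel > w:
                continue
            pairs = _link_frame_pair(xs[f], intens[f], xs[f + 1],
                                     intens[f + 1],
                                     config.max_link_step_px)
            for a, b in pairs:
                u1 = xs[f][a] - lhat[f] / 2.0
                u2 = xs[f + 1][b] - lhat[f + 1] / 2.0
                v = (u2 - u1) * px / dt
                if mode == "toward_nearest_pole":
                    if u1 > 0:
                        pass
                    elif u1 < 0:
                        v = -v
                    else:
                        v = abs(v)
                sums[rel + w] += v
                sq[rel + w] += v * v
                n[rel + w] += 1
    mean = np.divide(sums, n, out=np.full(2 * w + 1, np.nan), where=n > 0)
    var = np.divide(sq, n, out=np.zeros(2 * w + 1), where=n > 0) - \
        np.where(n > 0, mean, 0) ** 2
    sem = np.divide(np.sqrt(np.maximum(var, 0)),
                    np.sqrt(np.maximum(n - 1, 1)),
                    out=np.full(2 * w + 1, np.nan), where=n > 1)
    return pd.DataFrame({
        "rel_frame": np.arange(-w, w + 1),
        "mean_um_per_min": mean,
        "sem_um_per_min": sem,
        "n_steps": n,
    })


# ---------------------------------------------------------------------------
# nucleoid-signal kymograph and contours
# ---------------------------------------------------------------------------

def hu_kymograph(ds: Dataset, n_age_bins: int | None = None,
                 grid_points: int = 100,
                 config: PipelineConfig | None = None
                 ) -> PositionHistogram:
    """Age-binned mean of length-normalised nucleoid line profiles."""
    config = config or PipelineConfig()
    n_age_bins = n_age_bins or config.n_age_bins
    age_edges = np.linspace(0.0, 1.0, n_age_bins + 1)
    grid = np.linspace(-0.5, 0.5, grid_points)
    sums = np.zeros((grid_points, n_age_bins))
    counts = np.zeros(n_age_bins)
    seen = False
    for c in ds:
        if c.profiles is None:
            continue
        ages = c.ages()
        cols = np.clip(np.searchsorted(age_edges, ages, side="right") - 1,
                       0, n_age_bins - 1)
        for f, prof in enumerate(c.profiles):
            if prof is None or len(prof) < 2:
                continue
            seen = True
            xs = (np.arange(len(prof)) + 0.5) / len(prof) - 0.5
            sums[:, cols[f]] += np.interp(grid, xs, prof)
            counts[cols[f]] += 1
    if not seen:
        raise ChoreoQuantError("dataset carries no nucleoid profiles")
    matrix = np.divide(sums, counts[None, :],
                       out=np.zeros_like(sums),
                       where=counts[None, :] > 0)
    return PositionHistogram(matrix, grid, age_edges, counts, "hu")


def _column_level(col: np.ndarray, fraction: float) -> float:
    """Intensity level enclosing ``fraction`` of the column total.

    The achievable fractions are the steps of ``F(l) = sum(col[col >= l])``
    at the distinct column values; the target is linearly interpolated
    between neighbouring steps.
    """
    total = col.sum()
    vals = np.sort(np.unique(col))[::-1]
    cum = 0.0
    prev_cum = 0.0
    prev_v = vals[0]
    target = fraction * total
    for v in vals:
        cum += col[col == v].sum()
        if cum >= target:
            if cum == prev_cum or v == prev_v:
                return float(v)
            t = (target - prev_cum) / (cum - prev_cum)
            return float(prev_v + t * (v - prev_v))
        prev_cum, prev_v = cum, v
    return float(vals[-1])


def contour_level(matrix: np.ndarray, fraction: float) -> float:
    """Mean over columns of the per-column intensity level whose
    super-level set encloses ``fraction`` of the column total."""
    if not 0 < fraction < 1:
        raise ChoreoQuantError("fraction must be in (0, 1)")
    matrix = np.asarray(matrix, dtype=float)
    levels = [_column_level(matrix[:, c], fraction)
              for c in range(matrix.shape[1])
              if matrix[:, c].sum() > 0]
    if not levels:
        raise ChoreoQuantError("matrix has no populated columns")
    return float(np.mean(levels))


# ---------------------------------------------------------------------------
# timing statistics
# ---------------------------------------------------------------------------

@dataclass
class TimingSummary:
    events: pd.DataFrame
    pairs: pd.DataFrame
    ordered_fraction: float
    n_ordered_basis: int = 0
    flags: list[str] = field(default_factory=list)


def timing_summary(events_df: pd.DataFrame,
                   config: PipelineConfig | None = None) -> TimingSummary:
    """Mean/sd/median tables for event times and paired differences.

    Paired statistics are computed only over cycles where both events of
    the pair were detected; the ordered fraction is the share of cycles
    (with all three events) in which duplication precedes centralisation
    precedes constriction.  All outputs are in minutes.
    """
    config = config or PipelineConfig()
    flags: list[str] = []

    def stats_of(series: pd.Series, name: str) -> dict:
        x = series.dropna()
        if len(x) == 1:
            flags.append(f"{name}: n=1, sd reported as 0")
        return {
            "event": name,
            "n": int(len(x)),
            "mean_min": float(x.mean()) if len(x) else np.nan,
            "sd_min": float(x.std(ddof=1)) if len(x) > 1
            else (0.0 if len(x) == 1 else np.nan),
            "median_min": float(x.median()) if len(x) else np.nan,
        }

    ev_rows = [stats_of(events_df[col], col.replace("_min", ""))
               for col in ("t_ori_min", "t_matp_min", "t_nuc_min",
                           "t_tersep_min") if col in events_df]
    pair_defs = [("t_matp_min", "t_ori_min", "t_matp - t_ori"),
                 ("t_nuc_min", "t_matp_min", "t_nuc - t_matp")]
    pair_rows = []
    for a, b, name in pair_defs:
        if a not in events_df or b not in events_df:
            continue
        diff = (events_df[a] - events_df[b]).dropna()
        pair_rows.append(stats_of(diff, name))

    have_all = events_df.dropna(
        subset=["t_ori_min", "t_matp_min", "t_nuc_min"]) \
        if {"t_ori_min", "t_matp_min", "t_nuc_min"} <= set(events_df) \
        else events_df.iloc[0:0]
    if len(have_all):
        ordered = ((have_all["t_ori_min"] <= have_all["t_matp_min"])
                   & (have_all["t_matp_min"] <= have_all["t_nuc_min"]))
        frac = float(ordered.mean())
    else:
        frac = np.nan
    return TimingSummary(pd.DataFrame(ev_rows), pd.DataFrame(pair_rows),
                         frac, int(len(have_all)), flags)
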