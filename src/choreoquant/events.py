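"""Per-cycle cell-cycle event detection.

Implements the frame-grid event definitions used throughout the analysis:

* ``T_ori`` -- first frame with two ori foci, traced back into the mother
  cell (as a negative frame number) when the duplication is seen within the
  first few frames of the cycle;
* ``T_MatP`` -- first frame of the first run of ``persistence_frames``
  consecutive frames in which the MatP focus nearest mid-cell lies within
  the mid-cell window;
* ``T_Nucleoid`` -- earliest frame from which the nucleoid line profile
  remains constricted (relative dip depth above threshold) until division;
* ``T_terSep`` -- first frame of the first persistent run of >= 2 MatP
  foci (visible separation of the replicated ter sisters).

All detectors return frame indices (``None`` when the event is absent)
and operate on polarity coordinates (new pole at ``x = 0``).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .model import CellCycle, ChoreoQuantError, Dataset, EventTimes

__all__ = [
    "detect_ori_duplication", "detect_matp_centralisation",
    "midcell_residence_count", "relative_dip_depth",
    "derive_constriction_threshold", "detect_stable_constriction",
    "detect_ter_separation", "detect_orientation",
    "classify_daughter_inheritance", "detect_events",
]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _foci_counts(cycle: CellCycle, channel: str) -> np.ndarray:
    track = cycle.foci.get(channel)
    counts = np.zeros(cycle.n_frames, dtype=int)
    if track is not None and len(track):
        np.add.at(counts, track.frames, 1)
    return counts


def _nearest_midcell_u(cycle: CellCycle, channel: str
                       ) -> list[float | None]:
    """Signed mid-cell coordinate of the focus nearest mid-cell, per frame
    (``None`` where the channel has no detected focus)."""
    track = cycle.foci.get(channel)
    out: list[float | None] = [None] * cycle.n_frames
    if track is None or len(track) == 0:
        return out
    per_frame = track.by_frame(cycle.n_frames)
    for f, xs in enumerate(per_frame):
        if len(xs) == 0:
            continue
        us = xs - cycle.lengths_px[f] / 2.0
        out[f] = float(us[np.argmin(np.abs(us))])
    return out


def _first_run(qualifies: list[bool | None], run_length: int,
               skip_missing: bool) -> int | None:
    """First index starting a run of ``run_length`` qualifying frames.

    ``None`` entries are frames with no detected focus.  In the default
    (conservative) mode they break a run; in skip-tolerant mode they are
    ignored (neither counting toward nor breaking the run).
    """
    n = len(qualifies)
    start = None
    count = 0
    for f in range(n):
        q = qualifies[f]
        if q is None:
            if not skip_missing:
                start, count = None, 0
            continue
        if q:
            if start is None:
                start = f
            count += 1
            if count >= run_length:
                return start
        else:
            start, count = None, 0
    return None


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def detect_ori_duplication(cycle: CellCycle, ds: Dataset | None,
                           config: PipelineConfig) -> int | None:
    """First frame with two ori foci, with mother backtracking.

    If the duplication is seen within the first ``early_lookback_frames``
    frames and the mother cycle is available, the mother's half inherited
    by this daughter is searched for the first frame at which its ori
    focus count rose to two; when found, the time is reported as a
    negative frame number relative to this cycle's birth.  Foci are
    assigned to mother halves by the per-frame midline (the division
    plane); the inherited half follows from the daughter's position in
    the lineage record (daughter1 = old-pole half).
    """
    counts = _foci_counts(cycle, "ori")
    hits = np.nonzero(counts >= 2)[0]
    t = int(hits[0]) if len(hits) else None
    if t is None or t >= config.early_lookback_frames or ds is None:
        return t
    mother = ds.get(cycle.mother_id)
    if mother is None:
        return t
    if cycle.cell_id == mother.daughter_ids[0]:
        old_half = True
    elif cycle.cell_id == mother.daughter_ids[1]:
        old_half = False
    else:
        return t
    track = mother.foci.get("ori")
    if track is None or len(track) == 0:
        return t
    half_counts = np.zeros(mother.n_frames, dtype=int)
    mid = mother.lengths_px[track.frames] / 2.0
    in_half = track.x_px >= mid if old_half else track.x_px < mid
    np.add.at(half_counts, track.frames[in_half], 1)
    rises = np.nonzero(half_counts >= 2)[0]
    if len(rises):
        return int(rises[0]) - mother.n_frames
    return t


def detect_matp_centralisation(cycle: CellCycle, config: PipelineConfig
                               ) -> int | None:
    """First frame of the first persistent run of mid-cell MatP frames.

    A frame qualifies when the MatP focus nearest mid-cell satisfies
    ``|u| <= midcell_window_px / 2``; a frame with no detected MatP focus
    does not qualify and (conservatively) breaks the run unless
    ``config.skip_missed_frames`` is set.
    """
    half = config.midcell_window_px / 2.0
    us = _nearest_midcell_u(cycle, "matp")
    qualifies: list[bool | None] = [
        None if u is None else (abs(u) <= half) for u in us]
    return _first_run(qualifies, config.persistence_frames,
                      config.skip_missed_frames)


def midcell_residence_count(cycle: CellCycle, config: PipelineConfig
                            ) -> int:
    """Number of frames with a MatP focus inside the mid-cell window."""
    half = config.midcell_window_px / 2.0
    us = _nearest_midcell_u(cycle, "matp")
    return sum(1 for u in us if u is not None and abs(u) <= half)


def relative_dip_depth(profile: np.ndarray) -> float:
    """Relative depth of the central dip of a nucleoid line profile.

    The minimum ``m`` is taken over the middle third of the profile; the
    flanking maxima ``a`` (from the start up to the minimum) and ``b``
    (from the minimum to the end) are searched over the whole profile.
    Depth is ``(min(a, b) - m) / min(a, b)`` floored at 0, so an
    unconstricted or monotone profile scores 0.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 6:
        raise ChoreoQuantError("profile too short for dip analysis (< 6)")
    i0 = n // 3
    i1 = -(-2 * n // 3)  # ceil(2n/3)
    mid = profile[i0:i1]
    i = i0 + int(np.argmin(mid))
    m = profile[i]
    flank = min(profile[: i + 1].max(), profile[i:].max())
    if flank <= 0:
        raise ChoreoQuantError("non-positive flanking maximum")
    return max(0.0, float((flank - m) / flank))


def derive_constriction_threshold(ds: Dataset, config: PipelineConfig
                                  ) -> float:
    """Percentile of newborn (first-frame) dip depths over the dataset.

    Newborn cells do not have a constricted nucleoid, so the chosen
    percentile of their dip-depth distribution separates profile noise
    from genuine constriction.  Linear-interpolation percentile.
    """
    depths = [relative_dip_depth(c.profiles[0]) for c in ds
              if c.profiles is not None and c.profiles[0] is not None
              and len(c.profiles[0]) >= 6]
    if len(depths) < 20:
        raise ChoreoQuantError(
            f"need >= 20 newborn profiles to derive the threshold, "
            f"got {len(depths)}")
    return float(np.percentile(depths, config.constriction_percentile))


def detect_stable_constriction(cycle: CellCycle, threshold: float
                               ) -> int | None:
    """Earliest frame from which the nucleoid stays constricted until
    division (dip depth strictly above ``threshold`` on every later
    frame); ``None`` when the final frame is unconstricted."""
    if cycle.profiles is None:
        raise ChoreoQuantError(
            f"cycle {cycle.cell_id}: no profiles")
    missing = [f for f, prof in enumerate(cycle.profiles)
               if prof is None or len(prof) == 0]
    if missing:
        raise ChoreoQuantError(
            f"cycle {cycle.cell_id}: missing profiles at frames {missing}")
    depths = np.array([relative_dip_depth(prof)
                       for prof in cycle.profiles])
    below = np.nonzero(depths <= threshold)[0]
    if len(below) == 0:
        return 0
    last_below = int(below[-1])
    if last_below == cycle.n_frames - 1:
        return None
    return last_below + 1


def detect_ter_separation(cycle: CellCycle, config: PipelineConfig
                          ) -> int | None:
    """First frame of the first persistent run of >= 2 MatP foci."""
    counts = _foci_counts(cycle, "matp")
    qualifies: list[bool | None] = [bool(c >= 2) for c in counts]
    return _first_run(qualifies, config.persistence_frames,
                      skip_missing=False)


def detect_orientation(cycle: CellCycle, config: PipelineConfig) -> str:
    """Classify chromosome orientation from early MatP position.

    Mean signed mid-cell MatP position over the first (up to) 4 frames
    with a detected focus: new-pole side (negative) is the normal
    arrangement (ter toward the new pole), old-pole side is inverted.
    """
    if not cycle.polarity_known:
        return "unknown"
    us = [u for u in _nearest_midcell_u(cycle, "matp") if u is not None]
    if not us:
        return "unknown"
    mean_u = float(np.mean(us[:4]))
    if mean_u <= -0.5:
        return "normal"
    if mean_u >= 0.5:
        return "inverted"
    return "unknown"


def classify_daughter_inheritance(cycle: CellCycle, ds: Dataset,
                                  config: PipelineConfig) -> str:
    """Orientation inherited by the two daughters: normal / inverted /
    mixed (one each) / unknown (a daughter missing or unclassifiable)."""
    daughters = [ds.get(d) for d in cycle.daughter_ids]
    if any(d is None for d in daughters) or len(cycle.daughters) != 2:
        return "unknown"
    labels = {detect_orientation(d, config) for d in daughters
              if d is not None}
    if "unknown" in labels:
        return "unknown"
    if labels == {"normal"}:
        return "normal"
    if labels == {"inverted"}:
        return "inverted"
    return "mixed"


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def detect_events(ds: Dataset, config: PipelineConfig,
                  threshold: float | None = None) -> pd.DataFrame:
    """Run all detectors over a dataset.

    Returns one row per cycle with event frames, minute conversions,
    orientation and the mid-cell residence count.  ``T_Nucleoid`` is only
    computed for cycles carrying profiles on every frame.
    """
    theta = (config.constriction_threshold if threshold is None
             else threshold)
    rows = []
    for c in ds:
        t_ori = detect_ori_duplication(c, ds, config)
        t_matp = detect_matp_centralisation(c, config)
        t_nuc = None
        if c.profiles is not None and all(
                prof is not None and len(prof) >= 6 for prof in c.profiles):
            t_nuc = detect_stable_constriction(c, theta)
        t_tersep = detect_ter_separation(c, config)
        ev = EventTimes(config.frame_interval_min, t_ori, t_matp, t_nuc,
                        t_tersep)
        rows.append({
            "cell_id": c.cell_id,
            "t_ori_frames": t_ori,
            "t_matp_frames": t_matp,
            "t_nuc_frames": t_nuc,
            "t_tersep_frames": t_tersep,
            "t_ori_min": ev.t_ori_min,
            "t_matp_min": ev.t_matp_min,
            "t_nuc_min": ev.t_nuc_min,
            "t_tersep_min": ev.t_tersep_min,
            "orientation": detect_orientation(c, config),
            "midcell_frames": midcell_residence_count(c, config),
        })
    df = pd.DataFrame(rows)
    for col in ("t_ori_frames", "t_matp_frames", "t_nuc_frames",
                "t_tersep_frames", "t_ori_min", "t_matp_min", "t_nuc_min",
                "t_tersep_min"):
        df[col] = pd.to_numeric(df[col])
    return df
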