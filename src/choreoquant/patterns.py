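"""Multi-locus spatial arrangement patterns and inter-locus distances.

Arrangement strings order the labelled loci along the long axis from the
new pole (NP) to the old pole (OP), e.g. ``NP-L-O-OP`` for a newborn cell
whose left-arm locus lies new-pole-ward of the origin, or ``O-L-L-O``
for a pre-division cell whose duplicated arm loci lie inside the
duplicated origins.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .model import CellCycle, Dataset

__all__ = ["arrangement_pattern", "pattern_frequencies",
           "interlocus_distance", "colocalisation_fraction",
           "channel_letter"]

_LETTERS = {"ori": "O", "left": "L", "right": "R", "matp": "T", "ter": "T"}

AMBIGUOUS = "ambiguous"


def channel_letter(channel: str) -> str:
    return _LETTERS.get(channel, channel[:1].upper())


def arrangement_pattern(cycle: CellCycle, channels: list[str],
                        frame: int) -> str:
    """Pattern string at one frame, or ``"ambiguous"``.

    With exactly one focus per channel (newborn stage) the string is
    flanked by the poles (``NP-...-OP``); with exactly two per channel
    (pre-division stage) the bare letter sequence is returned.  Missing
    or extra foci, position ties and unknown polarity are ambiguous.
    """
    if not cycle.polarity_known:
        return AMBIGUOUS
    per = [(ch, cycle.foci_at(ch, frame)) for ch in channels]
    counts = {len(xs) for _, xs in per}
    if counts == {1}:
        flanked = True
    elif counts == {2}:
        flanked = False
    else:
        return AMBIGUOUS
    xs_all = np.concatenate([xs for _, xs in per])
    letters = np.concatenate([[channel_letter(ch)] * len(xs)
                              for ch, xs in per])
    if len(np.unique(xs_all)) != len(xs_all):
        return AMBIGUOUS
    order = np.argsort(xs_all)
    seq = "-".join(letters[order])
    return f"NP-{seq}-OP" if flanked else seq


def _stage_frame(cycle: CellCycle, channels: list[str],
                 stage: str) -> int | None:
    """First frame with exactly one focus per channel (birth stage) or
    last frame with exactly two per channel (pre-division stage)."""
    want = 1 if stage == "birth" else 2
    frames = range(cycle.n_frames) if stage == "birth" \
        else range(cycle.n_frames - 1, -1, -1)
    for f in frames:
        if all(len(cycle.foci_at(ch, f)) == want for ch in channels):
            return f
    return None


def pattern_frequencies(ds: Dataset, channels: list[str], stage: str,
                        config: PipelineConfig | None = None
                        ) -> tuple[pd.Series, float]:
    """Frequency of arrangement patterns over classifiable cycles.

    Returns (pattern -> fraction, ambiguous fraction).  The ambiguous
    fraction counts cycles that never match the stage's focus-count
    requirement or whose pattern is ambiguous at the stage frame.
    """
    if stage not in ("birth", "predivision"):
        raise ValueError(f"unknown stage {stage!r}")
    patterns: list[str] = []
    for c in ds:
        f = _stage_frame(c, channels, stage)
        patterns.append(AMBIGUOUS if f is None
                        else arrangement_pattern(c, channels, f))
    total = len(patterns)
    if total == 0:
        return pd.Series(dtype=float), 0.0
    good = [p for p in patterns if p != AMBIGUOUS]
    ambiguous_fraction = 1.0 - len(good) / total
    if not good:
        return pd.Series(dtype=float), ambiguous_fraction
    freq = pd.Series(good).value_counts(normalize=True).sort_index()
    return freq, ambiguous_fraction


def interlocus_distance(cycle: CellCycle, channel_a: str, channel_b: str,
                        frame: int,
                        config: PipelineConfig | None = None
                        ) -> float | None:
    """Distance (um) between the loci of two channels at one frame.

    With one focus per channel this is ``|x_a - x_b| * pixel_size``;
    with several, foci are paired by a minimum-total-distance assignment
    over the smaller focus count and the mean paired distance returned.
    ``None`` when a channel has no focus at the frame.  Symmetric in
    channel order.
    """
    config = config or PipelineConfig()
    xa = cycle.foci_at(channel_a, frame)
    xb = cycle.foci_at(channel_b, frame)
    if len(xa) == 0 or len(xb) == 0:
        return None
    cost = np.abs(xa[:, None] - xb[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean() * config.pixel_size_um)


def colocalisation_fraction(ds: Dataset, channel_a: str, channel_b: str,
                            config: PipelineConfig | None = None
                            ) -> float:
    """Fraction of frames (with both channels detected) whose nearest
    A-B focus pair lies within ``coloc_dist_um``."""
    config = config or PipelineConfig()
    n_both = 0
    n_close = 0
    for c in ds:
        ta = c.foci.get(channel_a)
        tb = c.foci.get(channel_b)
        if ta is None or tb is None:
            continue
        xa = ta.by_frame(c.n_frames)
        xb = tb.by_frame(c.n_frames)
        for f in range(c.n_frames):
            if len(xa[f]) == 0 or len(xb[f]) == 0:
                continue
            n_both += 1
            d = np.abs(xa[f][:, None] - xb[f][None, :]).min() \
                * config.pixel_size_um
            if d <= config.coloc_dist_um:
                n_close += 1
    return n_close / n_both if n_both else np.nan
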