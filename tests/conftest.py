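"""Shared fixtures and hand-built cycle factories."""
from __future__ import annotations

import numpy as np
import pytest

from choreoquant.config import PipelineConfig
from choreoquant.model import CellCycle, ChannelFoci, Dataset


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


def make_cycle(cell_id: str = "c0", n: int = 12, birth_length: float = 26.0,
               growth: bool = True, foci: dict | None = None,
               foci_u: dict | None = None, profiles=None,
               **kwargs) -> CellCycle:
    """Build a cycle with exponential (or constant) length.

    ``foci`` maps channel -> list of (frame, x_px[, intensity]);
    ``foci_u`` maps channel -> list of (frame, u_px[, intensity]) with u
    measured from mid-cell (converted using the frame's length).
    """
    if growth:
        lengths = birth_length * 2.0 ** (np.arange(n) / max(n - 1, 1))
    else:
        lengths = np.full(n, float(birth_length))
    areas = lengths * 10.7
    tracks: dict[str, ChannelFoci] = {}

    def add(channel, obs, from_u):
        frames, xs, ins = [], [], []
        for rec in obs:
            f, pos = rec[0], rec[1]
            inten = rec[2] if len(rec) > 2 else 1.0
            x = pos + lengths[f] / 2.0 if from_u else pos
            frames.append(f)
            xs.append(x)
            ins.append(inten)
        tracks[channel] = ChannelFoci(np.array(frames, dtype=int),
                                      np.array(xs, dtype=float),
                                      np.array(ins, dtype=float))

    for channel, obs in (foci or {}).items():
        add(channel, obs, from_u=False)
    for channel, obs in (foci_u or {}).items():
        add(channel, obs, from_u=True)
    return CellCycle(cell_id=cell_id, birth_frame_abs=0,
                     lengths_px=lengths, areas_px2=areas, foci=tracks,
                     profiles=profiles, **kwargs)


def make_dataset(*cycles) -> Dataset:
    return Dataset(list(cycles))


def matp_cycle_factory(us, cell_id: str = "c0",
                       length: float = 30.0) -> CellCycle:
    """Constant-length cycle with one MatP focus per frame at signed
    mid-cell coordinate ``us[f]`` (``None`` = missed detection)."""
    obs = [(f, u) for f, u in enumerate(us) if u is not None]
    return make_cycle(cell_id, n=len(us), growth=False,
                      birth_length=length, foci_u={"matp": obs})


def dip_profile(depth: float, n: int = 9) -> np.ndarray:
    """Profile of length ``n`` whose relative central dip depth is exactly
    ``depth`` (flat plateau at 1 with a single lowered centre pixel)."""
    prof = np.ones(n)
    prof[n // 2] = 1.0 - depth
    return prof


def constriction_cycle(depths, cell_id: str = "c0") -> CellCycle:
    """Cycle whose per-frame profiles have the given dip depths."""
    n = len(depths)
    profiles = [dip_profile(d) for d in depths]
    lengths = np.full(n, 9.0)
    return CellCycle(cell_id=cell_id, birth_frame_abs=0,
                     lengths_px=lengths, areas_px2=lengths * 10,
                     profiles=profiles)
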