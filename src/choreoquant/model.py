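"""In-memory data model for tracked mother-machine cell cycles.

Coordinate conventions used throughout the package:

* ``x_px`` -- long-axis position in pixels, 0 at the NEW pole and ``L`` at
  the OLD pole of the cell (polarity coordinates).
* ``u = x_px - L/2`` -- signed mid-cell coordinate; negative values lie on
  the new-pole side.
* ``r = u / L`` -- relative position in ``[-0.5, 0.5]``.
* cell age ``a = frame / (n_frames - 1)`` so that birth is exactly 0 and
  division exactly 1.

Each :class:`CellCycle` additionally records its orientation inside the
microfluidic device (``device_flipped``): registration operates in device
coordinates, where a lateral channel offset is the same for every cell,
while all biology-facing analyses use polarity coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ChoreoQuantError", "DatasetFormatError", "LineageError",
    "DatasetValidationError", "FocusObservation", "ChannelFoci", "CellCycle",
    "Dataset", "EventTimes", "signed_midcell", "relative_position",
    "from_signed_midcell", "from_relative",
]


class ChoreoQuantError(Exception):
    """Base class for package errors."""


class DatasetFormatError(ChoreoQuantError):
    """On-disk layout problem (missing file/column, unparsable row)."""


class LineageError(ChoreoQuantError):
    """Mother/daughter links do not resolve."""


class DatasetValidationError(ChoreoQuantError):
    """Dataset violates a model invariant; message lists offending rows."""


# ---------------------------------------------------------------------------
# coordinate transforms (involutive pairs)
# ---------------------------------------------------------------------------

def signed_midcell(x_px, length_px):
    """Pole coordinate -> signed mid-cell coordinate ``u = x - L/2``."""
    return np.asarray(x_px) - np.asarray(length_px) / 2.0


def from_signed_midcell(u_px, length_px):
    return np.asarray(u_px) + np.asarray(length_px) / 2.0


def relative_position(x_px, length_px):
    """Pole coordinate -> relative position ``r = (x - L/2)/L``."""
    length_px = np.asarray(length_px, dtype=float)
    return (np.asarray(x_px) - length_px / 2.0) / length_px


def from_relative(r, length_px):
    length_px = np.asarray(length_px, dtype=float)
    return np.asarray(r) * length_px + length_px / 2.0


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocusObservation:
    """A single detected fluorescent focus."""

    frame: int
    channel: str
    x_px: float
    intensity: float = 1.0


@dataclass
class ChannelFoci:
    """All focus observations of one channel within one cell cycle.

    Stored as parallel arrays sorted by frame; a frame may occur several
    times (several foci) or not at all (missed detection).
    """

    frames: np.ndarray
    x_px: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.frames, kind="stable")
        self.frames = self.frames[order]
        self.x_px = self.x_px[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.frames)

    def at(self, frame: int) -> np.ndarray:
        """Positions of all foci detected at ``frame``."""
        return self.x_px[self.frames == frame]

    def intensity_at(self, frame: int) -> np.ndarray:
        return self.intensity[self.frames == frame]

    def by_frame(self, n_frames: int) -> list[np.ndarray]:
        """Positions per frame as a length-``n_frames`` list of arrays."""
        out: list[np.ndarray] = [np.empty(0) for _ in range(n_frames)]
        if len(self.frames) == 0:
            return out
        idx = np.searchsorted(self.frames, np.arange(n_frames + 1))
        for f in range(n_frames):
            out[f] = self.x_px[idx[f]:idx[f + 1]]
        return out

    def copy(self) -> "ChannelFoci":
        return ChannelFoci(self.frames.copy(), self.x_px.copy(),
                           self.intensity.copy())


@dataclass
class CellCycle:
    """One tracked cell from birth (frame 0) to division (last frame)."""

    cell_id: str
    birth_frame_abs: int
    lengths_px: np.ndarray
    areas_px2: np.ndarray
    foci: dict[str, ChannelFoci] = field(default_factory=dict)
    profiles: list[np.ndarray] | None = None
    mother_id: str | None = None
    #: positional: (old-pole-half daughter, new-pole-half daughter)
    daughter_ids: tuple[str | None, str | None] = (None, None)
    device_flipped: bool = False
    polarity_known: bool = True

    def __post_init__(self) -> None:
        self.lengths_px = np.asarray(self.lengths_px, dtype=float)
        self.areas_px2 = np.asarray(self.areas_px2, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.lengths_px)

    @property
    def daughters(self) -> tuple[str, ...]:
        return tuple(d for d in self.daughter_ids if d)

    @property
    def birth_length_px(self) -> float:
        return float(self.lengths_px[0])

    def ages(self) -> np.ndarray:
        n = self.n_frames
        if n == 1:
            return np.zeros(1)
        return np.arange(n) / (n - 1)

    def foci_at(self, channel: str, frame: int) -> np.ndarray:
        track = self.foci.get(channel)
        if track is None:
            return np.empty(0)
        return track.at(frame)

    def observations(self) -> Iterator[FocusObservation]:
        for channel, track in self.foci.items():
            for f, x, i in zip(track.frames, track.x_px, track.intensity):
                yield FocusObservation(int(f), channel, float(x), float(i))

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.n_frames == 0:
            problems.append(f"cycle {self.cell_id}: no frames")
            return problems
        if np.any(self.lengths_px <= 0):
            bad = np.nonzero(self.lengths_px <= 0)[0]
            problems.append(
                f"cycle {self.cell_id}: non-positive length at frames "
                f"{bad.tolist()}")
        for channel, track in self.foci.items():
            inside = (track.frames >= 0) & (track.frames < self.n_frames)
            if not inside.all():
                bad = track.frames[~inside]
                problems.append(
                    f"cycle {self.cell_id}, channel {channel}: focus frames "
                    f"{sorted(set(bad.tolist()))} outside the cycle")
                continue
            lengths = self.lengths_px[track.frames]
            off = (track.x_px < 0) | (track.x_px > lengths)
            if off.any():
                for f, x in zip(track.frames[off], track.x_px[off]):
                    problems.append(
                        f"cycle {self.cell_id}, channel {channel}, frame "
                        f"{int(f)}: x_px={x:g} outside [0, L]")
        if self.profiles is not None:
            if len(self.profiles) != self.n_frames:
                problems.append(
                    f"cycle {self.cell_id}: {len(self.profiles)} profiles "
                    f"for {self.n_frames} frames")
            else:
                for f, prof in enumerate(self.profiles):
                    if prof is None:
                        continue
                    expected = int(round(self.lengths_px[f]))
                    if len(prof) != expected:
                        problems.append(
                            f"cycle {self.cell_id}, frame {f}: profile "
                            f"length {len(prof)} != round(L) = {expected}")
                    if np.any(np.asarray(prof) < 0):
                        problems.append(
                            f"cycle {self.cell_id}, frame {f}: negative "
                            f"profile values")
        return problems

    def copy(self) -> "CellCycle":
        return replace(
            self,
            lengths_px=self.lengths_px.copy(),
            areas_px2=self.areas_px2.copy(),
            foci={c: t.copy() for c, t in self.foci.items()},
            profiles=(None if self.profiles is None
                      else [p.copy() for p in self.profiles]),
        )


class Dataset:
    """An ordered collection of cell cycles with resolved lineage links."""

    def __init__(self, cycles: Sequence[CellCycle]):
        self.cycles: list[CellCycle] = list(cycles)
        self._index = {c.cell_id: c for c in self.cycles}
        if len(self._index) != len(self.cycles):
            seen: set[str] = set()
            dupes = {c.cell_id for c in self.cycles
                     if c.cell_id in seen or seen.add(c.cell_id)}
            raise DatasetFormatError(f"duplicate cell ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self) -> Iterator[CellCycle]:
        return iter(self.cycles)

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._index

    def __getitem__(self, cell_id: str) -> CellCycle:
        return self._index[cell_id]

    def get(self, cell_id: str | None) -> CellCycle | None:
        if cell_id is None:
            return None
        return self._index.get(cell_id)

    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cycles:
            for ch in c.foci:
                seen.setdefault(ch, None)
        return list(seen)

    def validate(self, strict: bool = True) -> list[str]:
        problems: list[str] = []
        for c in self.cycles:
            problems.extend(c.validate())
            if c.mother_id is not None and c.mother_id not in self._index:
                problems.append(
                    f"cycle {c.cell_id}: dangling mother_id {c.mother_id}")
            mother = self.get(c.mother_id)
            if mother is not None:
                expected = mother.birth_frame_abs + mother.n_frames
                if c.birth_frame_abs != expected:
                    problems.append(
                        f"cycle {c.cell_id}: birth_frame_abs "
                        f"{c.birth_frame_abs} != mother's last frame + 1 "
                        f"({expected})")
        if strict and problems:
            dangling = [p for p in problems if "dangling mother_id" in p]
            if dangling:
                raise LineageError("; ".join(dangling))
            raise DatasetValidationError("; ".join(problems))
        return problems

    def copy(self) -> "Dataset":
        return Dataset([c.copy() for c in self.cycles])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.cycles, other.cycles):
            if (a.cell_id != b.cell_id
                    or a.birth_frame_abs != b.birth_frame_abs
                    or a.mother_id != b.mother_id
                    or tuple(a.daughter_ids) != tuple(b.daughter_ids)
                    or a.device_flipped != b.device_flipped
                    or a.polarity_known != b.polarity_known
                    or not np.array_equal(a.lengths_px, b.lengths_px)
                    or not np.array_equal(a.areas_px2, b.areas_px2)):
                return False
            if set(a.foci) != set(b.foci):
                return False
            for ch in a.foci:
                ta, tb = a.foci[ch], b.foci[ch]
                if (not np.array_equal(ta.frames, tb.frames)
                        or not np.array_equal(ta.x_px, tb.x_px)
                        or not np.array_equal(ta.intensity, tb.intensity)):
                    return False
            if (a.profiles is None) != (b.profiles is None):
                return False
            if a.profiles is not None:
                assert b.profiles is not None
                if len(a.profiles) != len(b.profiles):
                    return False
                for pa, pb in zip(a.profiles, b.profiles):
                    if not np.array_equal(pa, pb):
                        return False
        return True


@dataclass
class EventTimes:
    """Per-cycle event times on the frame grid.

    ``t_ori_frames`` may be negative when the duplication was traced back
    into the mother cell; all other events are only ever detected within
    the cycle itself.  ``None`` marks an event that was not observed.
    """

    frame_interval_min: float = 5.0
    t_ori_frames: int | None = None
    t_matp_frames: int | None = None
    t_nuc_frames: int | None = None
    t_tersep_frames: int | None = None

    def _minutes(self, frames: int | None) -> float | None:
        if frames is None:
            return None
        return frames * self.frame_interval_min

    @property
    def t_ori_min(self) -> float | None:
        return self._minutes(self.t_ori_frames)

    @property
    def t_matp_min(self) -> float | None:
        return self._minutes(self.t_matp_frames)

    @property
    def t_nuc_min(self) -> float | None:
        return self._minutes(self.t_nuc_frames)

    @property
    def t_tersep_min(self) -> float | None:
        return self._minutes(self.t_tersep_frames)
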