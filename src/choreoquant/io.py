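"""CSV reader/writer for the tracked-cell dataset layout.

A dataset directory holds:

* ``cycles.csv``  -- cell_id, mother_id, daughter1_id, daughter2_id,
  birth_frame_abs, n_frames, device_flipped, polarity_known
* ``frames.csv``  -- cell_id, frame, length_px, area_px2
* ``foci.csv``    -- cell_id, frame, channel, x_px, intensity
* ``profiles.csv`` (optional) -- cell_id, frame, pos_px, intensity

All files are UTF-8 with a header row and '.' decimal separator.  By
convention ``daughter1_id`` is the daughter that inherited the mother's
old-pole half and ``daughter2_id`` the new-pole half; mother backtracking
relies on this to assign foci to the inherited half.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import (CellCycle, ChannelFoci, Dataset, DatasetFormatError,
                    DatasetValidationError)

__all__ = ["read_dataset", "write_dataset"]

_CYCLE_COLS = ["cell_id", "mother_id", "daughter1_id", "daughter2_id",
               "birth_frame_abs", "n_frames"]
_FRAME_COLS = ["cell_id", "frame", "length_px", "area_px2"]
_FOCI_COLS = ["cell_id", "frame", "channel", "x_px", "intensity"]
_PROFILE_COLS = ["cell_id", "frame", "pos_px", "intensity"]


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.is_file():
        raise DatasetFormatError(f"missing file: {path.name}")
    df = pd.read_csv(path, dtype={"cell_id": str},
                     float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise DatasetFormatError(
                f"{path.name}: missing required column '{col}'")
    return df


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_dataset(path: str | Path, validate: bool = True) -> Dataset:
    """Read a dataset directory; raises on malformed rows naming them.

    Lineage links are resolved (a ``mother_id`` that does not exist in
    ``cycles.csv`` raises :class:`LineageError`); unknown fluorescence
    channels are preserved verbatim.
    """
    path = Path(path)
    if path.is_file():
        path = path.parent
    if not path.is_dir():
        raise DatasetFormatError(f"dataset directory not found: {path}")

    cycles_df = _read_csv(path / "cycles.csv", _CYCLE_COLS)
    frames_df = _read_csv(path / "frames.csv", _FRAME_COLS)
    foci_df = _read_csv(path / "foci.csv", _FOCI_COLS)
    foci_df["channel"] = foci_df["channel"].astype(str)

    bad = frames_df.index[frames_df["length_px"] <= 0]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise DatasetValidationError(
            f"frames.csv: non-positive length_px at row(s) {rows}")

    frame_groups = {k: g for k, g in frames_df.groupby("cell_id", sort=False)}
    foci_groups = {k: g for k, g in foci_df.groupby("cell_id", sort=False)}

    profiles_path = path / "profiles.csv"
    profile_groups: dict = {}
    if profiles_path.is_file():
        prof_df = _read_csv(profiles_path, _PROFILE_COLS)
        profile_groups = {k: g for k, g
                          in prof_df.groupby("cell_id", sort=False)}

    cycles: list[CellCycle] = []
    for idx, row in cycles_df.iterrows():
        cid = str(row["cell_id"])
        g = frame_groups.get(cid)
        if g is None:
            raise DatasetFormatError(
                f"cycles.csv row {idx + 2}: cell {cid} has no frames")
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        n = int(row["n_frames"])
        if len(frames) != n or not np.array_equal(frames,
                                                  np.arange(len(frames))):
            raise DatasetFormatError(
                f"cycles.csv row {idx + 2}: cell {cid} frames are not "
                f"contiguous 0..{n - 1}")
        foci: dict[str, ChannelFoci] = {}
        fg = foci_groups.get(cid)
        if fg is not None:
            for channel, cg in fg.groupby("channel", sort=False):
                foci[str(channel)] = ChannelFoci(
                    cg["frame"].to_numpy(),
                    cg["x_px"].to_numpy(dtype=float),
                    cg["intensity"].to_numpy(dtype=float))
        profiles = None
        pg = profile_groups.get(cid)
        if pg is not None:
            profiles = []
            for f in range(n):
                sub = pg[pg["frame"] == f].sort_values("pos_px")
                profiles.append(sub["intensity"].to_numpy(dtype=float))
        cycles.append(CellCycle(
            cell_id=cid,
            birth_frame_abs=int(row["birth_frame_abs"]),
            lengths_px=g["length_px"].to_numpy(dtype=float),
            areas_px2=g["area_px2"].to_numpy(dtype=float),
            foci=foci,
            profiles=profiles,
            mother_id=_opt_str(row["mother_id"]),
            daughter_ids=(_opt_str(row["daughter1_id"]),
                          _opt_str(row["daughter2_id"])),
            device_flipped=bool(row.get("device_flipped", False)),
            polarity_known=bool(row.get("polarity_known", True)),
        ))

    ds = Dataset(cycles)
    if validate:
        problems = ds.validate(strict=False)
        if problems:
            from .model import LineageError
            msg = "; ".join(problems[:20])
            if any("dangling mother_id" in p for p in problems):
                raise LineageError(msg)
            raise DatasetValidationError(msg)
    return ds


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset directory (inverse of :func:`read_dataset`)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cyc_rows = []
    frame_rows = []
    foci_rows = []
    prof_rows = []
    any_profiles = False
    for c in ds:
        d1 = c.daughter_ids[0] or ""
        d2 = c.daughter_ids[1] or ""
        cyc_rows.append((c.cell_id, c.mother_id or "", d1, d2,
                         c.birth_frame_abs, c.n_frames,
                         c.device_flipped, c.polarity_known))
        for f in range(c.n_frames):
            frame_rows.append((c.cell_id, f, c.lengths_px[f],
                               c.areas_px2[f]))
        for channel, track in c.foci.items():
            for fr, x, i in zip(track.frames, track.x_px, track.intensity):
                foci_rows.append((c.cell_id, int(fr), channel, x, i))
        if c.profiles is not None:
            any_profiles = True
            for f, prof in enumerate(c.profiles):
                for p, v in enumerate(np.asarray(prof)):
                    prof_rows.append((c.cell_id, f, p, v))

    pd.DataFrame(cyc_rows, columns=_CYCLE_COLS + ["device_flipped",
                                                  "polarity_known"]
                 ).to_csv(path / "cycles.csv", index=False)
    pd.DataFrame(frame_rows, columns=_FRAME_COLS
                 ).to_csv(path / "frames.csv", index=False)
    pd.DataFrame(foci_rows, columns=_FOCI_COLS
                 ).to_csv(path / "foci.csv", index=False)
    if any_profiles:
        pd.DataFrame(prof_rows, columns=_PROFILE_COLS
                     ).to_csv(path / "profiles.csv", index=False)
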