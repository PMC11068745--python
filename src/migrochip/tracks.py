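"""The ``Track`` container and its CSV round-trip.

A track is one cell's time-ordered centroid path in device coordinates
(µm).  Every downstream migration statistic consumes this object,
whether the path came from the nucleus detector or from a simulator.

The on-disk format is a flat CSV with header
``track_id,frame,t_min,x_um,y_um`` — one row per (track, frame).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Track", "tracks_to_dataframe", "write_tracks_csv", "read_tracks_csv"]

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]


@dataclass
class Track:
    """One cell's time-ordered centroid path.

    Attributes
    ----------
    track_id
        Integer identifier, unique within a cohort.
    t
        Time points in minutes, strictly increasing.
    xy
        Positions, shape ``(len(t), 2)``, in µm.
    source
        ``"simulated"`` or ``"detected"``.
    frames
        Optional frame indices matching ``t`` (present for detected
        tracks and for simulator output; enables gap bookkeeping).
    meta
        Free-form annotations; simulators store ground truth here
        (e.g. ``entered``/``entry_frame`` for channel runs).
    """

    track_id: int
    t: np.ndarray
    xy: np.ndarray
    source: str = "simulated"
    frames: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError(f"xy must have shape (n, 2), got {self.xy.shape}")
        if self.t.shape[0] != self.xy.shape[0]:
            raise ValueError("t and xy lengths disagree")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("track times must be strictly increasing")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def displacements(self) -> np.ndarray:
        """Per-step displacement vectors, shape (n-1, 2)."""
        return np.diff(self.xy, axis=0)

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.displacements(), axis=1)


def tracks_to_dataframe(tracks: Iterable[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        frames = (
            tr.frames
            if tr.frames is not None
            else np.arange(len(tr), dtype=int)
        )
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": frames,
                    "t_min": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_tracks_csv(path: str | Path, tracks: Iterable[Track]) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks_csv(path: str | Path, source: str = "detected") -> list[Track]:
    """Load tracks from the flat CSV schema.

    Rows are sorted by time within each track; track order follows
    ascending ``track_id``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        tracks.append(
            Track(
                track_id=int(tid),
                t=grp["t_min"].to_numpy(),
                xy=grp[["x_um", "y_um"]].to_numpy(),
                frames=grp["frame"].to_numpy(dtype=int),
                source=source,
            )
        )
    return tracks


def top_k_by(tracks: Sequence[Track], key, k: int) -> list[Track]:
    """k tracks with largest ``key(track)``; ties broken by track_id."""
    ranked = sorted(tracks, key=lambda tr: (-key(tr), tr.track_id))
    return ranked[: max(k, 0)]
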