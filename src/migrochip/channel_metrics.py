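"""Microchannel migration statistics.

Given tracks and a channel geometry this module computes, per cell:
whether and when it entered the channel, its mean axial speed, its
speed fluctuation (sample SD of instantaneous speeds), and the furthest
axial distance it reached; and, per cohort: the entry count, the
furthest-distance density profile with the fraction of cells stuck in
the first part of the channel, and the time-resolved mean speed.

Channel motion is effectively one-dimensional (the lateral dimension is
of cell size), so channel speeds use the axial projection of the
displacement.  "Speed fluctuation" is the per-track sample standard
deviation (n−1) of instantaneous speeds, in µm/min; a coefficient-of-
variation variant is available since the statistic's normalization is a
convention, not a law.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ChannelGeometry, GeometryError
from .tracks import Track

__all__ = [
    "assign_to_channels",
    "instantaneous_speeds",
    "speed_fluctuation",
    "summarize_channel_cells",
    "count_entries",
    "density_profile",
    "fraction_within",
    "time_resolved_speed",
]

DEFAULT_ENTRY_MARGIN = 10.0  # µm, ~one cell length
DEFAULT_CUTOFF = 200.0  # µm, near-entrance accumulation cutoff


def assign_to_channels(
    tracks: Sequence[Track], geometries: Sequence[ChannelGeometry]
) -> dict[int, int | None]:
    """Map each track to the channel whose lateral band holds most of it.

    Returns ``{track_id: channel_id or None}``; ``None`` marks tracks
    outside every band.  Channel bands must not overlap.
    """
    bands = []
    for g in geometries:
        lo = g.lateral_center - g.width / 2
        hi = g.lateral_center + g.width / 2
        bands.append((lo, hi, g))
    for i, (lo1, hi1, g1) in enumerate(bands):
        for lo2, hi2, g2 in bands[i + 1 :]:
            if g1.axis != g2.axis:
                raise GeometryError("channel axes must be parallel")
            if lo1 < hi2 and lo2 < hi1:
                raise GeometryError(
                    f"channels {g1.channel_id} and {g2.channel_id} have "
                    "overlapping lateral bands"
                )
    assignment: dict[int, int | None] = {}
    for tr in tracks:
        # lateral from axial_lateral is already relative to the centerline
        counts = []
        for _, _, g in bands:
            _, lateral = g.axial_lateral(tr.xy)
            counts.append(int(np.sum(np.abs(lateral) <= g.width / 2)))
        if not counts or max(counts) == 0 or max(counts) <= len(tr) / 2:
            assignment[tr.track_id] = None
        else:
            best = int(np.argmax(counts))
            assignment[tr.track_id] = bands[best][2].channel_id
    return assignment


def instantaneous_speeds(
    track: Track, geometry: ChannelGeometry | None = None
) -> np.ndarray:
    """Per-step speeds |Δposition| / Δt in µm/min.

    With a ``geometry``, the axial component of the displacement is
    used (channel convention); otherwise the planar Euclidean norm.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 positions for speeds")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps")
    if geometry is not None:
        axial, _ = geometry.axial_lateral(track.xy)
        disp = np.abs(np.diff(axial))
    else:
        disp = track.step_lengths()
    return disp / dt


def speed_fluctuation(
    track: Track,
    geometry: ChannelGeometry | None = None,
    statistic: str = "sd",
) -> float:
    """Per-track speed variability.

    ``statistic="sd"`` (default): sample standard deviation (n−1) of
    the instantaneous speeds, µm/min.  ``"cv"``: the SD divided by the
    mean speed (dimensionless).  Returns NaN when fewer than two speeds
    exist (nothing to vary).
    """
    if len(track) < 3:
        return float("nan")
    v = instantaneous_speeds(track, geometry)
    sd = float(np.std(v, ddof=1))
    if statistic == "sd":
        return sd
    if statistic == "cv":
        m = float(np.mean(v))
        return sd / m if m > 0 else float("nan")
    raise ValueError(f"unknown statistic {statistic!r}")


def _entry(axial: np.ndarray, entry_margin: float) -> tuple[bool, int | None]:
    """Entry = crossing the entrance from below, then reaching the margin."""
    crossings = np.flatnonzero((axial[:-1] < 0) & (axial[1:] >= 0))
    if crossings.size == 0:
        return False, None
    first = crossings[0] + 1
    past = np.flatnonzero(axial[first:] >= entry_margin)
    if past.size == 0:
        return False, None
    return True, int(first + past[0])


def summarize_channel_cells(
    tracks: Sequence[Track],
    geometry: ChannelGeometry,
    entry_margin: float = DEFAULT_ENTRY_MARGIN,
    fluctuation_statistic: str = "sd",
) -> pd.DataFrame:
    """Per-cell channel summary.

    Columns: ``track_id, channel_id, entered, entry_frame, mean_speed,
    speed_fluctuation, furthest_distance``.  ``furthest_distance`` is
    the maximum axial position reached, clipped to ``[0, length]``.
    A track counts as entered at most once.
    """
    rows = []
    for tr in tracks:
        axial, _ = geometry.axial_lateral(tr.xy)
        entered, entry_frame = _entry(axial, entry_margin)
        speeds = (
            instantaneous_speeds(tr, geometry) if len(tr) >= 2 else np.array([])
        )
        rows.append(
            {
                "track_id": tr.track_id,
                "channel_id": geometry.channel_id,
                "entered": entered,
                "entry_frame": entry_frame,
                "mean_speed": float(np.mean(speeds)) if speeds.size else np.nan,
                "speed_fluctuation": speed_fluctuation(
                    tr, geometry, statistic=fluctuation_statistic
                ),
                "furthest_distance": float(
                    np.clip(axial.max(), 0.0, geometry.length)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "channel_id",
            "entered",
            "entry_frame",
            "mean_speed",
            "speed_fluctuation",
            "furthest_distance",
        ],
    )


def count_entries(
    tracks: Sequence[Track],
    geometry: ChannelGeometry,
    entry_margin: float = DEFAULT_ENTRY_MARGIN,
) -> int:
    """Number of cells that entered the channel (each counted once)."""
    summary = summarize_channel_cells(tracks, geometry, entry_margin)
    return int(summary["entered"].sum())


def density_profile(
    summaries: pd.DataFrame,
    bin_width: float = 50.0,
    length: float | None = None,
) -> pd.DataFrame:
    """Histogram of furthest distances of entered cells.

    Half-open bins ``[k·bin, (k+1)·bin)``; one count per entered cell,
    so bin counts sum to the entered-cell count.  Columns:
    ``bin_left, bin_right, count``.
    """
    entered = summaries[summaries["entered"]]
    if length is None:
        length = float(entered["furthest_distance"].max()) if len(entered) else bin_width
    edges = np.arange(0.0, length + bin_width, bin_width)
    d = entered["furthest_distance"].to_numpy()
    # np.histogram's last bin is closed; shift exact-edge values into it explicitly
    counts = np.zeros(len(edges) - 1, dtype=int)
    idx = np.minimum((d // bin_width).astype(int), len(counts) - 1)
    for i in idx:
        counts[i] += 1
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def fraction_within(summaries: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of entered cells whose furthest distance is below ``cutoff``.

    NaN when no cell entered (undefined, reported as missing).
    """
    entered = summaries[summaries["entered"]]
    if len(entered) == 0:
        return float("nan")
    return float((entered["furthest_distance"] < cutoff).mean())


def time_resolved_speed(
    tracks: Sequence[Track],
    window: float,
    duration: float | None = None,
    geometry: ChannelGeometry | None = None,
) -> pd.DataFrame:
    """Mean instantaneous speed per time window across a cohort.

    A step contributes to the window containing its midpoint time.
    Columns: ``window_start, window_end, mean_speed, n_steps``; empty
    windows report NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    mids, speeds = [], []
    for tr in tracks:
        if len(tr) < 2:
            continue
        v = instantaneous_speeds(tr, geometry)
        mids.append((tr.t[:-1] + tr.t[1:]) / 2)
        speeds.append(v)
    mids = np.concatenate(mids) if mids else np.array([])
    speeds = np.concatenate(speeds) if speeds else np.array([])
    if duration is None:
        duration = float(mids.max()) + 1e-9 if mids.size else window
    edges = np.arange(0.0, duration + window, window)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (mids >= lo) & (mids < hi)
        rows.append(
            {
                "window_start": lo,
                "window_end": hi,
                "mean_speed": float(speeds[sel].mean()) if sel.any() else np.nan,
                "n_steps": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
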