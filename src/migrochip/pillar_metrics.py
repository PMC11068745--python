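"""Micropillar (2-D confined) migration statistics.

The central quantity is the turning angle α at each interior point of a
track: the angle between the displacement vectors entering and leaving
the point, in degrees on [0, 180].  Steps above a minimal displacement
are "motile"; among motile interior steps, α < 30° marks a persistent
step and α ≥ 30° a confined one.  Exact 30° is assigned to confined —
the defining inequalities are strict on both sides, so the boundary is
a convention and the conservative choice (toward confinement) is made.
Per-track outputs are the percent of motile time spent confined, the
total path length, and top-N longest-trajectory selection.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import Track, top_k_by

__all__ = [
    "turning_angles",
    "step_metrics",
    "classify_steps",
    "percent_time_confined",
    "track_length",
    "top_n_tracks",
    "summarize_pillar_tracks",
]

ALPHA_THRESHOLD = 30.0  # degrees
DEFAULT_MOTILE_MIN_DISP = 0.65  # µm: one pixel-equivalent at 10x/CCD per step


def turning_angles(track: Track) -> np.ndarray:
    """Turning angle (degrees) at every interior point of the track.

    ``alpha[i]`` is the angle between displacements p_i→p_{i+1} and
    p_{i+1}→p_{i+2} (three consecutive timepoints), so the array has
    ``len(track) - 2`` entries.  0° = straight continuation, 180° =
    full reversal.  NaN where either displacement is zero (the angle is
    undefined at a pause).  Fewer than 3 positions → empty array.
    """
    if len(track) < 3:
        return np.array([])
    d = track.displacements()
    a, b = d[:-1], d[1:]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", a, b) / (na * nb)
    alpha = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    alpha[(na == 0) | (nb == 0)] = np.nan
    return alpha


def step_metrics(
    track: Track,
    alpha_threshold: float = ALPHA_THRESHOLD,
    motile_min_disp: float = DEFAULT_MOTILE_MIN_DISP,
) -> pd.DataFrame:
    """Per-step metrics table for one track.

    One row per step p_i→p_{i+1}; ``alpha_deg`` is the turning angle at
    the step's start point (defined for steps 1..n−2, NaN for the first
    step and at pauses).  Labels: ``non-motile`` when the step
    displacement is ≤ ``motile_min_disp``; else ``persistent`` /
    ``confined`` by the angle, or ``undefined`` when no angle exists.
    """
    if alpha_threshold < 0:
        raise ValueError("alpha_threshold must be >= 0")
    disp = track.step_lengths()
    dt = np.diff(track.t)
    speed = disp / dt
    alpha_interior = turning_angles(track)
    n_steps = disp.shape[0]
    alpha = np.full(n_steps, np.nan)
    if n_steps >= 2:
        alpha[1:] = alpha_interior
    motile = disp > motile_min_disp
    label = np.where(motile, "undefined", "non-motile").astype(object)
    defined = motile & np.isfinite(alpha)
    label[defined & (alpha < alpha_threshold)] = "persistent"
    label[defined & (alpha >= alpha_threshold)] = "confined"
    return pd.DataFrame(
        {
            "track_id": track.track_id,
            "step": np.arange(n_steps),
            "displacement_um": disp,
            "speed_um_min": speed,
            "alpha_deg": alpha,
            "motile": motile,
            "label": label,
        }
    )


def classify_steps(
    steps: pd.DataFrame,
    alpha_threshold: float = ALPHA_THRESHOLD,
    motile_min_disp: float = DEFAULT_MOTILE_MIN_DISP,
) -> pd.DataFrame:
    """Relabel an existing step table under different thresholds."""
    if alpha_threshold < 0:
        raise ValueError("alpha_threshold must be >= 0")
    out = steps.copy()
    disp = out["displacement_um"].to_numpy()
    alpha = out["alpha_deg"].to_numpy()
    motile = disp > motile_min_disp
    label = np.where(motile, "undefined", "non-motile").astype(object)
    defined = motile & np.isfinite(alpha)
    label[defined & (alpha < alpha_threshold)] = "persistent"
    label[defined & (alpha >= alpha_threshold)] = "confined"
    out["motile"] = motile
    out["label"] = label
    return out


def percent_time_confined(
    track_or_steps: Track | pd.DataFrame,
    alpha_threshold: float = ALPHA_THRESHOLD,
    motile_min_disp: float = DEFAULT_MOTILE_MIN_DISP,
) -> float:
    """Percent of motile interior steps classified confined.

    The denominator is the number of motile steps with a defined
    turning angle ("motile time"); NaN when there are none.
    """
    steps = (
        step_metrics(track_or_steps, alpha_threshold, motile_min_disp)
        if isinstance(track_or_steps, Track)
        else track_or_steps
    )
    confined = int((steps["label"] == "confined").sum())
    persistent = int((steps["label"] == "persistent").sum())
    denom = confined + persistent
    if denom == 0:
        return float("nan")
    return 100.0 * confined / denom


def track_length(track: Track) -> float:
    """Total path length (µm): the sum of step displacements, not the
    net displacement."""
    if len(track) < 2:
        return 0.0
    return float(track.step_lengths().sum())


def top_n_tracks(tracks: Sequence[Track], n: int = 16) -> list[Track]:
    """The n tracks with the largest path length (ties → smaller id);
    returns all tracks when fewer than n exist."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return top_k_by(tracks, track_length, n)


def summarize_pillar_tracks(
    tracks: Sequence[Track],
    alpha_threshold: float = ALPHA_THRESHOLD,
    motile_min_disp: float = DEFAULT_MOTILE_MIN_DISP,
) -> pd.DataFrame:
    """Per-track summary: path length, motile-step counts, percent confined."""
    rows = []
    for tr in tracks:
        steps = step_metrics(tr, alpha_threshold, motile_min_disp)
        confined = int((steps["label"] == "confined").sum())
        persistent = int((steps["label"] == "persistent").sum())
        rows.append(
            {
                "track_id": tr.track_id,
                "n_steps": len(steps),
                "track_length_um": track_length(tr),
                "n_motile_interior": confined + persistent,
                "n_confined": confined,
                "n_persistent": persistent,
                "percent_time_confined": (
                    100.0 * confined / (confined + persistent)
                    if confined + persistent
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
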