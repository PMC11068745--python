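"""Nucleus detection and frame-to-frame track linking.

Turns a nuclear-stain time-lapse into per-cell center-of-mass paths.
Detection is classical: Gaussian smoothing, a global threshold (Otsu by
default, or a fixed absolute value), connected components, and an
intensity-weighted centroid per component.  Linking is greedy
mutual-nearest-neighbor between consecutive frames with a hard
displacement gate; full assignment optimization is deliberately out of
scope at microchannel/micropillar cell densities.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .stacks import FrameStack
from .tracks import Track

__all__ = ["Detection", "detect_nuclei", "detect_movie", "link_tracks", "track_movie"]


@dataclass(frozen=True)
class Detection:
    """One nucleus in one frame.

    ``centroid_px`` / ``centroid_um`` are (x, y) with sub-pixel
    precision; the centroid is the intensity-weighted center of mass of
    the component in the raw (unsmoothed) frame.
    """

    frame: int
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_px: int
    mean_intensity: float


def detect_nuclei(
    frame: np.ndarray,
    pixel_size: float = 1.0,
    min_area: int = 4,
    smoothing_sigma: float = 1.0,
    threshold: str | float = "otsu",
    frame_index: int = 0,
) -> list[Detection]:
    """Detect bright blobs in one frame.

    Thresholding happens on the smoothed frame; centroids are computed
    on the raw frame.  A constant frame yields no detections (not an
    error); NaN pixels are an input error.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.isfinite(frame).all():
        raise ValueError("frame contains NaN or infinite pixels")
    smoothed = (
        gaussian(frame, sigma=smoothing_sigma, preserve_range=True)
        if smoothing_sigma > 0
        else frame
    )
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(smoothed) == 0:
            return []
        thr = threshold_otsu(smoothed)
    else:
        thr = float(threshold)
    mask = smoothed > thr
    if not mask.any():
        return []
    detections = []
    for prop in regionprops(label(mask), intensity_image=frame):
        if prop.area < min_area:
            continue
        cy, cx = prop.centroid_weighted
        detections.append(
            Detection(
                frame=frame_index,
                centroid_px=(float(cx), float(cy)),
                centroid_um=(float(cx * pixel_size), float(cy * pixel_size)),
                area_px=int(prop.area),
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return detections


def detect_movie(stack: FrameStack, **kwargs) -> list[list[Detection]]:
    """Run :func:`detect_nuclei` on every frame of a movie."""
    kwargs.setdefault("pixel_size", stack.pixel_size)
    return [
        detect_nuclei(stack.frames[f], frame_index=f, **kwargs)
        for f in range(stack.n_frames)
    ]


def _mutual_nn_pairs(
    prev_um: np.ndarray, cur_um: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-neighbor matching under a distance gate.

    Repeatedly links pairs that are each other's nearest unmatched
    neighbor, closest pairs first; ties break toward the smaller
    displacement, then the smaller row (track) index.
    """
    if len(prev_um) == 0 or len(cur_um) == 0:
        return []
    D = cdist(prev_um, cur_um)
    D[D > max_disp] = np.inf
    free_i = set(range(len(prev_um)))
    free_j = set(range(len(cur_um)))
    pairs: list[tuple[int, int]] = []
    while free_i and free_j:
        found = []
        for i in sorted(free_i):
            row = D[i]
            j = min(free_j, key=lambda jj: (row[jj], jj))
            if not np.isfinite(row[j]):
                continue
            col = D[:, j]
            i_back = min(free_i, key=lambda ii: (col[ii], ii))
            if i_back == i:
                found.append((row[j], i, j))
        if not found:
            break
        found.sort()
        for _, i, j in found:
            if i in free_i and j in free_j:
                pairs.append((i, j))
                free_i.discard(i)
                free_j.discard(j)
    return pairs


def link_tracks(
    detections: Sequence[Sequence[Detection]],
    max_disp: float,
    frame_interval: float,
    max_gap: int = 0,
    min_track_length: int = 2,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Parameters
    ----------
    detections
        One list of :class:`Detection` per frame, in frame order.
    max_disp
        Hard gate (µm) on a single link; longer jumps split tracks.
    max_gap
        Frames a track may go undetected and still be linked (default
        0: no gap closing — at a 2–3 min cadence gaps are rare).
    min_track_length
        Tracks with fewer points are discarded.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for f, dets in enumerate(detections):
        still, expired = [], []
        for tr in active:
            (still if f - tr["frames"][-1] <= max_gap + 1 else expired).append(tr)
        done.extend(expired)
        active = still
        cand = sorted(active, key=lambda tr: tr["id"])
        prev_um = np.array([tr["um"][-1] for tr in cand]).reshape(-1, 2)
        cur_um = np.array([d.centroid_um for d in dets]).reshape(-1, 2)
        pairs = _mutual_nn_pairs(prev_um, cur_um, max_disp)
        matched_j = set()
        for i, j in pairs:
            cand[i]["um"].append(tuple(cur_um[j]))
            cand[i]["frames"].append(f)
            matched_j.add(j)
        for j, det in enumerate(dets):
            if j not in matched_j:
                active.append(
                    {"id": next_id, "um": [det.centroid_um], "frames": [f]}
                )
                next_id += 1
    done.extend(active)
    tracks = []
    for tr in sorted(done, key=lambda d: d["id"]):
        if len(tr["frames"]) < min_track_length:
            continue
        frames = np.array(tr["frames"])
        tracks.append(
            Track(
                track_id=len(tracks),
                t=frames * frame_interval,
                xy=np.array(tr["um"]),
                frames=frames,
                source="detected",
            )
        )
    return tracks


def track_movie(
    stack: FrameStack,
    max_disp: float,
    max_gap: int = 0,
    min_track_length: int = 2,
    **detect_kwargs,
) -> list[Track]:
    """Detect + link in one call (the movie's frame interval is used)."""
    dets = detect_movie(stack, **detect_kwargs)
    return link_tracks(
        dets,
        max_disp=max_disp,
        frame_interval=stack.frame_interval,
        max_gap=max_gap,
        min_track_length=min_track_length,
    )
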