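"""Ground-truth motion simulators.

Two generators mirror the two migration assays:

* :func:`simulate_prw_2d` — a persistent random walk in a pillar forest.
  Each step the heading receives a wrapped-Gaussian increment of
  standard deviation ``angular_noise_sd`` (a rotational-diffusion
  surrogate) and the cell advances by a speed drawn from
  ``N(mean_speed, speed_sd)`` clipped at zero.  Pillar and arena-wall
  collisions are resolved by specular reflection, which preserves step
  length and keeps the zero-noise limit deterministic.
  ``angular_noise_sd = inf`` redraws the heading uniformly each step,
  giving the exact uniform turning-angle law.

* :func:`simulate_channel_1d` — channel-constrained motion.  Cells
  start just outside the entrance, enter with a per-frame Bernoulli
  probability, then advance along the channel axis with per-step speeds
  drawn as above; the far end reflects.  The lateral coordinate is
  pinned to the channel centerline.  Ground truth (whether and when each
  cell passed the entry margin) is stored in ``Track.meta``.

Identical seed + config reproduce output bit-for-bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from ..geometry import ChannelGeometry, GeometryError, PillarGeometry
from ..tracks import Track

__all__ = ["SimulationConfig", "simulate_prw_2d", "simulate_channel_1d"]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults follow the live-imaging protocol the devices were designed
    for: one frame every 3 minutes for 16 hours.  Speeds are µm/min,
    angular noise is radians per step.
    """

    mean_speed: float = 3.0
    speed_sd: float = 0.0
    angular_noise_sd: float = 0.3
    frame_interval: float = 3.0
    duration: float = 960.0
    n_cells: int = 1
    seed: int = 0
    geometry_ref: str = ""

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("mean_speed and speed_sd must be >= 0")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# 2-D persistent random walk in a pillar forest


def _first_hit(
    p: np.ndarray, d: np.ndarray, remaining: float, geom: PillarGeometry
) -> tuple[float, np.ndarray] | None:
    """Earliest obstacle along the segment p -> p + d*remaining.

    Returns (distance, inward surface normal) or None.  Obstacles are
    the arena walls and pillar disks.
    """
    best_t = np.inf
    best_n: np.ndarray | None = None
    w, h = geom.arena_size
    # walls: x=0, x=w, y=0, y=h
    for axis, bound, normal in (
        (0, 0.0, np.array([1.0, 0.0])),
        (0, w, np.array([-1.0, 0.0])),
        (1, 0.0, np.array([0.0, 1.0])),
        (1, h, np.array([0.0, -1.0])),
    ):
        if d[axis] != 0.0:
            t = (bound - p[axis]) / d[axis]
            if 1e-9 < t <= remaining and t < best_t:
                best_t, best_n = t, normal
    if geom.pillar_diameter > 0:
        q = p + d * remaining
        lo = np.minimum(p, q)
        hi = np.maximum(p, q)
        centers = geom.centers_in_box(lo, hi)
        R = geom.radius
        for c in centers:
            rel = p - c
            b = 2.0 * float(d @ rel)
            c0 = float(rel @ rel) - R * R
            disc = b * b - 4.0 * c0
            if disc <= 0:
                continue
            sq = math.sqrt(disc)
            for t in ((-b - sq) / 2.0, (-b + sq) / 2.0):
                if 1e-9 < t <= remaining and t < best_t:
                    hit = p + d * t
                    n = (hit - c) / np.linalg.norm(hit - c)
                    # only count hits entering the disk
                    if float(d @ n) < 0:
                        best_t, best_n = t, n
    if best_n is None:
        return None
    return best_t, best_n


def _advance(
    p: np.ndarray,
    theta: float,
    step_len: float,
    geom: PillarGeometry,
    max_bounce: int = 32,
) -> tuple[np.ndarray, float]:
    """Move step_len from p along heading theta with specular reflections.

    Returns the final position and the final heading (the reflected
    direction persists into the next step).
    """
    d = np.array([math.cos(theta), math.sin(theta)])
    remaining = step_len
    for _ in range(max_bounce):
        if remaining <= 0:
            break
        # fast path: cannot reach any pillar and stays inside the walls
        clr = float(geom.clearance(p[None])[0])
        q = p + d * remaining
        w, h = geom.arena_size
        inside = 0.0 <= q[0] <= w and 0.0 <= q[1] <= h
        if clr > remaining and inside:
            p = q
            remaining = 0.0
            break
        hit = _first_hit(p, d, remaining, geom)
        if hit is None:
            p = q
            remaining = 0.0
            break
        t, n = hit
        p = p + d * t + n * 1e-9  # nudge off the surface
        d = d - 2.0 * float(d @ n) * n
        remaining -= t
    return p, math.atan2(d[1], d[0])


def _spawn_positions(
    rng: np.random.Generator, n: int, geom: PillarGeometry, min_clearance: float = 0.5
) -> np.ndarray:
    w, h = geom.arena_size
    out = np.empty((n, 2))
    filled = 0
    for _ in range(1000):
        if filled >= n:
            break
        cand = rng.uniform([0, 0], [w, h], size=(n, 2))
        ok = geom.clearance(cand) > min_clearance
        take = min(int(ok.sum()), n - filled)
        out[filled : filled + take] = cand[ok][:take]
        filled += take
    if filled < n:
        raise GeometryError("could not place cells: arena effectively blocked")
    return out


def simulate_prw_2d(
    config: SimulationConfig, geometry: PillarGeometry
) -> list[Track]:
    """Persistent random walk of ``config.n_cells`` cells among pillars.

    Returns one :class:`Track` per cell with
    ``config.n_steps + 1`` positions; no position lies inside a pillar.
    """
    rng = np.random.default_rng(config.seed)
    n, steps = config.n_cells, config.n_steps
    dt = config.frame_interval
    pos = _spawn_positions(rng, n, geometry)
    theta = rng.uniform(-np.pi, np.pi, size=n)
    uniform_heading = not np.isfinite(config.angular_noise_sd)
    paths = np.empty((n, steps + 1, 2))
    paths[:, 0] = pos
    for k in range(steps):
        if uniform_heading:
            theta = rng.uniform(-np.pi, np.pi, size=n)
        elif config.angular_noise_sd > 0 and k > 0:
            theta = theta + rng.normal(0.0, config.angular_noise_sd, size=n)
        speeds = rng.normal(config.mean_speed, config.speed_sd, size=n)
        np.clip(speeds, 0.0, None, out=speeds)
        for i in range(n):
            p, th = _advance(paths[i, k], float(theta[i]), float(speeds[i] * dt), geometry)
            paths[i, k + 1] = p
            theta[i] = th
    assert not geometry.inside_pillar(paths.reshape(-1, 2)).any(), (
        "simulated position inside a pillar"
    )
    t = np.arange(steps + 1) * dt
    return [
        Track(track_id=i, t=t.copy(), xy=paths[i], source="simulated",
              frames=np.arange(steps + 1))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# 1-D channel migration


def simulate_channel_1d(
    config: SimulationConfig,
    geometry: ChannelGeometry,
    entry_probability: float = 1.0,
    entry_margin: float = 10.0,
    speed_profile: Callable[[float], float] | None = None,
) -> list[Track]:
    """Channel-constrained motion with Bernoulli entry at the entrance.

    Parameters
    ----------
    entry_probability
        Per-frame probability that a waiting cell starts moving into
        the channel.
    entry_margin
        Depth (µm) a cell must reach past the entrance to count as a
        ground-truth entry (default one cell length, 10 µm).  Waiting
        cells sit at axial positions in ``[-entry_margin, 0)``.
    speed_profile
        Optional ``t_min -> mean speed`` override, evaluated at each
        step midpoint; lets cohorts slow down or speed up over the
        course of a run.

    Ground truth in ``Track.meta``: ``entered`` (reached the margin)
    and ``entry_frame`` (first frame at/past the margin, or None).
    """
    if not 0.0 <= entry_probability <= 1.0:
        raise ValueError("entry_probability must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    n, steps = config.n_cells, config.n_steps
    dt = config.frame_interval
    L = geometry.length
    x0 = rng.uniform(-entry_margin, -min(1.0, entry_margin / 2), size=n)
    axial = np.empty((n, steps + 1))
    axial[:, 0] = x0
    moving = np.zeros(n, dtype=bool)
    for k in range(steps):
        start_now = ~moving & (rng.random(n) < entry_probability)
        moving |= start_now
        mean_k = (
            speed_profile((k + 0.5) * dt) if speed_profile is not None else config.mean_speed
        )
        speeds = rng.normal(mean_k, config.speed_sd, size=n)
        np.clip(speeds, 0.0, None, out=speeds)
        nxt = axial[:, k] + np.where(moving, speeds * dt, 0.0)
        # reflect off the far end of the channel
        over = nxt > L
        nxt[over] = 2 * L - nxt[over]
        np.clip(nxt, -entry_margin, L, out=nxt)
        axial[:, k + 1] = nxt
    t = np.arange(steps + 1) * dt
    tracks = []
    for i in range(n):
        xy = geometry.to_xy(axial[i])
        reached = axial[i] >= entry_margin
        entry_frame = int(np.argmax(reached)) if reached.any() else None
        tracks.append(
            Track(
                track_id=i,
                t=t.copy(),
                xy=xy,
                source="simulated",
                frames=np.arange(steps + 1),
                meta={
                    "entered": bool(reached.any()),
                    "entry_frame": entry_frame,
                    "channel_id": geometry.channel_id,
                },
            )
        )
    return tracks
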