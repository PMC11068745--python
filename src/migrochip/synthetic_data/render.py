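"""Render simulated tracks into DAPI-like fluorescence movies.

Each nucleus becomes an isotropic Gaussian blob; frames get a constant
background plus additive Gaussian read noise.  The point of rendering is
to exercise the detector/linker end-to-end against known ground truth,
so the model is deliberately minimal: no photobleaching, no drift, no
shape deformation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..stacks import FrameStack
from ..tracks import Track

__all__ = ["RenderConfig", "RenderError", "render_movie"]


class RenderError(ValueError):
    """A track position falls outside the image after µm→px conversion."""


@dataclass(frozen=True)
class RenderConfig:
    """Imaging model parameters.

    ``pixel_size`` defaults to 0.65 µm/px (typical for a 10× objective
    on a CCD camera); treat it as a placeholder to be replaced by the
    calibration of the actual optics.  Intensities are arbitrary units.
    """

    pixel_size: float = 0.65
    blob_sigma: float = 1.6  # µm; ~3–4 µm nucleus FWHM under 10×
    peak_intensity: float = 200.0
    background_mean: float = 20.0
    noise_sd: float = 2.0
    image_shape: tuple[int, int] = (512, 512)  # (ny, nx) px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.blob_sigma <= 0:
            raise ValueError("blob_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_movie(
    tracks: Sequence[Track],
    render: RenderConfig,
    frame_interval: float | None = None,
    seed: int = 0,
) -> FrameStack:
    """Render tracks as a (T, Y, X) movie.

    The frame count equals the (common) track length; positions are
    converted with image x = x_um / pixel_size, a position being the
    center of its pixel.  Raises :class:`RenderError` naming the track
    and frame for any out-of-bounds position.
    """
    ny, nx = render.image_shape
    if tracks:
        lengths = {len(tr) for tr in tracks}
        if len(lengths) != 1:
            raise ValueError("all tracks must have the same length for rendering")
        n_frames = lengths.pop()
        if frame_interval is None:
            dts = np.diff(tracks[0].t)
            frame_interval = float(dts[0]) if dts.size else 1.0
    else:
        n_frames = 1
        if frame_interval is None:
            frame_interval = 1.0
    rng = np.random.default_rng(seed)
    sigma_px = render.blob_sigma / render.pixel_size
    halfw = int(math.ceil(4 * sigma_px))
    frames = np.zeros((n_frames, ny, nx), dtype=np.float64)
    for tr in tracks:
        px = tr.xy / render.pixel_size  # columns: (x, y)
        for f in range(n_frames):
            cx, cy = px[f]
            if not (0.0 <= cx <= nx - 1 and 0.0 <= cy <= ny - 1):
                raise RenderError(
                    f"track {tr.track_id} frame {f} at ({cx:.1f}, {cy:.1f}) px "
                    f"is outside the {ny}x{nx} image"
                )
            x0, x1 = max(0, int(cx) - halfw), min(nx, int(cx) + halfw + 1)
            y0, y1 = max(0, int(cy) - halfw), min(ny, int(cy) + halfw + 1)
            xs = np.arange(x0, x1) - cx
            ys = np.arange(y0, y1) - cy
            blob = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_px**2))
            frames[f, y0:y1, x0:x1] += render.peak_intensity * blob
    frames += render.background_mean
    if render.noise_sd > 0:
        frames += rng.normal(0.0, render.noise_sd, size=frames.shape)
    return FrameStack(
        frames=frames.astype(np.float32),
        pixel_size=render.pixel_size,
        frame_interval=frame_interval,
    )
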