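"""Image containers (time-lapse movies, confocal z-stacks) and OME-TIFF I/O.

Movies are single-channel (nuclear stain) ``(T, Y, X)`` arrays with a
pixel size in µm/px and a frame interval in minutes.  Z-stacks are
multi-channel ``(C, Z, Y, X)`` arrays with anisotropic voxel sizes.
Physical sizes travel in OME metadata; readers take them from metadata
when present and fall back to caller-supplied values otherwise — the
frame interval in particular is never assumed, because acquisition
cadence varies between experiments even within one study.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FrameStack", "ZStack", "write_movie", "read_movie", "write_zstack", "read_zstack"]


@dataclass
class FrameStack:
    """Single-channel time-lapse: ``frames`` of shape (T, Y, X)."""

    frames: np.ndarray
    pixel_size: float  # µm / px
    frame_interval: float  # min

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, Y, X), got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ZStack:
    """Multi-channel confocal stack.

    ``channels`` maps a channel name (e.g. ``"phalloidin"``, ``"eea1"``)
    to a ``(Z, Y, X)`` array; all channels share one shape.
    ``voxel_size`` is ``(dz, dy, dx)`` in µm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ZStack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"all channels must share one shape, got {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive in z, y, x")
        self.channels = {k: np.asarray(v) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None


def write_movie(path: str | Path, stack: FrameStack) -> None:
    """Write a movie as OME-TIFF (TZCYX order, physical sizes in metadata)."""
    data = stack.frames.astype(np.float32)[:, None, None, :, :]
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval,
            "TimeIncrementUnit": "min",
        },
    )


def _ome_pixels_attrs(ome_xml: str) -> dict:
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    return dict(pixels.attrib) if pixels is not None else {}


def read_movie(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> FrameStack:
    """Read a single-channel movie; metadata wins over the fallbacks.

    Raises if neither metadata nor a fallback supplies pixel size or
    frame interval.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        attrs = _ome_pixels_attrs(tif.ome_metadata) if tif.ome_metadata else {}
    # collapse to (T, Y, X)
    keep = [i for i, ax in enumerate(axes) if ax in "TYX"]
    if len(keep) != data.ndim:
        squeeze = tuple(i for i in range(data.ndim) if i not in keep)
        for ax_i in squeeze:
            if data.shape[ax_i] != 1:
                raise ValueError(f"expected single-channel movie, axes {axes!r}")
        data = data.squeeze(axis=squeeze)
    if data.ndim == 2:
        data = data[None]
    px = float(attrs.get("PhysicalSizeX", 0)) or pixel_size
    dt = float(attrs.get("TimeIncrement", 0)) or frame_interval
    if not px:
        raise ValueError("pixel size absent from metadata; pass pixel_size=")
    if not dt:
        raise ValueError("frame interval absent from metadata; pass frame_interval=")
    return FrameStack(frames=data, pixel_size=float(px), frame_interval=float(dt))


def write_zstack(path: str | Path, stack: ZStack) -> None:
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)  # (C, Z, Y, X)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        data.astype(np.float32)[None],  # TCZYX
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def read_zstack(
    path: str | Path, voxel_size: tuple[float, float, float] | None = None
) -> ZStack:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        attrs = _ome_pixels_attrs(tif.ome_metadata) if tif.ome_metadata else {}
        names: list[str] = []
        if tif.ome_metadata:
            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            names = [
                ch.attrib.get("Name", f"channel{i}")
                for i, ch in enumerate(root.findall(".//ome:Channel", ns))
            ]
    order = [axes.index(ax) for ax in "CZYX" if ax in axes]
    extra = [i for i in range(data.ndim) if i not in order]
    for i in extra:
        if data.shape[i] != 1:
            raise ValueError(f"unexpected non-singleton axis in {axes!r}")
    data = data.transpose(extra + order).reshape(
        tuple(data.shape[i] for i in order)
    )
    if "C" not in axes:
        data = data[None]
    if not names or len(names) != data.shape[0]:
        names = [f"channel{i}" for i in range(data.shape[0])]
    if voxel_size is None:
        try:
            voxel_size = (
                float(attrs["PhysicalSizeZ"]),
                float(attrs["PhysicalSizeY"]),
                float(attrs["PhysicalSizeX"]),
            )
        except KeyError:
            raise ValueError("voxel size absent from metadata; pass voxel_size=")
    return ZStack(
        channels={n: data[i] for i, n in enumerate(names)}, voxel_size=voxel_size
    )
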