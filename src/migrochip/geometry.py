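"""Microfabricated device geometries.

Two devices are modeled, mirroring the common microfluidic assays for
confined leukocyte migration:

* **Microchannels** — straight channels (default 4 µm wide, 5 µm high,
  ~900 µm long) that force effectively one-dimensional migration.  A
  channel is described by its entrance position along the channel axis,
  the axis direction, and its lateral position in the device plane.
* **Micropillar forests** — a chamber filled with a square lattice of
  cylindrical pillars (default 10 µm diameter, 30 µm pitch) allowing
  confined two-dimensional migration.

All coordinates are continuous and in micrometres.  The origin sits at
the channel entrance (microchannels) or the arena corner (pillar
forests); images produced elsewhere use 0-based pixel indices with a
position at the pixel center.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GeometryError", "ChannelGeometry", "PillarGeometry"]


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate device descriptions."""


@dataclass(frozen=True)
class ChannelGeometry:
    """A single straight microchannel.

    Parameters
    ----------
    channel_id
        Identifier used when assigning tracks to channels.
    entrance_x
        Axial coordinate (µm) of the channel entrance; axial positions
        are measured from here, positive pointing into the channel.
    length, width, height
        Channel dimensions in µm.  ``height`` is metadata only (the
        analysis is planar).
    lateral_center
        Position (µm) of the channel centerline along the direction
        perpendicular to ``axis``.
    axis
        Unit vector of the channel axis in the device plane; normalized
        on construction.
    """

    channel_id: int = 0
    entrance_x: float = 0.0
    length: float = 900.0
    width: float = 4.0
    height: float = 5.0
    lateral_center: float = 0.0
    axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GeometryError(f"channel_length must be > 0, got {self.length}")
        if self.width <= 0:
            raise GeometryError(f"channel width must be > 0, got {self.width}")
        a = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(a))
        if norm == 0:
            raise GeometryError("channel axis must be a nonzero vector")
        object.__setattr__(self, "axis", (float(a[0] / norm), float(a[1] / norm)))

    @property
    def perp(self) -> tuple[float, float]:
        """Unit vector perpendicular to the channel axis."""
        ux, uy = self.axis
        return (-uy, ux)

    def axial_lateral(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project device-plane positions onto (axial, lateral) channel coordinates.

        Axial is measured from the entrance (positive = inside the
        channel); lateral from the centerline.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        u = np.asarray(self.axis)
        p = np.asarray(self.perp)
        axial = xy @ u - self.entrance_x
        lateral = xy @ p - self.lateral_center
        return axial, lateral

    def to_xy(self, axial: np.ndarray, lateral: float = 0.0) -> np.ndarray:
        """Inverse of :meth:`axial_lateral` (vectorized over ``axial``)."""
        axial = np.atleast_1d(np.asarray(axial, dtype=float))
        u = np.asarray(self.axis)
        p = np.asarray(self.perp)
        return (
            (axial + self.entrance_x)[:, None] * u[None, :]
            + (lateral + self.lateral_center) * p[None, :]
        )


@dataclass(frozen=True)
class PillarGeometry:
    """A square lattice of cylindrical pillars filling a rectangular arena.

    Pillar centers sit at ``(i + 1/2, j + 1/2) * spacing`` for integer
    ``i, j``, so the lattice tiles the whole arena.  Setting
    ``pillar_diameter = 0`` yields a pillar-free arena (useful for
    unconstrained persistent-random-walk limits).
    """

    pillar_diameter: float = 10.0
    spacing: float = 30.0
    lattice: str = "square"
    chamber_height: float = 5.0
    arena_size: tuple[float, float] = (300.0, 300.0)

    def __post_init__(self) -> None:
        if self.pillar_diameter < 0:
            raise GeometryError("pillar_diameter must be >= 0")
        if self.pillar_diameter > 0 and self.spacing <= self.pillar_diameter:
            raise GeometryError(
                "pillar spacing must exceed pillar diameter "
                f"(spacing={self.spacing}, diameter={self.pillar_diameter}); "
                "the arena is fully blocked otherwise"
            )
        if self.lattice != "square":
            raise GeometryError(f"unsupported lattice type: {self.lattice!r}")
        if self.arena_size[0] <= 0 or self.arena_size[1] <= 0:
            raise GeometryError("arena_size must be positive")

    @property
    def radius(self) -> float:
        return self.pillar_diameter / 2.0

    def nearest_centers(self, xy: np.ndarray) -> np.ndarray:
        """Nearest lattice pillar center for each position (n, 2)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        off = self.spacing / 2.0
        return np.round((xy - off) / self.spacing) * self.spacing + off

    def clearance(self, xy: np.ndarray) -> np.ndarray:
        """Distance (µm) from each position to the nearest pillar surface.

        Positive outside pillars, negative inside; ``+inf`` when the
        arena is pillar-free.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.pillar_diameter == 0:
            return np.full(xy.shape[0], np.inf)
        centers = self.nearest_centers(xy)
        return np.linalg.norm(xy - centers, axis=1) - self.radius

    def inside_pillar(self, xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        return self.clearance(xy) < -tol

    def centers_in_box(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Pillar centers whose disks could intersect the [lo, hi] box."""
        if self.pillar_diameter == 0:
            return np.empty((0, 2))
        off = self.spacing / 2.0
        pad = self.radius
        i0 = np.floor((lo - off - pad) / self.spacing).astype(int)
        i1 = np.ceil((hi - off + pad) / self.spacing).astype(int)
        ii, jj = np.meshgrid(
            np.arange(i0[0], i1[0] + 1), np.arange(i0[1], i1[1] + 1), indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel()]) * self.spacing + off
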