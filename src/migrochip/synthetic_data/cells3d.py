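"""Synthetic 3-D cells for morphometry validation.

Builds a two-channel confocal-like voxel stack with exact ground truth:

* channel ``"phalloidin"`` — a membrane shell (cortical-actin-like) on
  an ellipsoidal cell body, optionally decorated with ``n_spikes``
  radial protrusions in the equatorial plane (filopodium-like rods);
* channel ``"organelle"`` — spherical blobs inside the cell occupying an
  exact, known fraction of the cell volume (early-endosome-like).

The stack is auto-sized so the cell plus spikes fit with margin, and
the returned ground truth records both analytic values (ellipse area,
ellipsoid volume) and their voxelized counterparts on the generated
grid, so tests can separate discretization error from analysis error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..stacks import ZStack

__all__ = ["SyntheticCell3D", "synth_cell_3d"]


@dataclass(frozen=True)
class SyntheticCell3D:
    """Parameters of one synthetic cell.

    ``cell_radius`` may be a scalar (sphere) or ``(rz, ry, rx)``
    semi-axes in µm.  Spikes require equal in-plane semi-axes.  The
    default radius puts the projected area near the scale of a small
    lymphocyte (~38 µm²).
    """

    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2)  # (dz, dy, dx) µm
    cell_radius: float | tuple[float, float, float] = 3.47
    n_spikes: int = 0
    spike_length: float = 2.0
    spike_radius: float = 0.4
    organelle_fraction: float = 0.0
    organelle_blob_radius: float = 0.5
    shell_thickness: float = 0.4
    membrane_intensity: float = 200.0
    organelle_intensity: float = 180.0
    background_mean: float = 10.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.organelle_fraction <= 1.0:
            raise ValueError("organelle_fraction must be in [0, 1]")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        rz, ry, rx = self.semi_axes
        if min(rz, ry, rx) <= 0:
            raise ValueError("cell_radius must be positive")
        if self.n_spikes > 0 and not np.isclose(rx, ry):
            raise ValueError("spikes require equal in-plane semi-axes (rx == ry)")

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        r = self.cell_radius
        if np.isscalar(r):
            return (float(r), float(r), float(r))
        rz, ry, rx = r  # type: ignore[misc]
        return (float(rz), float(ry), float(rx))


def _ellipsoid_mask(
    zz: np.ndarray, yy: np.ndarray, xx: np.ndarray, semi: tuple[float, float, float]
) -> np.ndarray:
    rz, ry, rx = semi
    return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def synth_cell_3d(spec: SyntheticCell3D, seed: int = 0) -> tuple[ZStack, dict]:
    """Generate the two-channel stack and its ground truth.

    Returns ``(stack, truth)``; ``truth`` holds analytic and voxelized
    areas/volumes, spike parameters, the exact organelle voxel count,
    and the boolean ground-truth masks (``interior_mask``,
    ``organelle_mask``).
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = spec.voxel_size
    rz, ry, rx = spec.semi_axes
    ext_xy = spec.spike_length if spec.n_spikes > 0 else 0.0
    margin = 3.0 * max(spec.voxel_size)  # ≥ 2-voxel margin on each side
    half = np.array([rz + margin, ry + ext_xy + margin, rx + ext_xy + margin])
    shape = (2 * np.ceil(half / np.array([dz, dy, dx]))).astype(int) + 3
    nz, ny, nx = (int(v) for v in shape)
    z = (np.arange(nz) - (nz - 1) / 2) * dz
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")

    interior = _ellipsoid_mask(zz, yy, xx, (rz, ry, rx))
    inner = (
        max(rz - spec.shell_thickness, dz / 2),
        max(ry - spec.shell_thickness, dy / 2),
        max(rx - spec.shell_thickness, dx / 2),
    )
    shell = interior & ~_ellipsoid_mask(zz, yy, xx, inner)

    membrane = shell.copy()
    if spec.n_spikes > 0:
        phases = 2 * np.pi * np.arange(spec.n_spikes) / spec.n_spikes + 0.35
        r2 = xx**2 + yy**2 + zz**2
        for phi in phases:
            s = xx * np.cos(phi) + yy * np.sin(phi)
            perp2 = np.maximum(r2 - s**2, 0.0)
            rod = (
                (s >= 0.7 * rx)
                & (s <= rx + spec.spike_length)
                & (perp2 <= spec.spike_radius**2)
            )
            membrane |= rod

    # organelle blobs with an exact voxel count
    n_interior = int(interior.sum())
    target = int(round(spec.organelle_fraction * n_interior))
    organelle = np.zeros_like(interior)
    if target > 0:
        core = _ellipsoid_mask(
            zz, yy, xx,
            (
                max(rz - spec.organelle_blob_radius, dz),
                max(ry - spec.organelle_blob_radius, dy),
                max(rx - spec.organelle_blob_radius, dx),
            ),
        )
        core_idx = np.argwhere(core)
        for _ in range(10_000):
            if organelle.sum() >= target:
                break
            cz, cy, cx = core_idx[rng.integers(len(core_idx))]
            dist2 = (
                (zz - z[cz]) ** 2 + (yy - y[cy]) ** 2 + (xx - x[cx]) ** 2
            )
            new = (dist2 <= spec.organelle_blob_radius**2) & interior & ~organelle
            excess = int(organelle.sum() + new.sum()) - target
            if excess > 0:
                # trim the farthest-from-blob-center voxels to hit the target exactly
                new_idx = np.argwhere(new)
                order = np.argsort(dist2[tuple(new_idx.T)], kind="stable")
                drop = new_idx[order[len(new_idx) - excess :]]
                new[tuple(drop.T)] = False
            organelle |= new

    ch_mem = np.full((nz, ny, nx), spec.background_mean)
    ch_mem[membrane] += spec.membrane_intensity
    ch_org = np.full((nz, ny, nx), spec.background_mean)
    ch_org[organelle] += spec.organelle_intensity
    if spec.noise_sd > 0:
        ch_mem += rng.normal(0, spec.noise_sd, ch_mem.shape)
        ch_org += rng.normal(0, spec.noise_sd, ch_org.shape)

    stack = ZStack(
        channels={
            "phalloidin": ch_mem.astype(np.float32),
            "organelle": ch_org.astype(np.float32),
        },
        voxel_size=spec.voxel_size,
    )
    n_org = int(organelle.sum())
    truth = {
        "analytic_projected_area_um2": float(np.pi * rx * ry),
        "analytic_volume_um3": float(4.0 / 3.0 * np.pi * rx * ry * rz),
        "voxel_projected_area_um2": float(interior.any(axis=0).sum() * dy * dx),
        "voxel_volume_um3": float(n_interior * dz * dy * dx),
        "n_spikes": spec.n_spikes,
        "spike_length_um": spec.spike_length if spec.n_spikes else 0.0,
        "interior_voxels": n_interior,
        "organelle_voxels": n_org,
        "organelle_volume_um3": float(n_org * dz * dy * dx),
        "organelle_fraction_percent": 100.0 * n_org / n_interior,
        "interior_mask": interior,
        "organelle_mask": organelle,
    }
    return stack, truth
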