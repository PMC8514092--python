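"""Percent buried volume by voxel integration on a Cartesian grid.

The kinetic (steric) descriptor: the percent of the volume of a sphere of
fixed radius, centered on a chosen atom, that is occupied by the van der
Waals spheres of the molecule's atoms. Occupancy is decided per voxel
center on an axis-aligned cubic grid anchored at the center atom, using
unscaled Bondi radii for every atom — including the center atom itself
and all hydrogens under the default settings.

Defaults follow the descriptor's standard protocol: sphere radius 3.5 Å,
grid spacing 0.05 Å, Bondi radii. At that spacing the voxel-center
approximation is accurate to well under 0.2 percentage points for
single-sphere geometries (verified against the closed form in the test
suite), and grid-alignment jitter under rigid motion stays below 0.15
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .molio import BONDI, MolecularStructure, RadiiTable

__all__ = [
    "GridSpec",
    "BuriedVolumeResult",
    "buried_volume",
    "buried_volume_all_atoms",
    "radius_scan",
]


@dataclass(frozen=True)
class GridSpec:
    """Settings for buried-volume integration.

    Attributes
    ----------
    sphere_radius : float
        Radius (Å) of the probe sphere around the center atom. 3.5 Å is
        the conventional choice; results at 2.5–4.0 Å are very highly
        correlated.
    spacing : float
        Cubic voxel edge (Å). Must satisfy ``spacing <= sphere_radius/10``.
    radii : RadiiTable
        Van der Waals radii; unscaled Bondi by default.
    include_center_atom : bool
        Whether the center atom's own sphere occupies voxels. True by
        default (all atoms count); the ligand-style convention that
        excludes the center is available for sensitivity studies.
    include_hydrogens : bool
        Whether hydrogens occupy voxels. True by default.
    """

    sphere_radius: float = 3.5
    spacing: float = 0.05
    radii: RadiiTable = field(default=BONDI)
    include_center_atom: bool = True
    include_hydrogens: bool = True

    def __post_init__(self) -> None:
        if not self.sphere_radius > 0:
            raise ValueError(f"sphere_radius must be positive, got {self.sphere_radius}")
        if not 0 < self.spacing <= self.sphere_radius / 10:
            raise ValueError(
                f"spacing must satisfy 0 < spacing <= sphere_radius/10 "
                f"({self.sphere_radius / 10:.3g}), got {self.spacing}"
            )


@dataclass(frozen=True)
class BuriedVolumeResult:
    """Outcome of one buried-volume integration."""

    percent_buried: float
    occupied_voxels: int
    total_voxels: int
    center_index: int
    grid: GridSpec


def _sphere_voxel_centers(center: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Centers of all voxels whose center lies within the probe sphere.

    The grid is axis-aligned, anchored at the center atom's position, with
    voxel centers at half-integer multiples of the spacing so the grid is
    symmetric about the anchor.
    """
    r, h = grid.sphere_radius, grid.spacing
    n = int(np.ceil(r / h))
    axis = (np.arange(-n, n) + 0.5) * h
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij", sparse=True)
    inside = x * x + y * y + z * z <= r * r
    pts = np.empty((int(inside.sum()), 3))
    xx, yy, zz = np.broadcast_arrays(x, y, z)
    pts[:, 0] = xx[inside]
    pts[:, 1] = yy[inside]
    pts[:, 2] = zz[inside]
    return pts + center


def buried_volume(
    structure: MolecularStructure, center_index: int, grid: GridSpec | None = None
) -> BuriedVolumeResult:
    """Percent buried volume of the sphere around ``center_index``.

    A voxel belongs to the sphere if its center lies within
    ``grid.sphere_radius`` of the center atom; it is occupied if its
    center lies within the van der Waals radius of any included atom.

    Raises
    ------
    IndexError
        If ``center_index`` is out of range.
    KeyError
        If any included atom's element has no radius in ``grid.radii``.
    """
    if grid is None:
        grid = GridSpec()
    if not 0 <= center_index < structure.n_atoms:
        raise IndexError(
            f"center_index {center_index} out of range for "
            f"{structure.n_atoms}-atom structure"
        )
    center = structure.coords[center_index]
    pts = _sphere_voxel_centers(center, grid)
    total = pts.shape[0]
    occupied = np.zeros(total, dtype=bool)
    for i, (sym, pos) in enumerate(zip(structure.symbols, structure.coords)):
        if i == center_index and not grid.include_center_atom:
            continue
        if sym == "H" and not grid.include_hydrogens:
            continue
        radius = grid.radii[sym]
        # Atoms whose vdW sphere cannot reach the probe sphere are skipped;
        # this is a pure optimization with a bit-identical result.
        if np.linalg.norm(pos - center) - radius > grid.sphere_radius:
            continue
        d2 = np.einsum("ij,ij->i", pts - pos, pts - pos)
        occupied |= d2 <= radius * radius
    return BuriedVolumeResult(
        percent_buried=100.0 * int(occupied.sum()) / total,
        occupied_voxels=int(occupied.sum()),
        total_voxels=total,
        center_index=center_index,
        grid=grid,
    )


def buried_volume_all_atoms(
    structure: MolecularStructure, grid: GridSpec | None = None
) -> list[BuriedVolumeResult]:
    """Buried volume around every atom, in atom order."""
    return [buried_volume(structure, i, grid) for i in range(structure.n_atoms)]


def radius_scan(
    structure: MolecularStructure,
    center_index: int,
    radii_list: Sequence[float] | Iterable[float],
    grid: GridSpec | None = None,
) -> list[tuple[float, float]]:
    """Buried volume at a series of sphere radii, other settings fixed.

    Radii must be positive and strictly ascending. Returns
    ``[(radius, percent_buried), ...]``.
    """
    if grid is None:
        grid = GridSpec()
    radii_list = list(radii_list)
    if any(r <= 0 for r in radii_list):
        raise ValueError("sphere radii must be positive")
    if any(b <= a for a, b in zip(radii_list, radii_list[1:])):
        raise ValueError("sphere radii must be strictly ascending")
    out: list[tuple[float, float]] = []
    for r in radii_list:
        g = replace(grid, sphere_radius=r)
        out.append((r, buried_volume(structure, center_index, g).percent_buried))
    return out
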