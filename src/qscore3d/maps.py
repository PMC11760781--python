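"""Density maps: MRC/CCP4 reading and writing, trilinear interpolation.

A :class:`DensityGrid` is the package's in-memory map container: a 3-D scalar
array in x,y,z index order plus the voxel geometry needed to move between
world coordinates (Å) and fractional voxel indices.  Axis permutations in the
file (MAPC/MAPR/MAPS) are normalised to x,y,z on read, so downstream code
never sees a permuted array.

Origin convention follows the dominant cryo-EM dialect: the MRC-2014 ORIGIN
record wins when any component is non-zero, otherwise the origin is
NC/NR/NSSTART times the voxel size.  Samples requested outside the grid
interpolate to NaN, which downstream correlation code treats as "no data"
rather than zero — zero-filling would bias Q-scores at map edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

from .errors import MapFormatError

__all__ = ["DensityGrid", "read_map", "write_map"]

_VALID_MODES = (0, 1, 2)


@dataclass
class DensityGrid:
    """3-D scalar map with voxel geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Map values indexed so that ``values[ix, iy, iz]`` sits at world
        position ``origin + (ix, iy, iz) * voxel_size``.
    voxel_size : ndarray, shape (3,)
        Å per voxel along x, y, z; all components must be positive.
    origin : ndarray, shape (3,)
        World position (Å) of voxel (0, 0, 0).
    file_axis_order : tuple
        MAPC/MAPR/MAPS of the source file, kept for provenance; the array
        itself is always x,y,z.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    file_axis_order: tuple = (1, 2, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise MapFormatError(f"map array must be 3-D, got {self.values.ndim}-D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise MapFormatError(f"voxel size must be positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (Å) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - self.origin) / self.voxel_size

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices to world coordinates (Å)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx * self.voxel_size + self.origin

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world coordinates.

        Points outside the grid return NaN (the out-of-grid sentinel);
        callers exclude those samples instead of treating them as zero.
        """
        idx = self.world_to_voxel(points)
        return ndimage.map_coordinates(
            self.values, idx.T, order=1, mode="constant", cval=np.nan, prefilter=False
        )

    def voxel_center_coords(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[k] + self.voxel_size[k] * np.arange(self.shape[k])
            for k in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def bounds(self) -> tuple:
        """(lower, upper) world corners of the voxel-center lattice."""
        upper = self.origin + self.voxel_size * (np.array(self.shape) - 1)
        return self.origin.copy(), upper


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 density map.

    The file's axis permutation is undone so the returned array is x,y,z;
    the origin is resolved from the ORIGIN record when non-zero, else from
    the NSTART header words.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc

    mode = ccp4.header_i32(4)
    if mode not in _VALID_MODES:
        raise MapFormatError(f"unsupported MRC mode {mode} in {path!r} (need 0/1/2)")
    axis_order = tuple(ccp4.header_i32(w) for w in (17, 18, 19))
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(
            f"MAPC/MAPR/MAPS {axis_order} in {path!r} is not a permutation of x,y,z"
        )
    nstart_crs = [ccp4.header_i32(w) for w in (5, 6, 7)]
    origin_rec = np.array([ccp4.header_float(w) for w in (50, 51, 52)])

    ccp4.setup(np.nan, gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True)
    voxel = np.array(ccp4.grid.spacing, dtype=np.float64)

    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        nstart_xyz = np.zeros(3)
        for file_axis, xyz_axis in enumerate(axis_order):
            nstart_xyz[xyz_axis - 1] = nstart_crs[file_axis]
        origin = nstart_xyz * voxel
    return DensityGrid(values, voxel, origin, file_axis_order=axis_order)


def write_map(grid: DensityGrid, path) -> None:
    """Write a map as MRC mode 2 (float32), canonical x,y,z axis order."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    g.unit_cell = gemmi.UnitCell(
        nx * grid.voxel_size[0], ny * grid.voxel_size[1], nz * grid.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    g.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for w, val in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(val))
    ccp4.write_ccp4_map(str(path))
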