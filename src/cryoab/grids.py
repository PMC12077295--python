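"""Cryo-EM density grids: reading, writing, cropping, resampling, normalization.

A density map is a scalar field sampled on a regular orthogonal lattice.  We
use a node-centered convention: grid node ``(i, j, k)`` sits at the physical
point ``origin + (i, j, k) * voxel_size`` (all in Å).  Axis order is always
(x, y, z) after reading, regardless of how the file stores its sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates


class MapFormatError(ValueError):
    """The file is not a readable orthogonal MRC/CCP4 map."""


class EmptyCropError(ValueError):
    """The requested crop does not intersect the map extent."""


@dataclass
class DensityGrid:
    """A 3D scalar field with physical metadata.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values, float32.
    voxel_size : ndarray, shape (3,)
        Å per grid step along x, y, z (strictly positive).
    origin : ndarray, shape (3,)
        Å position of node (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.full(3, 2.0))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("density values must be a 3D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size components must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_max(self) -> np.ndarray:
        """Å position of the last grid node along each axis."""
        return self.origin + (np.array(self.shape) - 1) * self.voxel_size

    def node_position(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.voxel_size.copy(), self.origin.copy())


def read_map(path) -> DensityGrid:
    """Read an MRC/CCP4 map into a :class:`DensityGrid`.

    Axis order is normalized to (x, y, z).  The physical origin honors both
    the MRC ``ORIGIN`` record and the ``NXSTART/NYSTART/NZSTART`` fields,
    preferring the ``ORIGIN`` record when it is nonzero (the behavior of
    common visualization tools).
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read map file {path!r}: {exc}") from exc
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError("non-orthogonal unit cells are not supported")
    nstart = np.array([ccp4.header_i32(i) for i in (5, 6, 7)], dtype=float)
    origin_rec = np.array([ccp4.header_float(i) for i in (50, 51, 52)], dtype=float)
    # reorder axes so the array is indexed [x, y, z]
    ccp4.setup(float("nan"))
    values = np.array(ccp4.grid.array, dtype=np.float32)
    if np.any(~np.isfinite(values)):
        # NaN fill marks sections absent from the file; treat as empty density
        values = np.nan_to_num(values, nan=0.0)
    voxel = np.array(ccp4.grid.spacing, dtype=float)
    if np.any(origin_rec != 0):
        origin = origin_rec
    else:
        origin = nstart * voxel
    return DensityGrid(values, voxel, origin)


def write_map(grid: DensityGrid, path) -> None:
    """Write a :class:`DensityGrid` as an MRC/CCP4 mode-2 (float) map."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    a, b, c = np.array([nx, ny, nz]) * grid.voxel_size
    g.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    g.array[:] = grid.values
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


def crop_to_structure(grid: DensityGrid, coords, margin: float) -> DensityGrid:
    """Crop the grid to the bounding box of ``coords`` expanded by ``margin`` Å.

    Bounds round outward to whole nodes so the requested physical margin is
    never shrunk; the crop is intersected with the input extent.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("coords must be non-empty")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    ilo = np.floor((lo - grid.origin) / grid.voxel_size).astype(int)
    ihi = np.ceil((hi - grid.origin) / grid.voxel_size).astype(int)
    ilo = np.maximum(ilo, 0)
    ihi = np.minimum(ihi, np.array(grid.shape) - 1)
    if np.any(ihi < ilo):
        raise EmptyCropError("crop region lies entirely outside the map")
    values = grid.values[
        ilo[0] : ihi[0] + 1, ilo[1] : ihi[1] + 1, ilo[2] : ihi[2] + 1
    ].copy()
    return DensityGrid(values, grid.voxel_size.copy(), grid.origin + ilo * grid.voxel_size)


def resample(grid: DensityGrid, target_voxel: float) -> DensityGrid:
    """Resample onto a lattice of spacing ``target_voxel`` Å (trilinear).

    The new lattice starts at the same origin and covers the same physical
    extent; samples falling outside the source extent are zero.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be > 0")
    target = np.full(3, float(target_voxel))
    if np.allclose(target, grid.voxel_size):
        return grid.copy()
    n_new = np.floor(
        (np.array(grid.shape) - 1) * grid.voxel_size / target
    ).astype(int) + 1
    idx = np.indices(tuple(n_new), dtype=float)
    # fractional source indices of each new node
    src = idx * (target / grid.voxel_size)[:, None, None, None]
    values = map_coordinates(
        grid.values.astype(np.float64), src, order=1, mode="constant", cval=0.0
    )
    return DensityGrid(values.astype(np.float32), target, grid.origin.copy())


def normalize(grid: DensityGrid) -> DensityGrid:
    """Zero out negative values, then divide by the maximum (if positive)."""
    v = np.maximum(grid.values, 0.0)
    peak = float(v.max()) if v.size else 0.0
    if peak > 0:
        v = v / peak
    return DensityGrid(v, grid.voxel_size.copy(), grid.origin.copy())
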