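"""Encoding antibody poses as a coarse 10-channel grid and decoding back.

Each antibody placement (R, T) is stored in the cell containing its center
of mass.  The cell grid has a fixed physical cell size (default 8 Å — four
2 Å map voxels per output cell), so detection works on a lattice decoupled
from map resolution.  Channel layout over cells:

    0     occupancy (1 where a cell owns an antibody center)
    1-3   local offset T_loc from the cell corner, Å, in [0, cell_size)
    4-6   direction p (image of the template axis u_z)
    7-8   (cos theta, sin theta) of the in-plane angle
    9     VHH-vs-Fab indicator

Pose channels are defined only where occupancy is 1 and are zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotations import decompose_rotation, recompose_rotation

U_Z = np.array([0.0, 0.0, 1.0])
N_CHANNELS = 10


class CellCollisionError(ValueError):
    """Two poses fall in the same grid cell and cannot both be encoded."""


class DegeneratePoseError(ValueError):
    """A decoded direction vector has zero norm."""


@dataclass
class GridGeometry:
    """Placement of the coarse cell lattice in physical space."""

    shape: tuple[int, int, int]
    cell_size: float = 8.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_corner(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.cell_size

    def owner_cell(self, position) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(position, float) - self.origin) / self.cell_size)
        return tuple(int(i) for i in idx)

    def contains_cell(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.shape))

    @classmethod
    def covering(cls, origin, extent: np.ndarray, cell_size: float = 8.0) -> "GridGeometry":
        """Smallest cell grid covering a physical box of size ``extent`` Å."""
        shape = tuple(int(np.ceil(e / cell_size)) for e in np.asarray(extent, float))
        return cls(shape=shape, cell_size=cell_size, origin=origin)


@dataclass
class AbPose:
    """One antibody's rigid placement and its grid decomposition."""

    rotation: np.ndarray
    translation: np.ndarray
    ab_class: str = "fab"  # "fab" | "vhh"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.ab_class not in ("fab", "vhh"):
            raise ValueError("ab_class must be 'fab' or 'vhh'")
        rtr = self.rotation.T @ self.rotation
        if not (
            np.allclose(rtr, np.eye(3), atol=1e-6)
            and abs(np.linalg.det(self.rotation) - 1) < 1e-6
        ):
            raise ValueError("rotation must be a proper rotation matrix")

    @property
    def direction(self) -> np.ndarray:
        return decompose_rotation(self.rotation, U_Z)[0]

    @property
    def angle(self) -> float:
        return decompose_rotation(self.rotation, U_Z)[1]

    @property
    def is_vhh(self) -> bool:
        return self.ab_class == "vhh"

    def cell_index(self, geometry: GridGeometry) -> tuple[int, int, int]:
        return geometry.owner_cell(self.translation)

    def local_offset(self, geometry: GridGeometry) -> np.ndarray:
        return self.translation - geometry.cell_corner(self.cell_index(geometry))


@dataclass
class TargetGrid:
    """10-channel grid over cells; also holds network predictions."""

    channels: np.ndarray  # (10, nx, ny, nz)
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape != (N_CHANNELS, *self.geometry.shape):
            raise ValueError(
                f"channels shape {self.channels.shape} does not match geometry "
                f"{(N_CHANNELS, *self.geometry.shape)}"
            )

    @property
    def occupancy(self) -> np.ndarray:
        return self.channels[0]

    @property
    def n_occupied(self) -> int:
        return int(np.round(self.channels[0].sum()))

    def occupied_cells(self) -> list[tuple[int, int, int]]:
        return [tuple(idx) for idx in np.argwhere(self.channels[0] > 0.5)]


def encode_poses(poses: list[AbPose], geometry: GridGeometry) -> TargetGrid:
    """Build the ground-truth 10-channel grid for a list of poses."""
    channels = np.zeros((N_CHANNELS, *geometry.shape), dtype=np.float64)
    seen: dict[tuple[int, int, int], int] = {}
    for i, pose in enumerate(poses):
        cell = pose.cell_index(geometry)
        if not geometry.contains_cell(cell):
            raise ValueError(f"pose translation {pose.translation} outside the grid")
        if cell in seen:
            raise CellCollisionError(
                f"poses {seen[cell]} and {i} both own cell {cell}"
            )
        seen[cell] = i
        p, theta = decompose_rotation(pose.rotation, U_Z)
        channels[0][cell] = 1.0
        channels[1:4, cell[0], cell[1], cell[2]] = pose.local_offset(geometry)
        channels[4:7, cell[0], cell[1], cell[2]] = p
        channels[7, cell[0], cell[1], cell[2]] = np.cos(theta)
        channels[8, cell[0], cell[1], cell[2]] = np.sin(theta)
        channels[9][cell] = 1.0 if pose.is_vhh else 0.0
    return TargetGrid(channels, geometry)


def decode_cell(grid: TargetGrid, cell_index: tuple[int, int, int]) -> AbPose:
    """Decode the pose stored (or predicted) at one grid cell."""
    i, j, k = cell_index
    v = grid.channels[:, i, j, k]
    cs = grid.geometry.cell_size
    t_loc = np.clip(v[1:4], 0.0, np.nextafter(cs, 0.0))
    translation = grid.geometry.cell_corner(cell_index) + t_loc
    direction = v[4:7]
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise DegeneratePoseError(f"zero-norm direction at cell {cell_index}")
    direction = direction / norm
    theta = float(np.arctan2(v[8], v[7]))
    if theta >= np.pi:
        theta -= 2 * np.pi
    rotation = recompose_rotation(direction, theta, U_Z)
    ab_class = "vhh" if v[9] > 0.5 else "fab"
    return AbPose(rotation=rotation, translation=translation, ab_class=ab_class)
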