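"""Voxel-grid geometry and the two in-memory containers used everywhere.

All delineations and PET volumes in a comparison must live on one shared
grid; the pipeline refuses mixed grids rather than silently resampling,
because every downstream metric (Dice, Hausdorff, volume) assumes voxel-wise
correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "SUVVolume",
    "BinaryMask",
    "GridMismatchError",
    "assert_same_grid",
]

#: tolerance (mm) when deciding whether two grids are "the same"
GRID_TOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Raised when volumes/masks that must share a grid do not."""


def _as_triple(x, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected a length-3 sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3-D voxel grid: shape, spacing (mm), origin (mm), direction cosines.

    Voxel indices are 0-based; the world coordinate of voxel ``i`` is
    ``origin + direction @ (spacing * i)`` in mm, i.e. exactly what the
    NIfTI affine encodes, with no extra half-voxel offset.
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = field(default=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)))

    def __post_init__(self):
        shape = tuple(int(s) for s in _as_triple(self.shape, dtype=int))
        spacing = tuple(float(s) for s in _as_triple(self.spacing))
        origin = tuple(float(s) for s in _as_triple(self.origin))
        direction = np.asarray(self.direction, dtype=float)
        if direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if any(s < 1 for s in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0 mm, got {spacing}")
        if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise ValueError("direction columns must be orthonormal (tol 1e-6)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", tuple(tuple(row) for row in direction))

    # -- geometry ---------------------------------------------------------

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world (mm) affine in NIfTI convention."""
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """World (mm) coordinates of voxel center(s); accepts (..., 3) arrays."""
        idx = np.asarray(index, dtype=float)
        return idx @ (self.direction_matrix @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel index of world (mm) point(s)."""
        w = np.asarray(world, dtype=float) - np.asarray(self.origin)
        M = self.direction_matrix @ np.diag(self.spacing)
        return w @ np.linalg.inv(M).T

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of every voxel center."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    # -- comparison -------------------------------------------------------

    def matches(self, other: "ImageGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        return self.mismatch(other, tol_mm) is None

    def mismatch(self, other: "ImageGrid", tol_mm: float = GRID_TOL_MM):
        """Name of the first discordant field, or None if grids agree."""
        if self.shape != other.shape:
            return "shape"
        if not np.allclose(self.spacing, other.spacing, atol=tol_mm):
            return "spacing"
        if not np.allclose(self.origin, other.origin, atol=tol_mm):
            return "origin"
        if not np.allclose(self.direction_matrix, other.direction_matrix, atol=tol_mm):
            return "direction"
        return None


class _GriddedField:
    """Shared plumbing for a scalar/boolean field over an ImageGrid."""

    grid: ImageGrid
    values: np.ndarray

    def _check_shape(self):
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )


class SUVVolume(_GriddedField):
    """A PET volume in SUV units (dimensionless, non-negative) on a grid."""

    def __init__(self, grid: ImageGrid, values: np.ndarray):
        self.grid = grid
        self.values = np.asarray(values, dtype=np.float32)
        self._check_shape()
        n_bad = int(np.count_nonzero(~np.isfinite(self.values)))
        if n_bad:
            raise ValueError(f"SUV volume contains {n_bad} non-finite voxel(s)")
        if np.any(self.values < 0):
            n_neg = int(np.count_nonzero(self.values < 0))
            raise ValueError(f"SUV volume contains {n_neg} negative voxel(s); SUV must be >= 0")

    def __repr__(self):
        return (
            f"SUVVolume(shape={self.grid.shape}, spacing={self.grid.spacing} mm, "
            f"max={float(self.values.max()):.3g})"
        )


class BinaryMask(_GriddedField):
    """A binary delineation (e.g. a gross tumor volume) on a grid."""

    def __init__(self, grid: ImageGrid, occupancy: np.ndarray):
        self.grid = grid
        self.values = np.asarray(occupancy)
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(
                    f"mask contains non-binary values {uniq[:8]}; pass booleans or 0/1"
                )
            self.values = self.values.astype(bool)
        self._check_shape()

    @property
    def occupancy(self) -> np.ndarray:
        return self.values

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.values))

    def is_empty(self) -> bool:
        return self.n_occupied == 0

    def __repr__(self):
        return (
            f"BinaryMask(shape={self.grid.shape}, spacing={self.grid.spacing} mm, "
            f"occupied={self.n_occupied})"
        )


def assert_same_grid(items, tol_mm: float = GRID_TOL_MM) -> None:
    """Require all volumes/masks to share one grid (within ``tol_mm``).

    Raises :class:`GridMismatchError` naming the first discordant field.
    Registration/resampling is deliberately out of scope: inputs must arrive
    already co-registered on a common grid.
    """
    items = list(items)
    if not items:
        raise ValueError("assert_same_grid needs at least one item")
    ref = items[0].grid
    for k, item in enumerate(items[1:], start=1):
        bad = ref.mismatch(item.grid, tol_mm=tol_mm)
        if bad is not None:
            raise GridMismatchError(
                f"item {k} disagrees with item 0 on grid field '{bad}': "
                f"{getattr(ref, bad)} vs {getattr(item.grid, bad)}"
            )
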