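"""Grid-aware image containers.

All spatial quantities are expressed in physical millimetres.  A voxel with
0-based index ``i = (i0, i1, i2)`` sits at the physical location
``origin + i * spacing``; axes are not permuted or flipped relative to the
array layout, so the data model is deliberately simpler than a full NIfTI
affine (see :mod:`atrophynet.nifti` for how headers are mapped onto it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "DisplacementField",
    "AttentionMaps",
    "JacobianMap",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Raised when an operation receives images on different grids."""


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D sampling grid in physical space.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    spacing
        Voxel size in mm along each axis; must be positive.
    origin
        Physical coordinate (mm) of the voxel with index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be 3 positive reals, got {spacing}")
        if len(origin) != 3:
            raise ValueError("grid origin must have 3 components")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def coordinates(self) -> np.ndarray:
        """Physical coordinates of all voxel centres, shape ``(*shape, 3)``."""
        axes = [
            self.origin[k] + np.arange(self.shape[k]) * self.spacing[k]
            for k in range(3)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack(mesh, axis=-1)

    def isclose(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a: ImageGrid, b: ImageGrid, what: str) -> None:
    if not a.isclose(b):
        raise GridMismatchError(f"{what}: grids differ ({a} vs {b})")


@dataclass
class ScalarVolume:
    """A scalar 3D image (intensities in arbitrary units) on a grid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")


@dataclass
class DisplacementField:
    """Dense displacement u(x) in mm on the fixed image's grid.

    The field defines the mapping Phi(x) = x + u(x) taking fixed-image
    physical coordinates to moving-image physical coordinates.  ``vectors``
    has shape ``(*grid.shape, 3)``.
    """

    grid: ImageGrid
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"vectors shape {self.vectors.shape} != {(*self.grid.shape, 3)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(grid, np.zeros((*grid.shape, 3)))


@dataclass
class AttentionMaps:
    """Per-voxel (shrink, expand, background) soft assignment.

    ``channels`` has shape ``(3, *grid.shape)`` with channel order
    (shrink, expand, background); each voxel's channels sum to 1.
    """

    grid: ImageGrid
    channels: np.ndarray

    SHRINK: int = field(default=0, init=False, repr=False)
    EXPAND: int = field(default=1, init=False, repr=False)
    BACKGROUND: int = field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.shape != (3, *self.grid.shape):
            raise ValueError(
                f"channels shape {self.channels.shape} != {(3, *self.grid.shape)}"
            )
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("attention maps contain non-finite values")
        sums = self.channels.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("attention channels must sum to 1 per voxel")

    @property
    def shrink(self) -> np.ndarray:
        return self.channels[self.SHRINK]

    @property
    def expand(self) -> np.ndarray:
        return self.channels[self.EXPAND]

    @property
    def background(self) -> np.ndarray:
        return self.channels[self.BACKGROUND]

    @classmethod
    def from_masks(
        cls, grid: ImageGrid, shrink: np.ndarray, expand: np.ndarray
    ) -> "AttentionMaps":
        """Build hard attention maps from binary shrink/expand masks."""
        shrink = np.asarray(shrink, dtype=np.float64)
        expand = np.asarray(expand, dtype=np.float64)
        if np.any(shrink * expand > 0):
            raise ValueError("shrink and expand masks overlap")
        bg = 1.0 - shrink - expand
        return cls(grid, np.stack([shrink, expand, bg], axis=0))


@dataclass
class JacobianMap:
    """Determinant of the deformation gradient det(I + grad u), per voxel."""

    grid: ImageGrid
    det: np.ndarray

    def __post_init__(self) -> None:
        self.det = np.asarray(self.det, dtype=np.float64)
        if self.det.shape != self.grid.shape:
            raise ValueError(f"det shape {self.det.shape} != {self.grid.shape}")
        if not np.all(np.isfinite(self.det)):
            raise ValueError("Jacobian map contains non-finite values")
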