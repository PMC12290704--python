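"""NIfTI-1 I/O for scalar volumes and displacement fields.

Scalar images are stored as plain 3D NIfTI; displacement fields are written
as 5D NIfTI with shape (X, Y, Z, 1, 3) and intent code ``NIFTI_INTENT_VECTOR``
(the convention used by common registration tools), and the reader also
accepts the 4D dialect (X, Y, Z, 3).  Vector components are physical mm in
the fixed image's axis frame, fixed -> moving.

Only the diagonal part of the NIfTI affine is interpreted (spacing and
origin); oblique affines are rejected so that the simple index -> physical
mapping of :class:`~atrophynet.grids.ImageGrid` stays exact.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grids import DisplacementField, ImageGrid, ScalarVolume

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected NIfTI layout."""


def _grid_from_header(img: nib.Nifti1Image, shape3: tuple[int, int, int]) -> ImageGrid:
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise FormatError("oblique NIfTI affines are not supported; expected a diagonal affine")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise FormatError("NIfTI header has non-positive voxel spacing")
    origin = affine[:3, 3]
    return ImageGrid(shape3, tuple(spacing), tuple(origin))


def _affine(grid: ImageGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_volume(path: str | os.PathLike) -> ScalarVolume:
    """Read a 3D scalar NIfTI image.

    Raises
    ------
    FormatError
        If the payload is not a 3D scalar image (e.g. a 4D time series).
    """
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise FormatError(
            f"expected a 3D scalar image, got shape {np.asanyarray(img.dataobj).shape}"
        )
    grid = _grid_from_header(img, data.shape)
    return ScalarVolume(grid, np.asarray(data, dtype=np.float64))


def write_volume(path: str | os.PathLike, volume: ScalarVolume) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))


def read_field(path: str | os.PathLike) -> DisplacementField:
    """Read a displacement field (5D vector-intent or 4D 3-component NIfTI)."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        data = data[:, :, :, 0, :]
    elif data.ndim == 4 and data.shape[3] == 3:
        pass
    else:
        raise FormatError(
            "expected a displacement field with 3 vector components "
            f"(5D (X,Y,Z,1,3) or 4D (X,Y,Z,3)), got shape {data.shape}"
        )
    grid = _grid_from_header(img, data.shape[:3])
    return DisplacementField(grid, np.asarray(data, dtype=np.float64))


def write_field(path: str | os.PathLike, field: DisplacementField) -> None:
    data = field.vectors.astype(np.float64)[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data, _affine(field.grid))
    img.header.set_intent("vector")
    img.header.set_xyzt_units("mm")
    nib.save(img, os.fspath(path))
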