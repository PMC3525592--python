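"""Voxel grids: the common carrier for DWI volumes, masks, labels and scalar maps.

A :class:`VolumeGrid` couples a 3D or 4D array with a voxel-to-world affine
(RAS-mm, voxel centre at integer index, 0-based).  All downstream stages —
reconstruction, tracking, parcellation, connectome building — exchange data
through this one type, so the conventions fixed here hold package-wide.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class UnsupportedShapeError(ValueError):
    """Raised for volumes that are neither 3D nor 4D."""


@dataclass
class VolumeGrid:
    """A 3D/4D voxel array with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : ndarray
        Array indexed ``(i, j, k)`` or ``(i, j, k, v)``.
    affine : (4, 4) ndarray
        Maps homogeneous voxel indices to world millimetres (RAS).
    meta : dict
        Free-form provenance (source path, stage parameters, ...).
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise UnsupportedShapeError(
                f"expected 3D or 4D data, got {self.data.ndim}D"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape3(self) -> tuple:
        return self.data.shape[:3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 and np.asarray(ijk).ndim == 1 else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world` (fractional indices)."""
        xyz = np.asarray(xyz, dtype=float)
        squeeze = xyz.ndim == 1
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if squeeze else out

    def like(self, data: np.ndarray, **meta) -> "VolumeGrid":
        """New grid sharing this affine."""
        return VolumeGrid(np.asarray(data), self.affine.copy(), {**self.meta, **meta})


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI-1 volume.

    Raises :class:`FormatError` for unreadable files and
    :class:`UnsupportedShapeError` for data with more than 4 dimensions.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except UnsupportedShapeError:
        raise
    except Exception as exc:  # garbled header, truncated file, wrong magic ...
        raise FormatError(f"cannot read NIfTI volume {path!s}: {exc}") from exc
    if data.ndim > 4:
        raise UnsupportedShapeError(f"{path!s}: {data.ndim}D data not supported")
    if data.ndim < 3:
        data = data.reshape(data.shape + (1,) * (3 - data.ndim))
    return VolumeGrid(data, np.asarray(img.affine), {"source": str(path)})


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1; inverse of :func:`read_volume`."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    os.makedirs(parent, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + ((1.0,) if vol.data.ndim == 4 else ()))
    nib.save(img, str(path))


def resample_volume(
    vol: VolumeGrid,
    target_voxel_size,
    mode: str = "trilinear",
) -> VolumeGrid:
    """Resample a volume to a new voxel size, preserving world-space extent.

    ``mode`` is ``"trilinear"`` for continuous data or ``"nearest"`` for
    labels/masks; requesting trilinear for an integer-typed volume is an
    error (labels must not be blended).  The output grid keeps the input's
    world origin and axis directions; only the voxel spacing changes.
    """
    target = np.asarray(target_voxel_size, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target_voxel_size must be 3 positive numbers")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "trilinear" and np.issubdtype(vol.data.dtype, np.integer):
        raise ValueError("trilinear interpolation requested for integer label volume; use nearest")

    old = vol.voxel_size
    shape3 = np.asarray(vol.shape3)
    # same world extent within one voxel
    new_shape = np.maximum(1, np.ceil(shape3 * old / target - 1e-9).astype(int))
    scale = target / old
    # new affine: same origin/orientation, columns rescaled to target spacing
    dirs = vol.affine[:3, :3] / old  # unit direction columns
    new_affine = np.eye(4)
    new_affine[:3, :3] = dirs * target
    # keep voxel-centre alignment: world position of new index n is
    # origin + dirs*target*n; sample old fractional index = n*scale
    new_affine[:3, 3] = vol.affine[:3, 3]

    order = 1 if mode == "trilinear" else 0
    coords3 = np.indices(tuple(new_shape), dtype=float)
    coords3 = coords3 * scale[:, None, None, None]

    if vol.data.ndim == 3:
        out = ndimage.map_coordinates(
            vol.data.astype(float) if order else vol.data,
            coords3, order=order, mode="nearest",
        )
    else:
        vols = [
            ndimage.map_coordinates(
                vol.data[..., v].astype(float) if order else vol.data[..., v],
                coords3, order=order, mode="nearest",
            )
            for v in range(vol.data.shape[3])
        ]
        out = np.stack(vols, axis=-1)
    if mode == "nearest":
        out = out.astype(vol.data.dtype)
    return VolumeGrid(out, new_affine, {**vol.meta, "resampled_from": tuple(old)})
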