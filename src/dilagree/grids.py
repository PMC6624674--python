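"""Axis-aligned anisotropic 3D image grids, NIfTI I/O and rigid resampling.

All geometry is expressed in a simple physical convention: voxel indices are
0-based, the physical coordinate of index ``(i, j, k)`` is the *center* of
that voxel, and all physical quantities are millimetres.  Only axis-aligned
grids are supported; volumes whose NIfTI affine carries rotation or shear are
rejected rather than silently reinterpreted, because the downstream agreement
metrics assume co-registered axis-aligned grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGeometry",
    "ScalarVolume",
    "BinaryMask",
    "RigidTransform",
    "GridError",
    "FormatError",
    "OrientationError",
    "read_nifti",
    "write_nifti",
    "resample_to_reference",
    "resample_mask",
]

Modality = Literal["T2W", "ADC", "KTRANS", "OTHER"]

#: Tolerance on off-diagonal affine entries beyond which an orientation is
#: considered non-axis-aligned.
AXIS_ALIGN_TOL = 1e-6


class GridError(ValueError):
    """Geometry mismatch or invalid grid parameters."""


class FormatError(ValueError):
    """File content does not match the expected 3D scalar NIfTI layout."""


class OrientationError(ValueError):
    """NIfTI affine is not axis-aligned with positive spacing."""


@dataclass(frozen=True)
class ImageGeometry:
    """Descriptor of an axis-aligned 3D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel edge lengths in mm along (x, y, z); strictly positive.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise GridError("shape, spacing and origin must be length-3")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(n < 1 for n in self.shape):
            raise GridError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"all spacings must be > 0 mm, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 NIfTI-style affine for this grid (diagonal spacing, translation)."""
        aff = np.diag([*self.spacing, 1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_center_grid(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape ``(*shape, 3)``."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d]
            for d in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclass
class ScalarVolume:
    """A single MR sequence's voxel values on an :class:`ImageGeometry`."""

    geometry: ImageGeometry
    values: np.ndarray
    modality: Modality = "OTHER"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise GridError(
                f"values shape {self.values.shape} != geometry shape "
                f"{self.geometry.shape}"
            )
        if self.modality in ("ADC", "KTRANS") and np.any(self.values < 0):
            raise GridError(f"{self.modality} values must be non-negative")


@dataclass
class BinaryMask:
    """A rasterized lesion contour on an :class:`ImageGeometry`."""

    geometry: ImageGeometry
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.shape != self.geometry.shape:
            raise GridError(
                f"mask shape {self.voxels.shape} != geometry shape "
                f"{self.geometry.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def volume_ml(self) -> float:
        """True-voxel volume in millilitres (1 mL = 1000 mm^3)."""
        return self.n_voxels * self.geometry.voxel_volume_mm3 / 1000.0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map from reference physical space into moving physical space.

    ``p_moving = R(rotation) @ p_reference + translation`` with R built from
    extrinsic x-y-z Euler angles in radians.  The all-zero transform is the
    identity.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return mz @ my @ mx

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix().T + np.asarray(self.translation)


IDENTITY = RigidTransform()


def _geometry_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> ImageGeometry:
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > AXIS_ALIGN_TOL:
        raise OrientationError(
            "only axis-aligned NIfTI affines are supported; "
            f"off-diagonal magnitude {np.max(np.abs(off_diag)):.3g}"
        )
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise OrientationError(
            f"axis flips are not supported (affine diagonal {diag})"
        )
    return ImageGeometry(
        shape=tuple(shape), spacing=tuple(diag), origin=tuple(affine[:3, 3])
    )


def read_nifti(
    path: str | Path, kind: Literal["auto", "volume", "mask"] = "auto"
) -> ScalarVolume | BinaryMask:
    """Read a 3D NIfTI file as a :class:`ScalarVolume` or :class:`BinaryMask`.

    With ``kind='auto'`` the image is returned as a mask when its values are
    restricted to {0, 1}, otherwise as a scalar volume.  Geometry is taken
    from the affine: spacing from the diagonal, origin from the translation.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got {data.ndim}D at {path}")
    geom = _geometry_from_affine(np.asarray(img.affine, dtype=float), data.shape)
    data = np.asarray(data, dtype=float)
    binary = bool(np.isin(data, (0.0, 1.0)).all())
    if kind == "mask" or (kind == "auto" and binary):
        if not binary:
            raise FormatError(f"requested a mask but values are not 0/1 at {path}")
        return BinaryMask(geometry=geom, voxels=data > 0.5, label=Path(path).stem)
    return ScalarVolume(geometry=geom, values=data)


def write_nifti(obj: ScalarVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume (float32) or mask (uint8) to a 3D NIfTI file."""
    if isinstance(obj, BinaryMask):
        data = obj.voxels.astype(np.uint8)
    else:
        data = obj.values.astype(np.float32)
    img = nib.Nifti1Image(data, obj.geometry.affine())
    img.header.set_zooms(obj.geometry.spacing)
    nib.save(img, str(path))


def resample_to_reference(
    moving: ScalarVolume,
    reference: ImageGeometry,
    transform: RigidTransform = IDENTITY,
    interpolation: Literal["linear", "nearest"] = "linear",
    fill_value: float = 0.0,
) -> ScalarVolume:
    """Resample ``moving`` onto ``reference``, applying a rigid transform.

    Each reference voxel center is mapped into the moving volume's physical
    space with ``transform`` and the moving values are interpolated there.
    Points falling outside the moving volume's support receive ``fill_value``.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    pts = reference.voxel_center_grid().reshape(-1, 3)
    moving_idx = moving.geometry.physical_to_index(transform.apply(pts))
    # snap round-off-level deviations so grid-coincident samples are exact
    snapped = np.round(moving_idx)
    near = np.abs(moving_idx - snapped) < 1e-9
    moving_idx = np.where(near, snapped, moving_idx)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        moving.values,
        moving_idx.T,
        order=order,
        mode="constant",
        cval=fill_value,
    ).reshape(reference.shape)
    return ScalarVolume(
        geometry=reference, values=out, modality=moving.modality, units=moving.units
    )


def resample_mask(
    moving: BinaryMask,
    reference: ImageGeometry,
    transform: RigidTransform = IDENTITY,
) -> BinaryMask:
    """Resample a mask: linear interpolation of the 0/1 field, threshold 0.5."""
    as_vol = ScalarVolume(geometry=moving.geometry, values=moving.voxels.astype(float))
    interp = resample_to_reference(
        as_vol, reference, transform, interpolation="linear", fill_value=0.0
    )
    return BinaryMask(
        geometry=reference, voxels=interp.values >= 0.5, label=moving.label
    )
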