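"""Volumetric image I/O and resampling.

All volumes are held in a single in-memory convention: 0-based voxel indices
with axis order (x, y, z), reoriented to canonical anatomical (RAS) axes at
load time so that downstream adjacency and cropping logic never depends on
the on-disk orientation.  Two carrier types are distinguished: ``Volume3D``
for scalar fields (CT intensities in HU, probabilities in [0, 1]) and
``LabelVolume`` for integer label maps (lung mask, lobe segmentation,
integrity mask).

Supported formats: NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) for read and
write, MetaImage (``.mha``/``.mhd``, via SimpleITK) for read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3D volume."""


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


#: spacing/origin agreement tolerance (mm) for volumes required to share a grid
GRID_TOL_MM = 1e-3


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar field with grid metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values (HU for CT, [0, 1] for probability maps).
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm; strictly positive.
    origin : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in mm.
    direction : ndarray, shape (3, 3)
        Axis-direction matrix (identity after canonical reorientation).
    """

    data: np.ndarray
    spacing: np.ndarray = dataclasses.field(
        default_factory=lambda: np.ones(3))
    origin: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3))
    direction: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"volume must be 3D, got {self.data.ndim} dimensions")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on the same grid with replaced voxel values."""
        return dataclasses.replace(self, data=data)

    def same_grid(self, other: "Volume3D", tol: float = GRID_TOL_MM) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )


@dataclasses.dataclass
class LabelVolume(Volume3D):
    """Integer label map on a grid, values from a finite label set."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError(
                f"label volume requires integer dtype, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("label values must be non-negative")

    @property
    def labels(self) -> set[int]:
        return set(np.unique(self.data).tolist())


def require_same_grid(*volumes: Volume3D) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid(v):
            raise GridMismatchError(
                "volumes do not share a grid: "
                f"shape {ref.shape} vs {v.shape}, "
                f"spacing {ref.spacing} vs {v.spacing}, "
                f"origin {ref.origin} vs {v.origin}")


def _from_nifti(img: nib.Nifti1Image, path: str) -> Volume3D:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {data.shape}")
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    direction = affine[:3, :3] / spacing
    origin = affine[:3, 3]
    cls = LabelVolume if np.issubdtype(data.dtype, np.integer) else Volume3D
    return cls(data=data, spacing=spacing, origin=origin, direction=direction)


def _from_sitk(path: str) -> Volume3D:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise FormatError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)          # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    cls = LabelVolume if np.issubdtype(data.dtype, np.integer) else Volume3D
    return cls(data=data, spacing=spacing, origin=origin, direction=direction)


def read_volume(path: str | Path) -> Volume3D:
    """Read a volume, returning ``LabelVolume`` for integer-typed files.

    Raises
    ------
    FormatError
        If the file is missing, not a recognized format, or not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            return _from_nifti(nib.load(str(path)), str(path))
        if name.endswith((".mha", ".mhd")):
            return _from_sitk(str(path))
    except FormatError:
        raise
    except Exception as exc:  # corrupted file, header errors
        raise FormatError(f"unreadable volume {path}: {exc}") from exc
    raise FormatError(f"unsupported format: {path}")


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write as NIfTI-1. Labels stored as uint8, scalars as float32."""
    path = Path(path)
    if not path.name.lower().endswith((".nii", ".nii.gz")):
        raise FormatError(f"write supports NIfTI only, got {path}")
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    affine = np.eye(4)
    affine[:3, :3] = vol.direction * vol.spacing
    affine[:3, 3] = vol.origin
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def resample_isotropic(vol: Volume3D, target_spacing: float,
                       mode: str = "linear") -> Volume3D:
    """Resample to isotropic spacing, preserving physical extent.

    ``mode='nearest'`` is required for label volumes (linear interpolation
    would invent labels); it never introduces values absent from the input.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(vol, LabelVolume) and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")

    zoom = vol.spacing / target_spacing
    if np.allclose(zoom, 1.0, atol=1e-9):
        out = vol.data.copy()
    else:
        order = 0 if mode == "nearest" else 1
        out = ndimage.zoom(vol.data, zoom, order=order,
                           mode="nearest", grid_mode=True)
    new = dataclasses.replace(
        vol, data=out, spacing=np.full(3, float(target_spacing)))
    return new
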