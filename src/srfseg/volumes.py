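"""Canonical in-memory volume model, NIfTI I/O and grid resampling.

All volumes in this package live on a fixed anatomical convention: axis 0
increases toward the patient's anatomical *left*, so "left kidney" (label 1)
always sits at larger axis-0 indices than the right kidney (label 2).
Files are read with :func:`read_volume`, which reorients arbitrary NIfTI
orientations into this convention, and written with :func:`write_volume`,
which inverts it, so ``read(write(v)) == v``.

Voxel ``(i, j, k)`` has physical center ``origin + (i*sx, j*sy, k*sz)`` mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ContractError, DataError, FormatError

__all__ = [
    "Modality",
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "resample_to_grid",
]


class Modality(str, enum.Enum):
    """Scalar meaning of an image volume: CT in Hounsfield units or PET in SUV."""

    CT_HU = "CT_HU"
    PET_SUV = "PET_SUV"


def _check_geometry(data: np.ndarray, spacing, kind: str) -> None:
    if data.ndim != 3:
        raise FormatError(f"{kind} volume must be 3D, got {data.ndim}D shape {data.shape}")
    if min(data.shape) < 1:
        raise FormatError(f"{kind} volume has an empty axis: shape {data.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise DataError(f"spacing must be three positive numbers, got {spacing!r}")


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing, origin and modality tag.

    PET volumes carry SUV (nonnegative by definition; negatives are clamped
    at load), CT volumes carry Hounsfield units.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = Modality.CT_HU

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.modality = Modality(self.modality)
        _check_geometry(self.data, self.spacing, "image")
        if not np.all(np.isfinite(self.data)):
            raise DataError("image volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelVolume:
    """A 3D integer grid: 0 background, 1 left kidney, 2 right kidney."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    BACKGROUND = 0
    LEFT = 1
    RIGHT = 2

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype.kind == "f":
            if not np.all(np.isfinite(data)):
                raise DataError("label volume contains non-finite voxels")
            if not np.all(data == np.round(data)):
                raise DataError("label volume contains non-integer voxels")
        self.data = data.astype(np.uint8, casting="unsafe")
        if not np.isin(self.data, (0, 1, 2)).all():
            bad = sorted(set(np.unique(self.data)) - {0, 1, 2})
            raise DataError(f"label volume contains values outside {{0,1,2}}: {bad}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_geometry(self.data, self.spacing, "label")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "ImageVolume | LabelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one label class."""
        return self.data == label


def read_volume(path, modality: Modality | str | None = None):
    """Read a 3D NIfTI file into the canonical axis convention.

    Parameters
    ----------
    path : str or Path
        A ``.nii`` / ``.nii.gz`` file.
    modality : Modality or None
        ``CT_HU`` or ``PET_SUV`` for scalar images; ``None`` to load a label
        volume (values restricted to {0, 1, 2}).

    Returns
    -------
    ImageVolume or LabelVolume

    Notes
    -----
    The file is first reoriented to RAS with nibabel, then axis 0 is flipped
    so that it increases toward the patient's left. PET negatives (possible
    reconstruction artifacts) are clamped to 0.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)[::-1].copy()
    if not np.all(np.isfinite(data)):
        raise DataError(f"{path}: volume contains non-finite voxels")
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    origin = tuple(float(t) for t in img.affine[:3, 3])
    if modality is None:
        return LabelVolume(data, spacing, origin)
    modality = Modality(modality)
    if modality is Modality.PET_SUV:
        np.clip(data, 0.0, None, out=data)
    return ImageVolume(data, spacing, origin, modality)


def write_volume(vol: ImageVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI; labels are stored as unsigned 8-bit integers."""
    sx, sy, sz = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0]).astype(np.float64)
    affine[:3, 3] = vol.origin
    # invert the canonical axis-0 flip so the file is plain RAS
    data = np.asarray(vol.data)[::-1].copy()
    if isinstance(vol, LabelVolume):
        img = nib.Nifti1Image(data.astype(np.uint8), affine)
    else:
        img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((sx, sy, sz))
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed to write NIfTI to {path}: {exc}") from exc


def _resample_data(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    target: tuple[float, float, float],
    order: int,
) -> np.ndarray:
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(data.shape, spacing, target)
    )
    if new_shape == data.shape and np.allclose(spacing, target):
        return np.array(data)
    # new voxel center j sits at physical j*target, i.e. old index j*target/spacing;
    # mode="nearest" extends by the edge value so single-voxel axes never fail
    grids = [
        np.arange(n_new, dtype=np.float64) * (t / s)
        for n_new, t, s in zip(new_shape, target, spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return out


def resample_to_grid(vol, target_spacing):
    """Resample a volume onto a new voxel spacing over the same physical extent.

    Image volumes are interpolated trilinearly, label volumes by nearest
    neighbor (the only label-safe choice). The first voxel centers of input
    and output coincide, so resampling at the input spacing is the identity.
    """
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ContractError(f"target spacing must be three positive numbers, got {target_spacing!r}")
    if isinstance(vol, LabelVolume):
        out = _resample_data(vol.data, vol.spacing, target, order=0)
        return LabelVolume(out, target, vol.origin)
    out = _resample_data(vol.data, vol.spacing, target, order=1)
    return ImageVolume(out, target, vol.origin, vol.modality)


def mirror_left_right(vol):
    """Flip a volume across the mid-sagittal plane and swap kidney labels.

    For an :class:`ImageVolume` this reverses axis 0; for a
    :class:`LabelVolume` it additionally exchanges labels 1 and 2, so the
    anatomical meaning ("left kidney" = label 1) is preserved.
    """
    if isinstance(vol, LabelVolume):
        data = vol.data[::-1].copy()
        swapped = data.copy()
        swapped[data == 1] = 2
        swapped[data == 2] = 1
        return LabelVolume(swapped, vol.spacing, vol.origin)
    return replace(vol, data=vol.data[::-1].copy())
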