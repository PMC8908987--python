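"""Volumes, masks and multi-planar views.

A CT scan is held as a :class:`VoxelVolume`: a 3D grid of Hounsfield-unit (HU)
values indexed ``(x, y, z)`` with per-axis spacing in millimetres and a physical
origin.  Volumes are assumed axis-aligned; physical coordinate of voxel
``(i, j, k)`` is ``origin + index * spacing``.  Nodule segmentations are binary
:class:`NoduleMask` arrays on the same grid.

The multi-view descriptors share a single plane family: a pencil of planes that
all contain the scanner z-axis direction and the nodule centroid, rotated about
z by ``k * 180 / n_views`` degrees (antipodal planes coincide, hence 180 rather
than 360).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "NoduleMask",
    "ViewSlice",
    "FormatError",
    "MetadataError",
    "read_volume",
    "write_volume",
    "extract_voi",
    "resample_isotropic",
    "extract_views",
    "save_slice_png",
]

AIR_HU = -1000.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the requested image format."""


class MetadataError(ValueError):
    """Raised when required geometry metadata (spacing) is absent or invalid."""


@dataclass
class VoxelVolume:
    """3D scalar grid of HU values with voxel spacing (mm) and physical origin.

    ``data`` is indexed ``(x, y, z)``; ``spacing`` is ``(sx, sy, sz)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> np.ndarray:
        """Per-axis physical size in mm (cell-centred convention)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_physical(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def physical_to_index(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class NoduleMask:
    """Binary segmentation aligned to a :class:`VoxelVolume` grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not self.data.any():
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def centroid(self) -> np.ndarray:
        """Centre of mass in voxel coordinates."""
        return np.asarray(ndimage.center_of_mass(self.data))

    def centroid_physical(self) -> np.ndarray:
        return np.asarray(self.origin) + self.centroid * np.asarray(self.spacing)


@dataclass
class ViewSlice:
    """A 2D cross-section through the nodule on one plane of the view pencil.

    ``pixels`` is sampled on an orthogonal in-plane grid: axis 0 runs along the
    in-plane direction ``(cos a, sin a, 0)``, axis 1 along the z-axis.
    """

    pixels: np.ndarray
    plane_normal: np.ndarray
    in_plane_spacing: float
    view_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.plane_normal = np.asarray(self.plane_normal, dtype=np.float64)
        n = np.linalg.norm(self.plane_normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("plane_normal must be a unit vector")


def _read_sitk(path: str, fmt: str | None):
    import SimpleITK as sitk

    if fmt == "dicom_dir" or (fmt is None and os.path.isdir(path)):
        if not os.path.isdir(path):
            raise FormatError(f"not a DICOM directory: {path}")
        reader = sitk.ImageSeriesReader()
        series = reader.GetGDCMSeriesFileNames(path)
        if not series:
            raise FormatError(f"no DICOM series found in {path}")
        reader.SetFileNames(series)
        return reader.Execute()
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        return sitk.ReadImage(path)
    except Exception as exc:  # sitk raises bare RuntimeError
        raise FormatError(f"could not read {path}: {exc}") from exc


def read_volume(path: str, format: str | None = None) -> VoxelVolume:
    """Read a CT volume from a DICOM series directory, NIfTI or MetaImage file.

    Parameters
    ----------
    path : str
        File (``.nii``, ``.nii.gz``, ``.mhd``, ``.mha``) or DICOM directory.
    format : {"dicom_dir", "nifti", "metaimage"}, optional
        Forced format; auto-detected from the path when omitted.

    Spacing and origin are taken from the file metadata.  The returned array is
    re-ordered to ``(x, y, z)`` indexing.
    """
    img = _read_sitk(str(path), format)
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"non-positive spacing in {path}: {spacing}")
    arr = np.asarray(__import__("SimpleITK").GetArrayFromImage(img))  # (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0))).astype(np.float64)
    return VoxelVolume(data=data, spacing=tuple(spacing), origin=tuple(img.GetOrigin()))


def read_mask(path: str, format: str | None = None) -> NoduleMask:
    """Read a 0/1 segmentation mask stored in any supported volume format."""
    vol = read_volume(path, format)
    return NoduleMask(data=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def write_volume(volume: VoxelVolume | NoduleMask, path: str) -> None:
    """Write a volume or mask to NIfTI/MetaImage (format from the extension)."""
    import SimpleITK as sitk

    data = volume.data.astype(np.float64 if isinstance(volume, VoxelVolume) else np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def extract_voi(
    volume: VoxelVolume,
    center_mm,
    side_mm: float = 40.0,
    fill: float = AIR_HU,
) -> VoxelVolume:
    """Extract the cubic volume of interest of physical side ``side_mm``.

    The VOI is centred at ``center_mm`` (physical coordinates); regions falling
    outside the parent volume are padded with ``fill`` (default -1000 HU, air).
    """
    if side_mm <= 0:
        raise ValueError(f"side_mm must be positive, got {side_mm}")
    spacing = np.asarray(volume.spacing)
    n = np.maximum(np.rint(side_mm / spacing).astype(int), 1)
    center_idx = volume.physical_to_index(center_mm)
    start = np.rint(center_idx - (n - 1) / 2.0).astype(int)
    out = np.full(tuple(n), float(fill))
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + n, volume.shape)
    if np.all(src_hi > src_lo):
        dst_lo = src_lo - start
        dst_hi = dst_lo + (src_hi - src_lo)
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = volume.data[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    origin = volume.index_to_physical(start)
    return VoxelVolume(data=out, spacing=volume.spacing, origin=tuple(origin))


def resample_isotropic(volume: VoxelVolume, target_mm: float = 1.0) -> VoxelVolume:
    """Resample to isotropic voxels by trilinear interpolation.

    The output shape is ``round(extent / target_mm)`` per axis so the physical
    extent is preserved to within one voxel per axis.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if np.allclose(volume.spacing, target_mm):
        return VoxelVolume(volume.data.copy(), (target_mm,) * 3, volume.origin)
    extent = volume.physical_extent()
    new_shape = np.maximum(np.rint(extent / target_mm).astype(int), 1)
    zoom = new_shape / np.asarray(volume.shape)
    data = ndimage.zoom(volume.data, zoom, order=1, mode="nearest", grid_mode=True)
    return VoxelVolume(data=data, spacing=(target_mm,) * 3, origin=volume.origin)


def view_angles(n_views: int) -> np.ndarray:
    """Plane rotation angles ``k * pi / n_views`` (radians), k = 0..n_views-1."""
    if n_views < 1:
        raise ValueError(f"n_views must be >= 1, got {n_views}")
    return np.arange(n_views) * np.pi / n_views


def extract_views(
    volume_or_mask: VoxelVolume | NoduleMask,
    n_views: int,
    center=None,
    in_plane_spacing: float | None = None,
    width: int | None = None,
    height: int | None = None,
) -> list[ViewSlice]:
    """Sample the pencil of ``n_views`` planes through ``center``.

    Every plane contains the z-axis direction; plane ``k`` is rotated about z by
    ``k * 180 / n_views`` degrees.  Slices are sampled by bilinear interpolation
    at ``in_plane_spacing`` mm per pixel (default: the smallest voxel spacing).
    ``center`` is in voxel coordinates (default: the mask centroid for masks,
    the grid centre for volumes).

    Masks are interpolated as floats in [0, 1]; threshold at 0.5 to recover a
    binary cross-section.
    """
    obj = volume_or_mask
    angles = view_angles(n_views)
    spacing = np.asarray(obj.spacing)
    if center is None:
        center = obj.centroid if isinstance(obj, NoduleMask) else (np.asarray(obj.shape) - 1) / 2.0
    center = np.asarray(center, dtype=float)
    s = float(in_plane_spacing) if in_plane_spacing else float(spacing.min())
    if width is None:
        diag = np.hypot(obj.shape[0] * spacing[0], obj.shape[1] * spacing[1])
        width = int(np.ceil(diag / s)) + 1
    if height is None:
        height = int(np.ceil(obj.shape[2] * spacing[2] / s)) + 1
    data = obj.data.astype(np.float64)
    is_mask = isinstance(obj, NoduleMask)
    cval = 0.0 if is_mask else AIR_HU
    u_off = (np.arange(width) - (width - 1) / 2.0) * s
    v_off = (np.arange(height) - (height - 1) / 2.0) * s
    views = []
    for k, a in enumerate(angles):
        u_dir = np.array([np.cos(a), np.sin(a), 0.0])
        # physical offsets from the centre, converted to voxel coordinates
        px = center[0] + np.add.outer(u_off * u_dir[0], np.zeros(height)) / spacing[0]
        py = center[1] + np.add.outer(u_off * u_dir[1], np.zeros(height)) / spacing[1]
        pz = center[2] + np.add.outer(np.zeros(width), v_off) / spacing[2]
        pixels = ndimage.map_coordinates(
            data, np.stack([px, py, pz]), order=1, mode="constant", cval=cval
        )
        if is_mask:
            np.clip(pixels, 0.0, 1.0, out=pixels)
        normal = np.array([-np.sin(a), np.cos(a), 0.0])
        views.append(ViewSlice(pixels=pixels, plane_normal=normal, in_plane_spacing=s, view_index=k))
    return views


def save_slice_png(view: ViewSlice, path: str, window: tuple | None = None) -> None:
    """Export a view slice as an 8-bit PNG for visual inspection.

    ``window`` is an (lo, hi) intensity window; defaults to the slice range.
    """
    from PIL import Image

    px = view.pixels
    lo, hi = window if window is not None else (float(px.min()), float(px.max()))
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((px - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(scaled.T[::-1]).save(path)
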