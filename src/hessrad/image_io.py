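"""Volume/mask I/O, isotropic resampling and the CT gray-level look-up table.

Volumes are plain scalar 3D arrays with voxel spacing (mm) and a world-space
origin; masks are binary arrays on the same grid.  Voxel indices are 0-based
and world coordinates are ``origin + index * spacing``.  Masks are consumed
already voxelized and co-registered with their companion volume — no
registration is attempted here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
import pydicom
from scipy import ndimage

__all__ = [
    "Volume3D",
    "RoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "quantize_gray_levels",
    "DEFAULT_ISOVOXEL_MM",
    "HU_LUT_LO",
    "HU_LUT_HI",
    "HU_LUT_LEVELS",
]

#: Isotropic voxel edge used for resampling, in mm.
DEFAULT_ISOVOXEL_MM = 0.98
#: CT look-up table limits (Hounsfield units) and number of gray levels.
HU_LUT_LO = -1000.0
HU_LUT_HI = 1500.0
HU_LUT_LEVELS = 256


class VolumeReadError(RuntimeError):
    """A file could not be read or its metadata is inconsistent."""


class DegenerateRoiError(ValueError):
    """An ROI mask is empty where a non-empty region is required."""


@dataclass
class Volume3D:
    """A scalar 3D image (HU, Hessian index, or unitless) on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a 3D array with each axis >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        sx, sy, sz = self.spacing
        return np.isclose(sx, sy) and np.isclose(sy, sz)

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on the same grid carrying different voxel values."""
        return Volume3D(np.asarray(data), self.spacing, self.origin)


@dataclass
class RoiMask:
    """Binary region-of-interest (GTV) mask aligned to a :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, vol: Volume3D) -> None:
        if self.data.shape != vol.data.shape:
            raise ValueError(f"mask shape {self.data.shape} != volume shape {vol.data.shape}")
        if not np.allclose(self.spacing, vol.spacing):
            raise ValueError(f"mask spacing {self.spacing} != volume spacing {vol.spacing}")


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _affine_from_grid(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike, format: str = "nifti") -> Volume3D:
    """Read a 3D volume from a NIfTI file or a DICOM series directory.

    For DICOM series the HU rescale (slope/intercept) is applied, slices are
    sorted along the normal, and an inconsistent inter-slice spacing (relative
    spread > 1e-3) raises :class:`VolumeReadError`.
    """
    if format == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error plumbing
            raise VolumeReadError(f"cannot read NIfTI {path!s}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeReadError(f"{path!s}: expected 3D volume, got ndim={data.ndim}")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return Volume3D(np.asarray(data), tuple(float(z) for z in zooms), origin)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_series(directory: str | os.PathLike) -> Volume3D:
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    if not files:
        raise VolumeReadError(f"no DICOM files in {directory!s}")
    slices = [pydicom.dcmread(f) for f in files]
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        z_pos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    except AttributeError as exc:
        raise VolumeReadError(f"missing ImagePositionPatient in series: {exc}") from exc
    ref = slices[0]
    px, py = (float(v) for v in ref.PixelSpacing)
    for ds in slices[1:]:
        if not np.allclose([float(v) for v in ds.PixelSpacing], [px, py]):
            raise VolumeReadError("inconsistent in-plane pixel spacing across slices")
    if len(slices) > 1:
        dz_all = np.diff(z_pos)
        dz = float(np.mean(dz_all))
        if dz <= 0 or np.ptp(dz_all) > 1e-3 * abs(dz):
            raise VolumeReadError("inconsistent slice spacing beyond tolerance")
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM rows/cols are (y, x); transpose to (x, y) then stack z last.
    data = np.stack([p.T for p in planes], axis=-1)
    origin = (
        float(ref.ImagePositionPatient[0]),
        float(ref.ImagePositionPatient[1]),
        float(z_pos[0]),
    )
    return Volume3D(data, (px, py, dz), origin)


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI, preserving data, spacing and origin."""
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_from_grid(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> RoiMask:
    vol = read_volume(path, format="nifti")
    return RoiMask(vol.data > 0.5, vol.spacing, vol.origin)


def write_mask(mask: RoiMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_from_grid(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Isotropic resampling
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: Volume3D,
    mask: RoiMask | None = None,
    isovoxel: float = DEFAULT_ISOVOXEL_MM,
) -> Volume3D | tuple[Volume3D, RoiMask]:
    """Resample volume (cubic) and mask (shape-based) to an isotropic grid.

    The intensity volume is interpolated with cubic splines.  The mask goes
    through shape-based interpolation: its signed Euclidean distance transform
    (positive inside, in mm) is interpolated linearly and re-thresholded at
    zero, which keeps the result strictly binary with smooth boundaries.

    Returns the resampled volume, or ``(volume, mask)`` when a mask is given.
    Raises :class:`DegenerateRoiError` if a non-empty mask becomes empty.
    """
    if isovoxel <= 0:
        raise ValueError("isovoxel must be positive")
    zoom = tuple(s / isovoxel for s in vol.spacing)
    if np.allclose(zoom, 1.0):
        out_vol = Volume3D(vol.data.astype(np.float64, copy=True),
                           (isovoxel,) * 3, vol.origin)
        if mask is None:
            return out_vol
        mask.check_aligned(vol)
        return out_vol, RoiMask(mask.data.copy(), (isovoxel,) * 3, mask.origin)

    data = ndimage.zoom(vol.data.astype(np.float64), zoom, order=3, mode="nearest")
    out_vol = Volume3D(data, (isovoxel,) * 3, vol.origin)
    if mask is None:
        return out_vol

    mask.check_aligned(vol)
    sd = _signed_distance_mm(mask.data, vol.spacing)
    sd_iso = ndimage.zoom(sd, zoom, order=1, mode="nearest")
    # zoom may differ by one voxel from the intensity grid on awkward ratios;
    # crop/pad to keep volume and mask co-registered.
    sd_iso = _match_shape(sd_iso, data.shape)
    new_mask = sd_iso > 0
    if mask.n_foreground > 0 and not new_mask.any():
        raise DegenerateRoiError("mask became empty after resampling")
    return out_vol, RoiMask(new_mask, (isovoxel,) * 3, mask.origin)


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed EDT in mm: > 0 inside the mask, < 0 outside."""
    if mask.all():
        return np.ones(mask.shape)
    if not mask.any():
        return -np.ones(mask.shape)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _match_shape(arr: np.ndarray, shape) -> np.ndarray:
    slices = tuple(slice(0, min(a, s)) for a, s in zip(arr.shape, shape))
    out = np.full(shape, arr.min())
    out[slices] = arr[slices]
    return out


# ---------------------------------------------------------------------------
# Gray-level look-up table
# ---------------------------------------------------------------------------

def quantize_gray_levels(
    vol: Volume3D,
    lo: float = HU_LUT_LO,
    hi: float = HU_LUT_HI,
    levels: int = HU_LUT_LEVELS,
) -> Volume3D:
    """Map voxel values to integer gray levels 0..levels-1 by a linear LUT.

    ``level = round((v - lo) / (hi - lo) * (levels - 1))`` with values outside
    [lo, hi] clamped to the end levels.  Rounding is half-away-from-zero
    (the scaled argument is non-negative, so this is ``floor(x + 0.5)``).
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    x = (np.asarray(vol.data, dtype=np.float64) - lo) / (hi - lo) * (levels - 1)
    q = np.floor(x + 0.5)
    q = np.clip(q, 0, levels - 1).astype(np.int64)
    return Volume3D(q, vol.spacing, vol.origin)
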