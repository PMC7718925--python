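"""Hessian index images: multi-scale second-derivative filtering and eigen-counts.

The Hessian index of a voxel is the number of negative eigenvalues of the
3x3 Hessian matrix of the (Gaussian-smoothed) intensity field at that voxel:
3 marks a locally convex (bright) point, 0 a concave (dark) point, and 1 or 2
saddle points.  By Sylvester's law of inertia the count is invariant under
orthogonal changes of coordinates, so the index is a rotation-invariant local
descriptor of intensity topology.

One CT volume yields six index images: three Gaussian scales (sigma = 0.5,
1.0, 1.5 mm with derivative kernels of 3, 5, 7 voxels per axis) times two
box-averaging kernels (3^3 and 5^3) that raise the quantization of the index
from 2 bits (values 0..3) to 8 bits (0..255).

Derivative kernels are sampled from the analytic partial derivatives of the
3D Gaussian at voxel centers and then moment-normalized so that filtering a
quadratic polynomial is exact despite the tight truncation: the smoothing
taps sum to 1, first-derivative taps satisfy sum(t*w) = 1 (correlation
convention), and second-derivative taps satisfy sum(w) = 0, sum(t^2*w) = 2.
Without this correction the truncated taps leak a multiple of the local
intensity into the second derivative and can flip eigenvalue signs on smooth
quadratic patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import Volume3D

__all__ = [
    "GaussianScale",
    "HessianField",
    "IndexImage",
    "DEFAULT_SCALES",
    "DEFAULT_AVG_KERNELS",
    "gaussian_derivative_kernel",
    "second_derivative_filter_bank",
    "eigenvalues_symmetric3",
    "index_image",
    "smooth_and_requantize",
    "generate_index_images",
]


@dataclass(frozen=True)
class GaussianScale:
    """Gaussian scale: standard deviation in mm and odd kernel size in voxels."""

    sigma: float
    kernel_size: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")


#: The three filter-bank scales paired with their kernel sizes.
DEFAULT_SCALES = (
    GaussianScale(0.5, 3),
    GaussianScale(1.0, 5),
    GaussianScale(1.5, 7),
)
#: Box-averaging kernel edge lengths applied to the raw index images.
DEFAULT_AVG_KERNELS = (3, 5)

#: Hessian entry labels in storage order (diagonal first, then upper triangle).
HESSIAN_ENTRIES = ("xx", "yy", "zz", "xy", "xz", "yz")
_ENTRY_ORDERS = {
    "xx": (2, 0, 0),
    "yy": (0, 2, 0),
    "zz": (0, 0, 2),
    "xy": (1, 1, 0),
    "xz": (1, 0, 1),
    "yz": (0, 1, 1),
}


@dataclass
class HessianField:
    """The six independent entries of the symmetric Hessian at every voxel."""

    entries: dict[str, np.ndarray]
    scale: GaussianScale
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.entries.values()}
        if set(self.entries) != set(HESSIAN_ENTRIES) or len(shapes) != 1:
            raise ValueError("HessianField needs the six entries on one grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.entries["xx"].shape

    def matrices(self) -> np.ndarray:
        """All Hessians as an (..., 3, 3) array."""
        e = self.entries
        h = np.empty(self.shape + (3, 3))
        h[..., 0, 0] = e["xx"]
        h[..., 1, 1] = e["yy"]
        h[..., 2, 2] = e["zz"]
        h[..., 0, 1] = h[..., 1, 0] = e["xy"]
        h[..., 0, 2] = h[..., 2, 0] = e["xz"]
        h[..., 1, 2] = h[..., 2, 1] = e["yz"]
        return h


@dataclass
class IndexImage:
    """A volume of Hessian indices at one scale.

    Raw stage: integer values in {0, 1, 2, 3} (``avg_kernel is None``).
    Smoothed stage: 8-bit values in [0, 255] after box averaging and
    requantization (``avg_kernel`` in {3, 5}).
    """

    data: np.ndarray
    scale: GaussianScale
    avg_kernel: int | None
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def stage(self) -> str:
        return "raw" if self.avg_kernel is None else "smoothed"

    def as_volume(self) -> Volume3D:
        return Volume3D(self.data, self.spacing, self.origin)

    @property
    def tag(self) -> str:
        """Stable identifier, e.g. ``s1.0_k3``."""
        k = "raw" if self.avg_kernel is None else str(self.avg_kernel)
        return f"s{self.scale.sigma:g}_k{k}"


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def gaussian_derivative_kernel(
    sigma_vox: float, kernel_size: int, order: int, spacing_mm: float = 1.0
) -> np.ndarray:
    """1D sampled Gaussian-derivative taps with discrete moment normalization.

    Taps are indexed t = -r..r (correlation convention: the filter output at x
    is ``sum_t w[t] f(x + t)``) and calibrated so polynomial inputs up to the
    derivative order are filtered exactly; derivatives are per mm.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    r = (kernel_size - 1) // 2
    t = np.arange(-r, r + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (t / sigma_vox) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        w = (t / sigma_vox**2) * phi          # -G' flipped into correlation form
        m1 = np.sum(t * w)
        return w / (m1 * spacing_mm)
    w = ((t**2 - sigma_vox**2) / sigma_vox**4) * phi
    w -= w.mean()                             # zero response to constants
    m2 = np.sum(t**2 * w)
    return w * (2.0 / (m2 * spacing_mm**2))


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

def _require_isotropic(vol: Volume3D) -> float:
    if not vol.is_isotropic:
        raise ValueError(
            f"volume must be isotropic (spacing {vol.spacing}); resample first"
        )
    return float(vol.spacing[0])


def second_derivative_filter_bank(vol: Volume3D, scale: GaussianScale) -> HessianField:
    """Convolve the volume with the six second-partial-derivative Gaussian kernels.

    Each Hessian entry is the separable correlation of the image with
    per-axis kernels whose derivative orders sum to two; borders use
    replicate (nearest) padding.  Output units are per mm^2.
    """
    h = _require_isotropic(vol)
    sigma_vox = scale.sigma / h
    kernels = {
        order: gaussian_derivative_kernel(sigma_vox, scale.kernel_size, order, h)
        for order in (0, 1, 2)
    }
    data = np.asarray(vol.data, dtype=np.float64)
    entries: dict[str, np.ndarray] = {}
    for name, orders in _ENTRY_ORDERS.items():
        out = data
        for axis, order in enumerate(orders):
            out = ndimage.correlate1d(out, kernels[order], axis=axis, mode="nearest")
        entries[name] = out
    return HessianField(entries, scale, vol.spacing)


# ---------------------------------------------------------------------------
# Eigenvalues and index
# ---------------------------------------------------------------------------

def eigenvalues_symmetric3(
    field: HessianField, voxel: tuple[int, int, int]
) -> tuple[float, float, float]:
    """Eigenvalues of the Hessian at one voxel, sorted descending."""
    e = field.entries
    i, j, k = voxel
    m = np.array(
        [
            [e["xx"][i, j, k], e["xy"][i, j, k], e["xz"][i, j, k]],
            [e["xy"][i, j, k], e["yy"][i, j, k], e["yz"][i, j, k]],
            [e["xz"][i, j, k], e["yz"][i, j, k], e["zz"][i, j, k]],
        ]
    )
    lam = np.linalg.eigvalsh(m)  # ascending
    return (float(lam[2]), float(lam[1]), float(lam[0]))


def _negative_eigenvalue_count(field: HessianField, zero_tol: float | None) -> np.ndarray:
    h = field.matrices()
    lam = np.linalg.eigvalsh(h.reshape(-1, 3, 3))
    if zero_tol is None:
        max_entry = max(np.abs(a).max() for a in field.entries.values())
        zero_tol = 1e-8 * max(1.0, float(max_entry))
    counts = (lam < -zero_tol).sum(axis=1)
    return counts.reshape(field.shape).astype(np.uint8)


def index_image(
    vol: Volume3D,
    scale: GaussianScale,
    zero_tol: float | None = None,
    origin: tuple[float, float, float] | None = None,
) -> IndexImage:
    """Raw-stage index image: per-voxel count of negative Hessian eigenvalues.

    An eigenvalue counts as negative when it lies below ``-zero_tol``; the
    default tolerance ``1e-8 * max(1, max|H|)`` makes exactly flat regions
    yield index 0 deterministically instead of depending on floating-point
    noise around zero.
    """
    _require_isotropic(vol)
    field = second_derivative_filter_bank(vol, scale)
    counts = _negative_eigenvalue_count(field, zero_tol)
    return IndexImage(counts, scale, None, vol.spacing, origin or vol.origin)


def smooth_and_requantize(idx: IndexImage, avg_kernel: int) -> IndexImage:
    """Box-average a raw index image and requantize the mean to 8 bits.

    The continuous mean m in [0, 3] maps to ``round(m / 3 * 255)`` (replicate
    padding at borders), the minimal full-range linear 2-to-8-bit mapping.
    """
    if idx.stage != "raw":
        raise ValueError("smooth_and_requantize expects a raw-stage index image")
    if avg_kernel not in (3, 5):
        raise ValueError(f"avg_kernel must be 3 or 5, got {avg_kernel}")
    mean = ndimage.uniform_filter(
        idx.data.astype(np.float64), size=avg_kernel, mode="nearest"
    )
    q = np.floor(mean / 3.0 * 255.0 + 0.5).astype(np.uint8)
    return IndexImage(q, idx.scale, avg_kernel, idx.spacing, idx.origin)


def generate_index_images(
    vol: Volume3D,
    scales: tuple[GaussianScale, ...] = DEFAULT_SCALES,
    avg_kernels: tuple[int, ...] = DEFAULT_AVG_KERNELS,
    zero_tol: float | None = None,
) -> list[IndexImage]:
    """All smoothed-stage index images, ordered by sigma then averaging kernel.

    With the defaults this is the six-image bank: sigma in {0.5, 1.0, 1.5} mm
    crossed with 3^3 and 5^3 box averaging.
    """
    images = []
    for scale in sorted(scales, key=lambda s: s.sigma):
        raw = index_image(vol, scale, zero_tol=zero_tol)
        for k in sorted(avg_kernels):
            images.append(smooth_and_requantize(raw, k))
    return images
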