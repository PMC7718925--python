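"""Radiomic feature extraction within a tumor mask.

Two feature families are produced:

* conventional features from the CT volume — 14 histogram statistics on raw
  HU, 40 texture statistics on the 8-bit LUT-quantized volume, and the same
  54 statistics on each of the 8 sub-bands of a one-level undecimated 3D
  coiflet-1 wavelet decomposition (432), for 486 in total;
* index features from the six 8-bit Hessian index images — 54 per image
  (histogram + texture, no wavelets, which would break the index's rotation
  invariance), for 324 in total.

Texture statistics come from four matrices built over the quantized gray
levels with 3D 26-connectivity: the gray-level co-occurrence matrix (GLCM,
13 unique directions at distance 1, aggregated and symmetrized), the
gray-level run-length matrix (GLRLM, runs along the same 13 directions
pooled into one matrix), the gray-level size-zone matrix (GLSZM,
26-connected iso-intensity zones) and the neighborhood gray-tone difference
matrix (NGTDM).  Voxels outside the mask never pair with, extend runs into,
join zones with, or contribute neighbors to in-mask voxels.

Gray levels are 1-based bin indices (1..levels) in all matrix statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage, stats

from .hessian_index import IndexImage
from .image_io import (
    HU_LUT_HI,
    HU_LUT_LEVELS,
    HU_LUT_LO,
    DegenerateRoiError,
    RoiMask,
    Volume3D,
    quantize_gray_levels,
)

__all__ = [
    "FeatureVector",
    "TextureMatrixSet",
    "HISTOGRAM_FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "WAVELET_SUBBANDS",
    "histogram_features",
    "build_texture_matrices",
    "texture_features",
    "wavelet_decompose",
    "extract_conventional",
    "extract_index_features",
    "feature_table",
]

#: The 13 unique displacement directions of a 26-connected 3D neighborhood
#: (one representative per +/- pair).
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

WAVELET_SUBBANDS = ("LLL", "HLL", "LHL", "HHL", "LLH", "HLH", "LHH", "HHH")

#: Number of histogram bins for entropy/uniformity on continuous inputs.
HIST_ENTROPY_BINS = 64


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Ordered named feature values with category/source tags.

    ``meta[name]`` is a dict with at least ``category`` (histogram | texture |
    wavelet) and ``source`` (conventional | index); wavelet features carry a
    ``subband`` tag and index features a ``image`` tag (sigma / kernel).
    """

    names: list[str]
    values: np.ndarray
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)

    @staticmethod
    def concat(parts: list["FeatureVector"]) -> "FeatureVector":
        names = [n for p in parts for n in p.names]
        values = np.concatenate([p.values for p in parts]) if parts else np.array([])
        meta = {k: v for p in parts for k, v in p.meta.items()}
        return FeatureVector(names, values, meta)


@dataclass
class TextureMatrixSet:
    """GLCM / GLRLM / GLSZM / NGTDM for one quantized ROI.

    glcm : (levels, levels) probabilities summing to 1 (symmetric).
    glrlm : (levels, max_run) integer run counts.
    glszm : (levels, max_zone) integer zone counts.
    ngtdm : dict with ``n`` (per-level voxel counts) and ``s`` (per-level
        summed absolute differences from the neighborhood mean), plus the
        number of valid voxels ``n_valid``.
    n_voxels : in-mask voxel count.
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm: dict
    levels: int
    n_voxels: int


def _check_roi(vol: Volume3D, mask: RoiMask) -> np.ndarray:
    mask.check_aligned(vol)
    if mask.n_foreground == 0:
        raise DegenerateRoiError("empty ROI mask")
    return np.asarray(vol.data)[mask.data]


# ---------------------------------------------------------------------------
# Histogram features
# ---------------------------------------------------------------------------

HISTOGRAM_FEATURE_NAMES = (
    "hist_mean", "hist_variance", "hist_skewness", "hist_kurtosis",
    "hist_median", "hist_min", "hist_max", "hist_range", "hist_energy",
    "hist_entropy", "hist_uniformity", "hist_rms", "hist_mad",
    "hist_p10p90_range",
)


def histogram_features(vol: Volume3D, mask: RoiMask) -> FeatureVector:
    """The 14 first-order statistics of in-mask voxel values.

    Entropy and uniformity use a fixed 64-bin histogram spanning the ROI's
    min-max range; a constant ROI has entropy 0 and uniformity 1.  Skewness
    and kurtosis of a zero-variance ROI are defined as 0.
    """
    v = _check_roi(vol, mask).astype(np.float64)
    var = float(np.var(v))
    if var > 0:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, bias=True, fisher=False))
    else:
        skew = kurt = 0.0
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        counts, _ = np.histogram(v, bins=HIST_ENTROPY_BINS, range=(vmin, vmax))
    else:
        counts = np.array([v.size])
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    mean = float(v.mean())
    values = [
        mean, var, skew, kurt,
        float(np.median(v)), vmin, vmax, vmax - vmin, float((v**2).sum()),
        entropy, uniformity, float(np.sqrt((v**2).mean())),
        float(np.abs(v - mean).mean()),
        float(np.percentile(v, 90) - np.percentile(v, 10)),
    ]
    meta = {n: {"category": "histogram"} for n in HISTOGRAM_FEATURE_NAMES}
    return FeatureVector(list(HISTOGRAM_FEATURE_NAMES), values, meta)


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------

def _bbox_crop(q: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.nonzero(mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return q[sl], mask[sl]


def _shift_views(shape, d):
    """Slices (src, dst) so arr[src] and arr[dst] pair voxel i with i + d."""
    src, dst = [], []
    for dim, delta in zip(shape, d):
        if delta >= 0:
            src.append(slice(0, dim - delta))
            dst.append(slice(delta, dim))
        else:
            src.append(slice(-delta, dim))
            dst.append(slice(0, dim + delta))
    return tuple(src), tuple(dst)


def _glcm(q: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    counts = np.zeros((levels, levels), dtype=np.int64)
    for d in DIRECTIONS_13:
        src, dst = _shift_views(q.shape, d)
        both = mask[src] & mask[dst]
        a = q[src][both]
        b = q[dst][both]
        if a.size:
            counts += np.bincount(a * levels + b, minlength=levels**2).reshape(
                levels, levels
            )
    counts = counts + counts.T  # symmetrize: count each ordered pair both ways
    total = counts.sum()
    if total == 0:  # single-voxel ROI: degenerate but defined
        p = np.zeros_like(counts, dtype=np.float64)
        p[q[mask][0], q[mask][0]] = 1.0
        return p
    return counts / total


def _glrlm(q: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    max_run = max(q.shape)
    R = np.zeros((levels, max_run), dtype=np.int64)
    m = mask
    for d in DIRECTIONS_13:
        src, dst = _shift_views(q.shape, d)
        same = np.zeros(q.shape, dtype=bool)
        same[src] = m[src] & m[dst] & (q[src] == q[dst])
        # forward run length f[i] = 1 + f[i + d] where the run continues
        f = m.astype(np.int64)
        while True:
            nxt = np.zeros(q.shape, dtype=np.int64)
            nxt[src] = f[dst]
            f_new = np.where(same, 1 + nxt, m.astype(np.int64))
            if np.array_equal(f_new, f):
                break
            f = f_new
        prev_same = np.zeros(q.shape, dtype=bool)
        prev_same[dst] = same[src]
        start = m & ~prev_same
        np.add.at(R, (q[start], f[start] - 1), 1)
    last = np.nonzero(R.any(axis=0))[0]
    return R[:, : last[-1] + 1] if last.size else R[:, :1]


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _glszm(q: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    sizes_per_level: list[tuple[int, int]] = []
    in_levels = np.unique(q[mask])
    max_zone = 1
    for g in in_levels:
        lab, n = ndimage.label((q == g) & mask, structure=_STRUCT_26)
        if n == 0:
            continue
        zone_sizes = np.bincount(lab.ravel())[1:]
        for z in zone_sizes:
            sizes_per_level.append((int(g), int(z)))
            max_zone = max(max_zone, int(z))
    Z = np.zeros((levels, max_zone), dtype=np.int64)
    for g, z in sizes_per_level:
        Z[g, z - 1] += 1
    return Z


def _ngtdm(q: np.ndarray, mask: np.ndarray, levels: int) -> dict:
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    mf = mask.astype(np.float64)
    nbr_cnt = ndimage.correlate(mf, kernel, mode="constant", cval=0.0)
    nbr_sum = ndimage.correlate(q * mf, kernel, mode="constant", cval=0.0)
    valid = mask & (np.round(nbr_cnt) > 0)
    diff = np.zeros(q.shape)
    diff[valid] = np.abs(q[valid] - nbr_sum[valid] / nbr_cnt[valid])
    n = np.bincount(q[valid], minlength=levels).astype(np.float64)
    s = np.bincount(q[valid], weights=diff[valid], minlength=levels)
    return {"n": n, "s": s, "n_valid": int(valid.sum())}


def build_texture_matrices(
    vol_q: Volume3D, mask: RoiMask, levels: int = HU_LUT_LEVELS
) -> TextureMatrixSet:
    """Build GLCM, GLRLM, GLSZM and NGTDM for an integer-quantized ROI."""
    _check_roi(vol_q, mask)
    q_full = np.asarray(vol_q.data)
    if not np.issubdtype(q_full.dtype, np.integer):
        if not np.allclose(q_full, np.round(q_full)):
            raise ValueError("quantized volume must be integer-valued")
        q_full = np.round(q_full).astype(np.int64)
    inmask = q_full[mask.data]
    if inmask.min() < 0 or inmask.max() > levels - 1:
        raise ValueError(
            f"quantized values outside [0, {levels - 1}]: "
            f"[{inmask.min()}, {inmask.max()}]"
        )
    q, m = _bbox_crop(q_full.astype(np.int64), mask.data)
    return TextureMatrixSet(
        glcm=_glcm(q, m, levels),
        glrlm=_glrlm(q, m, levels),
        glszm=_glszm(q, m, levels),
        ngtdm=_ngtdm(q, m, levels),
        levels=levels,
        n_voxels=int(m.sum()),
    )


# ---------------------------------------------------------------------------
# Texture features (9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM = 40)
# ---------------------------------------------------------------------------

GLCM_FEATURE_NAMES = (
    "glcm_energy", "glcm_contrast", "glcm_correlation", "glcm_homogeneity",
    "glcm_variance", "glcm_sum_average", "glcm_entropy", "glcm_dissimilarity",
    "glcm_autocorrelation",
)
GLRLM_FEATURE_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
    "glrlm_lgre", "glrlm_hgre", "glrlm_srlge", "glrlm_srhge", "glrlm_lrlge",
    "glrlm_lrhge", "glrlm_glv", "glrlm_rlv",
)
GLSZM_FEATURE_NAMES = (
    "glszm_sze", "glszm_lze", "glszm_gln", "glszm_zsn", "glszm_zp",
    "glszm_lgze", "glszm_hgze", "glszm_szlge", "glszm_szhge", "glszm_lzlge",
    "glszm_lzhge", "glszm_glv", "glszm_zsv",
)
NGTDM_FEATURE_NAMES = (
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
)
TEXTURE_FEATURE_NAMES = (
    GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES + GLSZM_FEATURE_NAMES
    + NGTDM_FEATURE_NAMES
)


def _glcm_features(p: np.ndarray) -> list[float]:
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu = float((p * ii).sum())  # symmetric: row mean == col mean
    var_m = float((p * (ii - mu) ** 2).sum())
    sigma = np.sqrt(var_m)
    autoc = float((p * ii * jj).sum())
    correlation = (autoc - mu * mu) / var_m if var_m > 0 else 0.0
    pk = p[p > 0]
    return [
        float((p**2).sum()),
        float((p * (ii - jj) ** 2).sum()),
        correlation,
        float((p / (1.0 + np.abs(ii - jj))).sum()),
        var_m,
        float((p * (ii + jj)).sum()),
        float(-(pk * np.log2(pk)).sum()),
        float((p * np.abs(ii - jj)).sum()),
        autoc,
    ]


def _run_zone_features(M: np.ndarray, n_voxels: int) -> list[float]:
    """The 13 shared run-length / size-zone statistics of a (level, length)
    count matrix: emphasis, nonuniformity, percentage and variance terms."""
    total = M.sum()
    if total == 0:
        return [0.0] * 13
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, M.shape[1] + 1, dtype=np.float64)
    r_g = M.sum(axis=1).astype(np.float64)
    r_l = M.sum(axis=0).astype(np.float64)
    p = M / total
    mu_g = float((r_g / total * g).sum())
    mu_l = float((r_l / total * l).sum())
    gg, ll = np.meshgrid(g, l, indexing="ij")
    return [
        float((r_l / l**2).sum() / total),
        float((r_l * l**2).sum() / total),
        float((r_g**2).sum() / total),
        float((r_l**2).sum() / total),
        float(total / n_voxels),
        float((r_g / g**2).sum() / total),
        float((r_g * g**2).sum() / total),
        float((p / (gg**2 * ll**2)).sum()),
        float((p * gg**2 / ll**2).sum()),
        float((p * ll**2 / gg**2).sum()),
        float((p * gg**2 * ll**2).sum()),
        float((r_g / total * (g - mu_g) ** 2).sum()),
        float((r_l / total * (l - mu_l) ** 2).sum()),
    ]


def _ngtdm_features(ngtdm: dict) -> list[float]:
    n = ngtdm["n"]
    s = ngtdm["s"]
    n_valid = ngtdm["n_valid"]
    if n_valid == 0:
        return [0.0] * 5
    p = n / n_valid
    g = np.arange(1, n.size + 1, dtype=np.float64)
    nz = p > 0
    pg, gg, sg = p[nz], g[nz], s[nz]
    ngp = int(nz.sum())
    dot_ps = float((pg * sg).sum())
    coarseness = 1.0 / dot_ps if dot_ps > 0 else float(n_valid)  # flat-region cap
    if ngp > 1:
        dg = gg[:, None] - gg[None, :]
        pp = pg[:, None] * pg[None, :]
        contrast = float(
            (pp * dg**2).sum() / (ngp * (ngp - 1)) * (s.sum() / n_valid)
        )
        denom = float(np.abs(gg[:, None] * pg[:, None] - gg[None, :] * pg[None, :]).sum())
        busyness = dot_ps / denom if denom > 0 else 0.0
        num = (
            np.abs(dg)
            * (pg[:, None] * sg[:, None] + pg[None, :] * sg[None, :])
            / (pg[:, None] + pg[None, :])
        )
        complexity = float(num.sum() / n_valid)
        s_tot = float(s.sum())
        strength = (
            float(((pg[:, None] + pg[None, :]) * dg**2).sum()) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return [coarseness, contrast, busyness, complexity, strength]


def texture_features(mats: TextureMatrixSet) -> FeatureVector:
    """The 40 texture statistics of a matrix set (9 + 13 + 13 + 5)."""
    values = (
        _glcm_features(mats.glcm)
        + _run_zone_features(mats.glrlm, mats.n_voxels)
        + _run_zone_features(mats.glszm, mats.n_voxels)
        + _ngtdm_features(mats.ngtdm)
    )
    meta = {n: {"category": "texture"} for n in TEXTURE_FEATURE_NAMES}
    return FeatureVector(list(TEXTURE_FEATURE_NAMES), values, meta)


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------

def _coif1_filters() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet("coif1")
    return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def wavelet_decompose(vol: Volume3D) -> dict[str, Volume3D]:
    """One-level undecimated separable 3D coiflet-1 decomposition.

    Returns the 8 sub-bands (LLL .. HHH; letter order follows axis order
    x, y, z) at the original grid size, so every sub-band stays aligned with
    the ROI mask.  Borders use whole-sample symmetric extension.
    """
    lo, hi = _coif1_filters()
    if min(vol.shape) < lo.size:
        raise ValueError(
            f"volume shape {vol.shape} smaller than filter length {lo.size}"
        )
    data = np.asarray(vol.data, dtype=np.float64)
    out: dict[str, Volume3D] = {}
    for band in WAVELET_SUBBANDS:
        arr = data
        for axis, letter in enumerate(band):
            taps = lo if letter == "L" else hi
            arr = ndimage.correlate1d(arr, taps, axis=axis, mode="reflect")
        out[band] = vol.with_data(arr)
    return out


# ---------------------------------------------------------------------------
# Assembled extractors
# ---------------------------------------------------------------------------

def _minmax_quantize(vol: Volume3D, mask: RoiMask, levels: int) -> Volume3D:
    """Min-max requantization over the in-mask range (constant ROI -> level 0)."""
    v = np.asarray(vol.data, dtype=np.float64)
    inmask = v[mask.data]
    vmin, vmax = float(inmask.min()), float(inmask.max())
    if vmax <= vmin:
        return vol.with_data(np.zeros(v.shape, dtype=np.int64))
    x = (v - vmin) / (vmax - vmin) * (levels - 1)
    q = np.clip(np.floor(x + 0.5), 0, levels - 1).astype(np.int64)
    return vol.with_data(q)


def _tag_names(fv: FeatureVector, prefix: str, extra_meta: dict) -> FeatureVector:
    names = [f"{prefix}_{n}" for n in fv.names]
    meta = {
        f"{prefix}_{n}": {**fv.meta.get(n, {}), **extra_meta} for n in fv.names
    }
    return FeatureVector(names, fv.values, meta)


def _histogram_plus_texture(
    vol: Volume3D, vol_q: Volume3D, mask: RoiMask, levels: int
) -> FeatureVector:
    hist = histogram_features(vol, mask)
    tex = texture_features(build_texture_matrices(vol_q, mask, levels))
    return FeatureVector.concat([hist, tex])


def extract_conventional(
    vol_ct: Volume3D,
    mask: RoiMask,
    levels: int = HU_LUT_LEVELS,
    lut: tuple[float, float] = (HU_LUT_LO, HU_LUT_HI),
) -> FeatureVector:
    """The 486 conventional CT features (14 + 40 + 8 x 54 wavelet).

    Histogram features use raw HU; texture features use the fixed HU LUT;
    wavelet sub-band texture features use per-band min-max requantization
    (sub-band values have no fixed physical scale) and wavelet histogram
    features use the raw sub-band values.
    """
    mask.check_aligned(vol_ct)
    q_ct = quantize_gray_levels(vol_ct, lut[0], lut[1], levels)
    base = _histogram_plus_texture(vol_ct, q_ct, mask, levels)
    base = _tag_names(base, "ct", {"source": "conventional"})
    parts = [base]
    bands = wavelet_decompose(vol_ct)
    for band in WAVELET_SUBBANDS:
        bvol = bands[band]
        bq = _minmax_quantize(bvol, mask, levels)
        fv = _histogram_plus_texture(bvol, bq, mask, levels)
        fv = _tag_names(
            fv, f"wav_{band.lower()}",
            {"source": "conventional", "category": "wavelet", "subband": band},
        )
        parts.append(fv)
    return FeatureVector.concat(parts)


def extract_index_features(
    index_images: list[IndexImage], mask: RoiMask, levels: int = 256
) -> FeatureVector:
    """The 324 index features: 54 histogram + texture per smoothed index image.

    The 8-bit smoothed values feed both the histogram statistics and the
    texture matrices directly (they are already integer gray levels); no
    wavelet decomposition is applied.
    """
    if len(index_images) != 6:
        raise ValueError(f"expected 6 index images, got {len(index_images)}")
    parts = []
    for img in index_images:
        if img.stage != "smoothed":
            raise ValueError("index features require smoothed-stage images")
        vol = img.as_volume()
        fv = _histogram_plus_texture(vol, vol, mask, levels)
        fv = _tag_names(fv, f"idx_{img.tag}", {"source": "index", "image": img.tag})
        parts.append(fv)
    return FeatureVector.concat(parts)


def feature_table(rows: dict[str, FeatureVector]) -> pd.DataFrame:
    """Patients x features DataFrame from per-patient feature vectors."""
    return pd.DataFrame(
        {pid: fv.to_series() for pid, fv in rows.items()}
    ).T.rename_axis("patient_id")
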