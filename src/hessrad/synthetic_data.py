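"""Synthetic phantoms and survival cohorts for end-to-end testing.

The phantom generator places smooth analytic primitives — Gaussian blobs
(bright or dark) and quadratic saddle patches — on a background HU level,
with optional additive Gaussian noise, and records the expected raw Hessian
index at each primitive's center: a bright blob has a negative-definite
Hessian at its mode (index 3), a dark blob index 0, and a quadratic patch
``a x^2 + b y^2 + c z^2`` has index equal to the number of negative
coefficients.  Quadratic patches are written inside a spherical top-hat
window wide enough that the discontinuity at the window edge cannot reach
the center through any of the filter kernels.

The cohort generator draws features and survival times from a proportional
hazards law ``h(t | x) = rate * exp(beta' x)`` with an exponential baseline,
plus independent exponential censoring whose rate is calibrated so the
expected censoring fraction matches the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .image_io import RoiMask, Volume3D
from .survival_eval import SurvivalCohort

__all__ = [
    "GaussianBlob",
    "QuadraticPatch",
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GaussianBlob:
    """A bright (amplitude > 0) or dark (< 0) Gaussian blob."""

    center_mm: tuple[float, float, float]
    amplitude: float
    fwhm_mm: float

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def expected_index(self) -> int:
        return 3 if self.amplitude > 0 else 0

    @property
    def support_radius_mm(self) -> float:
        return 3.0 * self.fwhm_mm


@dataclass(frozen=True)
class QuadraticPatch:
    """Local quadratic ``a dx^2 + b dy^2 + c dz^2`` inside a top-hat window."""

    center_mm: tuple[float, float, float]
    coeffs: tuple[float, float, float]
    window_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.window_radius_mm <= 0:
            raise ValueError("window radius must be positive")

    @property
    def expected_index(self) -> int:
        return int(sum(1 for c in self.coeffs if c < 0))

    @property
    def support_radius_mm(self) -> float:
        return self.window_radius_mm


@dataclass
class PhantomSpec:
    """Grid geometry, primitives, background level and noise for a phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    isovoxel: float = 1.0
    primitives: list = field(default_factory=list)
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    mask_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        extent = [s * self.isovoxel for s in self.shape]
        for p in self.primitives:
            if any(not (0 <= c < e) for c, e in zip(p.center_mm, extent)):
                raise ValueError(f"primitive center {p.center_mm} outside grid")


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, RoiMask, pd.DataFrame]:
    """Render a phantom volume, an ellipsoidal GTV mask, and the ground truth.

    Returns ``(volume, mask, truth)`` where ``truth`` has one row per
    primitive: kind, center voxel indices, the expected raw Hessian index at
    the center, and an ``overlaps`` flag set when primitive supports
    intersect.  Deterministic given the spec seed.
    """
    h = spec.isovoxel
    grid = np.indices(spec.shape, dtype=np.float64)
    x, y, z = (grid[i] * h for i in range(3))
    data = np.full(spec.shape, float(spec.background))
    rows = []
    for k, prim in enumerate(spec.primitives):
        cx, cy, cz = prim.center_mm
        dx, dy, dz = x - cx, y - cy, z - cz
        if isinstance(prim, GaussianBlob):
            s = prim.fwhm_mm * _FWHM_TO_SIGMA
            data += prim.amplitude * np.exp(-(dx**2 + dy**2 + dz**2) / (2 * s**2))
            kind = "bright_blob" if prim.amplitude > 0 else "dark_blob"
        elif isinstance(prim, QuadraticPatch):
            r2 = dx**2 + dy**2 + dz**2
            a, b, c = prim.coeffs
            patch = a * dx**2 + b * dy**2 + c * dz**2
            data += np.where(r2 <= prim.window_radius_mm**2, patch, 0.0)
            kind = "quadratic_patch"
        else:
            raise TypeError(f"unknown primitive type {type(prim)!r}")
        center_vox = tuple(int(round(c / h)) for c in prim.center_mm)
        overlaps = any(
            np.linalg.norm(np.subtract(prim.center_mm, q.center_mm))
            < prim.support_radius_mm + q.support_radius_mm
            for j, q in enumerate(spec.primitives)
            if j != k
        )
        rows.append(
            {
                "kind": kind,
                "center_voxel": center_vox,
                "expected_index": prim.expected_index,
                "overlaps": overlaps,
            }
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    mask = _ellipsoid_mask(spec, x, y, z)
    vol = Volume3D(data, (h, h, h))
    return vol, RoiMask(mask, (h, h, h)), pd.DataFrame(rows)


def _ellipsoid_mask(spec: PhantomSpec, x, y, z) -> np.ndarray:
    h = spec.isovoxel
    extent = np.array([s * h for s in spec.shape])
    if spec.primitives:
        centers = np.array([p.center_mm for p in spec.primitives])
        radii = np.array([p.support_radius_mm for p in spec.primitives])
        lo = (centers - radii[:, None]).min(axis=0) - spec.mask_margin_mm
        hi = (centers + radii[:, None]).max(axis=0) + spec.mask_margin_mm
        lo = np.maximum(lo, 0.0)
        hi = np.minimum(hi, extent - h)
    else:
        lo, hi = extent * 0.25, extent * 0.75
    c = (lo + hi) / 2.0
    ax = np.maximum((hi - lo) / 2.0, 2.0 * h)
    return (
        ((x - c[0]) / ax[0]) ** 2
        + ((y - c[1]) / ax[1]) ** 2
        + ((z - c[2]) / ax[2]) ** 2
    ) <= 1.0


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Proportional-hazards cohort: size, baseline rate, effects, censoring."""

    n: int = 200
    baseline_rate: float = 0.01
    beta: tuple[float, ...] = (1.0,)
    censoring_target: float = 0.3
    artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if not (0 <= self.censoring_target < 1):
            raise ValueError("censoring target must lie in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if not (0 <= self.artifact_fraction <= 1):
            raise ValueError("artifact fraction must lie in [0, 1]")


def make_cohort(
    spec: CohortSpec, feature_generator=None
) -> tuple[pd.DataFrame, SurvivalCohort, dict]:
    """Draw features and proportional-hazards survival data.

    ``feature_generator(rng, n)`` may supply an (n, p) feature matrix or
    DataFrame with p = len(beta); by default features are independent
    standard normals.  Censoring times are exponential with a rate solved so
    the expected censoring fraction equals the target.  Returns the feature
    table, the cohort, and a ground-truth dict with the true beta and the
    calibrated censoring rate.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.beta)
    if feature_generator is None:
        X = rng.standard_normal((spec.n, p))
        columns = [f"feature_{j}" for j in range(p)]
    else:
        X = np.asarray(
            feature_generator(rng, spec.n).values
            if hasattr(feature_generator(np.random.default_rng(spec.seed), spec.n), "values")
            else feature_generator(rng, spec.n),
            dtype=np.float64,
        )
        columns = [f"feature_{j}" for j in range(X.shape[1])]
    if X.shape != (spec.n, p):
        raise ValueError(f"feature matrix shape {X.shape} != ({spec.n}, {p})")
    beta = np.asarray(spec.beta, dtype=np.float64)
    rates = spec.baseline_rate * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / rates)
    censor_rate = _calibrated_censoring_rate(rates, spec.censoring_target)
    if censor_rate > 0:
        t_censor = rng.exponential(1.0 / censor_rate, size=spec.n)
    else:
        t_censor = np.full(spec.n, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    ids = [f"P{i:04d}" for i in range(spec.n)]
    features = pd.DataFrame(X, index=ids, columns=columns)
    table = pd.DataFrame({"time": time, "event": event}, index=ids)
    if spec.artifact_fraction > 0:
        n_art = int(round(spec.artifact_fraction * spec.n))
        flags = np.array(["non_artifact"] * spec.n, dtype=object)
        flags[rng.choice(spec.n, size=n_art, replace=False)] = "artifact"
        table["artifact"] = flags
    truth = {"beta": beta, "censor_rate": censor_rate}
    return features, SurvivalCohort(table), truth


def _calibrated_censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Censoring rate c with mean_i c / (c + r_i) equal to the target fraction."""
    if target == 0:
        return 0.0
    scale = float(np.median(event_rates))

    def frac(c: float) -> float:
        return float(np.mean(c / (c + event_rates))) - target

    lo, hi = scale * 1e-9, scale * 1e9
    if frac(lo) > 0 or frac(hi) < 0:  # pragma: no cover - pathological rates
        raise ValueError("censoring target infeasible for these event rates")
    return float(brentq(frac, lo, hi, xtol=1e-12 * scale))
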