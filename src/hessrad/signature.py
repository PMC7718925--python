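"""Prognostic signature construction: elastic-net Cox candidate selection and
the stepwise combination strategy.

Candidate features are selected with elastic-net-penalized Cox regression
("Coxnet"): the blending parameter alpha interpolates between ridge
(alpha -> 0, keeps correlated features) and the lasso (alpha = 1, zeroes
correlated features), and is itself chosen by cross-validation over a grid.
Features with non-zero coefficients at the cross-validated penalty strength
become signature candidates.  A combined candidate set pools the
conventional and index candidates and re-runs the selection.

Signatures of sizes 1..K (K capped at min(12, n/10)) are then grown by
greedy forward selection: at each step the candidate whose addition
minimizes the training log-rank p-value of the median rad-score split is
appended (ties broken by higher concordance index, then feature name), and
the refit Cox model's coefficients and training rad-score median are stored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .survival_eval import (
    CoxFitError,
    SurvivalCohort,
    fit_cph,
    rad_score,
    stratify_and_test,
)

__all__ = [
    "CoxnetConfig",
    "Signature",
    "DEFAULT_ALPHA_GRID",
    "CLINICAL_ENCODING",
    "encode_clinical",
    "optimize_alpha",
    "select_candidates",
    "build_signatures",
    "integrate_clinical",
    "max_signature_size",
]

#: Blending-parameter grid; spans near-ridge to pure lasso.
DEFAULT_ALPHA_GRID = (0.01, 0.02, 0.05, 0.08, 0.1, 0.2, 0.5, 0.8, 1.0)


@dataclass(frozen=True)
class CoxnetConfig:
    """Settings for elastic-net Cox candidate selection."""

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_lambdas: int = 50
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0 < a <= 1) for a in self.alpha_grid):
            raise ValueError("blending parameters must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class Signature:
    """An ordered feature subset with Cox coefficients and training median."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    train_median: float

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError("names/coefficients length mismatch")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def size(self) -> int:
        return len(self.feature_names)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "coefficients": self.coefficients.tolist(),
                "train_median": self.train_median,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Signature":
        d = json.loads(text)
        return cls(
            tuple(d["feature_names"]),
            np.array(d["coefficients"]),
            float(d["train_median"]),
        )


def max_signature_size(n_train: int, cap: int = 12) -> int:
    """Largest allowed signature: at most one feature per ten patients."""
    return min(cap, n_train // 10)


# ---------------------------------------------------------------------------
# Cross-validated partial likelihood
# ---------------------------------------------------------------------------

def _cox_partial_loglik(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood of fixed risk scores (Breslow ties)."""
    order = np.argsort(time, kind="stable")
    t, e, s = time[order], event[order], scores[order]
    # risk-set log-sum-exp computed from the tail; stabilize by max
    smax = s.max() if s.size else 0.0
    exp_s = np.exp(s - smax)
    rev_cumsum = np.cumsum(exp_s[::-1])[::-1]
    ll = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            ll += s[i:j][e[i:j] == 1].sum()
            ll -= d * (np.log(rev_cumsum[i]) + smax)
        i = j
    return float(ll)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _fit_path(Xs, y, l1_ratio, lambdas=None, n_lambdas=50):
    model = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio,
        n_alphas=n_lambdas,
        alphas=None if lambdas is None else list(lambdas),
        normalize=False,
        fit_baseline_model=False,
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    return model


def _cv_lambda_score(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    l1_ratio: float, cfg: CoxnetConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean held-out Cox partial log-likelihood along the penalty path.

    Returns (lambda_path, mean_cv_loglik); the path is fitted once on the
    full standardized data and re-used across folds.
    """
    Xs, _, _ = _standardize(X)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    full = _fit_path(Xs, y, l1_ratio, n_lambdas=cfg.n_lambdas)
    lambdas = np.asarray(full.alphas_)
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    scores = np.zeros((cfg.cv_folds, lambdas.size))
    for f, (tr, te) in enumerate(kf.split(Xs)):
        if event[tr].sum() == 0 or event[te].sum() == 0:
            scores[f] = np.nan
            continue
        try:
            fold = _fit_path(Xs[tr], Surv.from_arrays(
                event=event[tr].astype(bool), time=time[tr]), l1_ratio, lambdas)
            coefs = fold.coef_  # (p, n_lambdas)
        except Exception:
            scores[f] = np.nan
            continue
        fitted = np.asarray(fold.alphas_)
        for li, lam in enumerate(lambdas):
            match = np.argmin(np.abs(fitted - lam))
            if not np.isclose(fitted[match], lam, rtol=1e-6):
                scores[f, li] = np.nan
                continue
            lp = Xs[te] @ coefs[:, match]
            scores[f, li] = _cox_partial_loglik(lp, time[te], event[te])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_scores = np.nanmean(scores, axis=0)
    return lambdas, mean_scores


def optimize_alpha(
    features: pd.DataFrame, surv: SurvivalCohort, cfg: CoxnetConfig = CoxnetConfig()
) -> float:
    """Choose the blending parameter maximizing cross-validated partial likelihood.

    Features are z-scored internally; for each grid alpha the penalty path is
    scored by k-fold held-out Cox partial log-likelihood and the alpha whose
    best (lambda-optimal) score is largest wins.  Deterministic given the
    config seed.
    """
    if surv.n_events < 2:
        raise CoxFitError("need at least 2 events to optimize the blending parameter")
    if len(cfg.alpha_grid) == 1:
        return float(cfg.alpha_grid[0])
    X = features.loc[surv.table.index].values.astype(np.float64)
    time = surv.time.values.astype(np.float64)
    event = surv.event.values.astype(np.int64)
    best_alpha, best_score = None, -np.inf
    for a in cfg.alpha_grid:
        _, mean_scores = _cv_lambda_score(X, time, event, a, cfg)
        if np.all(np.isnan(mean_scores)):
            continue
        score = np.nanmax(mean_scores)
        if score > best_score:
            best_alpha, best_score = a, score
    if best_alpha is None:
        raise CoxFitError("cross-validation failed for every blending parameter")
    return float(best_alpha)


def select_candidates(
    features: pd.DataFrame,
    surv: SurvivalCohort,
    alpha: float,
    cfg: CoxnetConfig = CoxnetConfig(),
) -> list[str]:
    """Signature candidates: features with non-zero Coxnet coefficients.

    The penalty strength is chosen at the maximum of the cross-validated
    partial likelihood along the path fitted at the given blending
    parameter.  An empty selection is a valid outcome (returned with a
    warning).
    """
    if surv.n_events < 2:
        raise CoxFitError("need at least 2 events to select candidates")
    X = features.loc[surv.table.index].values.astype(np.float64)
    time = surv.time.values.astype(np.float64)
    event = surv.event.values.astype(np.int64)
    lambdas, mean_scores = _cv_lambda_score(X, time, event, alpha, cfg)
    if np.all(np.isnan(mean_scores)):
        raise CoxFitError("cross-validation failed along the penalty path")
    lam = lambdas[int(np.nanargmax(mean_scores))]
    Xs, _, _ = _standardize(X)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = _fit_path(Xs, y, alpha, lambdas=[lam])
    coefs = model.coef_[:, 0]
    selected = [n for n, c in zip(features.columns, coefs) if c != 0.0]
    if not selected:
        warnings.warn("Coxnet selected no candidates at the chosen penalty")
    return selected


# ---------------------------------------------------------------------------
# Combination strategy
# ---------------------------------------------------------------------------

def _fit_signature(names: list[str], features: pd.DataFrame, surv: SurvivalCohort):
    cph = fit_cph(features[names], surv)
    coefs = cph.params_.reindex(names).values
    sig = Signature(tuple(names), coefs, 0.0)
    scores = rad_score(sig, features.loc[surv.table.index])
    sig.train_median = float(np.median(scores.values))
    strat = stratify_and_test(scores, surv, sig.train_median)
    p = strat.p_value if strat.p_value is not None else np.inf
    cindex = float(cph.concordance_index_)
    return sig, p, cindex


def build_signatures(
    candidates: list[str],
    features: pd.DataFrame,
    surv: SurvivalCohort,
    max_size: int = 12,
) -> list[Signature]:
    """Nested signatures of sizes 1..K by greedy forward selection.

    At step m every remaining candidate is tentatively added to the current
    set, the Cox model refit, and the training-cohort median-split log-rank
    p-value computed; the candidate with the lowest p wins (ties: higher
    concordance index, then lexicographic name).  Candidates whose refit
    fails (collinearity, separation) are skipped; the list truncates when no
    candidate can be added.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    cap = max_signature_size(surv.n)
    k = min(max_size, cap, len(candidates))
    current: list[str] = []
    out: list[Signature] = []
    remaining = sorted(candidates)
    for _ in range(k):
        best = None  # (p, -cindex, name, sig)
        for name in remaining:
            try:
                sig, p, cindex = _fit_signature(current + [name], features, surv)
            except CoxFitError:
                continue
            key = (p, -cindex, name)
            if best is None or key < best[0]:
                best = (key, name, sig)
        if best is None:
            break
        _, name, sig = best
        current.append(name)
        remaining.remove(name)
        out.append(sig)
    return out


# ---------------------------------------------------------------------------
# Clinical variables
# ---------------------------------------------------------------------------

#: Ordinal encodings for staged clinical variables; numeric variables
#: (age, tumor volume) pass through unchanged.
CLINICAL_ENCODING = {
    "t_stage": {"T1": 1, "T2": 2, "T3": 3, "T4": 4, "T4A": 4, "T4B": 4},
    "n_stage": {"N0": 0, "N1": 1, "N2": 2, "N2A": 2, "N2B": 2, "N2C": 2, "N3": 3},
    "tnm_stage": {"I": 1, "II": 2, "III": 3, "IV": 4, "IVA": 5, "IVB": 6},
    "hpv_status": {"NEGATIVE": 0, "POSITIVE": 1},
}


def encode_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of clinical covariates (ordinal stages, binary HPV).

    Unknown categories raise; columns without an encoding must already be
    numeric.  Missing values propagate as NaN (excluded per analysis by the
    caller).
    """
    out = {}
    for col in table.columns:
        if col in CLINICAL_ENCODING:
            mapping = CLINICAL_ENCODING[col]

            def enc(v, mapping=mapping, col=col):
                if pd.isna(v):
                    return np.nan
                key = str(v).strip().upper()
                if key not in mapping:
                    raise ValueError(f"unknown {col} category: {v!r}")
                return float(mapping[key])

            out[col] = table[col].map(enc)
        else:
            out[col] = pd.to_numeric(table[col])
    return pd.DataFrame(out, index=table.index)


def integrate_clinical(
    radiomic_sigs: list[Signature],
    clinical_sigs: list[Signature],
    features: pd.DataFrame,
    surv: SurvivalCohort,
) -> list[Signature]:
    """Cartesian product of radiomic and clinical signatures, each refit jointly.

    With 12 radiomic and 5 clinical signatures this yields the 60 integrated
    signatures.  ``features`` must contain both the radiomic columns and the
    numerically encoded clinical columns; overlapping names raise.
    """
    if not radiomic_sigs or not clinical_sigs:
        raise ValueError("both signature lists must be non-empty")
    out = []
    for rs in radiomic_sigs:
        for cs in clinical_sigs:
            overlap = set(rs.feature_names) & set(cs.feature_names)
            if overlap:
                raise ValueError(f"duplicate covariate names: {sorted(overlap)}")
            names = list(rs.feature_names) + list(cs.feature_names)
            sig, _, _ = _fit_signature(names, features, surv)
            out.append(sig)
    return out
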