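"""Cox proportional-hazards evaluation: rad-scores, median-split stratification,
Kaplan-Meier curves and the log-rank test.

A fitted signature assigns each patient a rad-score — the linear combination
of its feature values weighted by the Cox coefficients (no intercept).  The
training-cohort median of the rad-scores splits patients into low/high-risk
groups; prognostic power is the two-sample log-rank p-value between the two
Kaplan-Meier curves, with the training median (not the test median) re-used
on a test cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalCohort",
    "RiskStratification",
    "CoxFitError",
    "fit_cph",
    "rad_score",
    "stratify_and_test",
    "subgroup_pvalue_difference",
    "model_selection_grid",
]


class CoxFitError(RuntimeError):
    """Cox model could not be fitted (separation, singular design, ...)."""


@dataclass
class SurvivalCohort:
    """Per-patient time-to-event records.

    ``table`` is indexed by patient id with columns ``time`` (> 0, any
    consistent unit) and ``event`` (1 = event observed, 0 = censored); an
    optional ``artifact`` column holds 'artifact' / 'non_artifact' labels and
    any further columns are clinical covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"time", "event"} - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        if (self.table["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        ev = set(np.unique(self.table["event"]))
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, got {ev}")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]

    def subset(self, ids) -> "SurvivalCohort":
        return SurvivalCohort(self.table.loc[ids])


@dataclass
class RiskStratification:
    """Median-split result: groups, KM curves, log-rank statistic and p."""

    scores: pd.Series
    groups: pd.Series            # 'low' / 'high'
    median: float
    km_curves: dict              # group -> DataFrame(time, survival, at_risk)
    statistic: float | None
    p_value: float | None
    warnings_: list[str] = field(default_factory=list)


def fit_cph(features: pd.DataFrame, surv: SurvivalCohort) -> CoxPHFitter:
    """Maximum partial-likelihood Cox fit (Efron ties) of features on survival.

    Raises :class:`CoxFitError` on fewer than one event, constant columns,
    exactly collinear columns, or optimizer failure.
    """
    if surv.n_events < 1:
        raise CoxFitError("cohort has no events")
    X = features.loc[surv.table.index]
    if (X.std(ddof=0) == 0).any():
        bad = list(X.columns[X.std(ddof=0) == 0])
        raise CoxFitError(f"constant feature columns: {bad}")
    if X.shape[1] > 1 and np.linalg.matrix_rank(np.corrcoef(X.values.T)) < X.shape[1]:
        raise CoxFitError("exactly collinear feature columns (singular design)")
    df = X.copy()
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise CoxFitError(f"Cox fit failed: {exc}") from exc
    if not np.all(np.isfinite(cph.params_.values)):
        raise CoxFitError("non-finite coefficients (possible separation)")
    return cph


def rad_score(sig, features: pd.DataFrame) -> pd.Series:
    """Per-patient rad-score: sum of coefficient-weighted signature features."""
    missing = [n for n in sig.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"feature columns missing from table: {missing}")
    X = features[list(sig.feature_names)].values
    return pd.Series(
        X @ np.asarray(sig.coefficients), index=features.index, name="rad_score"
    )


def _km_table(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event)
    sf = km.survival_function_
    tbl = pd.DataFrame(
        {
            "time": sf.index.values,
            "survival": sf.iloc[:, 0].values,
            "at_risk": km.event_table["at_risk"].reindex(sf.index).values,
        }
    )
    return tbl


def stratify_and_test(
    scores: pd.Series, surv: SurvivalCohort, median: float
) -> RiskStratification:
    """Split patients at a (training) median rad-score and run the log-rank test.

    Scores strictly above the median go to the high-risk group; ties go low.
    If either group is empty the stratification is degenerate: KM/log-rank
    outputs are reported missing (None) with a warning recorded.
    """
    if not np.isfinite(median):
        raise ValueError("median must be finite")
    scores = scores.loc[surv.table.index]
    groups = pd.Series(
        np.where(scores.values > median, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    warns: list[str] = []
    km_curves: dict = {}
    for g in ("low", "high"):
        sel = groups == g
        if sel.any():
            km_curves[g] = _km_table(
                surv.time[sel].values, surv.event[sel].values
            )
    if len(km_curves) < 2:
        warns.append("degenerate stratification: one risk group is empty")
        return RiskStratification(scores, groups, median, km_curves, None, None, warns)
    lo, hi = groups == "low", groups == "high"
    if surv.n_events == 0:
        warns.append("all patients censored: log-rank undefined")
        return RiskStratification(scores, groups, median, km_curves, None, None, warns)
    res = logrank_test(
        surv.time[lo].values, surv.time[hi].values,
        event_observed_A=surv.event[lo].values,
        event_observed_B=surv.event[hi].values,
    )
    return RiskStratification(
        scores, groups, median, km_curves,
        float(res.test_statistic), float(res.p_value), warns,
    )


def subgroup_pvalue_difference(
    scores: pd.Series,
    surv: SurvivalCohort,
    median: float,
    flags: pd.Series,
) -> tuple[float | None, float | None, float | None]:
    """Log-rank p in the artifact and non-artifact subgroups and their |difference|.

    ``flags`` holds 'artifact' / 'non_artifact' per patient; the feature set
    whose best model shows the smallest difference is the one least affected
    by streak artifact.
    """
    flags = flags.loc[surv.table.index]
    out = {}
    for label in ("artifact", "non_artifact"):
        ids = flags.index[flags == label]
        if len(ids) == 0:
            raise ValueError(f"empty subgroup: {label}")
        strat = stratify_and_test(scores.loc[ids], surv.subset(ids), median)
        out[label] = strat.p_value
    p_a, p_n = out["artifact"], out["non_artifact"]
    delta = abs(p_a - p_n) if (p_a is not None and p_n is not None) else None
    return p_a, p_n, delta


def model_selection_grid(
    signatures: list,
    features_train: pd.DataFrame,
    surv_train: SurvivalCohort,
    features_test: pd.DataFrame,
    surv_test: SurvivalCohort,
) -> tuple[pd.DataFrame, object]:
    """Evaluate each signature on both cohorts; best = lowest test p-value.

    Returns a table with one row per signature (size, p_train, p_test) and
    the best signature (ties broken toward the smaller size).
    """
    rows = []
    for sig in signatures:
        p_tr = stratify_and_test(
            rad_score(sig, features_train), surv_train, sig.train_median
        ).p_value
        p_te = stratify_and_test(
            rad_score(sig, features_test), surv_test, sig.train_median
        ).p_value
        rows.append({"size": sig.size, "p_train": p_tr, "p_test": p_te})
    grid = pd.DataFrame(rows)
    order = grid.assign(
        _p=grid["p_test"].astype(float).fillna(np.inf)
    ).sort_values(["_p", "size"], kind="stable")
    best = signatures[order.index[0]]
    return grid, best
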