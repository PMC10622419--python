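"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Thin, validated wrappers around lifelines.  Event = disease-specific death
(1) vs censored (0); time in months.  Cox fits use Efron tie handling
(lifelines' default) and report per-covariate beta, HR = exp(beta), Wald
95% CI and p.  Subtype indicators are one-hot with the largest subtype as
reference; UICC stage enters as indicators with stage I as reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .consensus import SubtypeAssignment

log = logging.getLogger("subtyper.survival")


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame indexed by event/censoring time with columns
    at_risk, events, survival (non-increasing, starting at 1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "at_risk": tab["at_risk"],
        "events": tab["observed"],
        "survival": surv,
    })
    out.index.name = "time"
    return out


def logrank(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict:
    """Log-rank test across >= 2 groups of (times, events).

    Returns {chi2, df, p}.  If no group has any event the test is undefined
    and p = 1 is returned with a warning.
    """
    if len(groups) < 2 or any(len(t) == 0 for t, _ in groups.values()):
        raise ValueError("need >= 2 non-empty groups")
    times = np.concatenate([np.asarray(t, float) for t, _ in groups.values()])
    events = np.concatenate([np.asarray(e, int) for _, e in groups.values()])
    labels = np.concatenate([
        np.repeat(name, len(t)) for name, (t, _) in groups.items()
    ])
    df = len(groups) - 1
    if events.sum() == 0:
        log.warning("no events in any group: log-rank p set to 1")
        return {"chi2": 0.0, "df": df, "p": 1.0}
    res = multivariate_logrank_test(times, labels, events)
    return {"chi2": float(res.test_statistic), "df": df, "p": float(res.p_value)}


def pairwise_logrank(
    groups: dict[str, tuple[np.ndarray, np.ndarray]],
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise two-group log-rank tests; raw p plus optional BH column."""
    rows = []
    for g1, g2 in combinations(groups, 2):
        t1, e1 = groups[g1]
        t2, e2 = groups[g2]
        if np.sum(e1) + np.sum(e2) == 0:
            rows.append({"group1": g1, "group2": g2, "chi2": 0.0, "p": 1.0})
            continue
        res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        rows.append({"group1": g1, "group2": g2,
                     "chi2": float(res.test_statistic),
                     "p": float(res.p_value)})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class CoxResults:
    """Per-covariate estimates from a proportional-hazards fit."""

    table: pd.DataFrame  # index covariate; columns beta, HR, ci_low, ci_high, p
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return self.table

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "HR"])


def cox_fit(
    design: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
) -> CoxResults:
    """Cox proportional-hazards fit (Efron ties) on a numeric design matrix.

    Raises on a rank-deficient design (e.g. duplicated columns) before
    fitting; lifelines convergence problems propagate with its diagnostics.
    """
    X = design.astype(float)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} "
            "columns); drop collinear covariates"
        )
    df = X.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    table = pd.DataFrame({
        "beta": s["coef"],
        "HR": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxResults(table=table, n=len(df), n_events=int(df["_event"].sum()))


def subtype_design(
    assignment: SubtypeAssignment,
    clinical: pd.DataFrame,
    include_stage: bool = True,
    include_mpr: bool = False,
    reference: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build (design, times, events) with subtype one-hot indicators
    (reference = largest subtype unless given), UICC-stage indicators
    (reference = stage I) and optionally MPR."""
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    common = assignment.labels.index.intersection(clin.index)
    labels = assignment.labels.loc[common]
    clin = clin.loc[common]
    if reference is None:
        reference = labels.value_counts().idxmax()
    design = pd.get_dummies(labels, prefix="subtype").astype(float)
    ref_col = f"subtype_{reference}"
    if ref_col in design:
        design = design.drop(columns=ref_col)
    if include_stage:
        stage = pd.get_dummies(clin["uicc_stage"], prefix="uicc").astype(float)
        if "uicc_I" in stage:
            stage = stage.drop(columns="uicc_I")
        design = design.join(stage)
    if include_mpr:
        if "MPR" in clin.columns and clin["MPR"].notna().all():
            design["MPR"] = clin["MPR"].astype(float)
        else:
            log.warning("MPR column missing or incomplete: omitted from design")
    return design, clin["time"].to_numpy(float), clin["event"].to_numpy(int)
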