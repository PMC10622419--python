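"""Subtype transfer to an independent cohort via a metabolite-panel
nearest-centroid classifier.

The discovery subtypes train a transparent centroid model: features are
z-scored on the training cohort, the panel is the top metabolites by
Kruskal-Wallis H across subtypes (default 100), and each subtype's centroid
is the per-feature median in z-space.  New samples are assigned to the
nearest centroid by Euclidean distance, always standardized with the stored
training means/SDs (no leakage).  Downstream, assigned subtypes are tested
against chemotherapy response (pairwise Fisher exact tests on
resistant/sensitive counts) and outcome (pairwise log-rank plus a
multivariate Cox fit with subtype, MPR and UICC-stage covariates).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import SubtypeAssignment
from .io import CohortMatrix
from .survival import CoxResults, cox_fit, pairwise_logrank, subtype_design

log = logging.getLogger("subtyper.transfer")


@dataclass
class CentroidClassifier:
    compartment: str
    panel: list[str]
    centroids: pd.DataFrame  # index: subtype labels; columns: panel (z-space)
    feature_means: pd.Series
    feature_sds: pd.Series
    feature_medians: pd.Series  # raw-space medians, used for imputation

    def __post_init__(self) -> None:
        C = self.centroids.to_numpy(dtype=float)
        for i, j in combinations(range(len(C)), 2):
            if np.allclose(C[i], C[j]):
                a, b = self.centroids.index[i], self.centroids.index[j]
                raise ValueError(f"centroids of subtypes {a} and {b} coincide")

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroids.index)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "compartment": self.compartment,
            "panel": self.panel,
            "centroids": {s: self.centroids.loc[s].tolist()
                          for s in self.centroids.index},
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "feature_medians": self.feature_medians.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidClassifier":
        d = json.loads(Path(path).read_text())
        panel = d["panel"]
        centroids = pd.DataFrame(d["centroids"], index=panel).T
        centroids.index.name = "subtype"
        return cls(
            compartment=d["compartment"],
            panel=panel,
            centroids=centroids,
            feature_means=pd.Series(d["feature_means"], index=panel),
            feature_sds=pd.Series(d["feature_sds"], index=panel),
            feature_medians=pd.Series(d["feature_medians"], index=panel),
        )


def fit_classifier(
    cohort: CohortMatrix,
    assignment: SubtypeAssignment,
    panel_size: int = 100,
) -> CentroidClassifier:
    """Train a nearest-centroid classifier on discovery subtypes.

    Panel = top `panel_size` metabolites ranked by Kruskal-Wallis H across
    subtypes (capped, with a warning, at the number available); centroids are
    per-subtype medians in z-space.
    """
    labels = assignment.labels.loc[cohort.data.index]
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 subtypes with >= 3 samples each")
    X = cohort.data
    if panel_size > X.shape[1]:
        log.warning("panel_size %d > %d available metabolites: capped",
                    panel_size, X.shape[1])
        panel_size = X.shape[1]

    h_scores = {}
    for col in X.columns:
        groups = [X.loc[labels == s, col].to_numpy() for s in counts.index]
        if np.allclose(X[col], X[col].iloc[0]):
            h_scores[col] = 0.0
            continue
        try:
            h, _ = stats.kruskal(*groups)
        except ValueError:  # all values identical across groups
            h = 0.0
        h_scores[col] = float(h)
    ranked = sorted(X.columns, key=lambda c: (-h_scores[c], c))
    panel = list(ranked[:panel_size])

    sub = X[panel]
    means = sub.mean()
    sds = sub.std(ddof=0).replace(0.0, 1.0)
    Z = (sub - means) / sds
    centroids = Z.groupby(labels).median().sort_index()
    centroids.index.name = "subtype"
    return CentroidClassifier(
        compartment=cohort.compartment,
        panel=panel,
        centroids=centroids,
        feature_means=means,
        feature_sds=sds,
        feature_medians=sub.median(),
    )


def assign(
    classifier: CentroidClassifier,
    profile: pd.Series,
    min_coverage: float = 0.8,
) -> tuple[str, pd.Series]:
    """Assign one sample profile to the nearest subtype centroid.

    Missing panel features are imputed at the training median (logged);
    coverage below `min_coverage` of the panel is an error.  Ties go to the
    lower subtype index.  Returns (label, distances).
    """
    panel = classifier.panel
    present = [m for m in panel if m in profile.index and pd.notna(profile.get(m))]
    coverage = len(present) / len(panel)
    if coverage < min_coverage:
        raise ValueError(
            f"profile covers {coverage:.0%} of the panel (< {min_coverage:.0%})"
        )
    x = profile.reindex(panel)
    n_missing = int(x.isna().sum())
    if n_missing:
        log.info("imputing %d missing panel feature(s) at training median",
                 n_missing)
        x = x.fillna(classifier.feature_medians)
    z = (x - classifier.feature_means) / classifier.feature_sds
    diffs = classifier.centroids.to_numpy(dtype=float) - z.to_numpy(dtype=float)
    dists = pd.Series(np.sqrt((diffs**2).sum(axis=1)),
                      index=classifier.subtypes)
    # ties break toward the smaller subtype index (sorted label order)
    best = dists.index[np.argmin(dists.to_numpy())]
    return str(best), dists


def assign_cohort(
    classifier: CentroidClassifier,
    cohort: CohortMatrix,
    min_coverage: float = 0.8,
) -> SubtypeAssignment:
    labels = {}
    for sid in cohort.data.index:
        labels[sid], _ = assign(classifier, cohort.data.loc[sid], min_coverage)
    return SubtypeAssignment(labels=pd.Series(labels, name="subtype"),
                             compartment=classifier.compartment)


def response_association(
    assignment: SubtypeAssignment,
    response: pd.Series,
) -> dict:
    """Resistant proportion per subtype + all pairwise 2x2 Fisher tests.

    `response` maps sample id -> 'sensitive' / 'resistant'.  Subtypes without
    any assigned patient are excluded (logged).
    """
    common = assignment.labels.index.intersection(response.index)
    labels = assignment.labels.loc[common]
    resp = response.loc[common]
    counts = pd.crosstab(labels, resp).reindex(
        columns=["resistant", "sensitive"], fill_value=0)
    counts.columns.name = None
    present = counts.sum(axis=1) > 0
    if (~present).any():
        log.info("subtype(s) %s excluded: no assigned patients",
                 list(counts.index[~present]))
    counts = counts[present]
    if len(counts) < 2:
        raise ValueError("need responses in >= 2 assigned subtypes")
    props = counts["resistant"] / counts.sum(axis=1)
    rows = []
    for g1, g2 in combinations(counts.index, 2):
        table = counts.loc[[g1, g2]].to_numpy()
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"group1": g1, "group2": g2, "p": float(p)})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"counts": counts, "proportion_resistant": props, "pairwise": pairwise}


def nac_outcome_models(
    assignment: SubtypeAssignment,
    clinical: pd.DataFrame,
    reference: str | None = None,
) -> dict:
    """Pairwise log-rank across assigned subtypes plus a multivariate Cox fit
    with subtype indicators, MPR and UICC stage."""
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    common = assignment.labels.index.intersection(clin.index)
    labels = assignment.labels.loc[common]
    groups = {
        s: (clin.loc[labels.index[labels == s], "time"].to_numpy(float),
            clin.loc[labels.index[labels == s], "event"].to_numpy(int))
        for s in sorted(labels.unique())
    }
    lr = pairwise_logrank(groups) if len(groups) >= 2 else pd.DataFrame()
    design, times, events = subtype_design(
        assignment, clinical, include_stage=True, include_mpr=True,
        reference=reference,
    )
    # drop all-zero indicator columns (levels absent in the overlap)
    design = design.loc[:, (design != 0).any()]
    cox: CoxResults = cox_fit(design, times, events)
    return {"pairwise_logrank": lr, "cox": cox}
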