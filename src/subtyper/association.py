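"""Subtype characterization: immunomarker correlation and contingency tests.

Per-subtype marker association uses one-vs-rest indicator coding: for each
subtype the membership indicator (1 = member) is correlated with each marker
by Spearman's rank-order correlation (mid-rank ties, two-sided p via the
t approximation), then Benjamini-Hochberg adjusted across the whole
subtype x marker family of a compartment.  Group differences per marker use
the tie-corrected Kruskal-Wallis test with post hoc Dunn pairwise z tests
(BH over pairs).  Clinicopathological columns are tested subtype-vs-category
by chi-square, or an exact test when expected counts are small: Fisher's
exact test for 2x2 tables and a Freeman-Halton enumeration for larger tables
up to a table-count cap.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import SubtypeAssignment

log = logging.getLogger("subtyper.association")


# ---------------------------------------------------------------------------
# subtype <-> marker correlation
# ---------------------------------------------------------------------------

def subtype_marker_correlation(
    assignment: SubtypeAssignment,
    markers: pd.DataFrame,
    marker_cols: list[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest Spearman correlation of subtype membership with markers.

    Returns a tidy frame (subtype, marker, rho, p, q); q is BH-adjusted over
    all subtype x marker pairs.  Constant indicators or markers yield
    rho = NaN and are excluded from the BH family.
    """
    marker_cols = marker_cols or [c for c in markers.columns if c != "patient_id"]
    m = markers.set_index("patient_id") if "patient_id" in markers.columns else markers
    common = assignment.labels.index.intersection(m.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples with marker values")
    labels = assignment.labels.loc[common]
    rows = []
    for subtype in assignment.subtypes:
        indicator = (labels == subtype).astype(int)
        for marker in marker_cols:
            vals = m.loc[common, marker].astype(float)
            ok = vals.notna()
            if indicator[ok].nunique() < 2 or vals[ok].nunique() < 2:
                rows.append({"subtype": subtype, "marker": marker,
                             "rho": np.nan, "p": np.nan})
                continue
            rho, p = stats.spearmanr(indicator[ok], vals[ok])
            rows.append({"subtype": subtype, "marker": marker,
                         "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    valid = out["p"].notna()
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: dict[str, np.ndarray]) -> dict:
    """Tie-corrected Kruskal-Wallis H plus post hoc Dunn pairwise tests.

    Dunn's z uses pooled mid-ranks with the tie correction
    sigma^2_ij = (N(N+1)/12 - sum(t^3 - t)/(12(N-1))) (1/n_i + 1/n_j);
    pairwise p-values are two-sided normal and BH-adjusted.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return {"H": 0.0, "p": 1.0,
                "pairwise": pd.DataFrame(columns=["group1", "group2", "z", "p", "q"])}
    H, p = stats.kruskal(*arrays)

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    splits = np.cumsum([len(a) for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = {g: r.mean() for g, r in zip(names, group_ranks)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (N - 1))
    rows = []
    for g1, g2 in combinations(names, 2):
        n1, n2 = len(groups[g1]), len(groups[g2])
        var = (N * (N + 1) / 12 - tie_term) * (1 / n1 + 1 / n2)
        z = (mean_ranks[g1] - mean_ranks[g2]) / math.sqrt(var)
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p": 2 * stats.norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"H": float(H), "p": float(p), "pairwise": pairwise}


# ---------------------------------------------------------------------------
# exact tests on contingency tables
# ---------------------------------------------------------------------------

def fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Two-sided Fisher(-Freeman-Halton) exact p for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables at most as probable as the observed one
    (with a 1e-7 relative tolerance).  Raises if the enumeration would
    exceed `max_tables`.
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()

    def log_prob(t: np.ndarray) -> float:
        # multivariate hypergeometric log-probability of a full table
        lp = (sum(math.lgamma(r + 1) for r in row_sums)
              + sum(math.lgamma(c + 1) for c in col_sums)
              - math.lgamma(n + 1)
              - sum(math.lgamma(x + 1) for x in t.ravel()))
        return lp

    obs_lp = log_prob(table)
    r, c = table.shape
    total = 0.0
    count = 0

    def recurse(cells: list[int], row: int, col: int, rem_row: np.ndarray,
                rem_col: np.ndarray) -> None:
        nonlocal total, count
        if count > max_tables:
            raise RuntimeError("table enumeration cap exceeded")
        if row == r - 1:
            # last row fully determined by column margins
            last = rem_col.copy()
            if (last < 0).any():
                return
            t = np.array(cells + list(last)).reshape(r, c)
            count += 1
            lp = log_prob(t)
            if lp <= obs_lp + 1e-7:
                total += math.exp(lp)
            return
        if col == c - 1:
            v = rem_row[row]
            if v < 0 or v > rem_col[col]:
                return
            nr = rem_row.copy(); nr[row] = 0
            nc = rem_col.copy(); nc[col] -= v
            recurse(cells + [v], row + 1, 0, nr, nc)
            return
        hi = min(rem_row[row], rem_col[col])
        for v in range(hi + 1):
            nr = rem_row.copy(); nr[row] -= v
            nc = rem_col.copy(); nc[col] -= v
            recurse(cells + [v], row, col + 1, nr, nc)

    recurse([], 0, 0, row_sums.copy(), col_sums.copy())
    return min(1.0, total)


def clinicopath_tests(
    assignment: SubtypeAssignment,
    clinical: pd.DataFrame,
    columns: list[str],
    exact_cell_cap: int = 200_000,
) -> pd.DataFrame:
    """Subtype x clinical-category contingency tests, one row per column.

    Chi-square by default; when any expected cell count is < 5, a Fisher
    exact test is used (scipy for 2x2; Freeman-Halton enumeration for larger
    tables up to `exact_cell_cap` candidate tables, else chi-square with a
    warning).  Single-level columns are skipped with a message.
    """
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    common = assignment.labels.index.intersection(clin.index)
    labels = assignment.labels.loc[common]
    rows = []
    for col in columns:
        series = clin.loc[common, col].dropna()
        if series.nunique() < 2:
            log.info("column %s skipped: fewer than 2 levels", col)
            rows.append({"column": col, "test": "skipped", "p": np.nan,
                         "note": "single level"})
            continue
        table = pd.crosstab(labels.loc[series.index], series).to_numpy()
        chi2, p_chi2, _, expected = stats.chi2_contingency(table)
        if (expected < 5).any():
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table, alternative="two-sided")
                rows.append({"column": col, "test": "fisher", "p": float(p),
                             "note": ""})
                continue
            try:
                p = fisher_exact_rxc(table, max_tables=exact_cell_cap)
                rows.append({"column": col, "test": "fisher_freeman_halton",
                             "p": float(p), "note": ""})
                continue
            except RuntimeError:
                log.warning("column %s: exact enumeration too large; "
                            "falling back to chi-square", col)
                rows.append({"column": col, "test": "chi2", "p": float(p_chi2),
                             "note": "expected<5, enumeration capped"})
                continue
        rows.append({"column": col, "test": "chi2", "p": float(p_chi2),
                     "note": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tumor x stroma crosstab
# ---------------------------------------------------------------------------

def crosstab_subtypes(
    tumor: SubtypeAssignment,
    stroma: SubtypeAssignment,
) -> pd.DataFrame:
    """Contingency of tumor-subtype x stroma-subtype co-membership over the
    patients present in both compartments."""
    common = tumor.labels.index.intersection(stroma.labels.index)
    if len(common) == 0:
        raise ValueError("no patients with both tumor and stroma subtypes")
    return pd.crosstab(tumor.labels.loc[common], stroma.labels.loc[common],
                       rownames=["tumor"], colnames=["stroma"])
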