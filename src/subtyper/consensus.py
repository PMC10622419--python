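"""Resampling consensus clustering with CDF delta-area model selection.

The central computation of the package.  For each resampling iteration a
random 80% subset of samples is drawn and hierarchically clustered
(average linkage on the correlation distance 1 - Pearson); cutting the same
tree at every K in the candidate range yields, per K, a consensus matrix

    M_K(i, j) = (#iterations i and j co-clustered) / (#iterations both drawn).

The empirical CDF of the consensus values summarizes cluster stability; the
area under the CDF as a function of K, and its relative increase
Delta(K) = (A(K) - A(K-1)) / A(K-1), drive the elbow rule that picks the
number of subtypes: K* is the largest K whose relative increase still
exceeds a threshold tau.  Final subtype labels come from average-linkage
clustering of the distance 1 - M_{K*}, renumbered by descending cluster
size (T1..Tk / S1..Sk convention).

`ConsensusClustering` is the model object; `fit()` returns a
:class:`ConsensusResult` with every per-K artifact and a `summary()` table.
The module-level functions are the individual operations, usable directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .io import CohortMatrix

log = logging.getLogger("subtyper.consensus")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def subsample(
    n_samples: int,
    fraction: float = 0.8,
    rng: np.random.Generator | None = None,
    k: int | None = None,
) -> np.ndarray:
    """Uniform subset of floor(fraction * n) distinct indices, sorted."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = rng or np.random.default_rng()
    size = int(np.floor(fraction * n_samples))
    if k is not None and size < k:
        raise ValueError(
            f"subsample of {size} samples cannot support K={k} clusters"
        )
    return np.sort(rng.choice(n_samples, size=size, replace=False))


def pearson_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between sample rows.

    A zero-variance (constant) sample has undefined correlation; its distance
    to every other sample is defined as 1 (and 0 to itself), logged.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant sample(s): distance to them set to 1",
                    int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.corrcoef(X)
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    # numerical guard: tiny negatives from corrcoef rounding
    return np.clip(D, 0.0, 2.0)


def base_cluster(X: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative clustering of sample rows: average linkage on
    1 - Pearson, tree cut at `k` clusters.  Returns 0-based labels."""
    n = len(X)
    if n < k:
        raise ValueError(f"{n} samples cannot form {k} clusters")
    D = pearson_distance(X)
    Z = linkage(squareform(D, checks=False), method="average")
    return cut_tree(Z, n_clusters=k).ravel()


def consensus_matrix(
    runs: list[tuple[np.ndarray, np.ndarray]],
    n_samples: int,
) -> np.ndarray:
    """Consensus matrix from logged (subset, labels) iteration outputs.

    M(i, j) = co-clustered count / co-sampled count; pairs never co-sampled
    get M = 0 with a warning; the diagonal is forced to 1.
    """
    if not runs:
        raise ValueError("need at least one iteration")
    co = np.zeros((n_samples, n_samples))
    both = np.zeros((n_samples, n_samples))
    for subset, labels in runs:
        subset = np.asarray(subset)
        labels = np.asarray(labels)
        both[np.ix_(subset, subset)] += 1
        for lab in np.unique(labels):
            idx = subset[labels == lab]
            co[np.ix_(idx, idx)] += 1
    never = both == 0
    np.fill_diagonal(never, False)
    if never.any():
        log.warning("%d sample pair(s) never co-sampled: consensus set to 0",
                    int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(both > 0, co / np.maximum(both, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    return M


def consensus_cdf(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of the upper-triangle consensus values and its area.

    Returns (values, cdf, area): `values` are the sorted unique consensus
    entries, `cdf[i]` the fraction of entries <= values[i], and `area` the
    left Riemann sum of the CDF over [0, 1].
    """
    entries = M[np.triu_indices_from(M, k=1)]
    values, counts = np.unique(entries, return_counts=True)
    cdf = np.cumsum(counts) / entries.size
    # left Riemann sum over the grid of unique values extended to 1.0
    grid = np.append(values, 1.0)
    area = float(np.sum(cdf * np.diff(grid)))
    return values, cdf, area


def delta_areas(areas: dict[int, float]) -> dict[int, float]:
    """Relative change in CDF area: Delta(Kmin)=A(Kmin); thereafter
    Delta(K) = (A(K) - A(K-1)) / A(K-1)."""
    ks = sorted(areas)
    deltas = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
    return deltas


def select_k(areas: dict[int, float], tau: float = 0.1) -> tuple[int, dict[int, float]]:
    """Elbow rule on the delta-area curve.

    K* is the largest K whose relative area increase is still >= tau; if no K
    qualifies, K* falls back to the smallest K (with a warning).  Returns
    (K*, deltas).
    """
    if len(areas) < 3:
        raise ValueError("need at least 3 K values to select K")
    deltas = delta_areas(areas)
    qualifying = [k for k, d in deltas.items() if d >= tau]
    if not qualifying:
        log.warning("no K reaches delta >= %.3g; falling back to K=%d",
                    tau, min(areas))
        return min(areas), deltas
    return max(qualifying), deltas


def final_labels(M: np.ndarray, k: int) -> np.ndarray:
    """Cluster samples on the consensus distance 1 - M (average linkage, cut
    at `k`) and renumber clusters 0..k-1 by descending size (ties broken by
    smallest member index)."""
    n = len(M)
    if k > n:
        raise ValueError("K exceeds the number of samples")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(np.clip(D, 0, None), checks=False), method="average")
    raw = cut_tree(Z, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda lab: (-int(np.sum(raw == lab)), int(np.argmax(raw == lab))),
    )
    remap = {lab: i for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


def assignment_summary(labels: pd.Series) -> pd.DataFrame:
    """Per-subtype counts and integer percentages.

    Percentages use largest-remainder rounding so they always sum to 100
    (plain nearest-integer rounding can sum to 99 or 101).
    """
    if len(labels) == 0:
        raise ValueError("empty assignment")
    counts = labels.value_counts().sort_index()
    exact = 100 * counts.to_numpy() / counts.sum()
    floors = np.floor(exact).astype(int)
    remainder = exact - floors
    short = 100 - floors.sum()
    order = np.argsort(-remainder, kind="stable")
    pct = floors.copy()
    pct[order[:short]] += 1
    return pd.DataFrame({"count": counts, "percent": pct})


def separation_score(cohort: CohortMatrix, labels: np.ndarray) -> float:
    """Mean silhouette over samples on the 1 - Pearson distance.

    Samples in singleton clusters contribute silhouette 0 (logged).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("separation score needs >= 2 subtypes")
    D = pearson_distance(cohort.data.to_numpy())
    sizes = pd.Series(labels).value_counts()
    singletons = sizes[sizes == 1].index
    if len(singletons):
        log.info("%d singleton cluster(s): silhouette 0 for their samples",
                 len(singletons))
        keep = ~np.isin(labels, singletons)
        if keep.sum() == 0 or len(np.unique(labels[keep])) < 2:
            return 0.0
        s = np.zeros(len(labels))
        s[keep] = silhouette_samples(D[np.ix_(keep, keep)], labels[keep],
                                     metric="precomputed")
        return float(s.mean())
    return float(silhouette_samples(D, labels, metric="precomputed").mean())


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class SubtypeAssignment:
    """sample id -> subtype label (e.g. T1..T4 / S1..S4)."""

    labels: pd.Series
    compartment: str

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.labels.unique())

    def summary(self) -> pd.DataFrame:
        return assignment_summary(self.labels)


@dataclass
class ConsensusResult:
    """Everything `ConsensusClustering.fit` computed, per K."""

    sample_ids: list[str]
    compartment: str
    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]]
    areas: dict[int, float]
    deltas: dict[int, float]
    k_selected: int
    assignment: SubtypeAssignment
    labels_by_k: dict[int, np.ndarray]
    seed: int | None = None
    runs: dict[int, list[tuple[np.ndarray, np.ndarray]]] | None = None

    def labels_for(self, k: int) -> pd.Series:
        prefix = "T" if self.compartment == "tumor" else "S"
        lab = self.labels_by_k[k]
        return pd.Series([f"{prefix}{v + 1}" for v in lab],
                         index=self.sample_ids, name="subtype")

    def relabel(self, k: int) -> "SubtypeAssignment":
        """Manual override of the selected K."""
        return SubtypeAssignment(labels=self.labels_for(k),
                                 compartment=self.compartment)

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.k_range:
            rows.append({
                "K": k,
                "area": self.areas[k],
                "delta": self.deltas[k],
                "selected": k == self.k_selected,
            })
        return pd.DataFrame(rows).set_index("K")

    def to_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "k_range": self.k_range,
            "areas": {str(k): v for k, v in self.areas.items()},
            "deltas": {str(k): v for k, v in self.deltas.items()},
            "k_selected": self.k_selected,
            "labels": self.assignment.labels.to_dict(),
            "seed": self.seed,
        }


class ConsensusClustering:
    """Resampling consensus-clustering model for one compartment's cohort.

    Parameters
    ----------
    cohort : CohortMatrix
        Samples x metabolites; one compartment.
    k_range : iterable of int
        Candidate cluster numbers (default 2..10).
    fraction : float
        Subsampling fraction per iteration (default 0.8).
    n_iterations : int
        Number of resampling iterations (default 1000).
    tau : float
        Delta-area threshold of the elbow rule (default 0.1).

    Each iteration draws one subsample, builds one average-linkage tree on the
    1 - Pearson distance, and cuts it at every K; per-K consensus matrices
    therefore share the pair-sampling denominator.
    """

    def __init__(
        self,
        cohort: CohortMatrix,
        k_range: range | list[int] = range(2, 11),
        fraction: float = 0.8,
        n_iterations: int = 1000,
        tau: float = 0.1,
    ) -> None:
        self.cohort = cohort
        self.k_range = sorted(k_range)
        self.fraction = fraction
        self.n_iterations = n_iterations
        self.tau = tau
        n = len(cohort.data)
        if int(np.floor(fraction * n)) < max(self.k_range):
            raise ValueError(
                f"subsample of {int(np.floor(fraction * n))} samples cannot "
                f"support K={max(self.k_range)} clusters"
            )

    def fit(self, seed: int | None = None, keep_runs: bool = False) -> ConsensusResult:
        X = self.cohort.data.to_numpy(dtype=float)
        n = len(X)
        rng = np.random.default_rng(seed)
        D_full = pearson_distance(X)

        ks = self.k_range
        co = {k: np.zeros((n, n)) for k in ks}
        both = np.zeros((n, n))
        runs: dict[int, list] = {k: [] for k in ks} if keep_runs else None

        for _ in range(self.n_iterations):
            subset = subsample(n, self.fraction, rng, k=max(ks))
            Dsub = D_full[np.ix_(subset, subset)]
            Z = linkage(squareform(Dsub, checks=False), method="average")
            cuts = cut_tree(Z, n_clusters=ks)
            both[np.ix_(subset, subset)] += 1
            for col, k in enumerate(ks):
                labels = cuts[:, col]
                for lab in np.unique(labels):
                    idx = subset[labels == lab]
                    co[k][np.ix_(idx, idx)] += 1
                if keep_runs:
                    runs[k].append((subset.copy(), labels.copy()))

        never = both == 0
        np.fill_diagonal(never, False)
        if never.any():
            log.warning("%d pair(s) never co-sampled over %d iterations",
                        int(never.sum() // 2), self.n_iterations)

        matrices, cdfs, areas, labels_by_k = {}, {}, {}, {}
        for k in ks:
            with np.errstate(invalid="ignore"):
                M = np.where(both > 0, co[k] / np.maximum(both, 1), 0.0)
            np.fill_diagonal(M, 1.0)
            matrices[k] = M
            vals, cdf, area = consensus_cdf(M)
            cdfs[k] = (vals, cdf)
            areas[k] = area
            labels_by_k[k] = final_labels(M, k)

        k_star, deltas = select_k(areas, tau=self.tau)
        prefix = "T" if self.cohort.compartment == "tumor" else "S"
        final = pd.Series(
            [f"{prefix}{v + 1}" for v in labels_by_k[k_star]],
            index=self.cohort.sample_ids, name="subtype",
        )
        return ConsensusResult(
            sample_ids=self.cohort.sample_ids,
            compartment=self.cohort.compartment,
            k_range=ks,
            consensus_matrices=matrices,
            cdfs=cdfs,
            areas=areas,
            deltas=deltas,
            k_selected=k_star,
            assignment=SubtypeAssignment(labels=final,
                                         compartment=self.cohort.compartment),
            labels_by_k=labels_by_k,
            seed=seed,
            runs=runs,
        )


def run_consensus(
    cohort: CohortMatrix,
    k_range: range | list[int] = range(2, 11),
    fraction: float = 0.8,
    iters: int = 1000,
    seed: int | None = None,
    tau: float = 0.1,
    keep_runs: bool = False,
) -> ConsensusResult:
    """Functional entry point; see :class:`ConsensusClustering`."""
    model = ConsensusClustering(cohort, k_range=k_range, fraction=fraction,
                                n_iterations=iters, tau=tau)
    return model.fit(seed=seed, keep_runs=keep_runs)
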