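"""Partitioning Around Medoids and consensus clustering.

PAM is the classic BUILD + SWAP k-medoids: greedy seeding followed by
steepest-descent medoid/non-medoid swaps until no swap lowers the total
within-cluster dissimilarity. Consensus clustering repeats the base
clusterer on item subsamples and aggregates co-assignment proportions; the
empirical CDF of the consensus entries and its area increments drive the
choice of k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

from .containers import TMEScoreError, warn

__all__ = [
    "PAMResult",
    "ConsensusResult",
    "pam_cluster",
    "PAM",
    "consensus_cluster",
    "ConsensusCluster",
    "crosstab_association",
]


@dataclass
class PAMResult:
    medoid_indices: np.ndarray
    labels: np.ndarray
    total_cost: float


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise TMEScoreError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise TMEScoreError("dissimilarity matrix must be symmetric")
    if (D < -1e-12).any():
        raise TMEScoreError("dissimilarity matrix must be non-negative")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise TMEScoreError("dissimilarity matrix must have a zero diagonal")
    return D


def pam_cluster(dissimilarity, k: int, seed: int = 0) -> PAMResult:
    """k-medoids by BUILD + steepest-descent SWAP.

    Deterministic given the input order; ``seed`` is accepted for API
    uniformity but the algorithm itself has no random component.
    """
    D = _check_dissimilarity(dissimilarity)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise TMEScoreError(f"k={k} out of range for n={n}")

    # BUILD: start with the 1-medoid optimum, then add the point giving the
    # largest cost reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        d_near = np.minimum(d_near, D[h])

    medoids = np.array(medoids)
    # SWAP: evaluate all (medoid, candidate) swaps, apply the best strictly
    # improving one per pass.
    while True:
        Dm = D[medoids]  # k x n
        order = np.argsort(Dm, axis=0)
        near = order[0]                      # index into medoids
        d1 = Dm[near, np.arange(n)]
        if k > 1:
            d2 = Dm[order[1], np.arange(n)]
        else:
            d2 = np.full(n, np.inf)
        best_delta, best_swap = 0.0, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            owned = near == mi
            # candidate h replaces medoid mi: owned points fall back to
            # min(second-nearest, d(.,h)); others to min(nearest, d(.,h))
            alt = np.where(owned, np.minimum(d2, D.T), np.minimum(d1, D.T))  # n(h) x n(j)
            deltas = alt.sum(axis=1) - d1.sum()
            for h in non_medoids:
                if deltas[h] < best_delta - 1e-12:
                    best_delta, best_swap = deltas[h], (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    Dm = D[medoids]
    near = np.argmin(Dm, axis=0)
    cost = float(Dm[near, np.arange(n)].sum())
    return PAMResult(medoid_indices=medoids.copy(), labels=near, total_cost=cost)


class PAM:
    """sklearn-style PAM clusterer.

    ``metric='euclidean'`` computes pairwise distances from a feature
    matrix; ``metric='precomputed'`` expects a dissimilarity matrix.
    """

    def __init__(self, n_clusters: int = 2, metric: str = "euclidean", random_state: int = 0):
        self.n_clusters = n_clusters
        self.metric = metric
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"n_clusters": self.n_clusters, "metric": self.metric, "random_state": self.random_state}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        D = X if self.metric == "precomputed" else squareform(pdist(X))
        res = pam_cluster(D, self.n_clusters, seed=self.random_state)
        self.medoid_indices_ = res.medoid_indices
        self.labels_ = res.labels
        self.inertia_ = res.total_cost
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]  # (grid, CDF values)
    delta_area: dict[int, float]
    selected_k: int

    def labels_for(self, k: int | None = None) -> np.ndarray:
        return self.labels[self.selected_k if k is None else k]


def _base_labels(D: np.ndarray, k: int, base: str, seed: int) -> np.ndarray:
    if base == "pam":
        return pam_cluster(D, k, seed=seed).labels
    if base == "hierarchical":
        condensed = squareform(np.maximum(D, 0.0), checks=False)
        Z = linkage(condensed, method="average")
        return fcluster(Z, k, criterion="maxclust") - 1
    raise TMEScoreError(f"unknown base clusterer {base!r}")


def _distance_matrix(X: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return squareform(pdist(X))
    if distance == "one_minus_pearson":
        C = np.corrcoef(X)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)
    raise TMEScoreError(f"unknown distance {distance!r}")


def consensus_cluster(
    features,
    k_values=(2, 3, 4, 5, 6),
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    base: str = "pam",
    distance: str = "euclidean",
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering over item subsamples.

    For each k, ``n_resamples`` subsamples of ``ceil(item_fraction * n)``
    items are clustered; consensus[i, j] is the fraction of co-sampled runs
    in which i and j co-clustered. Final labels come from clustering
    (1 - consensus) with the same base method. k is selected as the value
    maximising the relative increment of the area under the consensus CDF
    (the first k on the list takes its full area), ties toward smaller k.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    k_values = [int(k) for k in k_values]
    if n_resamples < 2:
        raise TMEScoreError("n_resamples must be >=2")
    if not 0 < item_fraction <= 1:
        raise TMEScoreError("item_fraction must be in (0, 1]")
    if max(k_values) > n:
        raise TMEScoreError("k exceeds the number of items")
    D = _distance_matrix(X, distance)
    m = int(np.ceil(item_fraction * n))
    rng = np.random.default_rng(seed)

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    grid = np.linspace(0.0, 1.0, 101)
    for k in k_values:
        hits = np.zeros((n, n))
        tries = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            sub_labels = _base_labels(D[np.ix_(idx, idx)], k, base, seed)
            eq = (sub_labels[:, None] == sub_labels[None, :]).astype(float)
            hits[np.ix_(idx, idx)] += eq
            tries[np.ix_(idx, idx)] += 1.0
        never = (tries == 0) & ~np.eye(n, dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(tries > 0, hits / np.maximum(tries, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0

        lab = _base_labels(1.0 - M, k, base, seed)
        if never.any():
            warn(f"consensus k={k}: {int(never.sum()) // 2} item pairs never co-sampled; imputed from final labels")
            same = lab[:, None] == lab[None, :]
            M[never] = same[never].astype(float)
        consensus[k] = M
        labels[k] = lab

        tri = M[np.triu_indices(n, k=1)]
        cdf_vals = np.searchsorted(np.sort(tri), grid, side="right") / tri.size
        cdfs[k] = (grid, cdf_vals)
        areas[k] = float(np.trapezoid(cdf_vals, grid))

    delta: dict[int, float] = {}
    prev = None
    for k in k_values:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = max(0.0, (areas[k] - areas[prev]) / areas[prev]) if areas[prev] > 0 else 0.0
        prev = k
    selected_k = max(k_values, key=lambda k: (delta[k], -k))
    return ConsensusResult(
        k_values=k_values, consensus=consensus, labels=labels,
        cdf=cdfs, delta_area=delta, selected_k=selected_k,
    )


class ConsensusCluster:
    """sklearn-style wrapper around :func:`consensus_cluster`.

    Fitted attributes: ``labels_`` (at the selected k), ``selected_k_``,
    ``consensus_``, ``delta_area_``, ``result_``.
    """

    def __init__(
        self,
        k_values=(2, 3, 4, 5, 6),
        n_resamples: int = 1000,
        item_fraction: float = 0.8,
        base: str = "pam",
        distance: str = "euclidean",
        random_state: int = 0,
    ):
        self.k_values = k_values
        self.n_resamples = n_resamples
        self.item_fraction = item_fraction
        self.base = base
        self.distance = distance
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "k_values": self.k_values, "n_resamples": self.n_resamples,
            "item_fraction": self.item_fraction, "base": self.base,
            "distance": self.distance, "random_state": self.random_state,
        }

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        res = consensus_cluster(
            X, k_values=self.k_values, n_resamples=self.n_resamples,
            item_fraction=self.item_fraction, base=self.base,
            distance=self.distance, seed=self.random_state,
        )
        self.result_ = res
        self.selected_k_ = res.selected_k
        self.labels_ = res.labels[res.selected_k]
        self.consensus_ = res.consensus[res.selected_k]
        self.delta_area_ = res.delta_area
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def crosstab_association(labels_a, labels_b):
    """Pearson chi-square association between two labelings.

    Returns ``(chi2, p, table)`` where ``table`` is the contingency count
    DataFrame. Categories with a zero margin are dropped with a warning.
    """
    a = pd.Series(np.asarray(labels_a))
    b = pd.Series(np.asarray(labels_b))
    if len(a) != len(b):
        raise TMEScoreError("label vectors must have equal length")
    table = pd.crosstab(a, b)
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        warn("dropping zero-margin categories from the contingency table")
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise TMEScoreError("chi-square test needs >=2 categories in each labeling")
    chi2, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table
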