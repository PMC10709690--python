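"""Temporal co-expression clustering of the cytokine kinetics experiment.

Differentially expressed genes are row-standardized and partitioned with
seeded k-means (Lloyd, k-means++ init, multiple restarts); per-cluster mean
profiles with 90% confidence intervals summarize the temporal behaviour,
and a Spearman sample-correlation matrix with average-linkage ordering
provides the replicate/condition QC view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm, spearmanr
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterResult",
    "ClusterProfile",
    "zscore_rows",
    "kmeans_cluster",
    "choose_k",
    "cluster_profile",
    "sample_correlation_matrix",
]


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster label in 1..k
    k: int
    centroids: np.ndarray  # k x n_samples
    seed: int
    inertia: float

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])


@dataclass
class ClusterProfile:
    """Per (cluster, sample-group) mean expression with a 90% CI."""

    table: pd.DataFrame  # columns: cluster, group, mean, ci_low, ci_high, n_genes


def zscore_rows(m: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardize each row to mean 0, sd 1 (population sd).

    Constant rows map to all-zeros with a warning rather than NaN so that
    flat genes do not poison downstream distance computations.
    """
    values = np.asarray(m, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 columns to z-score rows")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant rows mapped to zeros")
    sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(z, index=m.index, columns=m.columns)
    return z


def kmeans_cluster(
    m: pd.DataFrame | np.ndarray,
    k: int,
    seed: int,
    restarts: int = 25,
) -> ClusterResult:
    """Seeded k-means (Lloyd) with k-means++ initialization and ``restarts``
    random restarts; the best-inertia solution is returned with cluster
    labels in 1..k."""
    values = np.asarray(m, dtype=float)
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {values.shape[0]}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts,
        algorithm="lloyd", random_state=seed,
    ).fit(values)
    index = m.index if isinstance(m, pd.DataFrame) else pd.RangeIndex(values.shape[0])
    assignments = pd.Series(km.labels_ + 1, index=index, name="cluster")
    return ClusterResult(assignments, k, km.cluster_centers_, seed, float(km.inertia_))


def choose_k(
    m: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(2, 13),
    seed: int = 0,
    restarts: int = 10,
    margin: float = 0.10,
) -> int:
    """Pick k by average silhouette width over ``k_range`` with a parsimony
    margin: the smallest k whose silhouette is within ``margin`` of the
    best is returned, so unstructured data (where silhouettes drift within
    noise of each other) falls back to the smallest k rather than chasing
    spurious splits.  A k_range of length 1 is returned as-is (the analysis
    configuration may force a specific k)."""
    ks = list(k_range)
    if len(ks) == 1:
        return ks[0]
    values = np.asarray(m, dtype=float)
    sils: dict[int, float] = {}
    for k in ks:
        if k >= values.shape[0]:
            continue
        labels = KMeans(
            n_clusters=k, n_init=restarts, algorithm="lloyd", random_state=seed
        ).fit_predict(values)
        if len(np.unique(labels)) < 2:
            continue
        sils[k] = silhouette_score(values, labels)
    if not sils:
        return ks[0]
    best = max(sils.values())
    return min(k for k, s in sils.items() if s >= best - margin)


def cluster_profile(
    m: pd.DataFrame,
    cr: ClusterResult,
    groups: dict[str, list[str]] | pd.Series,
    ci_level: float = 0.90,
) -> ClusterProfile:
    """Per-cluster mean expression and normal-approximation CI per sample
    group (default 90%: mean +/- 1.645 * sd / sqrt(n_genes)).

    ``groups`` maps a group name to its sample columns (replicates of one
    condition/day cell), or is a per-sample Series of group labels.
    Singleton clusters collapse to zero-width intervals with a warning.
    """
    if isinstance(groups, pd.Series):
        grouping = {g: list(groups.index[groups == g]) for g in groups.unique()}
    else:
        grouping = dict(groups)
    z = float(norm.ppf(0.5 + ci_level / 2.0))
    rows = []
    for cluster in range(1, cr.k + 1):
        genes = cr.members(cluster)
        if not genes:
            continue
        if len(genes) == 1:
            warnings.warn(f"cluster {cluster} has a single gene; CI width is 0")
        for group, samples in grouping.items():
            per_gene = m.loc[genes, samples].mean(axis=1).to_numpy()
            mean = float(per_gene.mean())
            sd = float(per_gene.std(ddof=1)) if len(per_gene) > 1 else 0.0
            half = z * sd / np.sqrt(len(per_gene))
            rows.append(
                dict(cluster=cluster, group=group, mean=mean,
                     ci_low=mean - half, ci_high=mean + half,
                     n_genes=len(per_gene))
            )
    return ClusterProfile(pd.DataFrame(rows))


def sample_correlation_matrix(
    m: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation between samples plus an average-linkage
    dendrogram ordering on the 1 - rho distance.

    Constant samples have undefined rank correlation; their entries are
    recorded as 0 with a warning.  Returns (correlation matrix, leaf order).
    """
    if method != "spearman":
        raise ValueError("only spearman correlation is supported")
    if m.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    values = np.asarray(m, dtype=float)
    rho = spearmanr(values, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        warnings.warn("constant sample(s): undefined correlations recorded as 0")
        rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    corr = pd.DataFrame(rho, index=m.columns, columns=m.columns)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [m.columns[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order
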