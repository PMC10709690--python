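"""SVD attribution of a weak genotype effect in expression data.

The centered (per-gene mean-subtracted) regularized-log expression matrix
is decomposed by thin SVD.  Each sample-side component (right-singular
vector) is modelled three ways — condition + genotype, condition only,
genotype only — and compared by AIC and likelihood-ratio chi-squared tests;
the component attributable to the conditional knockout is the one whose
genotype term is indispensable and whose sample scores diverge in sign
between knockout and control.  Gene-side loadings of that component are
split by sign and 1-D k-means (k = 2) keeps the most extreme cluster per
sign as the affected gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleDesign
from .kinetics_clustering import ClusterResult, kmeans_cluster

__all__ = [
    "SvdDecomposition",
    "ComponentModelFit",
    "ComponentSelection",
    "SelectionOutcome",
    "center_and_decompose",
    "fit_component_models",
    "select_component",
    "partition_left_vectors",
    "foldchange_cluster",
    "attribute_genotype_effect",
]


@dataclass
class SvdDecomposition:
    gene_ids: list[str]
    sample_ids: list[str]
    left_vectors: np.ndarray      # genes x components (gene loadings)
    singular_values: np.ndarray   # descending, >= 0
    right_vectors: np.ndarray     # samples x components (sample scores)

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def variance_fraction(self) -> np.ndarray:
        s2 = np.square(self.singular_values)
        return s2 / s2.sum()

    def reconstruct(self) -> np.ndarray:
        return self.left_vectors @ np.diag(self.singular_values) @ self.right_vectors.T


@dataclass
class ComponentModelFit:
    component: int
    aic_full: float
    aic_condition_only: float
    aic_genotype_only: float
    anova_p_vs_condition_only: float
    anova_p_vs_genotype_only: float
    padj: float
    sign_divergent: bool


class SelectionOutcome(NamedTuple):
    component: int
    weak: bool


@dataclass
class ComponentSelection:
    chosen_component: int
    positive_gene_set: set[str]
    negative_gene_set: set[str]
    gene_effect: pd.Series  # signed left-vector loading per gene
    weak: bool = False
    variance_fraction: float = float("nan")


def center_and_decompose(m: pd.DataFrame, design: SampleDesign) -> SvdDecomposition:
    """Thin SVD of the row-centered expression matrix.

    Components are oriented so the control (flox) samples' mean score is at
    least the knockout (cre) samples' mean score, removing the SVD sign
    indeterminacy; with a single genotype the orientation is left as
    returned by the decomposition.
    """
    values = np.asarray(m, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    centered = values - values.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("matrix is constant per gene; nothing to decompose")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T  # samples x components

    genotypes = design.column("genotype", list(m.columns))
    flox = genotypes == "flox"
    cre = genotypes == "cre"
    if flox.any() and cre.any():
        for j in range(v.shape[1]):
            if v[flox, j].mean() < v[cre, j].mean():
                v[:, j] *= -1.0
                u[:, j] *= -1.0
    return SvdDecomposition(list(m.index), list(m.columns), u, s, v)


def _ols_fit(y: np.ndarray, x: np.ndarray) -> tuple[float, int, float]:
    """Gaussian OLS: (log-likelihood at the MLE, n mean parameters, RSS)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = max(float(resid @ resid), 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    return loglik, int(np.linalg.matrix_rank(x)), rss


def _design_matrices(design: SampleDesign, sample_ids: list[str]):
    cond = pd.get_dummies(pd.Categorical(design.column("condition", sample_ids)),
                          drop_first=True).to_numpy(dtype=float)
    geno = pd.get_dummies(pd.Categorical(design.column("genotype", sample_ids)),
                          drop_first=True).to_numpy(dtype=float)
    ones = np.ones((len(sample_ids), 1))
    x_full = np.hstack([ones, cond, geno])
    x_cond = np.hstack([ones, cond])
    x_geno = np.hstack([ones, geno])
    return x_full, x_cond, x_geno


def fit_component_models(
    svd: SvdDecomposition, design: SampleDesign
) -> list[ComponentModelFit]:
    """Fit the full / condition-only / genotype-only linear models to each
    right-singular vector.

    AIC = 2k - 2 logL with Gaussian errors (k counts mean parameters plus
    the variance).  Nested models are compared by a chi-squared test on the
    scaled residual-sum-of-squares difference, (RSS_reduced - RSS_full) /
    sigma2_full with df equal to the parameter difference — the convention
    of R's ``anova(..., test = "Chisq")`` for linear models, which is far
    better calibrated at small sample counts than the raw likelihood-ratio
    statistic.  P-values of the full-vs-condition-only comparison (the
    genotype term) are BH adjusted across components.  ``sign_divergent``
    records whether the knockout and control mean sample scores have
    opposite signs AND are separated by more than the standard error of
    their difference, so noise fluctuating around zero does not count as
    divergence.
    """
    sample_ids = svd.sample_ids
    conditions = design.column("condition", sample_ids)
    genotypes = design.column("genotype", sample_ids)
    for cond in np.unique(conditions):
        for geno in np.unique(genotypes):
            if not np.any((conditions == cond) & (genotypes == geno)):
                raise ValueError(f"empty design cell: condition={cond}, genotype={geno}")

    x_full, x_cond, x_geno = _design_matrices(design, sample_ids)
    n = len(sample_ids)
    fits: list[ComponentModelFit] = []
    p_cond_list = []
    flox_mask = genotypes == "flox"
    cre_mask = genotypes == "cre"
    for j in range(svd.n_components):
        y = svd.right_vectors[:, j]
        ll_full, k_full, rss_full = _ols_fit(y, x_full)
        ll_cond, k_cond, rss_cond = _ols_fit(y, x_cond)
        ll_geno, k_geno, rss_geno = _ols_fit(y, x_geno)
        aic = lambda ll, k: 2.0 * (k + 1) - 2.0 * ll
        sigma2 = rss_full / max(1, n - k_full)
        stat_cond = max(0.0, (rss_cond - rss_full) / sigma2)
        stat_geno = max(0.0, (rss_geno - rss_full) / sigma2)
        p_vs_cond = float(stats.chi2.sf(stat_cond, max(1, k_full - k_cond)))
        p_vs_geno = float(stats.chi2.sf(stat_geno, max(1, k_full - k_geno)))
        flox, cre = y[flox_mask], y[cre_mask]
        se_diff = np.sqrt(flox.var(ddof=1) / len(flox) + cre.var(ddof=1) / len(cre))
        divergent = bool(
            flox.mean() * cre.mean() < 0
            and abs(flox.mean() - cre.mean()) > se_diff
        )
        fits.append(
            ComponentModelFit(
                component=j,
                aic_full=aic(ll_full, k_full),
                aic_condition_only=aic(ll_cond, k_cond),
                aic_genotype_only=aic(ll_geno, k_geno),
                anova_p_vs_condition_only=p_vs_cond,
                anova_p_vs_genotype_only=p_vs_geno,
                padj=np.nan,
                sign_divergent=divergent,
            )
        )
        p_cond_list.append(p_vs_cond)
    padj = multipletests(p_cond_list, method="fdr_bh")[1]
    for fit, adj in zip(fits, padj):
        fit.padj = float(adj)
    return fits


def select_component(
    fits: list[ComponentModelFit], max_padj: float = 0.05
) -> SelectionOutcome:
    """Choose the knockout-attributable component.

    Primary rule: among components whose genotype-only AIC beats the full
    model's AIC and whose sample scores diverge in sign between genotypes,
    with BH-adjusted genotype-term p below ``max_padj``, take the smallest
    genotype-term p.  If no component satisfies all three, fall back to the
    smallest genotype-term p among the sign-divergent components and flag
    the selection as weak.
    """
    divergent = [f for f in fits if f.sign_divergent]
    if not divergent:
        raise ValueError("no genotype-divergent component")
    strict = [
        f for f in divergent
        if f.aic_genotype_only < f.aic_full and f.padj < max_padj
    ]
    if strict:
        best = min(strict, key=lambda f: f.anova_p_vs_condition_only)
        return SelectionOutcome(best.component, weak=False)
    best = min(divergent, key=lambda f: f.anova_p_vs_condition_only)
    return SelectionOutcome(best.component, weak=True)


def partition_left_vectors(
    svd: SvdDecomposition, component: int, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Split a component's gene loadings by sign; within each sign class a
    1-D k-means (k = 2) separates the extreme cluster from the bulk and the
    cluster with the larger |centroid| is kept.

    A sign class with fewer than two genes is returned whole with a warning.
    """
    loadings = pd.Series(svd.left_vectors[:, component], index=svd.gene_ids)

    def extreme(side: pd.Series) -> set[str]:
        if len(side) < 2:
            if len(side):
                warnings.warn("sign class with < 2 genes returned whole")
            return set(side.index)
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(
            side.to_numpy().reshape(-1, 1)
        )
        centers = km.cluster_centers_.ravel()
        keep = int(np.argmax(np.abs(centers)))
        return set(side.index[km.labels_ == keep])

    positive = extreme(loadings[loadings > 0])
    negative = extreme(loadings[loadings < 0])
    return positive, negative


def foldchange_cluster(
    fc_matrix: pd.DataFrame, k: int = 7, seed: int = 0
) -> tuple[ClusterResult, pd.DataFrame]:
    """k-means over a genes x genotype-contrast log2 fold-change matrix
    (default k = 7); also reports per-cluster mean fold changes so the most
    decreased / most increased clusters can be ranked."""
    cr = kmeans_cluster(fc_matrix, k=k, seed=seed)
    means = fc_matrix.groupby(cr.assignments).mean()
    means.index.name = "cluster"
    return cr, means


def attribute_genotype_effect(
    m: pd.DataFrame,
    design: SampleDesign,
    seed: int = 0,
    max_padj: float = 0.05,
) -> ComponentSelection:
    """Full attribution pipeline: decompose, model, select, partition."""
    svd = center_and_decompose(m, design)
    fits = fit_component_models(svd, design)
    outcome = select_component(fits, max_padj=max_padj)
    positive, negative = partition_left_vectors(svd, outcome.component, seed=seed)
    gene_effect = pd.Series(svd.left_vectors[:, outcome.component], index=svd.gene_ids)
    return ComponentSelection(
        chosen_component=outcome.component,
        positive_gene_set=positive,
        negative_gene_set=negative,
        gene_effect=gene_effect,
        weak=outcome.weak,
        variance_fraction=float(svd.variance_fraction[outcome.component]),
    )
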