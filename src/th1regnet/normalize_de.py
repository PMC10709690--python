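"""Size-factor normalization, log transform, and negative-binomial tests.

RNA-seq and ATAC-seq peak counts are modelled as negative binomial with a
gene-shared mean-dispersion relationship estimated per gene by the method of
moments.  Two-group contrasts are tested with a Wald statistic on the log2
fold change; p-values are Benjamini-Hochberg adjusted across genes.  The
module also carries the relative-expression formula used for qPCR
validation of the knockouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, SampleDesign

__all__ = [
    "DeResult",
    "size_factors",
    "regularized_log",
    "nb_wald_test",
    "call_deg",
    "differential_accessibility",
    "qpcr_relative_expression",
]

_DISPERSION_FLOOR = 1e-8


@dataclass
class DeResult:
    """Per-gene differential test results for one two-group contrast."""

    table: pd.DataFrame  # index gene_id; log2fc, mean_expr, p, padj, flagged
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        needed = {"log2fc", "mean_expr", "p", "padj", "flagged"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValueError(f"DeResult table missing columns {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def flagged_genes(self) -> set[str]:
        return set(self.table.index[self.table["flagged"]])


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios library size factors, normalized to geometric mean 1.

    For every gene expressed in all samples the ratio of each sample's count
    to the gene's geometric mean is formed; a sample's factor is the median
    ratio.  Raises if no gene is expressed in every sample.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] == 1:
        return np.ones(1)
    expressed = np.all(counts > 0, axis=1)
    if not np.any(expressed):
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "consider a pseudo-reference or filtering samples"
        )
    log_counts = np.log(counts[expressed])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    log_factors = np.median(log_counts - log_geomean, axis=0)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return np.exp(log_factors)


def regularized_log(cm: CountMatrix, sf: np.ndarray | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1): a monotone, finite variance-damping
    transform of normalized counts used for clustering, correlation and SVD."""
    if sf is None:
        sf = size_factors(cm)
    sf = np.asarray(sf, dtype=float)
    normalized = cm.counts / sf[np.newaxis, :]
    return pd.DataFrame(
        np.log2(normalized + 1.0), index=cm.gene_ids, columns=cm.sample_ids
    )


def _group_moments(counts_norm: np.ndarray, idx: np.ndarray):
    sub = counts_norm[:, idx]
    mu = sub.mean(axis=1)
    var = sub.var(axis=1, ddof=1)
    return mu, var, sub.shape[1]


def nb_wald_test(
    cm: CountMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    group_column: str = "condition",
    subset: dict | None = None,
    prior_df: float = 20.0,
) -> DeResult:
    """Two-group negative-binomial Wald test on normalized counts.

    ``contrast = (group_a, group_b)`` tests group_a over group_b (b is the
    reference); the reported log2fc is log2(mean_a / mean_b) with a 0.5
    pseudocount on the means.  Per-gene dispersion is the method-of-moments
    estimate pooled over the two groups, floored at 1e-8 and shrunk toward
    the across-gene median with prior weight ``prior_df`` (an empirical-
    Bayes moderation in the limma/DESeq2 tradition that stabilizes the
    noisy small-sample estimates).  The Wald statistic uses the
    delta-method standard error of the log fold change against a t
    reference with (n_a - 1) + (n_b - 1) + prior_df degrees of freedom.
    All-zero genes get p = 1 and log2fc = 0.
    """
    design.validate_against(cm)
    group_a, group_b = contrast
    labels = design.column(group_column, cm.sample_ids)
    extra = np.ones(len(cm.sample_ids), dtype=bool)
    if subset:
        for col, value in subset.items():
            extra &= design.column(col, cm.sample_ids) == value
    idx_a = np.flatnonzero((labels == group_a) & extra)
    idx_b = np.flatnonzero((labels == group_b) & extra)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"need >=2 samples per group; got {len(idx_a)} vs {len(idx_b)} "
            f"for contrast {contrast}"
        )
    sf = size_factors(cm)
    counts_norm = cm.counts / sf[np.newaxis, :]

    mu_a, var_a, n_a = _group_moments(counts_norm, idx_a)
    mu_b, var_b, n_b = _group_moments(counts_norm, idx_b)

    # pooled method-of-moments NB dispersion: var = mu + alpha * mu^2
    mu_pool = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    var_pool = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pool - mu_pool) / np.square(mu_pool)
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)
    resid_df = (n_a - 1) + (n_b - 1)
    alpha = (alpha * resid_df + np.median(alpha) * prior_df) / (resid_df + prior_df)

    log2fc = np.log2((mu_a + 0.5) / (mu_b + 0.5))

    # delta method: Var(log2 mean) = (1/mu + alpha) / (n * ln(2)^2)
    ln2_sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore"):
        se_sq = ((1.0 / np.maximum(mu_a, 0.5) + alpha) / n_a
                 + (1.0 / np.maximum(mu_b, 0.5) + alpha) / n_b) / ln2_sq
    se = np.sqrt(se_sq)
    wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), resid_df + prior_df)

    all_zero = (mu_a == 0) & (mu_b == 0)
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.clip(p, 0.0, 1.0)

    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_expr": mu_pool,
            "p": p,
            "padj": padj,
            "flagged": (np.abs(log2fc) >= np.log2(1.5)) & (padj < 0.05),
        },
        index=cm.gene_ids,
    )
    return DeResult(table, contrast)


def call_deg(
    de: DeResult | list[DeResult],
    min_fc: float = 1.5,
    max_padj: float = 0.05,
) -> set[str]:
    """Differentially expressed genes: fold change >= ``min_fc`` and
    BH-adjusted p strictly below ``max_padj``.

    A list of results (e.g. every timepoint of each cytokine condition
    against the medium control) yields the union over contrasts.
    """
    results = de if isinstance(de, list) else [de]
    genes: set[str] = set()
    log2_min = np.log2(min_fc)
    for result in results:
        t = result.table
        hit = (np.abs(t["log2fc"]) >= log2_min) & (t["padj"] < max_padj)
        genes |= set(t.index[hit])
    return genes


def differential_accessibility(
    peak_counts: CountMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    group_column: str = "condition",
    min_fc: float = 1.5,
    max_padj: float = 0.05,
    subset: dict | None = None,
) -> DeResult:
    """Differential chromatin accessibility on peak counts.

    Same NB machinery as :func:`nb_wald_test`; a peak is flagged as
    remodelled chromatin when |fold change| > ``min_fc`` and FDR <
    ``max_padj``.
    """
    de = nb_wald_test(peak_counts, design, contrast, group_column, subset=subset)
    t = de.table
    t["flagged"] = (np.abs(t["log2fc"]) > np.log2(min_fc)) & (t["padj"] < max_padj)
    return de


def qpcr_relative_expression(ct_gene: float, ct_hprt: float) -> float:
    """Relative expression against the Hprt housekeeping gene:
    ``1.8 ** (ct_hprt - ct_gene) * 1e5`` (higher Ct means lower expression)."""
    return 1.8 ** (ct_hprt - ct_gene) * 1e5
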