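"""Screen for transcription factors whose temporal expression tracks a
target gene (Il10 in the reference analysis).

A gene counts as a transcription factor when it appears in at least two of
the supplied TF reference lists; candidate TFs are then ranked by Pearson
correlation of their mean expression profile against the target across all
condition x day cells, with |r| > 0.7 as the screening threshold, and the
top positively correlating TFs are each fitted by ordinary least squares.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleDesign

__all__ = [
    "TfAnnotation",
    "CorrelationResult",
    "tf_consensus",
    "mean_profiles",
    "correlate_with_target",
    "top_regression",
]


@dataclass
class TfAnnotation:
    votes: dict[str, int]  # gene -> number of reference lists containing it
    min_votes: int

    def is_tf(self, gene: str) -> bool:
        return self.votes.get(gene, 0) >= self.min_votes

    @property
    def tf_genes(self) -> set[str]:
        return {g for g, v in self.votes.items() if v >= self.min_votes}


@dataclass
class CorrelationResult:
    table: pd.DataFrame  # index gene; columns r, n_points, passes
    target_gene: str
    threshold: float

    def ranked(self, positive_only: bool = False) -> list[str]:
        t = self.table
        if positive_only:
            t = t[t["r"] > 0]
        return list(t.sort_values("r", ascending=False).index)

    def passing(self, sign: str | None = None) -> set[str]:
        t = self.table[self.table["passes"]]
        if sign == "+":
            t = t[t["r"] > 0]
        elif sign == "-":
            t = t[t["r"] < 0]
        return set(t.index)


def tf_consensus(lists: list[set[str] | list[str]], min_votes: int = 2) -> TfAnnotation:
    """Consensus TF annotation: a gene is a transcription factor if present
    in at least ``min_votes`` of the reference lists."""
    if not lists:
        raise ValueError("need at least one TF reference list")
    votes: Counter[str] = Counter()
    for lst in lists:
        for gene in set(lst):
            votes[gene] += 1
    return TfAnnotation(dict(votes), min_votes)


def mean_profiles(expr: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Average replicates into one column per (condition, day) cell.

    Column order is condition-major, day-minor, deterministic.
    """
    cells: dict[str, list[str]] = {}
    for sample in expr.columns:
        row = design.table.loc[sample]
        cells.setdefault(f"{row['condition']}_d{row['day']}", []).append(sample)
    ordered = sorted(cells)
    data = {cell: expr[cells[cell]].mean(axis=1) for cell in ordered}
    return pd.DataFrame(data, index=expr.index)


def correlate_with_target(
    expr: pd.DataFrame,
    target_gene: str,
    tf_set: set[str],
    threshold: float = 0.7,
) -> CorrelationResult:
    """Pearson correlation of each TF's profile against the target gene
    across all profile columns jointly; ``passes`` means |r| > threshold."""
    if target_gene not in expr.index:
        raise KeyError(f"target gene {target_gene!r} not in expression matrix")
    target = expr.loc[target_gene].to_numpy(dtype=float)
    if np.std(target) == 0:
        raise ValueError("target profile is constant; correlation undefined")
    rows = []
    for gene in sorted(tf_set & set(expr.index)):
        if gene == target_gene:
            continue
        profile = expr.loc[gene].to_numpy(dtype=float)
        if np.std(profile) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(profile, target)[0, 1])
        rows.append(dict(gene=gene, r=r, n_points=len(target),
                         passes=abs(r) > threshold))
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["r", "n_points", "passes"]
    )
    return CorrelationResult(table, target_gene, threshold)


def top_regression(
    expr: pd.DataFrame,
    target: str,
    ranked_tfs: list[str],
    top_n: int = 9,
) -> pd.DataFrame:
    """OLS of the target profile on each of the top-``top_n`` ranked TFs.

    Returns per-TF slope, intercept and r2 (the squared Pearson r).  With
    fewer than ``top_n`` candidates all are fitted, with a warning.
    """
    if len(ranked_tfs) < top_n:
        warnings.warn(
            f"only {len(ranked_tfs)} candidate TFs; fitting all of them"
        )
    chosen = ranked_tfs[:top_n]
    y = expr.loc[target].to_numpy(dtype=float)
    rows = []
    for tf in chosen:
        x = expr.loc[tf].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        rows.append(dict(tf=tf, slope=fit.slope, intercept=fit.intercept,
                         r2=fit.rvalue ** 2))
    return pd.DataFrame(rows).set_index("tf")
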