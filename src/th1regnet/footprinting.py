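"""Differential transcription-factor footprinting from Tn5 insertion tracks.

For every motif the per-base insertion counts around its genomic matches
are stacked into an aggregate profile.  Two log2 summary statistics are
taken per motif: flanking accessibility (FA, mean insertion rate in the
windows flanking the motif core) and footprint depth (FPD, the log2 ratio
of flank to core rate — a bound factor protects its core, so depth and
flanking accessibility are both high).  Between-timepoint deltas of the
two statistics form a bivariate cloud over motifs; motifs with divergent
chromatin behaviour are called as outliers by robust Mahalanobis distance
with a chi-squared test, BH correction, and a bagplot-style fence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .io_formats import InsertionTrack, PeakSet

__all__ = [
    "FootprintStats",
    "DeltaFootprint",
    "aggregate_profile",
    "footprint_stats",
    "motif_footprint_stats",
    "delta_footprint",
    "bagplot_outliers",
    "bagplot_figure",
]

PSEUDOCOUNT = 0.5


@dataclass
class FootprintStats:
    tf: str
    fpd: float
    fa: float
    n_sites: int


@dataclass
class DeltaFootprint:
    table: pd.DataFrame  # index tf; delta_fa, delta_fpd, mahalanobis_d2, p, padj, outlier

    def outliers(self) -> list[str]:
        return list(self.table.index[self.table["outlier"]])


def aggregate_profile(
    track: InsertionTrack, sites: PeakSet, window: int = 200
) -> np.ndarray:
    """Strand-oriented mean insertion count per offset around motif matches.

    All sites must share one width (the motif length); the profile covers
    offsets [-window, motif_len + window).  Minus-strand sites are
    reversed before stacking.  Sites whose window leaves the contig are
    skipped (and counted in a warning).
    """
    widths = {iv.length for iv in sites}
    if len(widths) != 1:
        raise ValueError(f"sites must have uniform width, got {sorted(widths)}")
    motif_len = widths.pop()
    profile_len = motif_len + 2 * window
    acc = np.zeros(profile_len, dtype=float)
    used = skipped = 0
    for iv in sites:
        contig = track.tracks.get(iv.contig)
        if contig is None:
            skipped += 1
            continue
        lo = iv.start - window
        hi = iv.end + window
        if lo < 0 or hi > len(contig):
            skipped += 1
            continue
        segment = contig[lo:hi].astype(float)
        if iv.strand == "-":
            segment = segment[::-1]
        acc += segment
        used += 1
    if skipped:
        warnings.warn(f"{skipped} motif sites skipped (outside contig bounds)")
    if used == 0:
        raise ValueError("no usable motif sites")
    return acc / used


def footprint_stats(
    profile: np.ndarray, motif_len: int, flank: int = 50,
    pseudocount: float = PSEUDOCOUNT,
) -> tuple[float, float]:
    """(fpd, fa) from an aggregate profile.

    fa = log2(mean insertions over the two ``flank``-bp windows adjacent to
    the motif core + pseudocount); fpd = fa - log2(mean over the core +
    pseudocount).  A protected (bound) motif has a deep core relative to
    its flanks, so both statistics are high.
    """
    window = (len(profile) - motif_len) // 2
    if window < flank:
        raise ValueError("profile window smaller than requested flank")
    core = profile[window:window + motif_len]
    left = profile[window - flank:window]
    right = profile[window + motif_len:window + motif_len + flank]
    flank_mean = np.concatenate([left, right]).mean()
    core_mean = core.mean()
    fa = float(np.log2(flank_mean + pseudocount))
    fpd = float(fa - np.log2(core_mean + pseudocount))
    return fpd, fa


def motif_footprint_stats(
    track: InsertionTrack,
    sites_by_tf: dict[str, PeakSet],
    window: int = 200,
    flank: int = 50,
) -> dict[str, FootprintStats]:
    """Aggregate profile and (fpd, fa) for each motif's site list.

    The statistics are taken on the summed insertion-count profile (the
    per-offset mean times the number of sites), so the pseudocount acts on
    the count scale regardless of how sparse individual sites are.
    """
    out: dict[str, FootprintStats] = {}
    for tf, sites in sites_by_tf.items():
        if len(sites) == 0:
            continue
        profile = aggregate_profile(track, sites, window=window)
        motif_len = sites[0].length
        fpd, fa = footprint_stats(profile * len(sites), motif_len, flank=flank)
        out[tf] = FootprintStats(tf, fpd=fpd, fa=fa, n_sites=len(sites))
    return out


def delta_footprint(
    day_a: dict[str, FootprintStats] | list[dict[str, FootprintStats]],
    day_b: dict[str, FootprintStats] | list[dict[str, FootprintStats]],
) -> pd.DataFrame:
    """Per-TF (delta_fa, delta_fpd) between two timepoints, day_b - day_a.

    Replicate pairs may be supplied as equal-length lists; pairwise deltas
    are then averaged.  Motifs missing on either side are excluded.
    """
    list_a = day_a if isinstance(day_a, list) else [day_a]
    list_b = day_b if isinstance(day_b, list) else [day_b]
    if len(list_a) != len(list_b):
        raise ValueError("replicate lists must pair up")
    frames = []
    for rep_a, rep_b in zip(list_a, list_b):
        shared = sorted(set(rep_a) & set(rep_b))
        dropped = (set(rep_a) | set(rep_b)) - set(shared)
        if dropped:
            warnings.warn(f"motifs missing on one side excluded: {sorted(dropped)}")
        frames.append(
            pd.DataFrame(
                {
                    "delta_fa": [rep_b[tf].fa - rep_a[tf].fa for tf in shared],
                    "delta_fpd": [rep_b[tf].fpd - rep_a[tf].fpd for tf in shared],
                },
                index=shared,
            )
        )
    combined = pd.concat(frames).groupby(level=0).mean()
    combined.index.name = "tf"
    return combined


def bagplot_outliers(
    deltas: pd.DataFrame,
    fence_factor: float = 2.0,
    alpha: float = 0.05,
    random_state: int = 0,
    support_fraction: float = 0.75,
) -> DeltaFootprint:
    """Bivariate outlier calls on the (delta_fa, delta_fpd) cloud.

    A robust center and covariance (minimum covariance determinant) give
    each motif a squared Mahalanobis distance d2, rescaled so the median d2
    matches the chi2(df=2) median (a finite-sample consistency correction
    for the robust covariance), then tested against chi2(df=2) and
    BH-adjusted over motifs.  The bagplot fence of factor ``fence_factor``
    is approximated by the ellipse at fence_factor^2 times the median d2;
    an outlier must lie beyond the fence and reach adjusted significance.
    A singular covariance falls back to the diagonal.
    """
    if deltas.shape[0] < 3:
        raise ValueError("need >= 3 motifs for outlier detection")
    x = deltas[["delta_fa", "delta_fpd"]].to_numpy(dtype=float)
    try:
        mcd = MinCovDet(random_state=random_state,
                        support_fraction=support_fraction).fit(x)
        center, cov = mcd.location_, mcd.covariance_
        if np.linalg.matrix_rank(cov) < 2:
            raise np.linalg.LinAlgError("rank-deficient covariance")
        cov_inv = np.linalg.inv(cov)
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular robust covariance; falling back to diagonal")
        center = np.median(x, axis=0)
        diag = np.maximum(x.var(axis=0), 1e-12)
        cov_inv = np.diag(1.0 / diag)
    diff = x - center
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    chi2_median = stats.chi2.ppf(0.5, df=2)
    raw_median = np.median(d2)
    if raw_median > 0:
        d2 = d2 * (chi2_median / raw_median)
    p = stats.chi2.sf(d2, df=2)
    padj = multipletests(p, method="fdr_bh")[1]
    median_d2 = np.median(d2)
    fence = fence_factor ** 2 * max(median_d2, 1e-12)
    outlier = (d2 > fence) & (padj < alpha)
    table = pd.DataFrame(
        {
            "delta_fa": deltas["delta_fa"],
            "delta_fpd": deltas["delta_fpd"],
            "mahalanobis_d2": d2,
            "p": p,
            "padj": padj,
            "outlier": outlier,
        },
        index=deltas.index,
    )
    return DeltaFootprint(table)


def bagplot_figure(result: DeltaFootprint, path: str, title: str = "") -> None:
    """Render the delta cloud with outliers highlighted (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    fig, ax = plt.subplots(figsize=(5, 5))
    inliers = t[~t["outlier"]]
    outliers = t[t["outlier"]]
    ax.scatter(inliers["delta_fa"], -inliers["delta_fpd"], s=12, c="grey")
    ax.scatter(outliers["delta_fa"], -outliers["delta_fpd"], s=24, c="crimson")
    for tf, row in outliers.iterrows():
        ax.annotate(tf, (row["delta_fa"], -row["delta_fpd"]), fontsize=8)
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel("ΔFA")
    ax.set_ylabel("-ΔFPD")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
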