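"""Multiomic direct-target calling and regulatory-network construction.

Putative binding sites come from two routes: ChIP-seq peaks filtered for
overlap with open chromatin (ATAC peaks), and motif matches found by
scanning the sequence under the ATAC peaks with a log-odds PWM scanner
whose p-values are exact under the background model (dynamic programming
over integerized scores).  Peaks are assigned to genes within +/- 3 kb of
the gene body; a gene is a direct target of a factor if one of its ATAC
peaks carries ChIP or motif evidence for that factor.  Edges of the
resulting network are weighted by a distance-decayed regulatory potential
around the TSS, and nodes carry the gene's loading on the knockout-
attributed SVD component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomicInterval, PeakSet, Pwm
from .normalize_de import DeResult
from .svd_components import ComponentSelection

__all__ = [
    "MotifHit",
    "BindingEvidence",
    "RegulatoryNetwork",
    "PwmScanner",
    "pwm_scan",
    "filter_chip_by_atac",
    "union_peaks",
    "assign_peaks_to_genes",
    "classify_binding",
    "regulatory_potential",
    "build_network",
    "direct_targets",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# every non-ACGT byte maps to code 4 (invalid)
_BASE_TO_CODE = {ord(b): i for i, b in enumerate(_BASES)}
_BASE_TO_CODE.update({c: 4 for c in range(256) if chr(c) not in _BASES})


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    motif_id: str
    score: float  # log2 odds vs background
    p: float


@dataclass(frozen=True)
class BindingEvidence:
    gene_id: str
    tf: str
    evidence: str  # chip | motif | both
    peak: GenomicInterval


# ---------------------------------------------------------------------------
# PWM scanning with exact null p-values
# ---------------------------------------------------------------------------


class PwmScanner:
    """Log-odds PWM scanner with exact p-values under the background model.

    Scores are log2(p_ib / bg_b) summed over motif positions, integerized at
    ``granularity``; the null distribution of the integer score is obtained
    by exact convolution over positions (each position contributes its four
    integer scores with background probabilities), from which a survival
    function gives P(score >= s) for any observed score.
    """

    def __init__(self, pwm: Pwm, granularity: float = 1e-3):
        self.pwm = pwm
        self.granularity = granularity
        with np.errstate(divide="ignore"):
            self.score_matrix = np.log2(pwm.matrix / pwm.background[np.newaxis, :])
        self.int_scores = np.round(self.score_matrix / granularity).astype(np.int64)
        self._sf_offset, self._sf = self._null_survival()

    def _null_survival(self) -> tuple[int, np.ndarray]:
        lo = int(self.int_scores.min(axis=1).sum())
        hi = int(self.int_scores.max(axis=1).sum())
        size = hi - lo + 1
        dist = np.zeros(size)
        # start: probability 1 at score 0, positioned at -lo
        pos_lo, pos_hi = 0, 0
        dist[-lo] = 1.0
        bg = self.pwm.background
        for i in range(len(self.pwm)):
            new = np.zeros(size)
            for b in range(4):
                shift = int(self.int_scores[i, b])
                src = dist[pos_lo - lo: pos_hi - lo + 1]
                new[pos_lo + shift - lo: pos_hi + shift - lo + 1] += bg[b] * src
            pos_lo += int(self.int_scores[i].min())
            pos_hi += int(self.int_scores[i].max())
            dist = new
        sf = np.cumsum(dist[::-1])[::-1]
        return lo, np.minimum(sf, 1.0)

    def pvalue(self, score: float) -> float:
        """Exact P(null score >= score) at the integerized resolution."""
        return self.pvalue_int(int(np.round(score / self.granularity)))

    def pvalue_int(self, int_score: int) -> float:
        """Survival probability for an already-integerized score (the sum of
        per-position integer scores, the same arithmetic the null uses)."""
        idx = int_score - self._sf_offset
        if idx < 0:
            return 1.0
        if idx >= len(self._sf):
            return 0.0
        return float(self._sf[idx])

    def score_window(self, window: str) -> float:
        idx = [_BASE_INDEX.get(b, -1) for b in window]
        if -1 in idx:
            return -np.inf
        return float(self.score_matrix[np.arange(len(idx)), idx].sum())

    def scan(self, sequence: str, p_threshold: float = 1e-4,
             contig: str = "seq", offset: int = 0) -> list[MotifHit]:
        """Scan both strands; at each position keep the better strand and
        report hits with p <= ``p_threshold``."""
        sequence = sequence.upper()
        length = len(self.pwm)
        hits: list[MotifHit] = []
        if len(sequence) < length:
            return hits
        # scanning the - strand at a window equals scoring the reverse-
        # complement matrix on the forward sequence
        rc_matrix = self.score_matrix[::-1, ::-1]
        rc_int = self.int_scores[::-1, ::-1]
        seq_idx = np.frombuffer(
            sequence.translate(_BASE_TO_CODE).encode("latin-1"), dtype=np.uint8
        ).astype(np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(seq_idx, length)
        valid = ~np.any(windows > 3, axis=1)
        pos = np.arange(length)
        fwd_int = np.where(
            valid, self.int_scores[pos, np.minimum(windows, 3)].sum(axis=1), 0
        )
        rev_int = np.where(
            valid, rc_int[pos, np.minimum(windows, 3)].sum(axis=1), 0
        )
        best_int = np.maximum(fwd_int, rev_int)
        idx = np.clip(best_int - self._sf_offset, 0, len(self._sf) - 1)
        pvals = np.where(best_int - self._sf_offset < 0, 1.0, self._sf[idx])
        pvals = np.where(best_int - self._sf_offset >= len(self._sf), 0.0, pvals)
        for start in np.flatnonzero(valid & (pvals <= p_threshold)):
            window = windows[start]
            if fwd_int[start] >= rev_int[start]:
                strand, score = "+", float(self.score_matrix[pos, window].sum())
            else:
                strand, score = "-", float(rc_matrix[pos, window].sum())
            hits.append(
                MotifHit(
                    GenomicInterval(contig, offset + int(start),
                                    offset + int(start) + length, strand=strand),
                    self.pwm.motif_id, score, float(pvals[start]),
                )
            )
        return hits


def pwm_scan(
    sequence: str, pwm: Pwm, p_threshold: float = 1e-4,
    contig: str = "seq", offset: int = 0,
) -> list[MotifHit]:
    """Convenience wrapper around :class:`PwmScanner` for one sequence."""
    return PwmScanner(pwm).scan(sequence, p_threshold, contig=contig, offset=offset)


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------


def _trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def filter_chip_by_atac(chip: PeakSet, atac: PeakSet) -> PeakSet:
    """ChIP peaks overlapping (>= 1 bp, half-open) any ATAC peak."""
    trees = _trees(atac)
    kept = [
        iv for iv in chip
        if iv.contig in trees and trees[iv.contig].overlaps(iv.start, iv.end)
    ]
    return PeakSet(kept)


def union_peaks(replicate_peaksets: Sequence[PeakSet]) -> PeakSet:
    """Union of peak sets with overlapping or book-ended intervals merged."""
    if not replicate_peaksets:
        raise ValueError("need >= 1 peak set")
    all_ivs = sorted(
        (iv for ps in replicate_peaksets for iv in ps),
        key=lambda iv: (iv.contig, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    for iv in all_ivs:
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return PeakSet(merged)


def _body_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    if peak.start < gene.body_end and gene.body_start < peak.end:
        return 0
    if peak.end <= gene.body_start:
        return gene.body_start - peak.end + 1
    return peak.start - gene.body_end + 1


def assign_peaks_to_genes(
    peaks: PeakSet, genes: Iterable[GeneModel], margin: int = 3000
) -> dict[GenomicInterval, str]:
    """Assign each peak to the gene whose +/- ``margin`` bp body window it
    overlaps; if several gene windows overlap, the nearest gene body wins
    (ties broken lexicographically by gene id).  Unassigned peaks are
    omitted from the map."""
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        win = g.window(margin)
        gene_trees.setdefault(g.contig, IntervalTree()).addi(win.start, win.end, g)
    assignment: dict[GenomicInterval, str] = {}
    for peak in peaks:
        tree = gene_trees.get(peak.contig)
        if tree is None:
            continue
        overlapping = [hit.data for hit in tree.overlap(peak.start, peak.end)]
        if not overlapping:
            continue
        best = min(overlapping, key=lambda g: (_body_distance(peak, g), g.gene_id))
        assignment[peak] = best.gene_id
    return assignment


def classify_binding(
    gene_peaks: dict[GenomicInterval, str],
    chip_by_tf: dict[str, PeakSet],
    motif_hits_by_tf: dict[str, list[MotifHit]],
) -> list[BindingEvidence]:
    """Per gene and factor, record ChIP and/or motif evidence inside the
    gene's assigned ATAC peaks.

    ``chip_by_tf`` should hold ChIP peaks already filtered for ATAC overlap
    (:func:`filter_chip_by_atac`); motif hits must carry genomic
    coordinates (from scanning ATAC-peak sequences).
    """
    chip_trees = {tf: _trees(ps) for tf, ps in chip_by_tf.items()}
    motif_trees: dict[str, dict[str, IntervalTree]] = {}
    for tf, hits in motif_hits_by_tf.items():
        trees: dict[str, IntervalTree] = {}
        for hit in hits:
            iv = hit.interval
            trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, hit)
        motif_trees[tf] = trees

    tfs = sorted(set(chip_by_tf) | set(motif_hits_by_tf))
    evidence: list[BindingEvidence] = []
    seen: set[tuple[str, str]] = set()
    for peak, gene in sorted(gene_peaks.items(),
                             key=lambda kv: (kv[1], kv[0].contig, kv[0].start)):
        for tf in tfs:
            has_chip = (
                tf in chip_trees
                and peak.contig in chip_trees[tf]
                and chip_trees[tf][peak.contig].overlaps(peak.start, peak.end)
            )
            mt = motif_trees.get(tf, {}).get(peak.contig)
            has_motif = bool(
                mt is not None
                and any(h.begin >= peak.start and h.end <= peak.end
                        for h in mt.overlap(peak.start, peak.end))
            )
            if not (has_chip or has_motif):
                continue
            kind = "both" if (has_chip and has_motif) else ("chip" if has_chip else "motif")
            key = (gene, tf)
            if key in seen:
                # upgrade to the richer evidence class if a second peak adds it
                for i, ev in enumerate(evidence):
                    if (ev.gene_id, ev.tf) == key and ev.evidence != "both" \
                            and kind != ev.evidence:
                        evidence[i] = BindingEvidence(gene, tf, "both", ev.peak)
                continue
            seen.add(key)
            evidence.append(BindingEvidence(gene, tf, kind, peak))
    return evidence


def regulatory_potential(
    gene: GeneModel, tf_peaks: PeakSet, decay_kb: float = 100.0
) -> float:
    """Distance-decayed regulatory potential of a factor for one gene:
    sum over peaks with |center - TSS| <= decay_kb kilobases of
    exp(-(0.5 + 4 d)) where d is the distance as a fraction of the decay
    range.  A peak centered on the TSS contributes exp(-0.5) ~= 0.607."""
    horizon = decay_kb * 1000.0
    rp = 0.0
    for peak in tf_peaks:
        if peak.contig != gene.contig:
            continue
        dist = abs(peak.center - gene.tss)
        if dist > horizon:
            continue
        d = dist / horizon
        rp += float(np.exp(-(0.5 + 4.0 * d)))
    return rp


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryNetwork:
    graph: nx.DiGraph

    @property
    def nodes(self) -> dict:
        return dict(self.graph.nodes(data=True))

    @property
    def edges(self) -> dict:
        return {(u, v): d for u, v, d in self.graph.edges(data=True)}

    def labelled_genes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("label_shown")]

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):
            for key, value in list(data.items()):
                if isinstance(value, (np.floating, np.integer)):
                    data[key] = value.item()
        nx.write_graphml(g, path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": [
                {"id": n, **{k: _plain(v) for k, v in d.items()}}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, **{k: _plain(val) for k, val in d.items()}}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


TF_GENES = {"Maf": "Maf", "Blimp1": "Prdm1"}


def build_network(
    selection: ComponentSelection,
    de: DeResult | None,
    evidence: list[BindingEvidence],
    rp: dict[tuple[str, str], float],
    label_top: int = 50,
) -> RegulatoryNetwork:
    """Assemble the TF -> target network.

    Nodes are the genes of the selected component's extreme clusters plus
    the regulator genes Maf and Prdm1 (always present).  Node size is the
    |left-singular loading| with the maximum capped at the second-highest
    value; node colour sign is the knockout fold change (up positive / down
    negative); only the ``label_top`` genes with the largest capped effect
    carry labels.  Edges are one per binding-evidence record, weighted by
    regulatory potential and classed by which factors bind (maf / blimp1 /
    both at the gene level)."""
    members = sorted(selection.positive_gene_set | selection.negative_gene_set)
    if not members:
        raise ValueError("empty component selection")
    genes = sorted(set(members) | set(TF_GENES.values()))

    effect = {
        g: float(abs(selection.gene_effect.get(g, 0.0))) for g in genes
    }
    sizes = sorted(effect.values(), reverse=True)
    if len(sizes) >= 2 and sizes[0] > sizes[1]:
        cap = sizes[1]
        for g, v in effect.items():
            if v > cap:
                effect[g] = cap

    log2fc = {}
    for g in genes:
        if de is not None and g in de.table.index:
            log2fc[g] = float(de.table.loc[g, "log2fc"])
        else:
            log2fc[g] = 0.0

    ranked = sorted(genes, key=lambda g: (-effect[g], g))
    labelled = set(ranked[:label_top])

    tf_per_gene: dict[str, set[str]] = {}
    for ev in evidence:
        tf_per_gene.setdefault(ev.gene_id, set()).add(ev.tf)

    graph = nx.DiGraph()
    for g in genes:
        gene_tfs = tf_per_gene.get(g, set())
        if {"Maf", "Blimp1"} <= gene_tfs:
            evidence_class = "both"
        elif "Maf" in gene_tfs:
            evidence_class = "maf"
        elif "Blimp1" in gene_tfs:
            evidence_class = "blimp1"
        else:
            evidence_class = "none"
        graph.add_node(
            g,
            effect_size=effect[g],
            log2fc=log2fc[g],
            direction="up" if log2fc[g] > 0 else ("down" if log2fc[g] < 0 else "flat"),
            label_shown=g in labelled,
            evidence_class=evidence_class,
        )
    for ev in evidence:
        if ev.gene_id not in graph:
            continue
        source = TF_GENES.get(ev.tf, ev.tf)
        if source not in graph:
            graph.add_node(source, effect_size=0.0, log2fc=0.0,
                           direction="flat", label_shown=False,
                           evidence_class="none")
        graph.add_edge(
            source, ev.gene_id,
            tf=ev.tf,
            evidence=ev.evidence,
            weight=float(rp.get((ev.tf, ev.gene_id), 0.0)),
        )
    return RegulatoryNetwork(graph)


# ---------------------------------------------------------------------------
# end-to-end direct-target calling
# ---------------------------------------------------------------------------


def direct_targets(
    genes: Iterable[GeneModel],
    atac: PeakSet,
    chip_by_tf: dict[str, PeakSet],
    sequences: dict[str, str],
    pwms_by_tf: dict[str, Pwm],
    margin: int = 3000,
    p_threshold: float = 1e-4,
) -> list[BindingEvidence]:
    """Full integration: filter ChIP by ATAC, scan ATAC-peak sequences for
    motifs, assign peaks to genes within +/- margin of the gene body, and
    classify binding evidence per (gene, factor)."""
    chip_filtered = {
        tf: filter_chip_by_atac(ps, atac) for tf, ps in chip_by_tf.items()
    }
    scanners = {tf: PwmScanner(pwm) for tf, pwm in pwms_by_tf.items()}
    motif_hits: dict[str, list[MotifHit]] = {tf: [] for tf in pwms_by_tf}
    for peak in atac:
        seq = sequences.get(peak.contig)
        if seq is None:
            continue
        window = seq[peak.start:peak.end]
        for tf, scanner in scanners.items():
            motif_hits[tf].extend(
                scanner.scan(window, p_threshold, contig=peak.contig,
                             offset=peak.start)
            )
    assignment = assign_peaks_to_genes(atac, genes, margin=margin)
    return classify_binding(assignment, chip_filtered, motif_hits)
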