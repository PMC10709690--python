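"""Motif scanning, interval integration, regulatory potential and network
construction contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import sharp_pwm
from th1regnet.io_formats import GeneModel, GenomicInterval, PeakSet, Pwm
from th1regnet.normalize_de import DeResult
from th1regnet.svd_components import ComponentSelection
from th1regnet.target_network import (
    BindingEvidence,
    PwmScanner,
    assign_peaks_to_genes,
    build_network,
    classify_binding,
    filter_chip_by_atac,
    pwm_scan,
    regulatory_potential,
    union_peaks,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


# --- PWM scanning ----------------------------------------------------------


def test_consensus_sequence_scores_maximally():
    rng = np.random.default_rng(0)
    pwm = sharp_pwm("M", 8, rng)
    scanner = PwmScanner(pwm)
    seq = "TTTTTT" + pwm.consensus + "TTTTTT"
    hits = scanner.scan(seq, p_threshold=1.0)
    best_p = min(h.p for h in hits)
    planted = [h for h in hits if h.interval.start == 6]
    assert planted and planted[0].p == best_p
    assert planted[0].score == max(h.score for h in hits)


def test_uniform_pwm_yields_no_hits():
    pwm = Pwm("uniform", np.full((6, 4), 0.25))
    hits = pwm_scan("ACGTACGTACGTACGT", pwm, p_threshold=1e-4)
    assert hits == []
    scanner = PwmScanner(pwm)
    assert scanner.pvalue(0.0) == pytest.approx(1.0)


def test_scan_pvalues_match_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    m = rng.dirichlet([0.6] * 4, size=6)
    m = m + 1e-4
    m = m / m.sum(axis=1, keepdims=True)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    scanner = PwmScanner(Pwm("M", m, bg))
    # exact null over all 4^6 words at the scanner's integer resolution
    word_probs = {}
    for word in itertools.product(range(4), repeat=6):
        score = sum(scanner.int_scores[i, b] for i, b in enumerate(word))
        word_probs[score] = word_probs.get(score, 0.0) + float(
            np.prod([bg[b] for b in word]))
    for word in itertools.islice(itertools.product(range(4), repeat=6), 0, 4096, 7):
        score = sum(scanner.int_scores[i, b] for i, b in enumerate(word))
        oracle = sum(v for s, v in word_probs.items() if s >= score)
        assert scanner.pvalue_int(score) == pytest.approx(oracle, abs=1e-9)


def test_scan_is_strand_symmetric():
    rng = np.random.default_rng(2)
    pwm = sharp_pwm("M", 9, rng)
    seq = "".join(rng.choice(list("ACGT"), 300)) + pwm.consensus \
        + "".join(rng.choice(list("ACGT"), 300))
    rc = seq.translate(COMPLEMENT)[::-1]
    scanner = PwmScanner(pwm)
    fwd = scanner.scan(seq, 1e-3)
    rev = scanner.scan(rc, 1e-3)
    assert len(fwd) == len(rev)
    mirrored = sorted(len(seq) - h.interval.end for h in rev)
    assert mirrored == sorted(h.interval.start for h in fwd)


def test_sequence_shorter_than_motif_gives_empty_list():
    rng = np.random.default_rng(3)
    pwm = sharp_pwm("M", 10, rng)
    assert pwm_scan("ACGT", pwm) == []


def test_ambiguous_bases_are_skipped():
    rng = np.random.default_rng(4)
    pwm = sharp_pwm("M", 6, rng)
    hits = pwm_scan("NNN" + pwm.consensus[:3] + "N" + pwm.consensus, pwm, 1e-2)
    for h in hits:
        window = ("NNN" + pwm.consensus[:3] + "N" + pwm.consensus)[
            h.interval.start:h.interval.end]
        assert "N" not in window


# --- interval operations ---------------------------------------------------


def test_chip_overlap_retained_touch_dropped():
    atac = PeakSet([GenomicInterval("c", 150, 300)])
    kept = filter_chip_by_atac(PeakSet([GenomicInterval("c", 100, 200)]), atac)
    assert len(kept) == 1
    atac2 = PeakSet([GenomicInterval("c", 200, 300)])
    dropped = filter_chip_by_atac(PeakSet([GenomicInterval("c", 100, 200)]), atac2)
    assert len(dropped) == 0


def test_chip_filter_matches_quadratic_oracle():
    rng = np.random.default_rng(5)
    def random_peaks(n):
        out = []
        for _ in range(n):
            start = int(rng.integers(0, 10_000))
            out.append(GenomicInterval(f"c{rng.integers(1, 3)}", start,
                                       start + int(rng.integers(10, 300))))
        return PeakSet(out)
    chip, atac = random_peaks(500), random_peaks(500)
    kept = filter_chip_by_atac(chip, atac)
    oracle = [c for c in chip if any(c.overlaps(a) for a in atac)]
    assert len(kept) == len(oracle)


def test_union_merges_overlapping_intervals():
    merged = union_peaks([PeakSet([GenomicInterval("c", 100, 200)]),
                          PeakSet([GenomicInterval("c", 150, 250)])])
    assert [(iv.start, iv.end) for iv in merged] == [(100, 250)]


def test_union_disjoint_sets_sorted_concatenation():
    merged = union_peaks([PeakSet([GenomicInterval("c", 500, 600)]),
                          PeakSet([GenomicInterval("c", 10, 20)])])
    assert [(iv.start, iv.end) for iv in merged] == [(10, 20), (500, 600)]


@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)),
                min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_union_is_idempotent(raw):
    ps = PeakSet([GenomicInterval("c", s, s + w) for s, w in raw])
    once = union_peaks([ps])
    twice = union_peaks([once, once])
    assert [(iv.start, iv.end) for iv in once] == \
        [(iv.start, iv.end) for iv in twice]


# --- peak-to-gene assignment ----------------------------------------------


GENES = [GeneModel("geneA", "c", 10_000, 12_000, "+"),
         GeneModel("geneB", "c", 30_000, 31_000, "-")]


def test_peak_ending_at_window_start_is_not_assigned():
    peak = GenomicInterval("c", 6000, 7000)  # ends exactly at 10_000 - 3000
    assert assign_peaks_to_genes(PeakSet([peak]), GENES) == {}


def test_peak_overlapping_window_by_one_base_is_assigned():
    peak = GenomicInterval("c", 6000, 7001)
    assert assign_peaks_to_genes(PeakSet([peak]), GENES) == {peak: "geneA"}


def test_assignment_matches_brute_force_oracle():
    rng = np.random.default_rng(6)
    genes = []
    for i in range(20):
        start = int(rng.integers(0, 190_000))
        genes.append(GeneModel(f"g{i:02d}", "c", start,
                               start + int(rng.integers(500, 3000)),
                               "+" if rng.random() < 0.5 else "-"))
    peaks = []
    for _ in range(200):
        start = int(rng.integers(0, 199_000))
        peaks.append(GenomicInterval("c", start, start + int(rng.integers(50, 400))))
    got = assign_peaks_to_genes(PeakSet(peaks), genes, margin=3000)

    def dist(peak, g):
        if peak.start < g.body_end and g.body_start < peak.end:
            return 0
        return (g.body_start - peak.end + 1 if peak.end <= g.body_start
                else peak.start - g.body_end + 1)

    for peak in peaks:
        cands = [g for g in genes
                 if peak.start < g.body_end + 3000
                 and max(0, g.body_start - 3000) < peak.end]
        if not cands:
            assert peak not in got
        else:
            best = min(cands, key=lambda g: (dist(peak, g), g.gene_id))
            assert got[peak] == best.gene_id


# --- binding classification ------------------------------------------------


def _mk_hit(contig, start, tf, length=10):
    from th1regnet.target_network import MotifHit
    return MotifHit(GenomicInterval(contig, start, start + length), tf, 10.0, 1e-6)


def test_classification_evidence_classes():
    peak_a = GenomicInterval("c", 11_000, 11_300)
    peak_b = GenomicInterval("c", 30_500, 30_800)
    gene_peaks = {peak_a: "geneA", peak_b: "geneB"}
    chip = {"Maf": PeakSet([GenomicInterval("c", 11_100, 11_200)]),
            "Blimp1": PeakSet()}
    motif = {"Maf": [], "Blimp1": [_mk_hit("c", 30_600, "Blimp1")]}
    evidence = classify_binding(gene_peaks, chip, motif)
    by_key = {(e.gene_id, e.tf): e.evidence for e in evidence}
    assert by_key == {("geneA", "Maf"): "chip", ("geneB", "Blimp1"): "motif"}


def test_classification_both_evidence_for_same_peak():
    peak = GenomicInterval("c", 11_000, 11_300)
    chip = {"Maf": PeakSet([GenomicInterval("c", 11_100, 11_200)])}
    motif = {"Maf": [_mk_hit("c", 11_050, "Maf")]}
    evidence = classify_binding({peak: "geneA"}, chip, motif)
    assert evidence == [BindingEvidence("geneA", "Maf", "both", peak)]


def test_chip_outside_atac_gives_no_evidence():
    atac = PeakSet([GenomicInterval("c", 11_000, 11_300)])
    chip_raw = PeakSet([GenomicInterval("c", 50_000, 50_200)])
    filtered = filter_chip_by_atac(chip_raw, atac)
    evidence = classify_binding({atac[0]: "geneA"}, {"Maf": filtered}, {"Maf": []})
    assert evidence == []


# --- regulatory potential --------------------------------------------------


def test_rp_no_peaks_in_range_is_zero():
    gene = GeneModel("g", "c", 500_000, 502_000, "+")
    peaks = PeakSet([GenomicInterval("c", 10, 20)])
    assert regulatory_potential(gene, peaks) == 0.0


def test_rp_peak_centered_at_tss():
    gene = GeneModel("g", "c", 10_000, 12_000, "+")
    peaks = PeakSet([GenomicInterval("c", 9_900, 10_100)])  # center == tss
    assert regulatory_potential(gene, peaks) == pytest.approx(np.exp(-0.5))


def test_rp_decreases_with_distance():
    gene = GeneModel("g", "c", 100_000, 102_000, "+")
    values = []
    for shift in (0, 10_000, 50_000, 99_000):
        peaks = PeakSet([GenomicInterval("c", 100_000 + shift - 100,
                                         100_000 + shift + 100)])
        values.append(regulatory_potential(gene, peaks))
    assert values == sorted(values, reverse=True)


def test_rp_additive_and_order_invariant():
    gene = GeneModel("g", "c", 100_000, 102_000, "+")
    p1 = GenomicInterval("c", 99_000, 99_200)
    p2 = GenomicInterval("c", 130_000, 130_400)
    separate = (regulatory_potential(gene, PeakSet([p1]))
                + regulatory_potential(gene, PeakSet([p2])))
    together = regulatory_potential(gene, PeakSet([p1, p2]))
    reversed_ = regulatory_potential(gene, PeakSet([p2, p1]))
    assert together == pytest.approx(separate)
    assert together == pytest.approx(reversed_)


# --- network construction --------------------------------------------------


def _selection(effects: dict[str, float]):
    genes = list(effects)
    return ComponentSelection(
        chosen_component=0,
        positive_gene_set={g for g in genes if effects[g] >= 0},
        negative_gene_set={g for g in genes if effects[g] < 0},
        gene_effect=pd.Series(effects),
    )


def _de(log2fc: dict[str, float]):
    table = pd.DataFrame({
        "log2fc": pd.Series(log2fc),
        "mean_expr": 10.0, "p": 0.01, "padj": 0.02, "flagged": True,
    })
    return DeResult(table, ("cre", "flox"))


def test_node_size_capped_to_second_highest():
    net = build_network(
        _selection({"gA": 10.0, "gB": 3.0, "gC": 2.0}),
        _de({"gA": 1.0, "gB": -1.0, "gC": 0.5}),
        evidence=[], rp={},
    )
    sizes = {n: d["effect_size"] for n, d in net.graph.nodes(data=True)}
    assert sizes["gA"] == 3.0 and sizes["gB"] == 3.0 and sizes["gC"] == 2.0


def test_exactly_fifty_labels_on_sixty_genes():
    effects = {f"g{i:02d}": float(i + 1) for i in range(60)}
    net = build_network(_selection(effects), None, [], {})
    assert len(net.labelled_genes()) == 50


def test_maf_and_prdm1_nodes_always_present():
    net = build_network(_selection({"gA": 1.0}), None, [], {})
    assert "Maf" in net.graph and "Prdm1" in net.graph


def test_edge_classes_follow_binding_evidence():
    peak = GenomicInterval("c", 0, 100)
    evidence = [BindingEvidence("gA", "Maf", "chip", peak),
                BindingEvidence("gB", "Blimp1", "motif", peak),
                BindingEvidence("gC", "Maf", "chip", peak),
                BindingEvidence("gC", "Blimp1", "chip", peak)]
    net = build_network(
        _selection({"gA": 1.0, "gB": 2.0, "gC": 3.0}), None, evidence,
        rp={("Maf", "gA"): 0.4, ("Blimp1", "gB"): 0.2},
    )
    nodes = net.nodes
    assert nodes["gA"]["evidence_class"] == "maf"
    assert nodes["gB"]["evidence_class"] == "blimp1"
    assert nodes["gC"]["evidence_class"] == "both"
    assert net.edges[("Maf", "gA")]["weight"] == pytest.approx(0.4)
    assert net.edges[("Prdm1", "gB")]["weight"] == pytest.approx(0.2)


def test_empty_selection_rejected():
    sel = ComponentSelection(0, set(), set(), pd.Series(dtype=float))
    with pytest.raises(ValueError, match="empty"):
        build_network(sel, None, [], {})


def test_network_export_roundtrip(tmp_path):
    net = build_network(_selection({"gA": 1.0, "gB": 2.0}), None, [], {})
    net.to_graphml(tmp_path / "n.graphml")
    net.to_json(tmp_path / "n.json")
    import json
    payload = json.loads((tmp_path / "n.json").read_text())
    assert {n["id"] for n in payload["nodes"]} >= {"gA", "gB", "Maf", "Prdm1"}


# --- end-to-end direct-target calling --------------------------------------


def test_direct_target_precision_and_recall(target_regulome):
    from th1regnet.target_network import direct_targets

    data, pwms = target_regulome
    called = {(e.gene_id, e.tf)
              for e in direct_targets(data.genes, data.atac, data.chip,
                                      data.sequences, pwms)}
    truth = {(r.gene_id, r.tf_id) for r in data.truth.itertuples()}
    tp = len(called & truth)
    assert tp / len(called) >= 0.9
    assert tp / len(truth) >= 0.9
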