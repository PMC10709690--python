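"""Shared fixtures: small PWMs and session-scoped synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from th1regnet.io_formats import Pwm
import th1regnet.synthetic_data as sd


def sharp_pwm(name: str, length: int, rng: np.random.Generator,
              consensus_p: float = 0.91) -> Pwm:
    """A high-information PWM with a random consensus sequence."""
    rest = (1.0 - consensus_p) / 3.0
    m = np.full((length, 4), rest)
    consensus = rng.integers(0, 4, length)
    m[np.arange(length), consensus] = consensus_p
    return Pwm(name, m)


@pytest.fixture(scope="session")
def footprint_regulome():
    """Toy regulome for differential footprinting: 40 motifs x 50 sites,
    with a footprint planted for TF00 in the IL-27 day-3 replicate tracks
    only (two replicates per condition/day for paired deltas)."""
    rng = np.random.default_rng(42)
    n_tf, n_sites, n_genes = 40, 50, 50
    motifs = tuple(sharp_pwm(f"TF{i:02d}", 10, rng) for i in range(n_tf))
    tracks = tuple(
        f"{cond}_d{day}_r{rep}"
        for cond in ("Medium", "IL27") for day in (2, 3) for rep in (1, 2)
    )
    sites = []
    k = 0
    for _ in range(n_sites):
        for i, m in enumerate(motifs):
            gene = f"gene{k % n_genes:03d}"
            offset = -2900 + 145 * (k // n_genes)
            planted_in = ("IL27_d3_r1", "IL27_d3_r2") if i == 0 else ()
            sites.append(sd.PlantedSite(gene, m.motif_id, offset, planted_in))
            k += 1
    spec = sd.GenomeSimSpec(
        n_contigs=1, contig_length=500_000, n_genes=n_genes,
        motif_set=motifs, planted_sites=tuple(sites), tracks=tracks,
        background_insertion_rate=0.05, footprint_depth_factor=0.3,
        decontaminate=False, seed=7,
    )
    return sd.simulate_regulome(spec)


@pytest.fixture(scope="session")
def target_regulome():
    """Toy regulome for direct-target calling: 50 planted (gene, TF)
    targets among 500 decoy genes, with decoy ATAC and ChIP peaks."""
    rng = np.random.default_rng(1)
    maf = sharp_pwm("Maf", 12, rng)
    blimp = sharp_pwm("Blimp1", 12, rng)
    sites = tuple(
        sd.PlantedSite(f"gene{i:03d}", "Maf" if i % 2 == 0 else "Blimp1",
                       offset=-1500 + 60 * i)
        for i in range(50)
    )
    spec = sd.GenomeSimSpec(
        n_contigs=1, contig_length=550 * 10_000, n_genes=550,
        motif_set=(maf, blimp), planted_sites=sites, tracks=("Medium_d2",),
        n_decoy_peaks=100, n_decoy_chip=20, seed=11,
    )
    data = sd.simulate_regulome(spec)
    return data, {"Maf": maf, "Blimp1": blimp}


@pytest.fixture(scope="session")
def ko_dataset():
    """One KO simulation (2000 genes, 200 affected, 3% genotype variance)."""
    gene_ids = [f"g{i:05d}" for i in range(2000)]
    spec = sd.KoSimSpec(
        base=sd.KineticsSimSpec(n_genes=2000, days=(3,), n_replicates=3, seed=0),
        affected_up=frozenset(gene_ids[:100]),
        affected_down=frozenset(gene_ids[100:200]),
        genotype_log2fc=1.0,
        genotype_variance_fraction=0.03,
        seed=0,
    )
    return sd.simulate_ko(spec)
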