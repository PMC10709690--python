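"""Synthetic inputs with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_kinetics` — negative-binomial RNA-seq counts over a
  condition x day design with planted co-expression clusters;
* :func:`simulate_ko` — a knockout experiment (two genotypes, four
  conditions) in which a chosen gene set carries a weak genotype effect
  contributing a controlled fraction of total expression variance;
* :func:`simulate_regulome` — a toy genome with gene bodies, planted motif
  instances, ATAC/ChIP peaks and per-condition Tn5 insertion tracks with
  plantable footprints.

All generators are pure functions of their spec (the seed included):
rerunning with the same spec reproduces the outputs bitwise.  Decoy ATAC
peaks are resampled until they contain no chance motif matches above the
scanning threshold, so the planted truth table is the complete set of
motif-supported direct targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CONDITIONS,
    CountMatrix,
    GeneModel,
    GenomicInterval,
    InsertionTrack,
    PeakSet,
    Pwm,
    SampleDesign,
)

__all__ = [
    "KineticsSimSpec",
    "KoSimSpec",
    "PlantedSite",
    "GenomeSimSpec",
    "RegulomeData",
    "default_cluster_profiles",
    "simulate_kinetics",
    "simulate_ko",
    "simulate_regulome",
    "realized_genotype_variance_fraction",
]

_BASES = np.array(list("ACGT"))
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# kinetics counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsSimSpec:
    """Negative-binomial kinetics experiment with planted expression clusters.

    ``cluster_profiles`` holds one mean log2-expression offset per
    (condition, day) cell and cluster; when None, independent Gaussian
    profiles of sd ``profile_amplitude`` are drawn from the seed.
    """

    n_genes: int = 2000
    n_clusters: int = 9
    conditions: tuple[str, ...] = CONDITIONS
    days: tuple[int, ...] = (1, 2, 3, 4)
    n_replicates: int = 3
    dispersion: float = 0.05
    base_log2_range: tuple[float, float] = (4.0, 10.0)
    profile_amplitude: float = 2.0
    cluster_profiles: np.ndarray | None = None  # n_clusters x (cond*day)
    library_size_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_genes:
            raise ValueError("n_clusters must not exceed n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    @property
    def cells(self) -> list[tuple[str, int]]:
        return [(c, d) for c in self.conditions for d in self.days]


def default_cluster_profiles(spec: KineticsSimSpec, rng: np.random.Generator) -> np.ndarray:
    n_cells = len(spec.cells)
    return rng.normal(0.0, spec.profile_amplitude, size=(spec.n_clusters, n_cells))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial draws; stable as dispersion -> 0."""
    if dispersion < 1e-6:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_kinetics(
    spec: KineticsSimSpec,
) -> tuple[CountMatrix, SampleDesign, pd.Series]:
    """Generate NB counts with planted clusters; returns the truth map
    (gene -> cluster label in 1..n_clusters) for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    profiles = (
        np.asarray(spec.cluster_profiles, dtype=float)
        if spec.cluster_profiles is not None
        else default_cluster_profiles(spec, rng)
    )
    if profiles.shape != (spec.n_clusters, len(spec.cells)):
        raise ValueError("cluster_profiles shape must be n_clusters x n_cells")
    if np.allclose(profiles, profiles[:, :1]):
        warnings.warn("degenerate (flat) cluster profiles; generating anyway")

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    cluster_of = rng.integers(0, spec.n_clusters, size=spec.n_genes)
    base = rng.uniform(*spec.base_log2_range, size=spec.n_genes)

    sample_ids, design_rows = [], []
    for cond, day in spec.cells:
        for rep in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{cond}_d{day}_r{rep}")
            design_rows.append(dict(condition=cond, day=day, genotype="flox",
                                    replicate=rep))
    n_samples = len(sample_ids)
    lo, hi = np.log(spec.library_size_range[0]), np.log(spec.library_size_range[1])
    lib = np.exp(rng.uniform(lo, hi, size=n_samples))

    cell_of_sample = np.repeat(np.arange(len(spec.cells)), spec.n_replicates)
    log2_mu = base[:, None] + profiles[cluster_of][:, cell_of_sample]
    mu = lib[None, :] * np.exp2(log2_mu)
    counts = _nb_counts(rng, mu, spec.dispersion)

    cm = CountMatrix(gene_ids, sample_ids, counts)
    design = SampleDesign(pd.DataFrame(design_rows, index=sample_ids))
    truth = pd.Series(cluster_of + 1, index=gene_ids, name="cluster")
    return cm, design, truth


# ---------------------------------------------------------------------------
# knockout experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KoSimSpec:
    """Knockout experiment at a single day: both genotypes across all
    conditions, with a planted genotype effect on disjoint up/down gene
    sets scaled to a target fraction of total expression variance."""

    base: KineticsSimSpec = field(
        default_factory=lambda: KineticsSimSpec(days=(3,), profile_amplitude=1.5)
    )
    affected_up: frozenset[str] = frozenset()
    affected_down: frozenset[str] = frozenset()
    genotype_log2fc: float = 1.0
    genotype_variance_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base.days) != 1:
            raise ValueError("KO simulation is restricted to a single day")
        if self.affected_up & self.affected_down:
            raise ValueError("affected_up and affected_down must be disjoint")
        if not (0.0 < self.genotype_variance_fraction < 1.0) and self.genotype_log2fc != 0:
            raise ValueError("genotype_variance_fraction must be in (0, 1)")


def _rlog_like(counts: np.ndarray) -> np.ndarray:
    # lightweight log2(normalized + 1) used only to calibrate the effect scale
    lib = counts.sum(axis=0)
    sf = lib / np.exp(np.mean(np.log(lib)))
    return np.log2(counts / sf[None, :] + 1.0)


def simulate_ko(
    spec: KoSimSpec,
) -> tuple[CountMatrix, SampleDesign, dict]:
    """Two-genotype counts with a weak planted genotype effect.

    The effect (+/- ``genotype_log2fc`` on the affected sets, applied to
    the knockout samples) is rescaled so its centered sum of squares on the
    log2 expression scale is the requested fraction of the total; the truth
    dict records the sets, the applied per-gene log2 fold changes and the
    realized variance fraction.
    """
    base = spec.base
    rng = np.random.default_rng(spec.seed)
    profiles = (
        np.asarray(base.cluster_profiles, dtype=float)
        if base.cluster_profiles is not None
        else default_cluster_profiles(base, np.random.default_rng(spec.seed + 1))
    )

    gene_ids = [f"g{i:05d}" for i in range(base.n_genes)]
    universe = set(gene_ids)
    for name, group in (("affected_up", spec.affected_up),
                        ("affected_down", spec.affected_down)):
        stray = set(group) - universe
        if stray:
            raise ValueError(f"{name} not in gene universe: {sorted(stray)[:5]}")

    cluster_of = np.random.default_rng(spec.seed + 2).integers(
        0, base.n_clusters, size=base.n_genes
    )
    base_expr = np.random.default_rng(spec.seed + 3).uniform(
        *base.base_log2_range, size=base.n_genes
    )

    day = base.days[0]
    sample_ids, design_rows = [], []
    for genotype in ("flox", "cre"):
        for cond in base.conditions:
            for rep in range(1, base.n_replicates + 1):
                sample_ids.append(f"{genotype}_{cond}_d{day}_r{rep}")
                design_rows.append(dict(condition=cond, day=day,
                                        genotype=genotype, replicate=rep))
    n_samples = len(sample_ids)
    genotype_vec = np.array([r["genotype"] for r in design_rows])
    cond_index = {c: i for i, c in enumerate(base.conditions)}
    cell_of_sample = np.array([cond_index[r["condition"]] for r in design_rows])

    lo, hi = np.log(base.library_size_range[0]), np.log(base.library_size_range[1])
    lib = np.exp(np.random.default_rng(spec.seed + 4).uniform(lo, hi, n_samples))

    delta = np.zeros(base.n_genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in spec.affected_up:
        delta[idx[g]] = spec.genotype_log2fc
    for g in spec.affected_down:
        delta[idx[g]] = -spec.genotype_log2fc

    log2_mu0 = base_expr[:, None] + profiles[cluster_of][:, cell_of_sample]

    def generate(effect_scale: float) -> np.ndarray:
        cre = (genotype_vec == "cre").astype(float)
        log2_mu = log2_mu0 + effect_scale * delta[:, None] * cre[None, :]
        mu = lib[None, :] * np.exp2(log2_mu)
        return _nb_counts(np.random.default_rng(spec.seed + 5), mu, base.dispersion)

    if spec.genotype_log2fc == 0 or (not spec.affected_up and not spec.affected_down):
        counts = generate(0.0)
        scale, realized = 0.0, 0.0
    else:
        # pass 1: calibrate the effect scale against the realized noise
        baseline = _rlog_like(generate(0.0))
        centered = baseline - baseline.mean(axis=1, keepdims=True)
        total_ss = float(np.sum(centered ** 2))
        n_cre = int(np.sum(genotype_vec == "cre"))
        # centered signal SS per unit scale: sum_g delta_g^2 * n_cre*(n-n_cre)/n
        signal_ss_unit = float(np.sum(delta ** 2)) * n_cre * (n_samples - n_cre) / n_samples
        f = spec.genotype_variance_fraction
        scale = float(np.sqrt(f / (1.0 - f) * total_ss / signal_ss_unit))
        counts = generate(scale)
        final = _rlog_like(counts)
        final_centered = final - final.mean(axis=1, keepdims=True)
        realized = (scale ** 2 * signal_ss_unit) / float(np.sum(final_centered ** 2))

    cm = CountMatrix(gene_ids, sample_ids, counts)
    design = SampleDesign(pd.DataFrame(design_rows, index=sample_ids))
    truth = dict(
        affected_up=set(spec.affected_up),
        affected_down=set(spec.affected_down),
        gene_log2fc=pd.Series(scale * delta, index=gene_ids),
        effect_scale=scale,
        realized_variance_fraction=realized,
    )
    return cm, design, truth


def realized_genotype_variance_fraction(
    expr: pd.DataFrame, design: SampleDesign, null_corrected: bool = True
) -> float:
    """Fraction of centered expression variance explained by genotype.

    Between-genotype sum of squares over the per-gene centered matrix,
    optionally corrected by subtracting the chance level a null genotype
    split would capture (one noise degree of freedom per gene, with the
    noise variance estimated within condition x genotype cells so that
    condition effects do not leak into the correction).
    """
    x = np.asarray(expr, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    total = float(np.sum(centered ** 2))
    cols = list(expr.columns)
    genotypes = design.column("genotype", cols)
    conditions = design.column("condition", cols)
    between = 0.0
    for geno in np.unique(genotypes):
        mask = genotypes == geno
        group_mean = centered[:, mask].mean(axis=1, keepdims=True)
        between += float(np.sum(mask) * np.sum(group_mean ** 2))
    if null_corrected:
        within_ss = 0.0
        n_cells = 0
        for geno in np.unique(genotypes):
            for cond in np.unique(conditions):
                mask = (genotypes == geno) & (conditions == cond)
                if mask.sum() < 2:
                    continue
                cell = centered[:, mask]
                within_ss += float(np.sum((cell - cell.mean(axis=1, keepdims=True)) ** 2))
                n_cells += 1
        n = x.shape[1]
        sigma2 = within_ss / (x.shape[0] * max(1, n - n_cells))
        between = max(0.0, between - x.shape[0] * sigma2)
    return between / total


# ---------------------------------------------------------------------------
# toy regulome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """One planted motif instance: motif consensus of ``tf_id`` written at
    ``offset`` bp from the gene's body start, covered by an ATAC peak and a
    ChIP peak; a Tn5 footprint appears only in the ``footprint_in`` tracks."""

    gene_id: str
    tf_id: str
    offset: int
    footprint_in: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenomeSimSpec:
    n_contigs: int = 1
    contig_length: int = 200_000
    n_genes: int = 20
    motif_set: tuple[Pwm, ...] = ()
    planted_sites: tuple[PlantedSite, ...] = ()
    tracks: tuple[str, ...] = ("Medium_d2", "Medium_d3", "IL27_d2", "IL27_d3")
    peak_width_range: tuple[int, int] = (150, 300)
    background_insertion_rate: float = 0.05
    footprint_depth_factor: float = 0.3
    flank_boost: float = 1.5
    flank_width: int = 50
    gene_body_length: int = 2000
    n_decoy_peaks: int = 0
    n_decoy_chip: int = 0
    scan_p_threshold: float = 1e-4
    decontaminate: bool = True
    seed: int = 0

    GENE_SLOT: int = 10_000  # per-gene territory; keeps +/-3 kb windows disjoint

    def __post_init__(self) -> None:
        if not (0.0 <= self.footprint_depth_factor <= 1.0):
            raise ValueError("footprint_depth_factor must be in [0, 1]")
        per_contig = -(-self.n_genes // self.n_contigs)
        if per_contig * self.GENE_SLOT > self.contig_length:
            raise ValueError("contig_length too small for n_genes")


@dataclass
class RegulomeData:
    genes: list[GeneModel]
    sequences: dict[str, str]
    atac: PeakSet
    chip: dict[str, PeakSet]
    insertions: dict[str, InsertionTrack]
    motif_sites: dict[str, PeakSet]
    truth: pd.DataFrame  # gene_id, tf_id, contig, start, end, footprint_in

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _layout_genes(spec: GenomeSimSpec) -> list[GeneModel]:
    genes = []
    per_contig = -(-spec.n_genes // spec.n_contigs)
    for i in range(spec.n_genes):
        contig = f"ctg{i // per_contig + 1}"
        slot_start = (i % per_contig) * spec.GENE_SLOT
        body_start = slot_start + (spec.GENE_SLOT - spec.gene_body_length) // 2
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(f"gene{i:03d}", contig, body_start,
                               body_start + spec.gene_body_length, strand))
    return genes


def _decontaminate(
    seq: np.ndarray,
    regions: list[tuple[int, int]],
    pwms: Sequence[Pwm],
    protected: np.ndarray,
    p_threshold: float,
    rng: np.random.Generator,
    max_rounds: int = 30,
) -> None:
    """Resample (in place) non-protected bases wherever a chance motif match
    above threshold falls inside a region, until the regions are clean."""
    from .target_network import PwmScanner

    scanners = [PwmScanner(p) for p in pwms]
    for _ in range(max_rounds):
        dirty = False
        for start, end in regions:
            window = _codes_to_str(seq[start:end])
            for scanner in scanners:
                for hit in scanner.scan(window, p_threshold):
                    lo = start + hit.interval.start
                    hi = start + hit.interval.end
                    if protected[lo:hi].all():
                        continue  # the planted instance itself
                    free = np.flatnonzero(~protected[lo:hi]) + lo
                    seq[free] = rng.integers(0, 4, size=free.size, dtype=np.uint8)
                    dirty = True
        if not dirty:
            return
    warnings.warn("decoy decontamination did not converge; chance hits may remain")


def simulate_regulome(spec: GenomeSimSpec) -> RegulomeData:
    """Toy genome with planted direct-target structure.

    Every planted site yields a motif-consensus sequence instance inside an
    ATAC peak inside the gene's +/- 3 kb window, a ChIP peak for its factor
    and — in the designated insertion tracks only — a rectangular Tn5
    footprint (core rate multiplied by ``footprint_depth_factor``, flanks
    elevated toward ``flank_boost``).  Decoy ATAC peaks (no motif, no ChIP)
    and decoy ChIP peaks (outside open chromatin) provide negatives.
    """
    if not spec.motif_set:
        raise ValueError("motif_set must not be empty")
    rng = np.random.default_rng(spec.seed)
    genes = _layout_genes(spec)
    gene_by_id = {g.gene_id: g for g in genes}
    pwm_by_tf = {p.motif_id: p for p in spec.motif_set}
    contigs = sorted({g.contig for g in genes})

    sequences = {
        c: rng.integers(0, 4, size=spec.contig_length, dtype=np.uint8)
        for c in contigs
    }
    protected = {c: np.zeros(spec.contig_length, dtype=bool) for c in contigs}

    # --- plant motif instances ------------------------------------------------
    site_rows = []
    atac_intervals: list[GenomicInterval] = []
    chip_intervals: dict[str, list[GenomicInterval]] = {tf: [] for tf in pwm_by_tf}
    motif_sites: dict[str, list[GenomicInterval]] = {tf: [] for tf in pwm_by_tf}
    for site in spec.planted_sites:
        if site.gene_id not in gene_by_id:
            raise ValueError(f"planted site references unknown gene {site.gene_id}")
        if site.tf_id not in pwm_by_tf:
            raise ValueError(f"planted site references unknown motif {site.tf_id}")
        unknown_tracks = set(site.footprint_in) - set(spec.tracks)
        if unknown_tracks:
            raise ValueError(f"unknown footprint tracks {sorted(unknown_tracks)}")
        gene = gene_by_id[site.gene_id]
        pwm = pwm_by_tf[site.tf_id]
        pos = gene.body_start + site.offset
        if pos < 0 or pos + len(pwm) > spec.contig_length:
            raise ValueError(f"planted site outside contig: {site}")
        consensus = np.array(["ACGT".index(b) for b in pwm.consensus],
                             dtype=np.uint8)
        sequences[gene.contig][pos:pos + len(pwm)] = consensus
        protected[gene.contig][pos:pos + len(pwm)] = True

        width = int(rng.integers(spec.peak_width_range[0], spec.peak_width_range[1] + 1))
        peak_start = max(0, pos + len(pwm) // 2 - width // 2)
        atac_intervals.append(GenomicInterval(gene.contig, peak_start,
                                              peak_start + width,
                                              label=f"atac_{site.gene_id}_{site.tf_id}"))
        chip_width = int(rng.integers(spec.peak_width_range[0], spec.peak_width_range[1] + 1))
        chip_start = max(0, pos + len(pwm) // 2 - chip_width // 2)
        chip_intervals[site.tf_id].append(
            GenomicInterval(gene.contig, chip_start, chip_start + chip_width)
        )
        motif_sites[site.tf_id].append(
            GenomicInterval(gene.contig, pos, pos + len(pwm), strand="+")
        )
        site_rows.append(dict(gene_id=site.gene_id, tf_id=site.tf_id,
                              contig=gene.contig, start=pos, end=pos + len(pwm),
                              footprint_in=",".join(site.footprint_in)))

    # --- decoy peaks ----------------------------------------------------------
    planted_genes = {s.gene_id for s in spec.planted_sites}
    decoy_genes = [g for g in genes if g.gene_id not in planted_genes]
    for i in range(spec.n_decoy_peaks):
        gene = decoy_genes[i % len(decoy_genes)] if decoy_genes else genes[i % len(genes)]
        width = int(rng.integers(spec.peak_width_range[0], spec.peak_width_range[1] + 1))
        center = (gene.body_start + gene.body_end) // 2 + int(rng.integers(-500, 501))
        atac_intervals.append(GenomicInterval(gene.contig, center - width // 2,
                                              center - width // 2 + width,
                                              label=f"decoy_atac_{gene.gene_id}_{i}"))
    for i in range(spec.n_decoy_chip):
        gene = decoy_genes[(i + 1) % len(decoy_genes)] if decoy_genes else genes[0]
        tf = sorted(pwm_by_tf)[i % len(pwm_by_tf)]
        width = int(rng.integers(spec.peak_width_range[0], spec.peak_width_range[1] + 1))
        # placed at the slot edge, outside any ATAC peak and the +/-3 kb window
        start = max(0, gene.body_start - 4500)
        chip_intervals[tf].append(GenomicInterval(gene.contig, start, start + width))

    atac = PeakSet(atac_intervals).sorted()

    # --- scrub chance motif matches from all ATAC peak sequence ---------------
    if spec.decontaminate:
        regions_by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in atac:
            regions_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        for contig, regions in regions_by_contig.items():
            _decontaminate(sequences[contig], regions, spec.motif_set,
                           protected[contig], spec.scan_p_threshold, rng)

    # --- insertion tracks -----------------------------------------------------
    insertions: dict[str, InsertionTrack] = {}
    for track_name in spec.tracks:
        rates = {c: np.full(spec.contig_length, spec.background_insertion_rate)
                 for c in contigs}
        depth = spec.footprint_depth_factor
        flank_mult = 1.0 + (spec.flank_boost - 1.0) * (1.0 - depth)
        for site, row in zip(spec.planted_sites, site_rows):
            if track_name not in site.footprint_in:
                continue
            contig, start, end = row["contig"], row["start"], row["end"]
            rates[contig][start:end] *= depth
            fl = spec.flank_width
            rates[contig][max(0, start - fl):start] *= flank_mult
            rates[contig][end:end + fl] *= flank_mult
        track_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, spec.tracks.index(track_name)])
        )
        insertions[track_name] = InsertionTrack(
            {c: track_rng.poisson(r) for c, r in rates.items()}
        )

    truth = pd.DataFrame(
        site_rows, columns=["gene_id", "tf_id", "contig", "start", "end", "footprint_in"]
    )
    return RegulomeData(
        genes=genes,
        sequences={c: _codes_to_str(s) for c, s in sequences.items()},
        atac=atac,
        chip={tf: PeakSet(ivs).sorted() for tf, ivs in chip_intervals.items()},
        insertions=insertions,
        motif_sites={tf: PeakSet(ivs).sorted() for tf, ivs in motif_sites.items()},
        truth=truth,
    )
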