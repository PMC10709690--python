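# Methods

This note documents the statistical models, parameter choices and known
limitations of th1regnet, in the order the pipeline runs.

## Coordinates and input conventions

All genomic intervals are 0-based half-open internally, matching BED.
Coordinate tables that mirror genome-browser display (the bundled
conserved non-coding element table for the *Il10*, *Prdm1*, *Ifng* and
*Maf* loci, mm10) are 1-based inclusive and converted on read; the
printed coordinates are recoverable via `printed_start`/`printed_end`,
so the reader can be checked against the published table exactly.

ATAC fragments are converted to insertion events by shifting the 5′ end
+4 bp and the rightmost base (frag_end − 1) −5 bp — the usual correction
for the 9-bp Tn5 dimer offset.  The anchoring of the minus-strand shift
to the rightmost fragment base is a convention choice; sources differ
and no downstream statistic is sensitive to a 1-bp anchor change.
Fragments spanning more than 99 bp are excluded as likely
nucleosome-spanning.  Each retained fragment contributes two insertion
events, one per end; whether the original analyses counted one or two
events per end is not generally stated, and two is assumed.

## Normalization and differential testing

Size factors are median-of-ratios over genes expressed in every sample,
rescaled to geometric mean 1.  The regularized transform is
`log2(count/size_factor + 1)`: deterministic, monotone and finite, with
the same variance-damping role as shrinkage-based transforms.  Exact
parity with DESeq2's rlog is explicitly not attempted; every downstream
result that depends on the transform is validated by planted-signal
recovery rather than by matching external outputs.

The two-group test models counts as negative binomial.  Per-gene
dispersion is the method-of-moments estimate pooled over both groups
(var = μ + αμ², floored at 1e-8).  Raw moment estimates at 3–5
replicates are extremely noisy, which makes a plain Wald test either
anticonservative (normal reference) or underpowered (t reference with
residual df), so the estimate is shrunk toward the across-gene median
with a prior weight of 20 df and the Wald statistic is referred to a t
distribution with residual + prior df — the moderation strategy of the
limma/DESeq2 family.  Measured under an equal-means NB null (μ = 100,
α = 0.05, 2000 genes), the type-I error at p < 0.05 is 0.04–0.06 across
seeds at 3–5 replicates per group and null p-values are uniform
(KS < 0.05 at 5000 genes).  Fold changes use a 0.5 pseudocount on group
means.  The DEG filter is fold change ≥ 1.5 with BH-adjusted p < 0.05
(strict inequality); knockout-vs-control contrasts use BH < 0.1;
differential accessibility flags |FC| > 1.5 at FDR < 0.05.

The qPCR relative-expression formula is `1.8^(Ct_Hprt − Ct_gene) × 10⁵`.
Published descriptions of this quantity appear with both sign
conventions; the one implemented makes a higher gene Ct mean lower
expression, which is the standard ΔCt semantics.

## Kinetics clustering

Expression rows are z-scored (constant rows map to zeros with a
warning) and clustered by seeded k-means: Lloyd iterations, k-means++
initialization, 25 restarts, best inertia kept.  k = 9 is the reference
configuration for the kinetics DEG matrix; `choose_k` scores k = 2..12
by average silhouette width and returns the smallest k within 0.10 of
the best.  The margin is a parsimony rule: on unstructured data the
silhouette drifts within ≈0.05–0.1 across k, and a pure argmax chases
spurious splits.  Cluster summaries are per-group means with normal
90 % confidence intervals (mean ± 1.645·sd/√n), validated against a
bootstrap on a 100-gene cluster.  Sample QC uses pairwise Spearman
correlation with average-linkage ordering on 1 − ρ.

## TF–target correlation screen

A gene counts as a transcription factor when it appears in at least two
of the supplied reference lists.  Replicates are first averaged into one
profile per condition × day cell (16 cells in the full design); Pearson
correlation of each TF profile against the target across all cells
jointly is screened at |r| > 0.7, split by sign.  The negative screen is
read as r < −0.7 (the symmetric threshold); the top 9 positive
correlates are each fitted by OLS of the target on the TF.

## SVD attribution of the knockout effect

The regularized expression matrix is centered per gene and decomposed by
thin SVD; component i carries variance fraction s_i²/Σs_j².  The SVD
sign indeterminacy is fixed by orienting every component so the control
(flox) samples' mean score is ≥ the knockout (cre) samples' mean, which
makes the positive/negative gene sets reproducible and column-order
invariant.

Each sample-score vector is fitted by three Gaussian linear models —
condition + genotype, condition only, genotype only — compared by AIC
(2k − 2logL, k counting mean parameters plus the variance).  The
"ANOVA with a chi-squared test" is implemented as R's
`anova(fit_reduced, fit_full, test = "Chisq")` convention for linear
models: the scaled residual-sum-of-squares difference
(RSS_r − RSS_f)/σ̂²_f against χ² with df equal to the parameter
difference.  The raw likelihood-ratio statistic n·log(RSS_r/RSS_f) is
markedly anticonservative at 16–24 samples and is not used.  Genotype
p-values (full vs condition-only) are BH-adjusted across components.

The knockout component is selected among components that (a) have a
genotype-only AIC below the full model's AIC, read literally — the
alternative reading, genotype-only vs condition-only, is computable
from the reported AIC fields — (c) show sign-divergent genotype means,
and reach BH p < 0.05; ties go to the smallest genotype p.  Sign
divergence additionally requires the flox/cre mean gap to exceed the
standard error of the difference, so noise fluctuating around zero does
not qualify.  When no component satisfies all three criteria the best
sign-divergent component by genotype p is returned flagged *weak*; with
permuted genotype labels this weak flag (or outright failure) occurs in
≥ 90 % of simulations, which is the operational null behaviour of the
selection.  Criterion (a) in its literal form is rarely decisive even
for cleanly planted effects (the condition terms absorb enough chance
variance that the full model's AIC stays competitive); recovery of the
planted gene sets is driven by criteria (b)/(c) plus the partition.

Gene loadings of the chosen component are split by sign; within each
sign class a 1-D k-means (k = 2) separates the extreme cluster from the
bulk and the cluster with the larger |centroid| is kept.  Fold-change
profiles across the three knockout backgrounds are clustered with
k = 7.

## Differential footprinting

For each motif, the per-base insertion counts in a ±200 bp window around
all genomic matches are stacked strand-orientedly and averaged; the
statistics are then taken on the summed profile (mean × site count) so
the 0.5 pseudocount acts on the count scale rather than on sparse
per-site rates.  Flanking accessibility FA = log2(mean over the two
50-bp flank windows + 0.5); footprint depth FPD = FA − log2(mean over
the motif core + 0.5).  A bound factor protects its core while its
flanks stay accessible, so both statistics are high.  FPD and FA are
named but not formally defined in the workflows this mirrors; these
log2-ratio forms satisfy the qualitative contract and the windows
(aggregate 200 bp, flank 50 bp) are module configuration.

Between-timepoint deltas (day B − day A) are computed per replicate
pair and averaged — the same replicate-averaging used by the reference
workflow, and necessary in practice: it halves the variance of the
deltas and is what lifts a planted footprint (depth factor 0.3 over a
0.05/bp background at 50 sites) clearly out of the noise cloud.

Outliers of the (ΔFA, ΔFPD) cloud are called by robust Mahalanobis
distance: minimum-covariance-determinant center/covariance (support
fraction 0.75 — the default half-sample support is too aggressive on
panels of a few dozen motifs), d² rescaled so its median matches the
χ²(2) median (a finite-sample consistency correction), p from χ²(2), BH
over motifs, and a bagplot-style fence at fence_factor² × median d²
(fence factor 2).  An outlier must be beyond the fence *and* reach
adjusted significance.  The true Tukey-depth bagplot is approximated by
this Mahalanobis ellipse; the statistical call, not the plot geometry,
is the scientific output.  Measured null behaviour: mean outlier
fraction 0.006 over 100 Gaussian clouds of 50 motifs (bound α + 0.03).

## Motif scanning and target integration

The PWM scanner scores log2(p/bg) sums, integerized at 1e-3 granularity;
the null distribution of the integer score is computed by exact
convolution across motif positions under the background model, giving
exact p-values (verified against exhaustive enumeration of all 4⁶
words to < 1e-9).  Both strands are scanned and the better strand kept
per position; the p ≤ 1e-4 default is the conventional scanning
threshold.  The minus-strand score is referred to the forward null,
exact whenever the background is complement-symmetric (as the default
uniform background is).

ChIP peaks are retained only when they overlap open chromatin (≥ 1 bp
of an ATAC peak, half-open).  Peaks are assigned to genes whose body
±3 kb window they overlap; among multiple candidates the nearest gene
body wins, ties broken lexicographically.  A gene is a direct target of
a factor if one of its ATAC peaks carries ChIP or motif evidence for
that factor.  Regulatory potential is a distance-decayed sum,
RP = Σ exp(−(0.5 + 4d)) over peaks with TSS distance ≤ 100 kb
(d = distance/100 kb), so a peak centered on the TSS contributes
exp(−0.5) ≈ 0.607 and contributions decay ≈ 90-fold across the window.
Networks cap the largest node at the second-highest loading, label the
50 most affected genes, always include the Maf and Prdm1 nodes, and
class edges by which factors bind (maf / blimp1 / both).

## Synthetic data

`simulate_kinetics` draws NB counts (gamma-Poisson, gene-shared
dispersion 0.05) with per-gene baselines log-uniform in 2⁴–2¹⁰,
log-uniform library factors in [0.7, 1.4], and per-cluster mean-log2
profiles over the condition × day cells (default amplitude 2.0 sd,
3 replicates).  `simulate_ko` plants ± a log2 effect on disjoint
up/down gene sets in the knockout samples and rescales it so its
centered sum of squares is a requested fraction of total variance
(default 3 %, the order of magnitude of the attribution problem);
calibration uses a first pass without the effect to measure the
realized noise, so the achieved fraction lands within a few percent of
the target.  `simulate_regulome` lays genes on 10-kb slots (bodies
2 kb, so ±3 kb windows never overlap), writes motif consensus sequences
at planted offsets, covers each with an ATAC and a ChIP peak, and draws
per-track Poisson insertion counts; a planted footprint multiplies the
core rate by the depth factor and raises the flanks toward 1.5×
(interpolated so a depth factor of 1 is an exact no-op).  Decoy ATAC
peak sequences are resampled until they contain no chance motif match
above the scanning threshold, making the planted truth table the
complete set of motif-supported targets; decoy ChIP peaks are placed
outside open chromatin.  All generators are pure functions of their
spec and seed (bitwise-reproducible).

What the generators do **not** emulate: Tn5 sequence bias, realistic
genome composition (sequences are i.i.d. uniform), read-level noise,
overlapping genes, correlated dispersion structure, or batch effects.
Passing the planted-recovery tests therefore shows the algorithms are
correct and calibrated under their stated model assumptions — not that
real-data preprocessing (alignment, peak calling) is handled, which is
out of scope.

## Problem sizes

The shipped simulations are desk-scale by design: 2000 genes ×
24 samples for attribution (20 seeds plus 20 permuted), a 500-kb toy
contig with 40 motifs × 50 sites for footprinting, and 550 genes /
5.5 Mb for target calling.  Published analyses at full scale (tens of
thousands of genes, hundreds of motifs, 10⁴–10⁵ peaks) use the same
code paths; nothing in the implementation assumes the small sizes.

## Known limitations

- The NB test supports two-group contrasts only; no covariate GLM or
  batch correction.
- The ANOVA χ² convention, while matching the reference R semantics, is
  still mildly anticonservative in the extreme tail at 16 samples
  (≈2.5× at p = 0.01); selection consumes BH-adjusted p-values, which
  absorbs most of this.
- The bagplot fence is an elliptical approximation; strongly
  non-elliptical delta clouds would be fenced differently than by a
  true Tukey-depth bag.
- Component indices and variance percentages from any specific
  published dataset are not reproduced; they depend on the deposited
  data and external preprocessing.
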