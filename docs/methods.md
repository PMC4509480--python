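# Methods

This note documents the models, estimators and numerical conventions
implemented in `finestruct`, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Data model

Genotypes are counts of `allele_b` per individual (0/1/2) in an `int8`
matrix with −1 as the missing sentinel. By convention `allele_b` is the
dataset-wide minor allele (lexicographically first on an exact 50/50 tie),
so genotype codes count minor-allele copies. All statistics are
missingness-aware: per-SNP sample sizes, frequencies and heterozygosities
are recomputed from non-missing calls, and LD r² uses pairwise-complete
observations. I/O is PLINK text PED/MAP ("0 0" = missing) and a delimited
metadata table (sample_id, state, region, latitude[, longitude]); binary
PLINK, VCF, strand-flipping and multi-allelic sites are out of scope.

Two packaged reference tables anchor the geography and the differentiation
scan: the 13 Peninsular Malaysian/Singaporean sampling locations with
region (North/Centre/South), latitude in decimal degrees and post-QC
subject counts (one printed count of 7 spans the Perlis/Kedah/Pulau Pinang
rows and is recorded on the Perlis row, the others left missing, mirroring
the source table); and the published list of the most differentiated
north–south SNPs (θ, regional minor-allele frequencies, gene annotations;
74 rows were recoverable from the source text). In the SNP table a few
chromosome/position entries were ambiguous in the source formatting; gene
annotations resolved most, and θ and frequency columns — the quantities the
analyses consume — are unambiguous throughout.

## Quality control

Stages run in a fixed order: sample missingness → SNP missingness → MAF →
HWE exact test → LD pruning, each recording removed/retained counts.
Thresholds are strict in their stated direction (missing fraction > 0.10
removed, MAF < 0.05 removed, HWE p < 0.002 removed), so boundary values are
retained. The HWE test is the two-sided exact test with probability-mass
ordering (no mid-p), computed on all samples pooled, via the standard
stable recurrence on the conditional distribution of heterozygote counts
given allele counts; the test suite checks it against an independent
log-gamma enumeration to 1e-12 for all counts up to n = 200. Whether the
original QC used the exact or chi-square HWE test is not documented; exact
was chosen as the PLINK-era default.

LD pruning slides a window of 50 SNPs advancing by 5 (configurable; only
the r² > 0.8 rule is dictated by the analysis being reproduced) over
(chrom, pos)-ordered variants; within a window, any pair with r² above
threshold loses its lower-MAF member (ties: later position). The procedure
is deterministic and idempotent.

## PCA

Standardization follows the smartPCA convention: center each SNP on its
observed mean, scale by √(p̂(1−p̂)) with the pseudocount estimate
p̂ = (1+count_b)/(2+2n), impute missing entries to the column mean, drop
constant columns with a warning. Scores are eigenvectors of the
sample-covariance matrix X Xᵀ/L scaled by √eigenvalue, with each PC's sign
fixed so its largest-magnitude entry is positive (the sign is theoretically
arbitrary; the convention makes outputs reproducible). Iterative
outlier removal (|score| > n·SD on any PC, refit, repeat) is available but
disabled by default: the analysis this package reproduces excluded "several
outliers" without stating a rule, so our rule (6 SD, up to 5 iterations) is
an explicit stand-in.

Detectability context: two-population structure at differentiation F
becomes visible on PC1 roughly when F exceeds 1/√(nL). At the full study
scale (n ≈ 402, L = 41,400) the threshold is ≈ 2.5 × 10⁻⁴, comfortably
below the observed F ≈ 10⁻³.

## F_ST

The estimator is the two-population Weir–Cockerham variance-components θ
(a = between-population, b = between-individual, c = within-individual),
with per-SNP nᵢ recomputed from non-missing genotypes and h̄ taken from
observed heterozygote counts. When only allele frequencies are available
(the worked examples from published regional frequencies), h̄ defaults to
its HWE expectation; the two published example SNPs reproduce to 0.0001
and 0.0011 of their printed θ under this convention. Frequencies must be
oriented to a common allele before comparison — published per-region MAFs
name each region's own minor allele, so the southern frequency is converted
to 1 − MAF where the regional minor alleles differ (the related
`minor_allele_discordance` scan counts exactly such SNPs, resolving
frequency-0.5 ties to `allele_b`).

Genome-wide combining is the ratio of sums Σa/Σ(a+b+c) (standard
near-unbiased practice), never the mean of per-SNP ratios, and negative
values are reported unclipped. Confidence intervals: percentile bootstrap
resampling SNPs with replacement (default 1,000 replicates, 2.5/97.5
percentiles), treating the genome as the resampling unit with samples
fixed; an individual-resampling bootstrap is available behind a flag. At
L = 5,000 the nominal 95% CI covers the generating F in ~90% of runs
(slightly anticonservative; computed by the acceptance script) and
calibration improves with L. Bootstrap standard errors at L = 41,400 and
F ≈ 10⁻³ are ≈ 3–4 × 10⁻⁵.

The top-differentiation scan ranks SNPs by θ descending; the top-fraction
cut includes every SNP tied with the boundary value, and the absolute
threshold mode returns θ strictly above the cutoff.

## Admixture EM

The likelihood is the binomial admixture model
g_ij ~ Bin(2, Σ_k q_ik f_kj) over non-missing genotypes, with mixture
probabilities clamped to [1e-10, 1−1e-10]. Fitting uses plain EM on
expected allele counts — the update reduces to three matrix products — which
is monotone in the log-likelihood; the quasi-Newton acceleration of the
dedicated tools is deliberately out of scope, since the scientific content
is the fitted Q, not the optimizer. Initialization is Dirichlet(1) rows of
Q and Uniform(0.05, 0.95) entries of F; defaults are tol 1e-6 on the
log-likelihood gain, max 2,000 iterations, and 3 seeded restarts keeping
the best likelihood (local optima exist at weak differentiation). K = 1 is
solved in closed form. Regional comparison of a component uses per-sample
means per region and a Welch two-sample t-test (the original analysis did
not name its test; Welch is the robust default).

## Geography

The latitude correlation uses state-level mean PC1 as the analysis unit by
default (matching the ~13-point regime in which such clines are reported);
a per-sample mode is available. Pearson r with the two-sided t-transform
p-value (n−2 df). Distances are haversine on a spherical Earth of radius
6371 km (sub-0.5% error at peninsular scale). F_ST-versus-distance reports
the simple Pearson correlation over unordered pairs, as is conventional,
with an optional Mantel permutation p alongside — pairs sharing a
population are not independent, making the parametric p anti-conservative,
so the permutation p is the honest significance measure.

A note on null expectations: with 13 state-level points the expected r²
between two unrelated variables is 1/(n−1) ≈ 0.08 by construction.
Null-coordinate checks (e.g. a longitude axis with no longitudinal
structure) are therefore run in per-sample mode (n = 402,
E[r²] ≈ 0.0025), where "no signal" is actually distinguishable from the
small-n baseline.

## GWAS simulation

Cohorts are built by drawing each individual's subpopulation from
phenotype-specific mixing fractions (unequal fractions between cases and
controls create the stratification confounder) and genotypes from that
subpopulation's Balding–Nichols frequencies. Disease risk is multiplicative
on the odds per copy of `allele_b` at causal SNPs
(risk = prevalence · Π rr^g, capped at 1), realized by rejection sampling
with a bounded attempt budget; with no causal SNPs acceptance is immediate.
The original simulation scenarios are not published in retrievable form, so
all scenario parameters are user-configurable, with documented defaults
mirroring the observed study regime (F = 10⁻³–10⁻², L up to 41,400 null
SNPs, 1,000 cases/1,000 controls, α ∈ {0.05, 10⁻⁴}).

The default test is the 1-df allelic chi-square (the era's standard
case–control test); the Cochran–Armitage trend test is provided, and the
two coincide exactly when the pooled sample is at HWE genotype proportions
(verified algebraically in the tests). λ_GC = median(χ²)/0.4549 over null
SNPs; genomic-control adjustment divides statistics by max(λ, 1). In the
balanced-mixture stratified design the per-SNP inflation is an
approximately constant scale factor on the chi-square (the ancestry-driven
frequency-difference shift is Gaussian across SNPs with variance
independent of pq), which is why genomic control restores the
false-positive rate essentially exactly in these simulations — a property
of this design, not of stratification in general.

Allele counts are discrete, so null p-values carry an atom at 1 (mass
≈ 0.02 at 500+500 samples); calibration checks bound the empirical
deviation from uniformity rather than a KS p-value.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the estimators assume:
independent SNPs, Hardy–Weinberg genotypes within subpopulations,
Beta-distributed subpopulation frequencies with variance F·p(1−p) (so the
generator's F is exactly the estimator's estimand), uniform ancestral MAF
in (0.05, 0.5) matching a post-QC spectrum, optional uniform genotype
missingness, and a latitudinal cline of `slope` allele-frequency units per
degree latitude on top of residual drift. Defaults for the cline were fixed
from the study regime before testing: slope 0.005/degree with residual
F = 3 × 10⁻⁴ yields a north–south θ ≈ 1.1 × 10⁻³ over the ~4° span between
the northern and southern state groups, matching the observed genome-wide
differentiation. The printed subject count spanning three northern states
is split 3/2/2 in simulation defaults.

Not emulated: linkage disequilibrium (so LD pruning is exercised only on
planted duplicates), relatedness, genotyping batch effects, sex
chromosomes, site-frequency-spectrum realism, and selection. Passing tests
therefore establish estimator correctness and calibration under the model's
assumptions, not robustness to LD or cryptic relatedness in real cohorts.
Counts that depend on the real genotypes (e.g. how many SNPs fall in the
top 1% with θ > 0.05) are checked as properties of the scan rules on
packaged reference values and constructed fixtures, not re-derived.

## Problem sizes and reproducibility

Full-scale runs use L = 41,400 SNPs with regional sample sizes 146/149/107;
bootstrap-calibration sweeps use L = 5,000 over 100 seeds; stratification
simulations 20,000 null SNPs at 1,000+1,000 samples; admixture recovery
L = 2,000 at n = 50/50; cline detection L = 20,000 over 20 seeds. These
sizes keep each analysis in the seconds-to-minutes range on one core while
staying in (or scaling down proportionally from) the study's regime. Every
stochastic component draws from `numpy.random.default_rng` substreams
spawned from one `SeedSequence`, so a fixed seed reproduces datasets,
bootstrap replicates and EM trajectories byte-for-byte; the pipeline fans
one global seed out to its stages and records it in every manifest.

## Known limitations

- The two-population variance-components θ only; no joint r > 2 estimator
  (pairwise matrices cover the multi-region analyses).
- EM admixture is slow to fully polarize Q near fixation; with tol 1e-6 it
  can hit the iteration cap with the likelihood still creeping — results
  there are accurate in Q to well under the reported tolerances, but the
  `converged` flag is honest about it.
- Percentile bootstrap CIs are mildly anticonservative at small L.
- The PED reader infers each site's minor allele from the file itself, so
  round-trip code identity holds for datasets already in minor-allele
  orientation; data content is preserved regardless.
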