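# Methods

## Model and procedure

The pipeline detects candidate selection signatures by contrasting two
phenotype groups (I: trait present, II: absent) within one breed dataset.
Its underlying model is pure drift: descendant group allele frequencies
scatter around an ancestral frequency π with variance c·π(1 − π), the
Balding–Nichols Beta parameterization with drift parameter c ∈ (0, 1).
Under exchangeable groups, per-SNP differentiation fluctuates around the
genome-wide background level; a region under differential selection shows
locally elevated differentiation across several adjacent markers. The scan
therefore (1) estimates per-SNP FST, (2) smooths it over a local SNP
window to suppress single-marker noise, (3) flags SNPs whose smoothed
value strictly exceeds the genome-wide empirical 99th percentile, and (4)
merges runs of flagged SNPs into regions for gene/QTL annotation.

### FST estimators

`weir_cockerham` (default) is the classical two-population
variance-components point estimate θ̂ = a/(a + b + c) computed from diploid
genotype counts, with the usual n̄, n_c, p̄, s², h̄ components; it is exact,
formula-anchored, and testable to machine precision against a scalar
transcription of the components. `pure_drift_moment` targets the drift
parameter directly: c̃ = (s² − v̄)/(p̄(1 − p̄)), with s² the unweighted
two-group sample variance of frequencies and v̄ the mean estimated binomial
sampling variance p̂ᵢ(1 − p̂ᵢ)/(2nᵢ − 1). The estimate is truncated at the
parameter-space bound 1 (a fixed difference gives exactly 1); negative
finite-sample values are retained in the raw track for audit. Both
estimators correlate > 0.99 on simulated variants at realistic sample
sizes, and the smoothing/quantile machinery is estimator-agnostic.

A caution documented here because it shapes what tests can assert: the
per-variant moment estimate from two groups has a 1-degree-of-freedom
χ²-like numerator, so its distribution across variants is strongly
right-skewed — its *median* is ≈ 0.45 of its mean even when the mean is
unbiased for c. Genome-wide drift should therefore be estimated with
`estimate_drift_c`, the pooled ratio of summed moments across variants,
which concentrates tightly around the true c (within a few percent at
2000 variants, n = 50/group).

### Smoothing, outlier rule, regions

Smoothing uses a centred window counted in SNPs (default 9, odd,
configurable; uniform mean or triangular kernel). Windows truncate at
chromosome ends and renormalize over the shrunken support; missing raw
values are excluded with renormalization; a chromosome shorter than the
window falls back to its chromosome-wide mean (logged). Raw values are
clamped into [0, 1] before smoothing by default to prevent cancellation
artifacts from negative finite-sample estimates; the unclamped raw column
is kept in the output. The window default reflects the ~25 kb marker
spacing of the target arrays: 9 SNPs ≈ 200 kb, small relative to
selective-sweep footprints but wide enough to damp single-marker noise.

The outlier threshold is the linear-interpolation empirical quantile
(default 0.99) of all smoothed values in the breed dataset, genome-wide —
one threshold per comparison, not per chromosome. Flagging is strict
(> threshold), so a constant track flags nothing and on 1000 distinct
values exactly the top 10 are flagged at q = 0.99. Consecutive flagged
SNPs within `region_merge_gap_bp` (default 1 Mb) form one region; region
bounds are the min/max member positions (1-based inclusive; converted to
0-based half-open only when written as BED).

A structural property of any fixed-quantile rule: it flags ≈ 1 − q of SNPs
*by construction*, whether or not true signal exists. On a 5000-SNP null
dataset ≈ 50 SNPs are flagged and merge into roughly 8–10 background
regions; planting one strong window re-allocates about half of the flags
to it but leaves ~25–30 background exceedances, hence several background
regions per run. Users should treat the region list as a ranked candidate
set — peak smoothed FST and member count separate planted-scale signals
from background — rather than as a calibrated discovery set with
controlled false-positive count.

## Quality control

Order: missingness → HWE → relatedness → monomorphic removal → LD pruning,
with exact bookkeeping per step.

- **Missingness**: remove variants with missing-call fraction strictly
  above 2% (a 2.0%-missing variant at n = 100 is retained).
- **HWE**: exact conditional test; conditions on the observed allele
  counts, enumerates all attainable heterozygote counts via the standard
  probability recurrence, and sums the probabilities of configurations no
  more probable than the observed one (no mid-p correction). Applied to
  the pooled breed sample at α = 1e-7; monomorphic variants get p = 1 and
  are never removed by this filter. Verified exhaustively against exact
  rational enumeration for all configurations up to 50 samples.
- **Relatedness**: the GRM is VanRaden method 1, G = ZZᵀ / (2Σpⱼ(1 − pⱼ)),
  with mean imputation of missing dosages; computed once, then samples are
  greedily removed (most over-cutoff partners first; ties by higher
  missingness, then sample id) until no off-diagonal exceeds the cutoff
  (default 0.75). The relatedness statistic behind the cutoff is the GRM
  off-diagonal — made explicit here since "relatedness cutoff" tools vary.
- **LD pruning**: windows of 50 SNPs advanced by 5, within-chromosome
  only; r² computed on mean-imputed, variance-standardized dosages
  (chosen over pairwise-complete correlation: one standardization serves
  the whole window and missingness at array scale is ≤ 2% post-filter);
  the later-positioned member of any pair with r² > 0.2 is removed until
  the window has no violating pair.

Monomorphic variants (FST undefined) are removed before the scan and
logged separately.

## Structure diagnostics

The GRM is eigendecomposed directly ("SVD of the GRM": for a symmetric PSD
matrix the two coincide); scores are eigenvectors scaled by √eigenvalue,
signs fixed so each axis's largest-magnitude loading is positive
(deterministic across BLAS builds). Variance explained is each
eigenvalue's share of the trace. The cluster report computes per-label
centroids and silhouette scores on axes 1–2 for the breed labeling and the
group labeling: a healthy dataset shows breeds as well-separated clusters
(high breed silhouette) and no case/control stratification (group
silhouette near zero). When breeds are present the diagnostic is run
jointly across breeds on the variants all breeds retained, while QC and
the scan run per breed.

## Synthetic data generator

The generator realizes exactly the model the scan assumes: π ~
Uniform(0.05, 0.5); per group p ~ Beta(π(1 − c)/c, (1 − π)(1 − c)/c) with
c = `background_c` (default 0.01, weak genome-wide differentiation of the
order seen between phenotype groups drawn from one herd); genotypes
Binomial(2, p) per sample; uniform missingness (default 1%). Defaults of
40 samples/group and 5000 SNPs on 5 chromosomes with ~25 kb mean
Exponential spacing echo, at desk scale, cohorts of 70–75 pigs per breed
genotyped on a ~68k array. Planted windows shift the two groups'
frequencies by ±δ/2 with opposite signs (clipped to [0.01, 0.99]), giving
a directly controllable effect size; a locally elevated drift mode
(`c_planted`) is also available. Genotypes are drawn by comparing two
per-cell uniforms to p, so with a fixed seed the data are monotone in δ —
common random numbers for power curves. A toy gene file places one named
gene in each planted window plus two decoys per chromosome so the
annotation stage runs end to end on simulated data.

What the generator does *not* emulate: linkage disequilibrium between
markers (SNPs are independent given frequencies), pedigree structure, and
ascertainment of array SNPs. Passing tests therefore validate the scan's
marginal statistics and calibration, not its behaviour under real LD — on
real arrays neighbouring SNPs are correlated, which widens smoothed-FST
exceedance clusters and makes the effective number of independent windows
smaller than the SNP count.

## Numerical choices

- HWE uses a multiplicative probability recurrence normalized at the end;
  observed-probability comparisons use a 1 + 1e-12 relative tolerance to
  absorb floating-point ties; exact to < 1e-12 against rational
  enumeration for n ≤ 50.
- GRM mean-imputation assigns z = 0 to missing cells (no information, no
  contribution); the all-monomorphic case (zero scale) is an error.
- Smoothing is implemented as two convolutions (values and validity
  masks) per chromosome; equal to the naive O(n·w) loop to 1e-12.
- The empirical quantile uses NumPy's default linear interpolation; this
  definition is part of the output contract and recorded in the track
  header.
- Ties in greedy removals (relatedness, LD) are broken by missingness
  then identifier, making every QC step deterministic.
- Degenerate inputs: empty variant sets round-trip through both PLINK
  dialects; monomorphic variants yield NaN FST and are excluded from
  smoothing with weight renormalization.

## Interfaces and conventions

Coordinates are 1-based inclusive (the `.bim`/`.map` convention)
everywhere inside the package; BED conversion happens only at the I/O
boundary. Dosage counts copies of `allele_a` (the A1 column). The missing
sentinel is −1, never 0 (0 is a valid homozygote dosage). The text
dialect records no A1/A2 designation, so the text reader canonicalizes
`allele_a` to the minor allele (ties and monomorphic sites:
lexicographically smaller observed allele); the binary dialect
round-trips any orientation exactly. Non-autosomal chromosomes (non-
numeric labels) are excluded from the scan by default, configurable.
Chromosome names are normalized by stripping `chr`/`SSC` prefixes plus an
optional user alias map. Case/control groups are read from and written to
the PLINK phenotype column (2 → group I, 1 → group II).

Enrichment replaces live gene/pathway services with user-supplied files:
gene models (BED/GFF3/TSV), a gene → category map, and a background set
defaulting to all genes in the supplied model file. The test is one-sided
Fisher exact (hypergeometric upper tail) per category with
Benjamini–Hochberg q-values across categories.

## Known limitations

- No LD-aware simulation; calibration claims transfer to real arrays only
  qualitatively (see generator section).
- The fixed-quantile outlier rule has no false-discovery control; the
  expected count of background regions per run is a property of the rule,
  not an implementation artifact.
- Two populations only; the variance-components estimator generalizes to
  r > 2 but the moment drift estimator as implemented does not.
- Haplotype statistics (iHS, XP-EHH), Bayesian FST posteriors, and
  association testing are out of scope.
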