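# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the frozen validation-study
designs behind `mirnet-gsa`.

## Mixed-model association scan

The scan is the classic two-step variance-component approximation.
Step 1 fits `y = 1μ + a + e` with `a ~ N(0, G σ²ₐ)`, `e ~ N(0, I σ²ₑ)`
by REML. `G` is a VanRaden method-1 genomic relationship matrix,
`G = WWᵀ / Σⱼ 2pⱼ(1−pⱼ)` with dosages centred by twice the observed
allele frequency; the method-1 form with observed frequencies is the
field standard for cattle. The design matrix linking records to animals
is the identity: one phenotypic record (a de-regressed proof, treated as
a plain quantitative value) per animal, so no incidence structure is
needed.

The one-dimensional REML problem in λ = σ²ₐ/σ²ₑ is solved on the
eigenbasis of `G`: one symmetric eigendecomposition per GRM, after which
each likelihood evaluation is O(n). A 61-point log-spaced grid over
λ ∈ [10⁻⁶, 10⁶] brackets the optimum and Brent's method refines it
(tolerance 10⁻¹⁰ on log₁₀ λ). Eigenvalues are clipped at zero (the GRM
is PSD up to numerical jitter); solutions pinned at the λ bounds are
flagged as boundary fits, with σ²ₐ set to 0 at the lower bound.

Step 2 holds (σ²ₐ, σ²ₑ) fixed and tests each marker by GLS. The data are
whitened by `(λG + I)^{-1/2}` on the same eigenbasis and an ordinary
two-column regression (intercept + marker) is run on the whitened data,
with the residual scale re-estimated per marker. The statistic is
Student-t with n−2 degrees of freedom. Rationale: at the small n of
synthetic studies the t reference is exact in the σ²ₐ = 0 limit (the
scan then reproduces OLS to machine precision, which the tests assert at
10⁻¹⁰), and it converges to the classic normal approximation at large n.
Markers monomorphic after projection get b = 0, p = 1 and an undefined
standard error rather than an exception.

**LOCO.** The GRM for a marker's test excludes the marker's chromosome,
so the candidate is not double-fitted. Because the GRM changes per
chromosome, the variance components are re-fitted per chromosome by
default; a single genome-wide fit (the cheaper classic shortcut) is
available via `vc_refit="once"`. With a single chromosome there is
nothing to leave out, and the scan falls back to the full GRM with a
warning.

**QC.** Markers are dropped when minor allele frequency ≤ 0.01 or when a
1-df chi-square Hardy–Weinberg test on rounded dosages (halves round up;
imputed dosages carry no hard calls) gives p ≤ 10⁻⁶.

**QTL demarcation.** Starting from the most significant genome-wide
significant SNP, a region extends contiguously up- and downstream while
−log₁₀ p stays within 3 of the top SNP's; the first failing SNP stops
the extension (contiguous-run semantics — allowing gaps is the other
reading, not taken here). The region's SNPs are then removed and the
procedure repeats. The variance explained by a region's top SNP is
`2pq b² / σ²ₐ`.

## Marker-set test

For feature *f*, `T_sum = Σ_{i∈f} t²ᵢ` over its member SNPs. The sum
statistic is chosen for highly polygenic traits, where many small
signals add up better than a max-based statistic would.

The null preserves LD: the genome-ordered t² vector (chromosomes
concatenated in natural order; rotation wraps across chromosome
boundaries) is rotated by a random offset and `T_sum` is re-read at the
feature's original positions. Numerical choices, each exposed as a flag
where genuinely open:

- offsets are sampled uniformly **with replacement** from {1, …, m−1};
  the identity offset is excluded (the observed configuration is not a
  null draw);
- when m−1 ≤ n_perm the m−1 rotations are enumerated exactly instead of
  sampled;
- the empirical p is add-one, `(1 + #{null ≥ obs}) / (n_perm + 1)`, so p
  is never 0 and −log₁₀ p is always defined; ties count against
  significance. The ≥ comparison uses a 10⁻⁹ relative tolerance so
  rotations that are mathematically tied with the observation (e.g. the
  feature covering the whole genome) are not split by floating-point
  summation order;
- one stream of rotation offsets per trait is shared across features by
  default (rotations are feature-independent; sharing halves cost and
  mirrors a single permutation stream per analysis); per-feature
  independent streams are available and are what the calibration study
  uses, since its binomial error band presumes independent Monte-Carlo
  noise across features.

Empty (non-testable) features are reported with NaN statistics, never
silently dropped.

## Features from annotations

SNP-to-gene assignment is purely positional: a SNP belongs to a gene
when its position lies between the gene's start and end, 1-based
inclusive on both ends (BED input is converted from 0-based half-open on
read); strand is ignored; a SNP inside overlapping genes belongs to each
of them. The all-miRNA set is the deduplicated union of markers within
±flank kb of every precursor, clipped at position 1 — flanks matter
because precursors are tens of bases long and rarely contain a marker.
A network's marker set is the union of its target genes' ORF SNPs;
targets without markers stay in the member list but contribute nothing.
Curated gene sets are kept only with ≥ 10 member genes by default.
Random comparison networks are size-matched uniform draws without
replacement from the *testable* gene universe (genes with ≥ 1 ORF SNP) —
the universe choice keeps random sets SNP-count-comparable. When GMT
descriptions carry `score=` values, networks can be restricted to the
top quantile of scores (e.g. the best 25% of predictions).

## Correlations between traits and breeds

Per-feature enrichment is −log₁₀ p. Correlations between two analyses
are Pearson by default (Spearman by flag) over the features present in
both (intersection semantics). Significance: all networks are redrawn at
random, size-matched, the marker-set test is rerun for both analyses
with the same random networks (one draw per repetition, reused across
both columns and across column pairs), and the correlation recomputed —
1,000 times by default. The observed r is referred to N(μ, σ²) with μ, σ
the mean and SD of the null correlations, upper tail. The normal
approximation can return p-values beyond the 1/1001 permutation
resolution; they are reported untruncated.

## Transcriptome integration

A network is significant for a trait when its marker-set p < α in every
breed (α = 0.05; implied joint level α³ = 1.25 × 10⁻⁴ at three breeds);
networks missing a p-value in any breed are not callable. DETs are
targets with FDR < 0.05 in ≥ 2 infection conditions. Regulation
direction is read from the log₂ fold-changes of the gene's *significant*
conditions only: all positive → up, all negative → down, mixed signs →
excluded from both and reported separately (forcing a side would invent
a direction the data contradict). Overlap tests are upper-tail
hypergeometric with the measured genes as universe (standard practice;
whole-genome universes inflate enrichment). Pathway screens adjust by
Benjamini–Hochberg and keep FDR < 0.1, reporting GeneRatio as enriched /
annotated query genes. The DET vs non-DET comparison is paired and
one-sided across networks (paired t by default; rank-sum and Welch
variants available), pairing each network's DET-side enrichment with its
own non-DET side.

## Synthetic cohorts: what they emulate, and what not

Genotypes are a mosaic of ancestral haplotypes: each LD block has K
founder haplotypes (default 20) and every individual draws two per
block, independently across blocks. This yields strong within-block LD,
weak between-block LD, background relatedness from founder sharing, and
rejection sampling at the founder-allele level enforces a floor on the
realized MAF (default 0.05). Defaults: 5 chromosomes × 2,000 markers at
2 kb spacing (10,000 markers, 4 Mb chromosomes), 5-marker (10 kb) LD
blocks, 200 genes of 3–7 markers, 30 miRNAs with precursor lengths
uniform on 52–148 bp, target networks of 5–60 genes averaging 20.

Phenotypes are `y = Σ xⱼβⱼ + e` with Gaussian effects. Enrichment in a
designated feature set is either a variance multiplier on in-feature
causal effects (`variance`, default) or a sampling-weight multiplier on
causal placement (`density`); both are plausible readings of "enriched
with causal variants" and the test must detect either. Two deliberate
generator choices:

- **Stratified causal placement.** The number of causal markers inside
  the enriched features is fixed at its (rounded) expectation rather
  than binomial. The marginal model is unchanged, but the planted
  condition is realized in every replicate — a power study against "a
  planted enrichment" should not be diluted by replicates where the
  plant failed. `enrichment_fold=inf` under `density` places every
  causal marker inside the features (used to emulate causal variants
  residing in DE genes).
- **Exact-h2 noise scaling.** The residual is orthogonalized against the
  genetic values and scaled so the realized genetic variance fraction
  equals h² exactly, making truth-based checks sharp.

A shared `SyntheticTruth` can be passed back in to reuse one causal
architecture (same markers, same effects) across several breed cohorts —
the same variants segregate in all breeds, which is precisely the
consistency that all-breeds significance calling exploits.

Expression contrasts plant a fraction (default 70%, echoing the observed
~3/4 DET share of real infected networks) of each responsive network's
targets as DE: one regulation sign per gene, nominally DE per condition
with probability 0.5 (conditioned on ≥ 2 conditions), |log₂FC| near 2
with SE 0.5; null genes get standard-normal z-scores, hence uniform
p-values; BH is applied within condition. Condition labels default to
the LPS/E. coli liver and mammary time-course contrasts (LL3 … ME24) but
are free-form.

Not emulated: coalescent-grade haplotype history, imputation error,
allele-frequency–effect-size coupling, sequence-level features,
miRNA-target prediction itself (networks are random sets), and
between-condition correlation of expression noise. Passing tests
therefore show the *pipeline* behaves as specified under its stated
statistical assumptions, not that real bovine data would yield the same
numbers.

## Validation-study designs (frozen)

All studies live in `mirnet_gsa.studies`, seed-controlled end to end.
Problem sizes were fixed at design time by a power analysis of the
generator — the marker-set z-score scales roughly as n·h²·φ/√(m_f) for a
feature holding a fraction φ of the causal variance, so reduced-scale
studies keep the signal-to-marker-count ratio, not the raw counts, in
the detectable regime — and were not revisited afterwards.

- **Null calibration**: default 10,000-marker cohort, n = 500, pure-noise
  trait, 500 random features of 50–500 markers, 1,000 rotations each
  with per-feature streams; type-I error at 0.05 is checked against the
  binomial 95% band [0.036, 0.064] and the p-values against uniformity
  (KS p > 0.01).
- **Power**: 1,250-marker genome, 60 genes, one planted 45-gene network
  (≈ 235 markers), prop_causal = 0.12, variance-mode fold 5, h² = 0.5,
  n = 500; 100 replicates; detection is p < 0.05.
- **REML recovery**: 2,000-marker cohorts, n = 500, true h² = 0.5
  realized exactly; 100 replicates; the mean estimate must lie in
  [0.45, 0.55]. The GLS/OLS identity is checked to 10⁻¹⁰ at σ²ₐ = 0.
- **Rotation oracle**: a 5,000-marker heavy-tailed t² vector; the
  sampled p (1,000 offsets) must sit within 3 Monte-Carlo SE of the
  exhaustive all-rotations p; the 4-marker enumeration
  (t² = [1,4,9,16], feature on the first two positions → null sums
  {13, 25, 17}) is checked exactly.
- **End-to-end integration**: three cohorts of n = 1,000 sharing one
  annotation (2,500 markers, 150 genes, 25 networks of 12–16 genes) and
  one causal architecture; 5 networks planted as infection-responsive,
  all causal variants inside their DE genes; per-breed scans + set
  tests, all-breeds calling at 0.05, and a paired one-sided DET vs
  non-DET t-test pooled over (network × breed) pairs; 10 replicates.

## Known limitations

- The EMMAX approximation fixes variance components per chromosome, not
  per marker; for very large single-SNP effects an exact mixed model
  would give slightly different p-values.
- Rotation nulls assume approximate stationarity of the t² field along
  the genome; strong megabase-scale heterogeneity (e.g. one enormous
  QTL) makes the null conservative for features near it.
- The normal approximation for correlation significance is parametric on
  1,000 replicates and can understate tail uncertainty.
- Random networks are size-matched on gene count, not on SNP count;
  networks of few long genes are compared against random sets that may
  carry fewer SNPs.
- X-chromosome handling, dominance/epistasis, multi-trait models and
  genotype imputation are out of scope.
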