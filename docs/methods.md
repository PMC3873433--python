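# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic-study generator does and does
not emulate, and the numerical choices a maintainer should know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modeled

The pipeline targets a pair of sex-stratified nested case-control studies
drawn from prospective cohorts: incident disease cases matched ~1:2 to
controls, genotyped on a common array, with quantitative biomarkers and
lifestyle covariates measured at baseline. Analysis is *unconditional*
logistic regression (matching is not modeled downstream), reflecting the
situation where original matches cannot be preserved; the matching variables
(age, smoking) are instead carried as covariates.

## Synthetic-study generator (`syndata`)

The generator inverts the analysis models so that every downstream stage has
planted truth to recover.

**Genotypes.** SNPs are biallelic hard calls at Hardy-Weinberg proportions.
SNPs are grouped into LD blocks of `ld_block_size` (default 10); each block
shares one MAF drawn from `maf_range` (default U(0.05, 0.5)). Each haplotype
is drawn by thresholding an exchangeable multivariate normal (Gaussian
copula) at Φ⁻¹(MAF). Because thresholding attenuates correlation, the latent
correlation is calibrated by Brent root-finding on the bivariate normal
orthant probability so the *genotype* correlation equals the configured
`ld_r` (default 0.6); calibrated values are cached per (MAF, r). Positions
advance in fixed 25 kb steps with a new chromosome every 400 SNPs, so a
10-SNP block spans 225 kb and the 100 kb pruning rule is non-trivial.
Missing calls are injected independently at `missing_rate` (default 1%,
below the 2% QC threshold so QC removes only unlucky SNPs).

**Binary endpoint.** logit P(case) = c + Σ log(OR)·dosage + 0.03·(age−mean)
+ 0.4·smoke (+ interaction terms). The intercept c is tuned by bisection so
the expected case fraction equals the design fraction (1/3 at the default
450:900); labels are drawn on an oversampled pool (factor 2) and exactly
`n_cases`/`n_controls` are then sampled, emulating nested case-control
ascertainment. Default per-allele OR 1.6 over 20 causal SNPs: detectable
but not trivial at n ≈ 1,350 per cohort.

**Biomarkers.** Seven traits, each with its own disjoint causal set:
trait = Σ ±β·dosage + N(0,1), re-standardized to mean 0, SD 1 (so recovered
slopes shrink by the trait SD — the tests account for this). Effect signs
are recorded per SNP so the risk-score sign-reversal rule for the protective
traits (HDL, adiponectin) is testable. All subjects carry all biomarkers;
trait-specific measurement subsets of real studies are not emulated.

**Environment and interactions.** A continuous exposure (alcohol-like,
N(0,1)) enters the endpoint's logit as `gxe_beta`·(dosage−mean)·E for
`gxe_snp_count` SNPs. Centering the dosage makes the planted SNPs carry *no*
marginal effect — the signature the interaction screen exists to find.

**Gene sets and eSNP map.** Sets are disjoint in genes (default 100 sets × 7
genes × 3 eSNPs/gene ≈ 21 SNPs per set). A set's eSNPs are distinct
variants; an *enriched* set (fraction `enriched_set_fraction`, default 3%)
realizes the configured causal fraction exactly: round(0.5 × 21) ≈ 10–11 of
its eSNPs are drawn without replacement from the endpoint's causal SNPs.
Earlier with-replacement drafts collapsed to far fewer unique causal eSNPs
than configured whenever the causal pool was small, silently weakening the
planted enrichment; exact realization makes the parameter mean what it says.

**What the generator does not emulate:** realistic human LD maps and allele
frequency spectra, imputation dosages, X-chromosome, genotyping batch
effects, population structure with real ancestry geometry (PCs are pure
noise), risk-set matching, or trait measurement subsets. Passing tests
therefore demonstrate correctness and calibration of the *methods* under
idealized sampling, not performance on real cohort data.

## QC (`qc`)

HWE uses the 1-df χ² goodness-of-fit at the observed allele frequency,
without continuity correction — the conventional array-QC default and
hand-checkable (counts (30,40,30) give χ²=4). An exact test is deliberately
not the default; monomorphic SNPs get HWE p = 1 and are removed by their own
rule. Filters are pure per-row predicates, hence order-independent; every
failing rule is recorded, not just the first. Duplicate samples are detected
by pairwise genotype concordance over the non-missing overlap (>0.95 flags
the lower-call-rate member) — a proxy for identity-by-descent that is
sufficient for hard-call data and testable. PCA mean-imputes missing calls,
standardizes by √(2p(1−p)), and flags samples beyond `sd_threshold` (3) SDs
on PC1/PC2; callers should pass a distance-thinned SNP subset
(`thin_by_distance`). Genomic control: λ = median(z²)/0.4549364 (the χ²₁
median); adjustment divides z by √max(λ, 1) so deflation is never inflated
back.

## Association (`assoc`)

Per-SNP maximum-likelihood logistic (Newton-Raphson with step-halving;
`_glm.py`) or OLS fits of the additive model with covariates, complete-case
per SNP. Wald z rather than LRT per SNP, matching GWAS convention and the
z-based meta-analysis downstream. Separation and non-convergence are
reported as row flags with missing p, never exceptions, so a scan survives
degenerate SNPs; collinear covariates are rejected up front with the
offending column named. The hand-rolled Newton core exists because a scan
makes 10⁴–10⁵ small fits and per-call overhead dominates with a general
modeling package; the test suite verifies it against statsmodels to 10⁻⁶ on
shared fits.

## Meta-analysis (`meta`)

Inverse-variance fixed effects on the effect scale and the
sample-size-weighted signed-z method, with wᵢ = √(nᵢ/(n₁+n₂)) so squared
weights sum to one. "Effective number of individuals" defaults to the total
analyzed n per cohort; `effective_n(..., "binary")` provides the
4/(1/n_cases+1/n_controls) alternative — at a ~1:2 case:control ratio in
both cohorts the two conventions give nearly identical weights. The two
combiners agree in z exactly when se ∝ 1/√n. Allele harmonization handles
ref/alt swaps by negating effects; strand flips are not attempted (the
synthetic data is strand-consistent).

## SNP-set enrichment (`ssea`)

Default is the two-sample mode: set p-values versus all mapped eSNPs outside
the set, which controls for eSNP-ascertainment bias in the background; a
one-sample Uniform(0,1) mode is a config switch. The test is one-sided
toward stochastically smaller p (enrichment), D = sup[F_set − F_ref]. Sets
mapping to fewer than 5 SNPs are skipped with a logged reason. For sets
smaller than 30 the asymptotic p is replaced by a permutation p over 10,000
equal-size resamples from the background (seeded); the resampled D reduces
to maxᵢ(i/n − F_bg(x₍ᵢ₎)) because the supremum is attained at set
observations. Benjamini-Hochberg q-values are reported alongside raw p.
Per-set QQ data (observed vs expected −log₁₀ p) is exported for plotting.
All eSNPs per gene are retained; optional distance thinning (keep the
smallest-p SNP per window) damps LD-driven dependence.

## Gene-environment screen (`gxe`)

The four model sets are the cross {linear, 3-df natural cubic spline} ×
{interaction-only, joint}: the minimal structure containing both the
interaction-vs-main-effects comparison and the joint main+interaction
screen, under both environment codings. Printed model ids map to the cross
as 1=(linear, interaction-only), 2=(linear, joint), 3=(spline,
interaction-only), 4=(spline, joint) by default; the mapping is
configuration, not inference. The spline is the truncated-power natural
cubic basis with interior knots at the tertiles and boundary knots at
min/max, centered; with spline coding the interaction contributes one
product term per basis column (3 terms), so the df accounting is 1/2/3/4.
LRT statistics are floored at 0 against numerical noise; p from χ² with
df = parameter-count difference; separation in either fit yields a flagged
missing result. The marginal main-effect p (dosage + covariates only) is
reported per SNP so pure-interaction loci are recognizable. A conservative
Bonferroni threshold of 10⁻⁹ flags `significant_any`.

A calibration subtlety: within one study every SNP's interaction test shares
the same realized (status, environment) vector, so the *per-study* rejection
rate at α fluctuates around α with irreducible conditional variance
(~±0.01 at these sample sizes) even for a perfectly calibrated test. Size is
therefore a marginal quantity; the acceptance suite estimates it over ten
replicate null studies rather than one.

## Risk scores (`riskscore`)

Selection is a greedy sweep in ascending p keeping a candidate iff it lies
≥100 kb (inclusive) from every already-kept SNP on the same chromosome —
distance is measured against kept SNPs only, reading the spacing rule as a
property of the selected set. The scored allele is the trait-raising one;
per subject each entry contributes sign × (+1 hom scored / −1 hom other /
0 het), with sign −1 for HDL and adiponectin and +1 otherwise (including
CRP and total cholesterol). Missing genotypes contribute 0, keeping scores
integer and bounded by the entry count. Merged multi-trait scores
deduplicate shared SNPs keeping the smaller source p, then re-apply the
distance rule. Evaluation is logistic regression of the endpoint on the
score; `sweep_thresholds` runs the grid N ∈ {10, 50, 100, 500, 1000} by
default (the grid is configuration — no canonical grid exists).

## Problem sizes and numerical choices

Acceptance-level statistical checks run at the study's design shape
(450 cases + 900 controls per cohort, 2,000 SNPs): null calibration pools λ
over all 16 scans of a zero-effect study (the median estimator has SD ≈0.05
on a single 2,000-SNP scan, so the pooled λ is the stable study-level
quantity, with per-scan λ sanity-bounded); G×E size is pooled over 10
replicate studies × 1,000 SNPs; SSEA power uses 50 replicates of the
two-cohort meta; risk-score behavior uses a polygenic pleiotropic
architecture (βⱼ ~ N(0, 0.05²) on the trait, endpoint logit = 0.7 × the same
genetic value) — an architecture with only a few hundred causal SNPs makes
aggregate-score significance dip once N exceeds the causal count, whereas
the increasing-with-N behavior of real lipid scores presumes polygenicity.
Null-calibration runs use `ld_r = 0`: calibration of p-value distributions
presumes independent tests.

Newton fits converge on relative log-likelihood change < 10⁻¹⁰ with 30-step
halving; separation is declared on singular Hessians, non-convergence, or
|β| > 15. λ never deflates (floored at 1). Ties in p-sorted tables are
broken stably (mergesort) so outputs are order-invariant and byte-identical
under a fixed seed.

## Known limitations

Single-threaded; dense int8 genotype storage (fine to ~10⁷ genotypes);
no imputation or dosage support; no conditional-logistic option; no
random-effects meta-analysis or heterogeneity statistics; SSEA treats eSNPs
as exchangeable within the background (no per-gene collapsing); the CLI
covers the simulated end-to-end flow rather than every library option.
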