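# Methods

## Scope and design

`mrcausal` implements the complete two-sample Mendelian randomization
workflow for summary statistics: instrument selection, allele
harmonization, univariable and multivariable causal estimation with the
standard pleiotropy-robust sensitivity battery, MR-PRESSO outlier
detection, and a desk-scale cross-trait LD score regression. A synthetic
summary-statistics generator with full ground-truth bookkeeping makes
every stage testable end to end: each estimator has a parameter-recovery
oracle, each diagnostic a planted-signal detection check, and each test a
known type-I-error target.

The library functions and the TSV-based scripts are the primary
interface; the `mrcausal` command-line tool is a thin wrapper over them
for shell pipelines.

## The synthetic generator

For each SNP j the generator draws an effect-allele frequency pⱼ uniform
on `maf_range` (default (0.05, 0.5]) and assigns the true SNP-exposure
effect the magnitude √(r²ⱼ/(2pⱼ(1−pⱼ))) with a random (or, with
`aligned_effects`, positive) sign, where r²ⱼ = `target_r2`/n_snps. The
equal split makes the instrument set explain exactly `target_r2` of the
exposure variance in the noiseless limit, the simplest spectrum that
still yields heterogeneous weights through the frequency term.

Observed effects add Gaussian noise with the standardized-trait standard
error 1/√(2p(1−p)N); for a binary outcome analysed on the log-odds scale
the SE carries the case-fraction attenuation 1/√(2p(1−p)·N·K(1−K)), and
betas are interpreted as log odds ratios directly (no liability-scale
conversion — matching how case-control GWAS betas enter MR in practice).
The noiseless outcome mean is Γⱼ = Σₖ θₖγⱼₖ + αⱼ, with direct effects αⱼ
given to exactly `round(invalid_fraction·n_snps)` SNPs, drawn
N(`pleiotropy_mean`, `pleiotropy_sd`²). Allele codings include a
configurable fraction of palindromic (A/T, C/G) pairs, and outcome rows
can be emitted with swapped effect/other alleles or complementary-strand
letters to exercise harmonization. One `numpy` generator stream seeded
once drives every draw, so a config plus seed reproduces tables
byte-identically.

Defaults mirror the study scale the package targets: exposure
N = 79,055, outcome N = 1,030,836 with K = 60,620/1,030,836, total
instrument R² = 0.0198 — the size regime of a SpiroMeta-scale
lung-function GWAS against a very large atrial-fibrillation
meta-analysis.

What the generator does **not** emulate: genome-wide LD structure
(instruments are independent by construction; clumping is exercised
through user-supplied r² matrices), frequency-dependent effect-size
architectures, imputation error, and sample overlap between exposure and
outcome. Passing tests therefore demonstrate correctness of the
estimators and bookkeeping under the stated sampling model, not
robustness to every failure mode of real GWAS data.

The `aligned_effects` flag exists because the Egger orientation
convention (flip rows until γ̂ⱼ ≥ 0) turns sign-independent directional
pleiotropy into balanced pleiotropy: with random effect signs,
sign(γⱼ)·αⱼ has mean zero, so recovering a planted directional intercept
requires effect alleles aligned to the trait-increasing direction.

## Harmonization rules

Records are aligned to the exposure's effect allele: identical pairs are
kept; swapped effect/other alleles negate the outcome beta and reflect
its EAF; complementary-strand codings are mapped through A↔T/C↔G first.
Palindromic pairs cannot be resolved by letters: when either study's EAF
lies in the ambiguity window (default [0.42, 0.58]) the SNP is dropped
and counted, otherwise the two EAFs' positions relative to 0.5 decide the
alignment. Irreconcilable pairs are dropped as unmatched; SNPs absent
from the outcome are counted but never imputed (no proxy search).
Harmonization is idempotent, and a wholesale recoding of the outcome
table (swap alleles, β → −β, EAF → 1−EAF) leaves every downstream
estimate bit-identical, since only negations are involved.

Clumping is greedy: significant SNPs in ascending p-value order (ties
broken lexicographically by identifier, for determinism), keeping a SNP
iff its r² with every kept SNP is below the threshold (default 1e-4).
The multivariable instrument set unions the per-exposure clumped lists,
resolves duplicates by the smallest p-value, extracts every retained
SNP's effects from all exposure tables, and harmonizes once against the
outcome.

## Estimators and numerical choices

* IVW defaults to the multiplicative random-effects model — SE scaled by
  max(1, √(Q/df)) — with fixed effects behind a flag; point estimates
  are identical under both. The bound at 1 makes the test conservative
  at small instrument counts (measured rejection ~2% at J = 20 under
  the null) and asymptotically nominal at large J (~5% at J ≈ 93);
  calibration checks therefore use many-instrument scenarios.
* MR-Egger uses the t reference with J−2 df (instrument counts in
  practice are small) and the same overdispersion bound; mvMR-Egger uses
  J−K−1 df and records its orientation exposure (default: first listed).
* The weighted median interpolates the ratio at the 50th percentile of
  the cumulative weight midpoints pⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2 and bootstraps its
  SE parametrically (1000 seeded replicates by default).
* MR-PRESSO follows the residual-sum-of-squares recipe: observed
  statistic from leave-one-out IVW slopes with outcome-variance weights
  (consistent with the IVW fit); null distribution from `n_sim` (default
  1000) parametric redraws with leave-one-out slopes refit per replicate;
  add-one empirical p-values (floor 1/(n_sim+1)); per-SNP p Bonferroni
  multiplied by J; distortion test against 1000 random same-sized SNP
  subsets. A planted 10-SE outlier among 20 SNPs is detected essentially
  always, but it also biases the other SNPs' leave-one-out slopes by
  ~10/(J−1) residual SDs, lifting the family false-flag rate from the
  clean-data ~3.7% to ~7%; this swamping behaviour is inherent to the
  single-pass outlier test and is left as-is rather than masked with an
  iterative variant.
* mvIVW treats instruments as uncorrelated (they are clumped to
  r² < 1e-4) and does not propagate exposure-beta measurement error;
  with weak instruments and highly correlated exposures the conditional
  estimates are therefore attenuation-biased, which is a property of the
  estimator, not a bug — de-biasing simulations use strong instruments
  (per-SNP F in the thousands) where the no-measurement-error assumption
  holds.
* Power uses the closed-form two-sided asymptotic: non-centrality
  N·R²·b² for a continuous outcome and N·R²·K(1−K)·log(OR)² for a binary
  one, the standard mRnd-style approximation.

## LDSC lite

Heritability is the slope of z² on N·ℓⱼ/M with a free intercept; genetic
covariance the slope of z₁z₂ on √(N₁N₂)·ℓⱼ/M, whose free intercept
absorbs sample overlap. Weighting is one heteroskedasticity iteration: a
first pass with stabilizing weights 1/(1+x)² (the response variance grows
like (1+h²x)², and the crude form damps the heavy right tail of the LD
score distribution without favouring any h²), then variance weights
1/aᵢ² and 1/(a₁a₂+c²) from the first-pass fits. Full iterative LDSC
weighting is out of scope. SEs are delete-one-block jackknifes over
contiguous SNP blocks (default 200 blocks, or M/5 below M = 1000), with
rg pseudo-values recomputing all three regressions per deleted block.

rg = gencov/√(h²₁h²₂) is only meaningful over positive heritabilities.
The result is reported as *undefined* (NaN rg/SE/p, `defined=False`) when
either heritability estimate is non-positive **or** below 1.96 jackknife
SEs — i.e., not distinguishable from zero at the 95% level — mirroring
the NA rows that cross-trait LDSC reports produce for traits whose
heritability cannot support a correlation scale. This mechanical trigger
is an interpretation choice; |rg| > 1 in defined but noisy estimates is
flagged in reports but never truncated.

## Pipeline conventions

A run executes, per enabled direction and exposure-outcome pair:
selection → harmonization → IVW, Egger, weighted median, MR-PRESSO,
Q/I², leave-one-out, funnel coordinates → instrument strength and power,
logging the SNP attrition at each stage so that
n_input = n_not_significant + n_clumped_away + n_missing_outcome +
n_palindromic + n_unmatched + n_retained holds on every line. Using the
same file as exposure and outcome is refused (two-sample MR requires
non-overlapping samples). Significance flags use the Bonferroni level
α = 0.05/3 = 0.017 by default (three exposure traits per outcome); ORs
and p-values are printed to 3 decimals, CIs as "OR (low–high)".
Forward-direction ORs read "outcome risk per SD increase in exposure";
reverse-direction rows are labelled per unit log-odds of the (binary)
trait used as exposure. Replication cohorts are additional input pairs,
reported side by side without adjudication.

## Problem sizes in tests

Monte-Carlo checks are sized to finish in minutes on one CPU while
keeping MC error well below the tested tolerances: 2000 seeds for
type-I-error and de-biasing bands (binomial SE ≈ 0.5 pp), 500 for
recovery means, 200 for detection/coverage rates, with MR-PRESSO null
draws reduced to 200 inside the 2000-seed loop. Calibration scenarios
use the many-instrument regime (93–100 instruments, instrument R²
0.1866, exposure N ≈ 10⁶) where the random-effects SE bound is
asymptotically nominal; recovery of directional pleiotropy is run at
θ = 0 so the intercept estimate is not contaminated by the (documented)
finite-spread attenuation of the Egger slope.

## Known limitations

No LD-aware (generalized) IVW, mode-based estimators, Steiger filtering,
proxy-SNP lookup, multi-allelic variants or indels; no liability-scale
conversions; LD matrices must be supplied, never computed from
genotypes; LDSC is the two-parameter core, not partitioned or
constrained-intercept variants; figures are emitted as plottable
coordinates only.
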