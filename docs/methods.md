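# Methods

## Model and assumptions

The pipeline estimates the causal effect of each exposure (a blood
metabolite, in SD units) on a binary outcome (disease, log-odds) from two
independent GWAS summary datasets.  A valid instrument must satisfy
relevance (associated with the exposure), independence (no confounder of
the instrument-outcome relation), and exclusion restriction (no effect on
the outcome except through the exposure).  Under these, each SNP's Wald
ratio `theta_j = Gamma_j / gamma_j` estimates the same causal effect
`beta`, and the estimators differ only in how they defend against
violations:

* **IVW** assumes all instruments valid; it is the weighted mean of ratios
  with weights `w_j = gamma_j^2 / sigma_Yj^2`, equivalent to zero-intercept
  weighted regression of Gamma on gamma.
* **MR-Egger** replaces exclusion restriction with InSIDE (instrument
  strength independent of direct effects): direct effects enter an
  intercept, the slope remains consistent for `beta`.  Instruments are
  oriented so `gamma_j >= 0` before fitting, since the intercept is not
  invariant to arbitrary allele orientation.
* **Weighted median** is consistent while valid instruments carry more
  than half the total weight.
* **Simple/weighted mode** are consistent under ZEMPA: the modal direct
  effect across instruments is zero.

First-order Wald-ratio SEs (`sigma_Yj / |gamma_j|`) neglect the
second-sample-only noise's interaction with exposure noise; this is the
standard summary-data approximation.

## Instrument selection

Defaults: exposure P < 1e-5 (strict inequality); greedy LD clumping at
r^2 > 0.001 within an inclusive 10,000 kb same-chromosome window, index
SNPs chosen by ascending p-value with ties broken by (chrom, pos, snp_id)
so the output is deterministic and order-independent; removal of SNPs
significantly associated with >= 2 exposures (shared metabolic regulation
undermines exclusion restriction; the count is configurable); removal of
exclusion-listed SNPs (a user-supplied file of disease/confounder-associated
variants, one rsID per line); exposures retained only with 3-100
instruments.  Candidates absent from the LD panel are kept and logged by
default (`missing_snp_policy="keep"`): silently dropping them would bias
screens toward sparse panels; the alternative is available.

## Harmonization

Outcome effects are aligned to the exposure's effect allele: swapped allele
order negates Gamma and complements the outcome allele frequency;
non-palindromic pairs that match after strand complementing are aligned the
same way.  Palindromic (A/T, G/C) SNPs carry no strand information in their
labels, so under the default `infer` policy they are resolved by frequency:
a SNP is kept only when `min(eaf, 1-eaf) <= 0.42` in both studies, and a
strand correction is applied when the two (post-alignment) frequencies
disagree about which allele is minor.  The 0.42 default mirrors mainstream
two-sample MR tooling; palindromic SNPs with missing frequency are dropped.
Indels and multi-allelic records are rejected at read time.  Coordinates
are 1-based base pairs.

## Variance models and p-values

IVW and Egger use a multiplicative random-effects model by default: the
fixed-effect SE is inflated by `max(1, phi)` where `phi^2 = Q / df`
(`df = J-1` for IVW, `J-2` for Egger).  Flooring at 1 means apparent
underdispersion is never credited with extra precision.  IVW, median, and
mode p-values use the normal approximation; Egger slope and intercept use
the t distribution with J-2 df.  All tests are two-sided; 95% CIs use
1.96 SEs and odds ratios are exact exponentials of the log-odds columns.

Median and mode SEs come from a parametric bootstrap (default 1000
replicates, seeded): ratios are resampled as `theta_j* ~ N(theta_j, se_j)`
with weights held fixed, and the SE is the SD of the re-estimates.  The
mode's bandwidth is `phi * 1.06 * min(sd, 1.4826*MAD) * J^(-1/5)` (`phi`
defaults to 1); the robust scale guards against pleiotropic outliers
inflating the bandwidth, and when one scale is zero the other is used
(all-equal ratios return that value).  The density argmax is found on a
512-point grid spanning the ratios plus three bandwidths, refined by
golden-section search; plateau ties resolve toward the smallest ratio.

## Sensitivity layer

* **Cochran's Q** with `w_j (theta_j - fitted_j)^2`; heterogeneity is
  declared absent when P > 0.05 (both IVW and Egger fits).
* **Egger intercept**: no evidence of directional pleiotropy when
  |intercept| < 0.1 (strict) and P > 0.05.
* **MR-PRESSO**: observed `RSS = sum_j w_j (Gamma_j - slope_{-j}
  gamma_j)^2` with leave-one-out IVW slopes, referred to its distribution
  over `n_sim` (default 1000) parametric simulations
  (`Gamma* ~ N(slope_{-j} gamma_j, sigma_Y^2)`,
  `gamma* ~ N(gamma, sigma_X^2)`).  Per-SNP outlier p-values are
  Bonferroni-adjusted over J (outliers at adjusted p < 0.05); the
  distortion test compares the IVW shift after outlier removal with 1000
  random same-size removals.  Empirical p-values use `(1+k)/(1+n)` so zero
  is impossible.  The global test is mildly *conservative* at small J
  (parametric-bootstrap calibration is asymptotic) and under weak
  instruments, where simulating `gamma*` around the already-noisy observed
  `gamma` double-counts first-sample noise and inflates the simulated RSS
  by roughly 1/F; both effects shrink the type-I rate, never inflate it.
  Null-uniformity checks therefore run at J=50 with near-noise-free
  instruments, which isolates the resampling construction itself.
* **Leave-one-out**: IVW on every J-1 subset; the analysis is stable when
  every reduced-set 95% CI excludes zero.

## Decision rule and reporting

A candidate requires nominal IVW significance, >= 3 of 5 significant
models including IVW, and sign-consistent estimates across all five
("similar estimates" is operationalized as sign consistency; a magnitude
criterion would need an arbitrary scale and is left off).  The Bonferroni
denominator defaults to the number of exposures supplied to the screen,
not the number surviving filters.  Report tables print P in scientific
notation with two mantissa decimals and effects/ORs to two decimals;
master rows sort by ascending IVW p.

## Synthetic data generator

`simulate_two_sample` draws per-SNP minor-allele frequencies uniformly on
(0.05, 0.45), true exposure effects `gamma_j ~ N(0.10, 0.03)` per allele,
and observed effects with noise `sigma_X = 1/sqrt(2 n1 p(1-p))` at
`n1 = 7824`; outcome effects are `beta * gamma_j + alpha_j` plus noise
`sigma_Y = 1/sqrt(2 n2 p(1-p))` at `n2 = 977,323`, generated directly on
the summary (log-odds) scale — no individual-level case-control sampling,
which keeps desk-scale runtimes.  The defaults emulate a 7,824-person
metabolome GWAS feeding a ~977k-person disease meta-analysis, with
instrument strength (z around 5-8, F around 30) typical of metabolite
instruments that just clear the P < 1e-5 selection at that sample size;
`true_beta` defaults to 0.2 log-odds per SD.  Pleiotropy regimes: `none`,
`balanced` (mean-zero direct effects), `directional` (mean `mean_alpha`),
and `inside_violating` (direct effects tracking instrument strength with
slope 0.5), applied to an `invalid_fraction` share of SNPs.  LD blocks are
exchangeable within-block correlations; the pairwise panel records the
analytic r^2, and `simulate_dosages` produces genotype matrices whose
empirical dosage correlation matches the target.  All randomness descends
from one seed through per-component `SeedSequence` splits, so adding
exposures never perturbs existing ones.

What the generator does **not** emulate: real metabolite effect-size
spectra or genetic architectures; correlated summary-statistic noise
across SNPs in LD (the panel drives clumping only); selection effects such
as winner's curse; sample overlap.  Passing tests therefore demonstrate
the pipeline's correctness and calibration under its stated model, not
robustness to those artifacts of real data.

## Known finite-sample biases

With noisy exposure effects, IVW is attenuated by the classical
regression-dilution factor `F/(F+1)` with
`F = E[gamma^2]/E[sigma_X^2]`: at the generator's study-scale defaults the
recovered mean is about 0.194 for a true 0.2 (3% relative), matching the
first-order prediction, and vanishes as n1 grows (the test suite checks
both facts).  MR-Egger inherits a corresponding small positive intercept
bias under directional pleiotropy (~0.003 at mean pleiotropy 0.05).  These
are properties of the two-sample design at finite instrument strength, not
of the implementation; at 500-replicate Monte-Carlo precision they are
detectable, so strict zero-bias checks at study scale are expected to flag
them.

## Numerical and degenerate-input choices

Zero exposure effects raise an undefined-ratio error rather than
propagating infinities.  Estimator minimums: 2 instruments (IVW, median),
3 (Egger, modes), 4 (MR-PRESSO); below them an insufficient-instruments
error is raised, and the batch driver records such exposures in the skip
log instead of aborting.  A zero bootstrap SD yields p = 0 for a nonzero
estimate and p = 1 otherwise.  Batch runs are deterministic given the
config seed: per-exposure sub-seeds derive from a `SeedSequence` of (seed,
exposure index), and per-method bootstrap seeds are decoupled the same
way.

## Fixture study

`make_fixture_study` writes a complete on-disk study (small: 20 exposures
x 500 SNPs at n1 = 7824, n2 = 100,000) with planted features at known
locations: E01 causal with beta = 0.2 and one +10 sigma outlier
instrument; E02 with exactly two instruments (IV-count exclusion); a SNP
instrumenting both E03 and E04 (cross-exposure exclusion); an
exclusion-listed instrument of E05; a palindromic A/T instrument of E06
written allele-swapped in the outcome file; an r^2 = 0.8 pair inside the
clumping window for E07.  Planted instrument effects are set large enough
that selection succeeds for any seed.  The full batch over the small
fixture completes in well under a minute on one CPU.

## Problem sizes used in checks

Monte-Carlo suites use 150-500 replicates for recovery, 2000 for
calibration (Cochran's Q type-I; MR-PRESSO null uniformity at n_sim = 200
per replicate, scaled down from the analysis default of 1000), 300 random
instances for estimator-oracle equivalence at J <= 25, and exhaustive
comparison against a directly-transcribed greedy reference for clumping at
J <= 10.  These sizes give Monte-Carlo error well below the assertion
tolerances while keeping the default test run fast.
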