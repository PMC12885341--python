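# Methods

This note documents the models implemented in `validmr`, the synthetic
data-generating process the tests rely on, the numerical choices, and what
passing tests do and do not demonstrate about real cohort data.

## 1. The valid-PRS instrument

For an exposure trait A and outcome trait B with harmonized GWAS summary
tables, the instrument at purging threshold c is the polygenic score over SNPs
with p_A < 0.05 and p_B > c. The default grid is c = 0.05, 0.10, …, 0.50
(ten instruments). Scores are weighted allelic sums, score_i = Σ_j β_j d_ij,
with missing dosages mean-imputed to 2·MAF and scores standardized by default.

**Harmonization.** Inner join on SNP id; where effect alleles disagree the
outcome β is sign-flipped onto the exposure's allele convention; SNPs absent
from the genotype panel are dropped with a logged count. Strand-ambiguous
(A/T, C/G) pairs can be dropped via `drop_palindromic`; the synthetic tables
are already unambiguous.

**Clumping order.** SNPs passing the exposure filter are greedily LD-clumped
*once* (keep the smallest exposure p, remove neighbours within 250 kb with
dosage r² > 0.1, ties broken by position then id); the per-c outcome filter
is applied afterwards. Clumping once guarantees that the retained set at a
larger c nests inside the set at a smaller c — a structural invariant the
grid asserts on every build — while every retained SNP still satisfies the
selection rule. Clumping each filtered set separately would break nesting,
because greedy selection on a subset can keep a SNP the superset run removed.
Under mutually independent SNPs the two orders coincide. The r²/window
defaults follow common PRS practice; they are exposed as parameters.

## 2. The longitudinal permutation test

Let S be the n × 10 matrix of instrument scores and y_w the phenotype at wave
w (covariates residualized per wave beforehand; sex enters as an indicator,
site as dummy contrasts; covariates constant within a wave are dropped with a
warning). The observed statistic is the mean r̄ of the 10 × 4 grid of Pearson
correlations, computed pairwise-complete per wave; degenerate cells
(zero-variance score, fewer than 3 pairs) are excluded from the mean rather
than zero-filled.

The null reshuffles the union of participant ids with a single permutation π
applied identically at all four waves: participant i receives the complete
phenotype record (all columns and the per-wave presence flags) of participant
π(i), so within-person linkage and the missingness pattern travel with the
record while scores stay attached to genotypes. All phenotype columns are
permuted jointly — this preserves the within-person covariance structure
under the null. With B permutations the two-sided empirical p is
(1 + #{|r̄₀| ≥ |r̄_obs|}) / (B + 1); per-wave tests use the same draws with
wave-wise means of 10 r-values. Under exchangeability the test's exact size
at α = 0.05 with B = 200 is 10/201 ≈ 4.98%.

**Two-stage logic.** A causal readout is only reported if the instrument
first shows a significant longitudinal correlation with its *own* exposure
phenotype (stage 1, same machinery). `LongitudinalMRTest` refuses otherwise;
`force=True` overrides with a logged warning (used for sensitivity runs).

Pearson correlation is used throughout (the surrounding models are all
linear/least-squares); sex-stratified analyses are plain subgroup re-runs
with the identical union-id machinery.

## 3. Two-wave cross-lagged panel model

For a wave pair (t, t+1) and focal variables x, y plus time-t controls, the
saturated path model regresses each t+1 variable on all time-t predictors.
Because the model is saturated (df = 0), maximum-likelihood point estimates
coincide with per-equation least squares, which is how the model is fitted
(statsmodels OLS on standardized complete cases); the test suite asserts
equality with a hand-rolled normal-equations oracle to 1e-8. Controls enter
both equations symmetrically, so swapping x and y exactly swaps the cross-lag
estimates. Wald 95% CIs and two-tailed p-values are reported per path, with
R² per equation as the fit summary (a saturated model admits no omnibus fit
indices). Missing data: listwise deletion within the wave pair. Predictor
pairs correlated beyond |r| = 0.999 raise a singularity error; fewer complete
cases than predictors + 2 raises an insufficient-data error.

## 4. Mediation

Simple mediation: a from m ~ x; b and the direct effect from y ~ x + m; total
effect from y ~ x; indirect = a·b, and c_total = c_direct + a·b exactly in
least squares. Serial mediation uses the recursive system m₁ ~ x;
m₂ ~ x + m₁; y ~ x + m₁ + m₂ with serial indirect a₁·d₂₁·b₂ and the exact
decomposition c_total = c_direct + a₁·b₁ + a₂·b₂ + a₁·d₂₁·b₂ (asserted in
tests).

Inference is a nonparametric case-resampling bootstrap of the indirect
product (default 10,000 draws, minimum 1,000), implemented as multinomial
case weights so the per-draw OLS systems are formed from one weighted
cross-product and solved in batch; draws are chunked to bound memory.
Because the hypothesis direction is declared a priori, the p-value is
one-tailed — the share of bootstrap indirect estimates on the wrong side of
zero — and the interval is the matching one-sided percentile interval
([q05, +∞) for a positive hypothesis). The percentile (not BCa) bootstrap is
the minimal assumption-free choice. The proportion mediated, indirect/total,
is reported only when the two agree in sign; inconsistent (suppression) cases
are flagged instead, as a proportion is not interpretable there.

## 5. Association and attrition reports

Partial correlation conditions x and y on z by least-squares residualization
(equivalently the recursive correlation formula, asserted to 1e-12 and
cross-checked against pingouin); the CI is Fisher-z with standard error
1/√(n − |z| − 3) and the two-tailed p comes from the t statistic with
n − 2 − |z| degrees of freedom. Attrition comparisons use Welch's t by
default (pooled-variance optional) for continuous baseline measures and the
Pearson χ² (no continuity correction) for sex, one row per variable per
follow-up; categorical variables constant in the analysed subsample (e.g.
sex in a stratified run) are skipped. "Any alcohol use" at a wave is
operationalized as either alcohol score > 0; never-initiators are
complete-data participants with no use at any wave, reported as a count and a
two-decimal percentage and excludable for MR sensitivity runs.

## 6. The synthetic cohort

The generator emulates a four-wave adolescent cohort (waves BL, FU1, FU2,
FU3) with known causal structure; its defaults encode the self-medication
scenario the analyses are designed to detect.

**Genotypes.** m SNPs in consecutive LD blocks of 10; within a block, latent
Gaussians share an exchangeable correlation of 0.8 (one factor per block) and
dosages are Binomial(2, MAF) quantiles of the latent normal CDF — exact
Hardy–Weinberg marginals with block LD, the simplest structure that makes
clumping non-trivial. MAFs are uniform on [0.05, 0.5].

**Architecture.** SNPs belong to hidden classes — exposure-only,
outcome-only, pleiotropic, null — with counts fixed exactly by a
largest-remainder rule. Classes are laid out block-coherently (block order
randomly permuted): causal loci of the two traits occupy disjoint LD blocks
except for the pleiotropic class. This mirrors the sparse colocalization of
two traits' causal loci relative to LD-block size; with interleaved classes,
LD tagging would make essentially *every* exposure SNP carry an outcome
association and the pleiotropy filter would (correctly) empty the grid.
True standardized effects are N(0, h²/m_causal); defaults h² = 0.09 per
trait, in line with SNP-heritability estimates for major depression.

**GWAS tables.** GWAS report marginal associations, so each SNP's estimate
centres on the joint effects projected through the empirical within-block
dosage correlation (u_marginal = R·u_joint), plus estimation noise of
variance 1/(N_GWAS·2·MAF·(1−MAF)) with N_GWAS = 75,000 by default (the scale
of a well-powered continuous-trait discovery sample); p-values are Wald.
This marginalization is what lets the outcome-p filter see
pleiotropy-by-linkage.

**Phenotypes.** Depression (dep), alcohol consumption (cons) and alcohol-use
problems (probs) follow a standardized panel VAR:

    dep'   = 0.35·dep − 0.10·cons + √h²·G_dep + sex/site + e
    cons'  = 0.40·cons + √h²·G_alc + sex/site + e
    probs' = 0.40·probs + (0.15 − b·d₂₁·a)·dep + b·impulsivity + site/sex + e

with contemporaneous mediators hopelessness = a·dep + e and impulsivity =
d₂₁·hopelessness + e (defaults a = 0.30, d₂₁ = 0.35, b = 0.25), plus anxiety
and neuroticism as additional depression-loaded mediator columns. Because the
mediator chain is a contemporaneous function of depression, the *total*
standardized depression → problems lag equals the configured 0.15 exactly,
and a two-predictor regression recovers it. Innovation variances are
calibrated empirically each wave so every variable has unit sample variance;
configured coefficients are therefore standardized coefficients up to
O(n^-1/2). Baseline is produced after two burn-in transitions so BL already
reflects the causal structure. A configuration whose systematic variance
leaves less than 2% residual raises a configuration error, as does a lag
matrix with spectral radius ≥ 1.

**Attrition.** Monotone dropout after baseline with per-wave probabilities
(0.20, 0.12, 0.12) and log-odds offsets +0.35 for male sex and +0.25 per SD
of baseline alcohol consumption — missing at random given observables, in
the direction observed in longitudinal alcohol cohorts (heavier-drinking
males drop out more). Missing-not-at-random mechanisms are deliberately out
of scope.

**What the generator does not emulate.** Scores are continuous Gaussians,
not questionnaire item sums, so "any use > 0" is a stand-in for a true
abstinence rule; LD is block-exchangeable rather than realistically decaying;
GWAS noise is Gaussian with known variance (no case-control asymmetry); and
attrition is never outcome-dependent beyond baseline drinking. Passing tests
therefore demonstrate statistical correctness and calibration of the
*methods* under a known linear-Gaussian world, not robustness to measurement
artefacts of real questionnaire data.

## 7. Study conditions used by tests and the acceptance script

Chosen once as the package's standing experimental design:

* Permutation-test size: 500 null cohorts (n = 1,000, 300 SNPs, B = 200);
  the acceptance script runs a 100-replicate version.
* Sign recovery: 100 cohorts (n = 5,000, 800 SNPs), both MR directions.
* CLPM recovery: one cohort of n = 100,000 (tolerance ±0.01); CI coverage
  over 200 null cohorts of n = 2,000.
* Serial-mediation recovery: n = 100,000 from the dedicated linear-Gaussian
  mediation generator (a₁ = 0.4, d₂₁ = 0.5, b₂ = 0.3, direct 0.2); one-sided
  CI coverage over 200 replicates of n = 500 with 1,000 bootstrap draws.
  The full cohort's mediators are downstream of depression, so a PRS-based
  mediation there estimates an attenuated product; the dedicated generator
  isolates the configured paths.
* Default B = 1,000 permutations and 10,000 bootstrap draws for single runs.

Coverage assertions use the binomial 95% band around the nominal rate.

## 8. Known limitations

CLPM estimates of paths into *depression* absorb genetic confounding (the
persistent polygenic forcing is an omitted variable), which inflates its AR
and reverse-path coefficients — exactly the limitation that motivates the MR
stage; the generating-equation audit recovers those coefficients only when
the true score is included as a regressor. The permutation test assumes
participants are exchangeable under the null (no family/population structure
beyond the residualized covariates). One-sided bootstrap p-values can be
exactly zero when no draw crosses zero; they should be read as < 1/n_boot.
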