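# Methods

`dietmr` implements a one-sample Mendelian-randomisation (MR) workflow for
estimating causal effects of habitual dietary intake on colorectal-cancer
(CRC) risk, together with the synthetic biobank-style cohort generator used
to validate every stage. This note documents the models, the defaults and
why they were chosen, and what the synthetic validation does and does not
establish.

## Dietary trait derivation

Touchscreen FFQ categories are mapped to quantitative frequencies
(times/week) through a versioned YAML table: the six-level meat/fish/cheese
scale (0, 0.5, 1, 3, 5.5, 7) and the seven-level alcohol scale (0, 0.125,
0.5, 1.5, 3.5, 5.5, 7). Quantitative items (fruit pieces/day, vegetable
tablespoons/day, coffee/tea cups/day) pass through unchanged. Daily milk
volume is estimated from where milk is consumed:

    milk (mL/day) = 100·cereal bowls + 25·coffee cups + 35·tea cups,

and 0 for never/rarely consumers. Composite food groups: red meat =
pork + beef + lamb; total fish = oily + non-oily; total fruits = fresh +
½·dried (servings/day); total vegetables = cooked + raw. A composite is
missing iff any constituent is missing (complete-case analysis downstream;
no imputation). Labels are matched case-insensitively after whitespace and
dash normalisation; "do not know"/"prefer not to answer" become missing.
Cheese is assumed to share the meat/fish response scale. Normality is
assessed by Shapiro–Wilk on a seeded subsample capped at 5,000 — the test
is overpowered (and in scipy undefined) at biobank n — and the summary
reports mean ± sd or median (IQR) accordingly.

## Genotype QC and association scans

Variant QC applies, in order, INFO < 0.3, missingness > 0.05,
MAF < 0.0002, and Hardy–Weinberg p < 1e-6 (1-df chi-square against
expected genotype counts from the estimated allele frequency; monomorphic
variants conventionally pass with p = 1). Each variant is attributed to
the first filter it fails so removal counts are reproducible and sum
correctly.

The association scan is an ordinary least-squares regression of the trait
on per-variant dosage with covariates (age, sex, optional genotype PCs),
computed by Frisch–Waugh residualisation so a panel is scanned in a single
matrix pass. Familial relatedness is handled by a GRAMMAR-style two-step:
the covariate-adjusted trait is further adjusted by the empirical BLUP of
family-block means (variance components from one-way ANOVA), and the
residuals are scanned. This approximates a per-variant linear mixed model
at a small fraction of its cost; it is conservative rather than exact, and
the family random effect in the generator is independent of genotype, so
calibration is preserved. Genomic risk loci are defined by greedy distance
clumping: the smallest-p significant variant (p < 5e-8) leads a locus and
absorbs significant variants within ±250 kb (inclusive); LD-based clumping
is not meaningful on a panel simulated without reference LD.

## Heritability and genetic correlation

SNP heritability is estimated by Haseman–Elston regression: products of
the covariate-residualised, standardised trait over sample pairs are
regressed (with intercept) on genomic relatedness K = ZZ′/M built from
standardised dosages. The implementation evaluates all required sums
through trace identities on Z′Z and Z′y, so the n×n GRM is never formed;
this is algebraically identical to the pair-level regression. Standard
errors come from a delete-a-block jackknife over 20 contiguous sample
blocks. Bivariate HE on cross-trait products gives the genetic covariance,
normalised by the two h² slopes to yield r_g; r_g of a trait with itself
is exactly 1 by construction. Estimates are clipped to their parameter
ranges with a flag. HE is noisier than REML but unbiased, estimator-free
of convergence issues, and sufficient at the simulated scales.

## Instruments and the allele score

Lead variants of a trait's loci are candidate instruments. Two screens
guard the MR assumptions: (i) variants significant for ≥ `min_traits`
dietary traits are flagged for horizontal pleiotropy (default 2; set 3
for the more lenient "more than two traits" rule — both wordings exist in
the literature this emulates and the choice is left configurable); (ii)
variants with outcome-association p < 0.05 are excluded under the
exclusion restriction. The internally weighted allele score is
score_i = Σ_j β_j·dosage_ij with β from the trait GWAS in the same sample;
missing dosages are mean-imputed per variant. Internal weighting incurs
winner's curse — a warning is logged and no correction applied. Instrument
strength is F = (β̂/se)², the squared first-stage t-statistic; the pipeline
refuses F < 10 unless overridden.

## Two-stage estimation with a Cox second stage

Stage 1 regresses the trait on its allele score (plus covariates) by OLS;
stage 2 fits a Cox proportional-hazards model of CRC on the stage-1 fitted
values with **age as the time scale**: subjects enter the risk set at
enrolment age (left truncation) and exit at event or censoring age. Ties
use the Efron approximation. The reported HR is per unit of exposure
(e.g. 1 serving/day). The default CI uses the naive model-based Cox SE;
an optional nonparametric bootstrap over individuals (refitting both
stages, default B=200) propagates first-stage uncertainty. In the
simulated designs the first stage is strong (F ≫ 100) and the two agree;
the naive SE is the default because it is deterministic and the
calibration experiments show 90–99% empirical coverage under the null.

Single-instrument 2SLS with a *linear* second stage reduces algebraically
to the Wald ratio β_out/β_exp (tested to 1e-8); with the Cox second stage
the correspondence is approximate (rare-event log-linearity) and is
exercised only statistically.

## Pleiotropy diagnostics

*MR-Egger*: weighted least squares of per-instrument outcome effects on
exposure effects with intercept, weights 1/se_out²; alleles are flipped so
all exposure effects are non-negative (identification requirement). The
intercept t-test on k−2 df flags directional pleiotropy. With the
intercept constrained to zero the fit equals the IVW estimate exactly.

*MR-PRESSO*: the observed weighted residual sum of squares of the IVW fit
(each instrument's residual against its leave-one-out prediction) is
compared to a parametric simulation null in which exposure/outcome effects
are redrawn from their sampling distributions (default n_sim = 1,000,
seeded); per-instrument residuals give empirical outlier p-values,
Bonferroni-adjusted over k. Note the empirical p has resolution
1/(n_sim+1), so n_sim must exceed k/α for any outlier to be detectable.
The distortion test compares the IVW estimate before/after outlier removal
against a null of removing equally many random instruments; it is reported
as undefined when no outlier is found.

*Multivariable MR* groups traits whose allele scores correlate
(|r| > 0.10) or whose genetic correlation is high (|r_g| > 0.30) into
connected components; within a group, each trait is regressed on all group
scores jointly and one Cox model includes all fitted exposures, giving
direct effects. A condition-number gate (1e8) rejects collinear designs.
Singleton groups are skipped.

*Subgroups*: the estimator is re-run by sex and by subsite; for a subsite
analysis the competing subsite's events are censored at their event age
(no competing-risk model).

## Observational arm

Univariate and multivariable age-scale Cox models per trait; the
multivariable adjustment set is sex, family history, household income,
smoking, alcohol (dropped when alcohol is the exposure), BMI and physical
activity, optionally pre-screened by univariate Cox p < 0.05
(configurable). Under simulated confounding with no causal effect the
observational HR is biased away from 1 while the 2SLS CI covers 1 — the
package's reproducible analogue of the MR design's purpose.

## Synthetic cohort generator

Genotypes are biallelic dosages Binomial(2, maf) per variant (HWE), maf
uniform in a configurable range (default 0.05–0.5), positions strictly
increasing within chromosomes with 5–60 kb spacing; `hwe=False` induces a
het deficit (F = 0.25) so HWE filters have true positives. INFO and
missingness are metadata drawn from Beta distributions with a tail of QC
failures. Traits are built on a unit-variance scale: standardised genetic
value (variance = h²), family-block random effect (variance = icc,
default 0.05, block size 4), latent confounder contribution, Gaussian
remainder; the realised variance decomposition is returned and matches the
target within ±0.02 at n ≥ 20,000. Outcomes follow an exponential
baseline hazard on the age scale with linear predictor
Σ logHR_t·(trait−mean) + logHR_U·U, delayed entry at enrolment age
(Normal(56.6, 8) clipped to 40–70), administrative censoring at 12.4
years of follow-up or age 85, and a 2:1 colon:rectal label split. The
baseline rate can be calibrated by bisection to a target event fraction
(closed-form event probability, deterministic). Default validation runs
use ~10% events to give the Cox stages adequate information at desk scale;
a realistic biobank fraction (~1.3%) is a parameter choice away.

What the generator does **not** emulate: linkage disequilibrium and
reference panels, population stratification beyond a two-subpopulation
test construction, non-Gaussian trait distributions and trait-trait
copulas, age-varying hazards, and competing mortality. Passing tests
therefore establish the estimators' statistical correctness under the
assumed data-generating process, not robustness to real-biobank artefacts.

## Problem sizes and numerics

Validation experiments use n = 20,000 / M = 2,000 (recovery, 20 seeds) and
n = 10,000 (calibration and confounding, 100 replicates each), h² 0.08–0.10
over 20–60 causal variants — sizes chosen so every stage retains genuine
genome-wide discovery (selection at 5e-8) while the full suite runs on one
CPU in minutes. Tolerances: HE h² within ±0.05 of truth on 10-seed
averages; CI coverage 90–99/100; type-I rates within [0.02, 0.09]. All
randomness flows through numpy `SeedSequence`-derived generators; seeded
runs are bit-reproducible. Degenerate inputs (constant traits, empty risk
sets, monomorphic variants, collinear designs, weak instruments) raise
informative errors rather than returning silent numbers.
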