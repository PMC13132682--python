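# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## The measurement model for g

g is defined operationally as the first unrotated principal component of
the z-standardized test battery, computed from the battery correlation
matrix (equivalent to covariance-PCA after z-scoring, stated for clarity).
Loadings are the unit-norm eigenvector entries; the sign is fixed so the
mean loading is positive, i.e. higher g means better performance when
tests are scored positively. PC1 scores are standardized to mean 0 / SD 1
post hoc; no normalizing transform is applied to skewed batteries. The
variance share of PC1 is eigenvalue/n_tests — with 19 tests an eigenvalue
of 7.90 is 41.6%, with 14 tests an eigenvalue of 5.53 is 39.5%.

Missing test scores are imputed deterministically from the battery's
pairwise-complete correlation matrix: a subject's missing z-scores are the
conditional expectations R_mo R_oo⁻¹ z_o given their observed z-scores
(ridge jitter 1e-8 on R_oo). Subjects missing more than half the battery
are excluded. This is a linear-Gaussian stand-in for whatever
study-specific imputation a real battery would use; it is exact in the
perfect-correlation limit and beats mean imputation whenever the battery
is positively intercorrelated.

## The score model

The trainer solves

(1/2n)‖y − β₀ − Xβ‖² + λ Σ_j w_j [α|β_j| + ((1−α)/2)β_j²]

by cyclic coordinate descent on the Gram matrix with warm starts along a
geometric λ path and active-set sweeps. Penalty factors are binary: CpG
columns w = 1, covariate columns (five of six cell fractions z-scored with
one reference cell type omitted; sex and batch dummy-coded with reference
levels dropped) w = 0, updated without shrinkage. The intercept is
unpenalized and recovered from centered data.

Numerical choices:

- **λ path**: 100 geometrically spaced values from λ_max down to
  λ_max·1e-4. λ_max is computed from the partial residual after an OLS fit
  of y on the unpenalized covariates — the smallest λ at which every
  penalized coefficient is zero — and is nudged up by a factor (1+1e-10)
  so the first path point is exactly all-zero in floating point. For
  α < 1e-3 the denominator is floored at 1e-3 (pure ridge has no finite
  zeroing λ).
- **Convergence**: maximum absolute coefficient change per sweep below
  1e-7 (final fits), 100,000-sweep cap with a hard error on
  non-convergence. Cross-validation fold fits use 1e-5: held-out MSE is
  flat at that precision (selection was bit-identical at 1e-4 in
  development-scale checks) and it is ~5x faster.
- **Tuning**: one fixed fold assignment (default seed 20251014) shared by
  every α on the 0–1 grid (step 0.1). Per α, λ_1SE is the largest λ whose
  mean CV MSE is within one SE (SD of fold MSEs/√K) of the path minimum;
  across α the pair with minimal CV MSE at λ_1SE wins. Ties go to the
  smallest α, and within an α multiple λ meeting the 1-SE threshold
  resolve to the largest (sparsest). The cross-α comparison uses CV MSE at
  λ_1SE, not at λ_min; both conventions exist in practice and this one is
  the sparser, documented here as the package's choice.
- **Degenerate columns**: a zero-variance training CpG is dropped with a
  warning (σ undefined); a candidate probe absent from the cohort enters
  as an all-zero standardized column so the design always spans the
  candidate pool. Subjects missing more than 10% of the pool are excluded.

Scoring a cohort never re-estimates anything: probes are standardized with
the stored training μ_j, σ_j, non-finite entries become exactly zero, the
weighted sum runs over the nonzero-weight CpGs, and the raw score is
z-scaled by the training raw-score mean/SD (taken from the final refit
sample). Covariate coefficients are stored in the artifact for provenance
but never applied outside the training design. Consequently two platforms
measuring the same probes give identical z-scores, and dropping a probe
changes a sample's raw score by exactly that probe's weighted standardized
contribution — the transport property the tests assert.

R² against g is reported primarily as the squared Pearson correlation; the
calibrated 1 − SS_res/SS_tot variant is reported alongside but is not the
headline number, because the score is z-scaled rather than calibrated to
the units of g.

## Quality control

Pipeline order is fixed: probe filtering (cross-reactive, non-"cg",
SNP-proximal, optional candidate allowlist) → detection-p masking
(p > 0.01) and imputation → replicate collapsing (per-sample arithmetic
mean within a CpG locus; idempotent) → M-values for sample QC only.
Whether sample-outlier removal should precede probe filtering is not
settled; filtering-first is this package's order. Betas are clipped to
[1e-6, 1−1e-6] before M = log2(β/(1−β)).

Imputation replaces a matrix-completion package with per-probe
ridge-stabilized regression (ridge n·1e-3) on the k = 10 most correlated
other probes. Donor probes are mean-initialized first: at realistic
per-cell missingness essentially no probe is observed in every sample, so
conditioning on strictly complete donors would degenerate to mean
imputation. Probes with too few donors or fewer than 3 observed cells fall
back to the probe mean; probes missing everywhere are dropped and
reported.

Sample-level assay checks (bisulfite conversion > 85%, reported-vs-
predicted sex) are metadata filters over an optional per-sample QC table;
no assay-level quantity is computed here. PCA outlier flagging z-scores
the first two PC scores of the column-centered (unscaled) sample-by-CpG
M matrix and flags |z| > 3 on either; flags are PC-sign-invariant.

## Synthetic study conditions

The generator emulates an older-adult discovery cohort and a smaller,
younger external cohort measured on a second array platform, with all
randomness flowing from named seeds through one generator stream per
purpose (cohort draws, battery, platform split, QC flags).

Discovery defaults: n = 2,069; age truncated-normal 75.22 ± 7.01 on
[65, 98]; 57% female; race 80/14/6% with 10% Hispanic ethnicity; education
12.8 ± 3.0 years; MCI prevalence 23.8% via a logistic model in −g and age
whose intercept is solved to hit the target prevalence; six Dirichlet cell
fractions (concentration 60 around typical blood composition); 2–4 plates
with additive M-scale batch shifts (SD 0.08). The external configuration
is n = 112, age 68.4 ± 10.4 on [46, 89], 33% MCI, a 14-test battery, and a
second-platform panel keeping 558/600 of the probes with detection
failures at 0.5% of cells and six replicate loci.

Methylation is generated on the M scale and mapped through the inverse
logit-like transform, so betas live in (0, 1) by construction. Each probe
is baseline + causal term a_j·g (30 causal probes, |a_j| = 0.06, random
signs) + age, cell-composition and batch terms + five latent
co-methylation factors (loading SD 0.15) + N(0, 0.4) noise. The factors
matter twice: they give the imputer genuine inter-probe structure to
exploit, and they make the elastic net face correlated nuisance, as real
arrays do. With this calibration a single causal probe correlates with g
at |r| ≈ 0.13 and the oracle linear combination of all causal probes
reaches R² ≈ 0.3 against the measured g — chosen a priori so that a
realized penalized fit lands in the low-R² regime blood-based cognitive
proxies occupy (roughly 0.1–0.35 held out), and not revisited afterwards.

The battery is test_k = λ_k·g + noise with λ_k ~ U(0.4, 0.8) and noise SD
0.8, giving a PC1 variance share near 0.40 for 19 tests and PC1–g
correlation ≈ 0.96. A minority-group indicator shifts education downward
(−1.5 years), g downward (−0.35 SD direct), and the baselines of half the
causal probes against their weight signs (0.06 M units), so the
group → methylation → cognition mediation structure genuinely exists; a
GrimAge-like comparator is 0.97·age − 1.2·g + N(0, 3.5), age-dominated
with a small inverse cognitive component; biomarker columns are
age-correlated log-normals; a screener is a discretized noisy g.

A separate linear mediation benchmark (`simulate_mediation_triple`)
generates treatment/mediator/outcome with exactly known paths; its default
a·b/(a·b + c′) = 0.35, and an optional education carrier routes part of
the a path through an education column so covariate adjustment attenuates
the mediated share. This benchmark — not the cohort — is the calibrated
target for mediation-recovery tests, because when the trained score itself
is the mediator its proportion mediated is not a free parameter (the score
is driven by g, so ACME/total can legitimately approach or exceed 1 in the
cohort).

What the generator does **not** emulate: genomic autocorrelation along
chromosomes, probe-type chemistry differences, realistic EWAS effect-size
distributions, non-Gaussian test scores, dementia cases, or missingness
that is informative rather than random. Passing tests therefore establish
that the machinery is correct and calibrated under the assumed structure,
not that a real cohort would yield any particular R².

## Inferential procedures

- Welch t (Welch–Satterthwaite df) via scipy; Welch ANOVA implemented from
  the Welch (1951) formulas (cross-checked against an independent
  implementation in the tests); Pearson with t-based p.
- Incremental validity by hierarchical OLS (statsmodels): ΔR², semi-partial
  R² per added predictor (= ΔR² for a single one), t-based 95% CIs.
- AUC is the Mann–Whitney concordance with half credit for ties; the
  paired-AUC test uses DeLong's structural-components covariance with a
  two-sided z test, degenerating to p = 1 when the difference has zero
  variance. Nested logistic models are compared by likelihood ratio;
  logistic fits use Newton/IRLS with log-likelihood tolerance 1e-8, and
  separation surfaces as a hard error naming the predictors. DeLong for
  nested models runs on each model's fitted probabilities.
- Partial correlations are correlations of OLS residuals with t(n−k−2) p
  and Fisher-z CIs, on pairwise-complete rows.
- Mediation is product-of-coefficients with case-resampling percentile
  bootstrap CIs (BCa was considered and rejected as unwarranted
  complexity for a descriptive analysis); ACME + ADE equals the total
  effect exactly in the linear case, and the proportion mediated is
  reported as undefined when the total effect is negligible. Estimates
  are descriptive, not causal.
- Outliers: |z| ≥ 3 or |MAD-z| ≥ 3.5 with MAD-z = 0.6745(x − median)/MAD;
  a zero MAD skips that criterion with a warning.
- No multiple-testing adjustment anywhere: all p are unadjusted two-tailed
  at α = 0.05, and the report makes that explicit by carrying raw p-values
  only.

## Problem sizes

Default test-suite and acceptance problem sizes are chosen to exercise the
full default study conditions once (n = 2,069 × 600 probes with the full
α grid; a few minutes on one CPU) and scaled-down variants everywhere
else. Null calibrations use 5,000 replicates for DeLong, Welch ANOVA and
likelihood-ratio tests; bootstrap coverage checks use 150 replicates of
B = 200; the mediation recovery benchmark uses n = 1,500 with B = 1,000.

## Known limitations

- The imputation, battery imputation, and comparator clock are principled
  stand-ins, not re-implementations of any specific external tool.
- The 1-SE tuning convention (cross-α comparison at λ_1SE) is one of two
  defensible readings; both are deterministic and documented.
- The elastic-net solver assumes a dense Gram matrix in memory
  (fine to ~10⁴ predictors); genome-wide training is out of scope.
- Mediation with the trained score as mediator inherits the
  outcome-driven-mediator caveat above; cohort-level proportions mediated
  should be read qualitatively.
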