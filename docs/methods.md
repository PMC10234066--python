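# Methods

## Scope and estimands

The package implements a candidate-gene G×E workflow around three
estimands: (i) the interaction coefficient B3 between a cumulative
genetic score (CGS) and parental education (PE) in an OLS model for timed
reading fluency; (ii) the crossover point C of the equivalent
reparameterized model, whose position relative to the observed PE range
arbitrates differential susceptibility vs diathesis-stress (and flags
vantage-sensitivity candidates); and (iii) specific indirect effects
a_j·b_j of the score on the outcome through parallel endophenotype
mediators.

## Score construction

Coding uses only the *sign* of each SNP's phenotype β: positive β counts
first-allele copies, negative β counts the complement (2 − copies), so
`code(g, β) + code(g, −β) = 2` for every genotype. The default score is
the unweighted sum; a |β|-weighted variant exists behind a flag but is
not used by any downstream default. Two score columns (one per phenotype
β set, reading fluency and character recognition) can be produced from
one panel. Missing genotypes default to mean-dosage imputation (the
SNP's mean coded dosage); `rescale` (sum × n_snps/n_used) and
`complete_case` are available, and the policy in force is echoed into
every pipeline report.

## Genotype QC

Fixed PLINK-like order: sample call rate > 0.90 → SNP call rate > 0.95
(recomputed on surviving samples, so a SNP whose missingness sat in bad
samples can be rescued) → HWE → MAF > 0.01 → relatedness. HWE uses the
asymptotic 1-df chi-square against expectations from the sample allele
frequency (screening threshold p ≥ 1e−5); a monomorphic SNP returns
(statistic 0, p 1) by convention. The exact test would be a natural
extension but is not needed at screening thresholds. Relatedness uses the
method-of-moments estimate
`mean_m (x_im − 2p_m)(x_km − 2p_m) / (2 p_m (1 − p_m))` — ~0 for
unrelated pairs, ~0.5 for first-degree relatives, ~1 for duplicates, the
PI_HAT scale. Because allele frequencies are estimated from the sample
itself, the duplicate-pair value shrinks by roughly (1 − 2/n)²; at the
13-SNP panel scale the estimate is too noisy to act on, so the filter
warns and skips below a configurable marker floor (default 50). Of a
flagged pair the member with the lower call rate is dropped (tie: the
later sample id). The full pipeline is idempotent and logs every removal
with exactly one primary reason, the metric value and the threshold.

## Interaction and crossover estimation

Both models are estimated on complete cases; covariates (age in years,
sex coded 0/1) enter raw, and the score enters untransformed on the G×E
stage. The crossover form is an exact reparameterization of the linear
form (B1 = b1, B2 = b3, C = −b2/b3, B0 = b0 + b1·C), so the free-C
nonlinear least squares is seeded at that closed-form map and converges
deterministically to the OLS solution's RSS; a coarse grid multi-start
over the observed PE range backs up near-degenerate starts, and
|b3| below tolerance (default 1e−10) raises "crossover unidentifiable"
rather than returning a meaningless ratio. SEs come from the NLS Jacobian
(σ̂²(JᵀJ)⁻¹); the CI for C is Wald by default, with a profile-likelihood
option (`{C : n·log(RSS(C)/RSS_min) ≤ χ²₁}`).

Model competition: the fixed-C model pins C at the observed PE maximum
(configurable), one fewer mean parameter. The F test uses
(RSS_fixed − RSS_free)/(RSS_free/(n − 6)) with df (1, n − 6); AIC/BIC use
the Gaussian log-likelihood at the residual-variance MLE with k = mean
parameters + 1 for the variance. "Selected" requires AIC and BIC to
agree; otherwise the call is "ambiguous" and the F test stands alongside.
Regime classification is strict: differential susceptibility requires C
*and its entire CI* inside the environment range (observed min/max by
default; the theoretical 1–8 scale range is available). A crossover in
the lowest fraction of the range (default 0.2) is flagged
`vantage_sensitivity_candidate` instead, since a crossover at the adverse
extreme means score levels differ only in benefit from enriched
environments.

**Finite-sample behavior of Ĉ.** The free-crossover estimate equals
−b̂2/b̂3 and is a ratio statistic: its second-order bias is approximately
Var(b̂3)(C − E[PE])/b3². At the package-default effect sizes (b3 = 0.52,
model R² ≈ 0.0875, n = 1589) this is ≈ −0.1 PE units — the recovery
simulation measures mean Ĉ ≈ 2.15 against a generating 2.27, while the
interaction and environment slopes recover without detectable bias and
the Wald CI covers the true C at ≈ 95%. Users comparing mean Ĉ across
replicates to a generating value should expect this attraction toward
the PE mean whenever b3 is only a few SEs from zero.

## Mediation

The parallel-mediator model is recursive (mediators on score + age + sex;
outcome on score + mediators + age + sex) with mediator residual
covariances free, so per-equation least squares gives the ML point
estimates and no general SEM engine is required. Coefficients are
reported on the input scale (plus sd-ratio standardized versions);
the study-style workflow standardizes score, mediators and outcome to
Z scores *within grade* (sample SD, ddof 1) before fitting, and a
re-standardized mean of the per-grade-Z RAN tasks is the recommended
single-mediator summary. Total indirect ≡ Σ specific indirects by
construction.

Inference: percentile bootstrap over whole-case resamples (default 5000
replicates, 95% CIs; optional stratification by grade, off by default);
significance = CI excluding zero; degenerate resamples with a constant
score are redrawn and counted. Under a comfortably nonzero a·b the CI is
asymptotically calibrated (measured 95.5% coverage at n = 500); when both
paths are truly zero the product is the well-known non-regular case and
the percentile interval over-covers — it does not attain 95% exactly, and
the test suite asserts the conservative direction only.

Fit indices compare the sample covariance of the modeled variables with
the implied covariance (I − B)⁻¹Ψ(I − B)⁻ᵀ at the per-equation estimates:
χ² = (n−1)·F_ML, baseline = independence model, CFI/TLI clamped to
[0, 1], RMSEA = √(max(χ²−df, 0)/(df·(n−1))). The full model is just
identified (df = 0) and reports the saturated convention (χ² = 0,
CFI = 1, RMSEA = 0); dropping the direct path yields one testable df.
Degrees of freedom follow this package's own parameter accounting; other
SEM software may bind different constraints and print different dfs for
nominally similar models. Moderated mediation adds a first-stage
score × PE term per mediator; its index is (interaction a-path)·b with a
bootstrap CI, and its fit indices treat the product term as an exogenous
variable of its own, making them descriptive rather than strictly
distributional.

## Synthetic cohort generator

The generator emulates the statistical structure the estimators assume,
not the behavioral tasks themselves:

* **Genotypes** — 13 biallelic SNPs, independent, each in exact HWE
  (copy counts Binomial(2, freq)); panel MAFs fixed in [0.05, 0.45] with
  mixed β signs so both coding orientations are exercised. No LD and no
  stratification, by design.
* **Environment** — parent-averaged education drawn directly on the
  half-step lattice 1, 1.5, …, 6 (the observed parent-average range;
  averaging two 1–8 ordinal parents yields half steps). Weights are
  uniform by default and configurable; only the average enters any
  analysis, so parents are not simulated separately.
* **Covariates** — grade uniform on 3–6; age = grade + 6.5 ± 0.5 years;
  sex Bernoulli(1/2) coded 0/1.
* **Outcome** — the crossover-form mean structure plus Gaussian noise.
  Default truth: B0 = 246.63 s, B1 = −10.40 s/level, B2 = 0.52, C = 2.27,
  age −0.83, sex −2.13, with the residual SD set by closed-form moment
  calibration so the full-model R² ≈ 0.0875 (`calibrate_resid_sd`);
  under these conditions the residual SD is ≈ 17.9 s. Gaussian noise
  matches the OLS/ML machinery downstream.
* **Mediators** — M_j = a_j·z(CGS) + e_j with e multivariate normal
  (default: four RAN tasks, exchangeable residual correlation 0.5,
  residual SDs √(1−a_j²) for unit variance); outcome
  c′·z(CGS) + Σ b_j·M_j + noise. Default paths (a ≈ 0.01–0.05, one
  dominant b ≈ 0.42, c′ ≈ 0.02) mirror a weak gene → endophenotype →
  reading chain. The combined study cohort routes a share of the G×E
  residual through the mediator residuals so one table carries both
  structures with the total residual SD unchanged (requires
  bᵀCov(e)b < 1).

All generators take an explicit integer seed, are bit-reproducible, and
record the seed (and truth, via the JSON sidecar) in provenance metadata.
Because the generator omits LD, selection, measurement unreliability,
floor/ceiling effects and non-uniform PE distributions, passing recovery
tests demonstrate estimator correctness and calibration under the assumed
structure — not robustness of the scientific conclusions to real-data
violations of it.

## Problem sizes and numerical conventions

Recovery simulations use 200 cohorts of n = 1589; regime-competition
checks use 100; bootstrap-coverage checks use 500 outer replicates with
199 inner resamples at n = 500 — sizes chosen so Monte-Carlo error is
small relative to the tolerances being asserted while the whole suite
stays quick on one CPU. Reproducibility conventions: seeds spawn via
`numpy.random.SeedSequence` so sub-streams are independent; per-grade Z
scores use ddof = 1; Pearson correlations use pairwise-complete
observations with Benjamini–Hochberg adjustment across the full reported
set; the per-SNP interaction scan uses 0.05/m Bonferroni control and
skips monomorphic SNPs with a log entry.

## Known limitations

No imputation, no X-chromosome handling, no latent variables or FIML
missing-data support, no robust/sandwich SEs, no Johnson–Neyman regions,
and no quadratic-environment crossover variants. The relatedness filter
is statistically meaningless at candidate-panel marker counts and says
so. The moderated-mediation fit indices are descriptive (see above).
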