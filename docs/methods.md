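# Methods

`mrtea` implements a two-sample Mendelian randomization (MR) pipeline for
estimating the causal effect of green tea intake on Parkinson's disease
(PD) age at onset and 28 clinical progression phenotypes from GWAS summary
statistics, together with a synthetic summary-statistics generator so that
every stage is testable without external downloads.

## Model and assumptions

For SNP *j*, let γ_j be its true effect on the exposure (green tea intake,
standard-deviation units) and let the outcome effect be

    Γ_j = θ·γ_j + α_j,

where θ is the causal effect of interest and α_j is a horizontal-pleiotropy
(direct) effect. The three instrumental-variable assumptions are: relevance
(γ_j ≠ 0, enforced by genome-wide significance), independence from
confounders, and exclusion (α_j = 0). MR-Egger instead requires InSIDE —
α_j independent of γ_j — under which its intercept estimates the mean
directional pleiotropy and its slope remains a consistent estimate of θ.

Observed per-SNP estimates are `bx_j ~ N(γ_j, sebx_j²)` and
`by_j ~ N(Γ_j, seby_j²)` from two non-overlapping samples.

## Pipeline stages

1. **Instrument selection** — exposure SNPs with P strictly below 5e-8,
   greedily clumped: the unassigned SNP with the smallest p-value becomes an
   index SNP and removes every unassigned SNP on the same chromosome within
   10 Mb with r² ≥ 0.001 against it (ties broken by (chrom, pos), then id,
   for determinism). Per-SNP instrument strength is F = (β/SE)², the squared
   Wald z; the explained-variance form (N−2)R²/(1−R²) with
   R² = 2·eaf·(1−eaf)·β² is available as `f_statistic_r2`.
2. **Harmonization** — outcome effects are aligned to the exposure's effect
   allele by snp id. Non-palindromic SNPs resolve through label matching
   (direct / effect-other swap / strand complement). Palindromic SNPs (A/T,
   C/G) carry no strand information in their labels, so orientation comes
   from allele frequency: both studies' eaf must be further than the window
   (default 0.08) from 0.5, and the effect is sign-flipped when the
   frequencies sit on opposite sides of 0.5. Frequency-ambiguous
   palindromes, indels and irreconcilable allele sets are dropped; every
   input SNP receives exactly one action in the log.
3. **Estimation** — five estimators over the harmonized set:
   * *Wald ratio* (per SNP): by/bx, first-order delta SE |seby/bx|
     (second-order optional).
   * *IVW*: weighted regression of by on bx through the origin, weights
     1/seby². The primary analysis is multiplicative random effects: the
     fixed-effects SE is inflated by max(1, √(Q/(J−1))) with Q the Cochran
     statistic below — the same Q, by construction.
   * *MR-Egger*: the same weighted regression with a free intercept, after
     orienting all bx ≥ 0; p-values from t with J−2 df (statsmodels WLS
     with estimated residual scale; no floor at 1 is applied to the scale).
   * *Weighted median*: the 50% point of the weighted empirical CDF of
     per-SNP ratios (weights bx²/seby², linear interpolation between order
     statistics); SE from a seeded parametric bootstrap (resampling bx and
     by from their sampling distributions, default 1000 draws).
   * *Weighted mode*: mode of the normal-kernel weighted density of ratios,
     bandwidth 0.9·min(sd, IQR/1.34)·J^(−1/5) times a user factor; SE is
     1.4826 × MAD of bootstrap modes.
   95% CIs use the fixed 1.96 normal multiplier; binary and survival
   outcomes are reported as OR = exp(β) with exponentiated CI.
4. **Sensitivity** — Cochran's Q (χ², J−1 df); MR-PRESSO; leave-one-out
   IVW; and I²GX (instrument-strength heterogeneity, see *Limitations*).
5. **Study orchestration** — one exposure against a configured outcome
   panel; Bonferroni familywise control at α/m over the explicit outcome
   family (0.05/28 = 1.79e-3 in the default design); age at onset can be
   analysed outside the family. The three verification estimators run for
   every outcome by default, or only for Bonferroni-significant outcomes
   when `verify_significant_only` reproduces the original reporting flow.
   Outcomes with fewer than two harmonized SNPs are marked `not_estimable`
   and the run continues. Outputs are forest/sensitivity/scatter/funnel
   tables plus a JSON manifest of seeds, instrument counts and
   harmonization actions; runs are byte-reproducible given the seed.

## MR-PRESSO details

The observed statistic is the weighted residual sum of squares about
leave-one-out IVW slopes, RSS = Σ_j w_j (by_j − β̂⁽⁻ʲ⁾ bx_j)², w_j = 1/seby_j².
Its null distribution comes from parametric simulation (default 1000
draws): by*_j ~ N(β̂⁽⁻ʲ⁾ bx_j, seby_j), bx*_j ~ N(bx_j, sebx_j), with the
leave-one-out slopes re-derived within each simulated dataset. Empirical
p-values use (1+k)/(1+n_sim), so they are floored at 1/(n_sim+1). Per-SNP
residual contributions give two-sided empirical outlier p-values,
Bonferroni-adjusted by J; note this implies no SNP can be flagged unless
n_sim > 2J/α − 1. Outliers are removed worst-first, re-testing after each
removal until the survivors are clean or fewer than 4 SNPs remain; the
per-round simulation stream is keyed on (seed, surviving id set), so
re-running the test on the survivors reproduces the final round and
confirms cleanliness deterministically. The distortion test compares the
outlier-corrected IVW shift against random removals of the same number of
SNPs; it is reported but never used for gating.

## Synthetic-data generator

`simulate_pair` / `simulate_study` emulate the study's data regime:

| parameter | default | rationale |
|---|---|---|
| n_exposure | 64,949 | exposure GWAS sample size |
| n_outcome | 4,093 | progression GWAS sample size |
| j_snps | 15 | instrument counts implied by the diagnostics table (J−1 = 4–19) |
| maf_range | (0.05, 0.45) | common variants, clear of fixation and of eaf = 0.5 |
| f_range | (30, 44) | the printed instrument-strength band; per-SNP expected F ~ Uniform(30,44), so γ_j = σ_xj·√(E[F]−1) with random sign |
| palindromic_fraction | 0.2 | roughly the A/T + C/G share among common GWAS variants |
| pleiotropy mean/sd, outlier fraction/size | 0 | clean null; scenario knobs (outlier size is in units of the SNP's outcome SE) |

Sampling SEs close under a standardized trait:
σ_x = (2·maf·(1−maf)·N)^(−1/2), and analogously for the outcome; binary and
survival outcomes reuse the same normal machinery on the log-odds /
log-hazard scale, which is adequate for estimator testing but does not model
case-control ascertainment. Pleiotropy α_j is drawn independently of γ_j,
so InSIDE holds by construction. Effect-allele frequencies are reported
identically in both studies (no between-study frequency noise), which makes
palindrome disambiguation cleaner than in real data. Optional LD blocks
replicate each index SNP with noise correlated at √r² and attenuated
tagging effects; positions place independent instruments 20 Mb apart so
clumping windows never span them. One global seed expands into
per-component streams via `numpy.random.SeedSequence` spawning, so adding
outcomes never perturbs earlier streams.

What passing tests on these data do **not** show about real data:
genome-wide LD structure, allele-frequency mismatch between studies,
sample overlap, winner's-curse selection of instruments, and
trait-appropriate link functions are all absent.

## Numerical choices

* Strict `<` at the significance threshold, per the stated design.
* Missing p-values are recomputed as two-sided normal from β/SE; rows with
  non-positive SE, malformed alleles or unparseable numerics are dropped
  (and counted) rather than failing the read.
* Degenerate ratio sets (all identical) short-circuit the mode bandwidth to
  zero and return the common value; bootstrap SEs are floored at the
  smallest positive float to keep CIs well-defined.
* Weighted-median/mode drop bx = 0 SNPs with a warning; fewer than three
  survivors is an error.
* Empirical p-values never reach exactly zero ((1+k)/(1+n) estimator).

## Sizes used by the acceptance checks

The test suite and `scripts/acceptance.py` run the Monte-Carlo checks at
1000 replicates (type-I error), 500 (estimator recovery, PRESSO null
calibration, harmonization invariants), 200 (outlier power, clump-oracle
instances) and 60–500 end-to-end study runs with per-study MR-PRESSO
simulation counts reduced to 200; these sizes give Monte-Carlo standard
errors comfortably inside each check's tolerance.

## Known limitations

* **MR-Egger dilution.** Under the study's instrument regime (expected F
  confined to the 30–44 band at the exposure sample size), the
  between-instrument spread of true effects is comparable to their sampling
  error: I²GX ≈ 0.57. MR-Egger's slope is attenuated by exactly this factor
  (regression dilution), and the intercept absorbs θ·mean(bx)·(1−I²GX).
  The package reports I²GX (`mrtea.sensitivity.i2_gx`) so users can judge
  Egger reliability; no SIMEX correction is implemented. The acceptance
  suite's Egger recovery check documents this bias rather than masking it.
* The multiplicative random-effects IVW is conservative under homogeneity
  (type-I error ≈ 0.04 at nominal 0.05 for J = 15) because of the
  inflation floor at 1; the fixed-effects variant is exactly calibrated.
* No proxy-SNP search, no multi-allelic or indel harmonization, no
  PhenoScanner-style confounder lookup (out of scope), no additive
  random-effects IVW.
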