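# mrtea

Two-sample Mendelian randomization (MR) pipeline for estimating the causal
effect of green tea intake on Parkinson's disease (PD) age at onset and 28
clinical progression phenotypes from GWAS summary statistics.

Observational studies link green tea to lower PD risk, but confounding and
reverse causation cloud whether it slows PD *progression*. MR sidesteps
both by using genetic variants as instruments: for SNP *j* with exposure
effect γ_j and outcome effect Γ_j = θ·γ_j + α_j, the causal effect θ is
estimated by inverse-variance-weighted (IVW) meta-analysis of the per-SNP
Wald ratios Γ̂_j/γ̂_j — equivalently, weighted regression of outcome on
exposure effects through the origin — with MR-Egger, weighted-median and
weighted-mode estimators, Cochran's Q, MR-PRESSO outlier detection and
leave-one-out analysis guarding against horizontal pleiotropy (α_j ≠ 0).

The package provides:

* `mrtea.sumstats` — summary-statistics / LD-reference containers and TSV I/O;
* `mrtea.instruments` — genome-wide-significance filtering (P < 5e-8),
  greedy LD clumping (r² < 0.001 within 10 Mb), per-SNP F statistics;
* `mrtea.harmonize` — allele harmonization incl. strand flips and
  frequency-based palindrome resolution;
* `mrtea.estimators` — Wald ratio, fixed/multiplicative-random-effects IVW,
  MR-Egger, weighted median, weighted mode, odds-ratio transforms;
* `mrtea.sensitivity` — Cochran's Q, MR-PRESSO (global / outlier /
  distortion tests), leave-one-out, I²GX;
* `mrtea.pipeline` — the multi-outcome study driver with Bonferroni
  familywise control (0.05/28) and forest/sensitivity/scatter/funnel tables;
* `mrtea.simulate` — a synthetic two-sample GWAS generator with known
  ground truth (exposure N = 64,949, outcome N = 4,093, instrument F in the
  30–44 band), so the whole pipeline runs without external downloads.

See `docs/methods.md` for the statistical details and known limitations.

## Worked example

The `analysis/` scripts run the full study on synthetic data:

```sh
python analysis/01_simulate_study.py   # writes results/synthetic_study/
python analysis/02_run_study.py        # writes results/study_run/
```

which prints

```
29 outcomes analysed with 10 instruments (median F = 44.3)
Bonferroni threshold 0.00179; 1 outcome(s) significant:
  continuous_seadl [continuous]: beta -1.37 (-1.74--1.00), P = 4.57e-13
tables written to .../results/study_run
```

Here the generator injected one truly causal outcome (index 11, the SEADL
disability scale) among 28; the pipeline selects 10 independent
genome-wide-significant instruments (all F > 30, i.e. no weak-instrument
concern), harmonizes each outcome, and flags exactly the causal outcome at
the Bonferroni threshold 0.05/28 = 1.79e-3 — the estimate −1.37
(95% CI −1.74 to −1.00) recovers the injected protective effect of −1.5
within its confidence interval. `results/study_run/` then contains the
forest table (`results.tsv`), the per-outcome heterogeneity/pleiotropy
diagnostics (`sensitivity.tsv`, with Q, Egger intercept and MR-PRESSO
global p per outcome), scatter/funnel tables per outcome and a
`manifest.json` of seeds and harmonization actions. The same pipeline is
scriptable from the shell via the `mrtea` CLI
(`mrtea simulate|instruments|harmonize|estimate|sensitivity|run`).

`analysis/03_calibration.py` prints a quick Monte-Carlo calibration
summary (IVW type-I error ≈ 0.03 at nominal 0.05, estimator means within a
few thousandths of an injected θ = −0.14, MR-PRESSO null global p ≈ 0.50,
10-SE outliers detected in 100% of runs).

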