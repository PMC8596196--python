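# msdr — doubly robust comparison of MS disease-modifying therapies

`msdr` is an analysis pipeline for real-world comparative effectiveness of
multiple sclerosis (MS) disease-modifying therapies (DMTs), built for
biostatisticians working with registry-linked electronic health record (EHR)
data. It compares two treatment arms (e.g. dimethyl fumarate vs fingolimod,
or rituximab vs natalizumab) on three relapse outcomes — the 1-year relapse
rate, the 2-year relapse rate, and time to relapse — while correcting
confounding by indication with high-dimensional EHR covariates.

Because real registry/EHR cohorts are private, the package ships a
first-class synthetic-cohort generator with known causal ground truth, and
every statistical claim the pipeline makes is validated against that truth
in the test suite.

## The estimator

For each binary horizon outcome `Y = 1(T ≤ h)`, with treatment `A ∈ {0,1}`,
confounders `X`, propensity score `π(X) = P(A=1|X)` and per-arm outcome
regressions `m_a(X) = P(Y=1|A=a,X)`, the augmented inverse probability
weighted (AIPW) per-arm mean is

    μ̂_a = (1/n) Σ_i [ m̂_a(X_i) + 1(A_i=a) · w_i · (Y_i − m̂_a(X_i)) / π̂_a(X_i) ]

where `w_i` is an inverse-probability-of-censoring (IPCW) observation
weight (0 when `Y_i` is unobservable because follow-up ended before `h`).
The estimator is *doubly robust*: consistent if either `π` or `m_a` is
correctly specified. Reported contrasts are the risk differences
`μ̂₁ − μ̂₀` at 1 and 2 years and the relative risk of 2-year non-relapse
`(1−μ̂₁)/(1−μ̂₀)` from the time-to-relapse analysis.

Nuisance models are adaptive-LASSO-penalized logistic regressions (ridge
initial coefficients, weights `w_j = 1/(|b_j|^γ + ε)`, penalty chosen by
5-fold cross-validated deviance); the time-to-relapse outcome uses a pooled
logistic discrete-hazard model over 30-day intervals. Confounders combine an
expert-defined feature set (utilization, normalized MS ICD/CUI frequencies,
corticosteroid/MRI/hospitalization/emergency procedure frequencies, prior
DMT and relapse history, demographics) with full-EHR counts (ICD rolled up
to PheCodes, CPT consolidated into groups with MS-relevant MRI exceptions,
positively-mentioned CUIs), filtered at <10% prevalence and screened by
marginal logistic regression with Benjamini–Hochberg FDR control at 0.1.
Inference is by patient-level bootstrap (nuisances refit per replicate)
with percentile CIs, min-p resampling adjustment across the three
estimands, and closed-form E-values for unmeasured-confounding sensitivity.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts (n=1200 per comparison, two latent confounders acting on both
treatment choice and relapse hazard):

```bash
python analysis/01_simulate_cohorts.py     # tables + truth oracle
python analysis/02_assemble_cohorts.py     # arm assignment + outcomes
python analysis/03_build_features.py       # expert + full-EHR confounders
python analysis/04_estimate_effects.py     # nuisances + DR estimates
python analysis/05_inference_report.py     # bootstrap + min-p + E-values (slow)
python analysis/06_figures.py              # crude KM vs DR-adjusted curves
python analysis/07_simulation_studies.py   # robustness/coverage/FDR studies
```

Script 04 prints, per comparison (here the standard-efficacy pair, seed 0):

```
[standard]  (crude 2-y rate difference +0.3200)
  rd_1y          DR=+0.1672 (se 0.0278)  oracle-covariate DR=+0.0509  truth=+0.0292
  rd_2y          DR=+0.2657 (se 0.0324)  oracle-covariate DR=+0.1060  truth=+0.0375
  rr_nonrelapse  DR=+0.6221 (se 0.0400)  oracle-covariate DR=+0.8266  truth=+0.9342
  worst post-IPTW |SMD| = 0.078 (unweighted 0.320)
```

Reading this: the crude 2-year contrast (+0.32) is dominated by confounding
by indication (the true effect is +0.04). Adjusting with the *measured*
EHR proxy features removes part of that bias (+0.27) and balances the
measured covariates (worst standardized mean difference drops from 0.32 to
0.08), while the same DR machinery given the generator's latent confounders
(the "oracle-covariate" column, unobservable in practice) recovers the
truth to within sampling error. The gap between the two columns is exactly
the residual confounding that coded proxies cannot explain — the reason
richer EHR feature sets matter in this kind of study.

Script 07 runs the package's simulation studies; with the defaults it
prints (seed 0):

```
Double robustness (confounded null cohort, n=4000):
  crude contrast            +0.1641  (truth 0)
  DR, propensity correct    -0.0001 (se 0.0228)
  DR, outcome model correct -0.0179 (se 0.0169)
Bootstrap 95% CI coverage over 200 cohorts: 0.950
Marginal-screen empirical FDR at q=0.1: 0.042
Post-IPTW max |SMD| of designed confounders: 0.035 (unweighted 0.839)
```

A `msdr` CLI (`msdr simulate`, `msdr validate`, `msdr run …`) exposes the
same stages for ad-hoc runs on CSV inputs.

## Layout

```
src/msdr/        library: simulate, cohort, features, nuisance,
                 estimation, inference, studies, pipeline, cli
analysis/        numbered narrative drivers (above)
tests/           pytest suite incl. end-to-end statistical properties
docs/methods.md  model, assumptions, parameter choices, limitations
```
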