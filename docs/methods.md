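# Methods

## Problem and estimands

The pipeline targets intent-to-treat comparative effectiveness of two MS
disease-modifying therapies under confounding by indication: neurologists
choose treatments partly on prognosis (prior relapse activity, disease
burden visible in the EHR), so crude arm comparisons are biased. Three
estimands are reported with arm 0 (drug_a) as reference:

* `rd_1y`, `rd_2y` — differences in the probability of any relapse
  (clinical or radiologic, counted identically) within 365 / 730 days of
  treatment initiation, on the probability scale;
* `rr_nonrelapse` — the ratio of 2-year relapse-free probabilities,
  derived from the time-to-relapse analysis; values below 1 mean more
  relapse in arm 1.

Horizon intervals are half-open `(0, h]` with 1 year = 365 days and
2 years = 730 days; relapses on the index day itself are excluded by
default (`include_index_day` flips this). These conventions are fixed for
reproducibility, not clinically load-bearing.

## Cohort assembly

DMT episodes carry an efficacy tier (standard: interferon-beta, glatiramer
acetate, daclizumab, dimethyl fumarate, fingolimod, teriflunomide; higher:
natalizumab, rituximab, alemtuzumab; chemotherapy: cyclophosphamide,
mitoxantrone). The standard-efficacy comparison indexes on the first
episode of either study drug and excludes patients with any higher-tier or
chemotherapy exposure before that date. The higher-efficacy comparison
indexes on the first-ever higher-tier episode — covering both direct
starters and switchers from standard therapy — assigns its drug when it is
one of the two study drugs, and excludes patients with chemotherapy before
the index. Assignment is order-invariant (episodes are sorted internally).

Patients censored before a horizon without a prior relapse have that
horizon indicator *missing*; it is handled by inverse-probability-of-
censoring weighting (IPCW) downstream rather than complete-case deletion,
which would bias rates whenever follow-up length correlates with outcome
risk.

## Confounder construction

Expert-defined features mirror standard practice: health-care utilization
on a `log(1 + count)` scale (raw counts feed the normalizing denominators),
MS diagnosis-code and narrative-concept frequencies normalized by
utilization, normalized corticosteroid / MRI / hospitalization / emergency
procedure frequencies, months of prior DMT exposure, relapse counts in the
prior 1 and 2 years, age, sex, a race/ethnicity indicator, disease duration
and follow-up duration. Windows are measured backward from the index day:
3 months = 90 days, 6 months = 180 days, overall = all history, half-open
`(index − w, index]`. Zero-denominator normalized features are set to 0
(with a warning) to keep the matrix dense for the penalized fits.

Full-EHR features are windowed counts of every ICD code rolled up to a
PheCode (many-to-one; a code mapped to two PheCodes is an error), every
CPT code consolidated into its group except MS-relevant MRI procedures
kept as individual codes, and every narrative concept (CUI) counting only
positive mentions — negated mentions are dropped at ingestion. Features
present in fewer than 10% of patients are removed (exactly 10% is kept);
the survivors are screened by univariate logistic regression against the
2-year relapse label with Benjamini–Hochberg FDR control at q = 0.1.
Expert features bypass both filters. The screen's univariate Wald tests
are computed by a vectorized two-parameter Newton solver (validated
against statsmodels) so that the 500-replicate FDR simulation runs in
seconds.

## Nuisance models

All nuisance fits are adaptive-LASSO logistic regressions. Stage 1 fits a
ridge-penalized logistic model with the ridge strength chosen by the same
K-fold CV (deviance); under a global null the selected ridge penalty is
strong, initial coefficients collapse into the `ε = 1e-4` cap and the
adaptive weights `w_j = 1/(|b_j|^γ + ε)` become near-uniform, which is
what gives the procedure its clean null behaviour. Stage 2 solves the
weighted L1 problem over a 15-point log-spaced penalty grid (liblinear),
columns standardized internally, coefficients returned on the input
scale. `γ = 1` by default; `γ = 0` reduces exactly to the plain LASSO.

Two penalty-selection rules are exposed. Model selection uses the glmnet
1-SE convention (sparsest penalty within one SE of the CV-deviance
minimum); this reproduces the selection behaviour of the reference R
implementation. Nuisance estimation inside the DR pipeline uses the
CV-deviance *minimum*: the extra shrinkage of the 1-SE rule is good for
parsimony but leaves residual confounding (we observed post-IPTW SMDs of
~0.19 on designed confounders under 1-SE vs ~0.04 under CV-min), and DR
theory wants nuisance predictions, not sparse support.

The time-to-relapse outcome regression is a pooled logistic discrete-time
hazard model over 30-day intervals up to the horizon with a constant
conditional hazard given covariates (no per-interval intercepts); for a
covariate-free fit the predicted horizon probability is exactly
`1 − (1 − ĥ)^T`. Propensity scores are truncated to `[0.01, 0.99]` as
positivity protection. An arm with no observed events gets the constant
model `m_a ≡ 0` with a warning; per-arm fits require at least 25 patients.

## Doubly robust estimation

The AIPW per-arm mean combines the outcome regression with the weighted
residual correction (formula in the README). Observation weights for
horizon indicators are `D_i / Ĝ(min(T_i, h)−)` where `D_i` flags an
observable indicator (relapse before censoring and the horizon, or
follow-up reaching the horizon) and `Ĝ` is a product-limit estimate of
the censoring survival curve (censoring treated as the event; ties
resolved events-first; left-continuous evaluation; floored at 0.05 with
flooring logged). Censoring is covariate-independent by default in the
generator and the KM censoring model matches that; a covariate-dependent
switch exists for stress-testing. Per-arm DR means are deliberately not
clipped to [0, 1] — out-of-range values are flagged instead, since
clipping would mask positivity problems. The ratio estimand's SE comes
from delta-method influence contributions; all estimates carry their
influence vectors for SE computation and reuse.

Balance diagnostics report standardized mean differences
`(weighted mean₁ − weighted mean₀) / pooled unweighted SD` before and
after IPTW; crude curves are lifelines Kaplan–Meier cumulative incidence,
and DR-adjusted curves standardize the pooled-logistic hazard predictions
over the whole cohort (g-computation).

## Inference

Bootstrap resamples patients with replacement and re-runs the *entire*
nuisance-plus-DR pipeline per replicate; failed replicates (e.g. an empty
arm) are redrawn and counted, with more than 5% failures aborting. CIs
are percentile intervals using the `(B+1)α` order-statistic convention
(Davison–Hinkley), which matters at the scaled-down B = 200 used in
simulation studies; the production default is B = 10,000. Raw p-values
are `2·min(frac ≤ null, frac ≥ null)` with null 0 for differences and 1
for ratios (ratios handled on the log scale).

Multiplicity across the three estimands uses a min-p step-down resampling
adjustment computed from the same draws: each estimand's draws are
centered at its point estimate, per-replicate pseudo p-values come from
each estimand's own empirical two-sided tail (midranks), and the adjusted
p for estimand j is the fraction of replicates whose minimum pseudo-p is
at most j's raw p, with step-down monotonicity and `adjusted ≥ raw`
enforced. On independent nulls this reproduces `1 − (1 − p)^3`; on
perfectly correlated estimands it collapses to the raw p.

E-values use the published closed form `E = RR* + sqrt(RR*(RR*−1))`,
`RR* = max(RR, 1/RR)`, with `E*` from the CI limit closer to 1 (1 when
the CI crosses 1). Risk differences are converted to the ratio of the DR
per-arm means first; the output labels this as an approximation.
Significance is `p < 0.05` after adjustment.

## Synthetic cohorts and what they do (not) show

The generator draws low-dimensional latent Gaussian covariates `Z` per
patient; a logistic model on `Z` assigns arms, an exponential
proportional-hazards model (`baseline_hazard` 0.25/year at covariate
zero) draws relapse times, and censoring combines an exponential hazard
(0.2/year) with an administrative cutoff at 1825 days. The default
confounder spec `(z0: +1.0 on treatment log-odds, +0.7 on log-hazard)`
produces a crude 2-year bias of ≈ 0.16 under a null effect — large enough
that any unadjusted analysis is visibly wrong. Coded features (ICD, CPT,
CUI; ~140 codes by default) occur as Bernoulli-gated negative-binomial
counts whose occurrence logits load on `Z` for half the codes, so the
screen has true positives; per-code prevalences are Beta-distributed
around the `sparsity` target (0.2) so the <10% filter has work to do.
CUIs carry a positivity flag with 15% negated mentions. Dates are integer
day offsets from a fixed epoch.

The truth oracle evaluates both potential outcomes per Monte-Carlo draw
through the closed-form exponential survival function (no censoring), a
Rao-Blackwellised estimate whose `mc_se` is exactly zero under the null
(floored at 1e-12); under the exponential model the horizon probability
is cloglog-linear in the covariates, which the coverage study exploits to
have an exactly-specified outcome model.

What the synthetic world does *not* reproduce: real code semantics,
visit-process informativeness, treatment discontinuation/switching after
the index, multi-site heterogeneity, and — importantly — the strength of
real EHR proxies. Measured code counts here carry only part of the latent
confounder signal, so the feature-adjusted DR estimates remove only part
of the designed bias while oracle-covariate adjustment recovers the truth
(script 04 shows both). Passing tests therefore demonstrate that the
machinery is correct given its inputs, not that any particular feature
set suffices for a real cohort.

## Problem sizes and numerical choices

Simulation studies run at desk scale chosen for stable Monte-Carlo
behaviour: double robustness and estimand recovery at n = 4000;
coverage over 200 cohorts of n = 1500 with B = 200 (the coverage study
uses fast exactly-specified Newton/cloglog nuisances, since it tests the
bootstrap machinery, not the penalized fits); FDR over 500 replicates of
n = 500, p = 200; balance at n = 5000. "Within 3 SE" checks use the
estimator's influence-function SE combined in quadrature with the
oracle's `mc_se`. Degenerate inputs are handled explicitly: constant
features get coefficient 0 (and screening p-value 1), all-equal labels
give a constant model with a warning, complete CV failure falls back to
the maximum penalty, and zero pooled SDs give SMD 0.

## Known limitations

* Intent-to-treat only; no adherence or time-varying treatment modelling.
* Censoring model for IPCW is marginal (or arm-specific) KM; covariate-
  dependent censoring in the generator will bias it by design.
* No cross-fitting; nuisance overfitting bias is mitigated only by
  penalization.
* The RD→RR E-value conversion is an approximation, and printed E-values
  from adapted high-dimensional variants elsewhere are not comparable to
  the closed form used here.
* The pooled-logistic hazard has no time-varying baseline; with strongly
  non-constant hazards the survival outcome model is misspecified (the DR
  construction still protects it through the propensity model).
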