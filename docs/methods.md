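# Methods

This note documents the models and procedures the package implements, the
choices made where the published material left the design open, and what the
synthetic-data results do and do not show about real cohorts.

## Instruments and scoring conventions

All scores are computed exactly from the published formulas; nothing is
rounded before band classification (reports round scores to 2 dp, rho to
3 dp, AUC to 3 dp for display only).

**Band boundaries.** Every activity band is half-open with the cut-off on
the closed (lower) side, as the cut-offs are published: DAPSA 4.0 is
remission, 4.0 + ε is low activity; PsAID-12 likewise at 1.4 / 4.1 / 6.7.
The MDA verdict is true iff at least 5 of the 7 criteria hold, each
evaluated inclusively (e.g. HAQ = 0.5 counts as met).

**PASDAS global scales.** The published equation takes the patient and
physician globals on a 0–100 VAS while records store them as 0–10 NRS. The
default (`global_scale="vas100"`) multiplies the NRS by 10 before the square
root, matching the source instrument's convention; `"nrs10"` is available
for data already on the 10-point scale. The `pcs` input is whichever SF
physical component summary the record carries (the published equation's
SF-12/SF-36 distinction is not resolvable from the record; no conversion is
applied).

**CPDAI grid.** The 0–3 per-domain cut-offs are not part of this package's
validation data, so the grid is a configuration object: ordered
`(upper bound, grade)` thresholds per domain plus an optional
functional-impairment escalation (HAQ > 0.5 raises an active domain one
grade, capped at 3). The shipped default is adapted from the original
instrument's published cut-offs; because the DLQI is not collected in this
record layout, the skin domain is graded on PASI alone
(0 / ≤10 / ≤20 / >20). Tests exercise the rule engine, not the default
numbers. The spinal domain reads BASDAI when axial disease is present and
contributes 0 otherwise.

**PASI and HAQ.** PASI uses the standard region weights (head 0.1, upper
limbs 0.2, trunk 0.3, lower limbs 0.4) applied to
(erythema + induration + desquamation) × area-grade. HAQ items are rated
0–3 (the instrument's standard item scale) and aggregated
category-maximum-then-mean over the 8 categories, with at least 6 complete
categories required and no aids/devices adjustment.

**Missing data.** No imputation anywhere: any index with a missing input
raises a typed `MissingDataError`, and the pipeline reports excluded-record
counts, so the analysis n is always explicit.

**CRP units.** DAPSA and PASDAS take CRP in mg/dL. The cohort reader
rejects files declared in mg/L unless conversion is explicitly requested.

## Content validity

CVI is the proportion of panel experts rating a domain 2–4 on Lynn's 1–4
relevance scale; mean importance is the panel mean on the separate 0–3
scale; FIP = 100 · CVI · mean importance. Bands: adequate ≥ 88%,
unacceptable ≤ 69%, questionable between (the published bands leave
(69%, 70%) undefined; it is assigned to questionable for continuity, and
the retention rule — eliminate at ≤ 69%, require mean importance ≥ 2.0 —
is unaffected by the gap). Ranking is strictly by descending FIP with ties
broken by CVI then label.

The packaged development-panel summary carries the printed per-domain CVI
and mean importance. Two of its printed values are anomalous and are kept
as printed rather than corrected: the functional-capacity FIP (printed
193.60; 100 · 0.88 · 2.18 = 191.84, consistent with an unrounded CVI near
88.8%) and the sexual-life row's position (printed below a row with a
smaller FIP). The module always recomputes FIP from CVI and mean
importance, so its table shows 191.84 and strict FIP order.

## Validation statistics

**Spearman.** Midrank tie handling with the t-approximation p-value
(delegated to scipy). Interpretation bands on |rho|: < 0.26
little-to-none, [0.26, 0.50) low, [0.50, 0.70) moderate, [0.70, 0.90] high,
> 0.90 very high (the published cut points leave slivers between bands;
they are closed into these half-open intervals). Constant input raises an
error rather than returning an undefined coefficient.

**ROC/AUC.** The AUC is the tie-corrected Mann–Whitney statistic divided by
n₁n₀ (midranks; ties count one half), which tests verify against an
exhaustive pair-counting oracle. The positive class is the *active*
(non-MDA) state, and inverse-coded instruments (SF-36) are negated before
the ROC so every AUC reads in the same orientation. The standard error is
Hanley–McNeil with Q₁ = A/(2−A), Q₂ = 2A²/(1+A); it is exactly 0 at A = 1
and shrinks with either class size. The 95% CI is a Clopper–Pearson-shaped
interval with the effective sample size implied by the Hanley–McNeil
variance, n_eff = A(1−A)/SE²; this keeps the Hanley–McNeil variance while
respecting the [0, 1] bounds (at degenerate AUCs n_eff falls back to
min(n₁, n₀)). Paired AUC comparison uses DeLong's covariance method on
placement values; tests check its SE against a paired bootstrap.

**Group contrasts.** Mann–Whitney for two groups, Kruskal–Wallis for more
(the pipeline's thermometer-subscale contrasts use Kruskal–Wallis even at
k = 2; its chi-square p is the asymptotic equivalent of the Mann–Whitney
normal approximation). Chi-square (without continuity correction) for
categorical tables. All p-values two-sided; no multiple-testing correction
is applied, matching the validation design this package mirrors.

**Descriptives.** Mean with t-based 95% CI; median with a conservative
equal-tailed exact binomial order-statistic 95% CI (lower rank l is the
largest with P(Bin(n, ½) ≤ l−1) ≤ 0.025, upper rank n+1−l); unbiased
skewness/excess kurtosis with their scipy tests (skewness requires n ≥ 8,
kurtosis n ≥ 20); Shapiro–Wilk normality decision at α = 0.05. Statistics
undefined for a sample (e.g. normality of constant data) are reported as
unavailable rather than guessed.

## Synthetic cohort generator

The generator emulates the statistical structure a PsA validity study
assumes, not any individual patient data.

**Model.** A single latent severity z per patient, drawn from a
two-component Gaussian mixture: a low-activity component at −1.55
(SD 0.35) with weight 0.22 — the MDA prevalence observed in the development
cohort — and an active component at +0.437 (SD 0.616), placed so the
default latent has mean 0 and variance 1. Each raw input is
`location + sd·loading·z + noise·ε` with per-input loadings (a one-factor
Gaussian copula); the default noise SD is `sd·√(1−loading²)` so the
marginal SD equals its target. Inputs are then mapped to their scales:
counts by rounding and truncation (truncated rounded Gaussians rather than
Poisson, to reach the overdispersed target SDs), bounded scales by clipping
and step-rounding. SF-36 summaries load negatively, encoding their inverse
coding.

**Calibration.** Channel locations are solved analytically so the
*post-transform* marginal mean equals its target (mixture-normal
expectations for the round/clip transforms, Brent root-finding); an
unreachable target raises a configuration error. Marginal SDs are matched
through the pre-transform scale and shrink where a hard bound truncates a
wide target — most visibly the 0–6 enthesitis count, whose published SD
(3.38) exceeds what its range supports; the generated SD is ≈ 1.8.

**Targets.** Count, CRP, PASI, HAQ and PCS means/SDs come from the
development cohort's descriptive table (e.g. TJC 6.73 ± 6.66,
CRP 3.62 ± 2.95, PASI 5.41 ± 5.09, HAQ 1.08 ± 0.70, PCS 41.14 ± 9.55). The
NRS items are not tabulated there; their defaults (pain 4.1 ± 2.6,
PtGA 4.2 ± 2.6, PhGA 3.8 ± 2.4, thermometers 3.94 ± 2.28) are set so the
derived composites land near their published means (thermometer items at
39.39/10, the PsA-5Ts mean over its weight sum). PsAID items target the
published PsAID-12 mean (4.90) with a realistic item SD of 2.6; the
published PsAID-12 SD (4.11) is internally inconsistent with its own
median/IQR (median outside the IQR) and is not targeted. Loadings for the
seven MDA-relevant inputs are high (0.8–0.95) so the low-activity component
mostly satisfies the MDA criteria, giving an MDA fraction near the 0.22
mixture weight; axial involvement (BASDAI present) defaults to 30% of
patients, a realistic mixed-pattern clinic fraction.

**Truth vs criterion.** The mixture component and latent value are recorded
as generator truth, but MDA labels used by every analysis are computed from
the generated records through the clinical criteria, so the pipeline's
external criterion is exactly the clinical one.

**What passing tests show.** On default cohorts the pipeline recovers the
qualitative validity structure: bimodal, normality-rejecting composite
distributions; all-positive intercorrelations among activity indices with
all-negative SF-36 correlations; composite AUCs against MDA status above
the SF-36 AUC. Because every instrument shares one latent factor, the
synthetic intercorrelations (rho ≈ 0.8–0.95) are stronger than the
multifactorial patterns of real cohorts (≈ 0.4–0.8), and AUCs are
correspondingly higher; the generator demonstrates that the pipeline
measures these structures correctly, not that the instrument attains any
particular AUC in practice. Responsiveness/longitudinal behaviour is not
simulated.

**Problem sizes.** The test suite exercises the study-sized cohort
(n = 155) across 50 seeds for the recovery checks, n = 10⁴ for marginal
calibration, and n ≈ 1200–2500 for the independence and separation
properties — sizes at which binomial/rank noise is small relative to the
asserted margins.

## Known limitations

- The CPDAI default grid is an adaptation (PASI-only skin domain); users
  with DLQI data should supply their own grid.
- The AUC confidence interval is an exact-binomial-shaped approximation
  around the Hanley–McNeil variance, not a published closed-form method.
- The generator matches means exactly and SDs approximately (truncation);
  it makes no attempt to match higher moments or real multifactorial
  correlation structure.
- SF-36 and BASDAI are consumed as summary inputs; item-level scoring of
  either questionnaire is out of scope.
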