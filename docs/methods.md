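# Methods

## Blood circulation model

Circulating blood is modelled as `N = V/v` discrete elements (defaults
V = 5.3 L, v = 0.053 mL, so N = 100,000) moving through a closed cycle of
compartments. The default topology is heart → lungs → remainder → heart with
blood-volume fractions 0.090 / 0.105 / 0.805 and cardiac output 6.5 L/min,
ICRP Publication 89 reference-adult values. These are configuration defaults,
not fitted quantities, and are overridable through the model config
(`total_blood_volume_l`, `element_volume_ml`, `cardiac_output_l_min`,
`compartments`, `transit_law`).

Only the heart and lungs act as dose sources, so a finer systemic anatomy
would be unidentifiable from the available inputs; the remainder pool exists
to keep transit timing correct. Mean sojourn time in compartment *c* is
τ_c = f_c·V/CO (≈ 4.4 s heart, 5.1 s lungs, 39.4 s remainder). Sojourns are
drawn exponentially with mean τ_c by default — a memoryless renewal cycle —
with a `fixed` transit law available for sensitivity checks. The renewal
reconstruction is a modelling choice: the upstream hematological-dose
framework's exact path law is not published with this analysis. Elements
start from the stationary distribution (the volume fractions) with a
residual-life draw (exponential: memoryless; fixed: U(0, τ)), so occupancy
is unbiased even over windows as short as one beam. Long-run occupancy of
each compartment converges to its volume fraction; this stationarity is
asserted in tests at 3 Monte-Carlo standard errors with 10⁴ elements.

## Dose accumulation

Each fraction delivers the per-fraction organ dose — the composite plan DVH
with its dose axis divided by the number of fractions (identical fractional
anatomy each day; only composite DVHs are available) — at a uniform rate
during beam-on. The default schedule is 2 beams × 60 s back-to-back with no
gap; finer delivery time structure is deliberately not modelled. For every
visit of an element to a dose-source organ, one voxel dose is drawn from the
organ's per-fraction differential DVH and accrued in proportion to the
beam-on seconds the visit covers. Drawing per visit (rather than fixing a
voxel per element) represents blood moving through a heterogeneous dose
field and makes multi-fraction averaging meaningful. Fractions are summed
with paths and draws resampled independently, sub-seeded via
`SeedSequence(seed, spawn_key=(k,))` for fraction *k*, so runs are
bit-reproducible and the 30-fraction distribution is genuinely narrower than
one fraction scaled by 30.

Consequences used as test oracles: accrual is exactly linear in the plan
dose axis; the expected mean blood dose equals Σ_o f_o·D̄_o (blood-fraction-
weighted organ mean doses); a uniform-dose plan in a single-compartment model
yields every element exactly the prescription. Doses are recorded in GyE with
no re-weighting — plan DVHs are assumed already RBE-weighted.

## DVH conventions and metrics

Cumulative DVHs use the "volume receiving ≥ dose" convention (closed at the
threshold); differential bins sit at interval midpoints, with the terminal
mass at the last grid dose. D*x*% is the empirical quantile — the largest
sample dose received by at least *x*% of elements, lower tie-break — and
V_tGyE counts elements at ≥ t. Organ V_t interpolates the cumulative curve
linearly. Exported bDVH curves use 0.01 GyE bins; metrics recomputed from
the binned curve agree with per-element values within half a bin.
BED = nd(1 + d/(α/β)), reported to one decimal.

## SRIL classification and models

SRIL is ≥ 2 weekly ALC values strictly below 200/µL (CTCAE grade 4) during
the course; missing weeks are skipped, never imputed, and an all-missing
series is an error (such patients are excluded, not classified). Events need
not be consecutive.

Logistic models are fitted by maximum likelihood (statsmodels) with Wald 95%
intervals and AIC = −2ℓ + 2(k+1). Rank-deficient designs raise an error
naming the collinear terms; (quasi-)separation falls back to a
gradient-based fit and flags the result instead of silently diverging.

"Stepwise selection after ten-fold cross-validation" is implemented as a
bidirectional stepwise-AIC search from the base model within each fold's
training portion (seeded fold assignment), retaining a candidate selected in
more than half the folds. Because folds share ~80% of the data, fold votes
are correlated: a pure-noise candidate whose full-sample AIC happens to
favour it (~15% of draws) is usually retained in most folds, so the
per-candidate false-selection rate is ~10–15%, not the naive per-fold rate.

The maxstat cutpoint maximises the standardised two-sample linear rank
statistic |S − E[S]|/√Var[S] over candidate thresholds (distinct predictor
values inside the inner 10–90% quantile range, avoiding boundary
instability), returning the midpoint between the argmax and the next
distinct value. For a binary outcome, 0/1 scores are affinely equivalent to
Wilcoxon midranks, so the standardised statistic is identical. An optional
permutation p-value resamples outcome labels. No multiplicity adjustment is
applied beyond AIC comparison across candidate models; the permutation p is
provided for users who want one.

AIC comparison ranks fits ascending with ties broken toward fewer terms, and
requires a common sample. Dose–response curves evaluate the fitted logistic
at a grid of the dose variable with other covariates at their sample means
(note: the logistic of mean covariates is not the mean fitted probability;
the model's exact invariant — mean fitted probability equals outcome
prevalence — is the one asserted in tests).

## Survival

Times are months from the first day of chemoradiation. Kaplan–Meier curves
use right-continuous step lookup; the log-rank statistic is the standard
observed-minus-expected chi-square over pooled risk sets; Cox models use the
Efron tie correction (the less-biased standard when event times tie). A
univariable screen (retain p < 0.05) is provided as a helper for choosing
multivariable entry terms, not hard-wired. lifelines provides the fitting
machinery behind this module's interface; an independent first-principles
risk-set computation serves as the log-rank test oracle.

## Synthetic cohort generator

The generator emulates the structure of a 201-patient locally-advanced NSCLC
chemoradiation cohort (164 IMRT / 37 PBSPT, 66 GyE in 30 fractions):

- **Organ DVHs**: renormalised logistic sigmoids V(d) = σ((m−d)/s)/σ(m/s) on
  a 0–70 GyE grid, (m, s) drawn per patient from modality-specific normal /
  lognormal families. Defaults put lung mean dose near 18 GyE (IMRT) vs
  13 GyE (PBSPT) and heart near 13 vs 8 GyE, reproducing the proton sparing
  of the low-dose bath directionally; the resulting blood-dose medians
  (mean ≈ 2.97, D90 ≈ 2.44 GyE) fall where a mixed photon/proton thoracic
  cohort's do. These are soft calibrations — distributions resemble, not
  equal, any particular cohort.
- **Volumes and baseline ALC**: lognormal (PTV median 576 cc, σ_log 0.54;
  baseline ALC median 2.1 × 10³/µL, σ_log 0.33).
- **Weekly ALC (mechanistic mode)**: ALC_w = baseline·exp(−α·D_cum(w))·exp(ε_w),
  ε_w ~ N(0, 0.25²), cumulative mean blood dose linear over 6 weeks, floored
  at 1/µL. α defaults to 0.87 per GyE, calibrated once so mechanistic SRIL
  incidence matches the ~37% cohort rate at the default dose mix (yielding
  ~44% IMRT vs ~3% PBSPT). Exponential depletion is the simplest mechanism
  consistent with gradual on-treatment decline and lymphocyte
  radiosensitivity; it is a synthetic construct, not an estimated kinetic.
- **Parametric mode**: SRIL drawn directly from a logistic model with exactly
  known coefficients (defaults: OR 0.48 per 10³ ALC/µL, 1.01 per 10 cc PTV,
  6.38 for a binary high-D90 indicator at prevalence 0.42); the intercept is
  solved once on a large fixed reference draw so marginal prevalence is
  75/201. Weekly series are then minimally adjusted so the counting rule
  reproduces the drawn label — a bookkeeping step, clearly synthetic.
- **Survival**: exponential event times with hazard scaled by exp(log HR·SRIL)
  (defaults HR 1.42 OS, 1.65 PFS), baseline hazards solved from 3-year
  marginal rates (62.4% OS, 26.2% PFS), progression-free time capped at the
  death time, administrative censoring U(12, 60) months.

What passing tests show — and don't: parameter-recovery tests demonstrate
that the statistical machinery is correct when the data-generating model is
exactly the fitted model; they cannot show that real lymphopenia follows an
exponential depletion law, that real DVHs are sigmoid, or that covariates
are lognormal and independent. The mechanistic mode couples dose to outcome
far more tightly than clinical data (dichotomised ORs come out much larger
than published clinical estimates), so analysis outputs on synthetic cohorts
are pipeline demonstrations, not clinical inferences.

## Problem sizes and numerical choices

Simulation-based tests use 10⁴ blood elements (Monte-Carlo SE of the mean
blood dose ~0.01 GyE) and the analysis drivers 2 × 10³ per patient; both are
package defaults chosen to keep cohort-scale runs interactive while leaving
assertions at 3 SE comfortably powered. Recovery checks use 100 cohorts of
n = 201 (logistic) and 50 replicates of n = 1000 (cutpoint); CI-coverage
checks use 100–400 replicates, sized so the binomial error of the coverage
estimate is small against the asserted margin. Ties in the maxstat scan
break toward the lower cutpoint; degenerate inputs (single-class outcomes,
zero-variance covariates, empty distributions, windows of zero measure) are
rejected with named errors rather than propagating NaNs.

## Known limitations

One shared circulation model for all patients (blood volume and flow are not
patient-specific); no sub-beam delivery time structure, respiratory motion,
or dose-rate effects; no dose to non-circulating lymphocytes in nodes,
spleen, or marrow; the three-compartment topology is the coarsest model
consistent with heart/lung dose inputs; synthetic cohorts share none of the
correlation structure of real clinical covariates beyond what is explicitly
generated.
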