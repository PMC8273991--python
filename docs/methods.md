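# Methods

`shockdtr` implements a two-part analysis of septic shock: (1) latent-class
phenotyping of ICU patient-days with a constrained Gaussian finite mixture
model, confirmed by a k-means cluster-number index battery, and (2)
individualized daily dosing of fluid volume and norepinephrine-equivalent
vasopressor dose by a regression-based dynamic treatment regime (dynamic
weighted ordinary least squares, dWOLS), with downstream dose-gap, risk-factor
and time-varying survival analyses. Because the motivating multicenter cohort
is not public, a calibrated synthetic cohort generator is a first-class part
of the package; every analysis is exercised against it and against known
ground truth.

## Phenotyping model

Patient-days (ICU days 0, 1, 2, 3, 7; 17 clinical features each) are pooled
into one sample and modeled as a K-component Gaussian mixture in which each
feature has one variance shared by all components and all covariances are
fixed at zero. For component k with mean mu_k and shared diagonal covariance
diag(v),

    p(x) = sum_k  w_k  N(x | mu_k, diag(v)),        sum_k w_k = 1,

so the free parameter count is K*d + d + (K-1) with d = 17. The constraint
keeps components axis-aligned and equally dispersed, which makes class
centers directly interpretable as clinical profiles and keeps the model
estimable on ~10^3-10^4 patient-days. EM is hand-written: the E-step reduces
to one matrix product per iteration under the shared diagonal covariance;
the M-step pools one variance per feature over all components. The
log-likelihood sequence is checked to be non-decreasing at every iteration
(tolerance 1e-7 relative) and a violation raises.

Numerical choices: k-means++ centers hardened into one-hot responsibilities
initialize each of 20 restarts (best restart by log-likelihood kept);
convergence at 1e-6 relative log-likelihood change, at most 500 iterations; a
variance floor of 1e-8 times the overall mean feature variance prevents
component collapse; a restart that empties a component is redrawn.

### Class-number selection

Candidate counts K = 2..8 are each fit and scored by:

- AIC = -2 loglik + 2 p and SABIC = -2 loglik + p log((n+2)/24) (the
  sample-size-adjusted penalty);
- normalized entropy E = 1 - [sum_i sum_k (-p_ik ln p_ik)] / (n ln K), which
  is 1 for perfectly crisp assignment (K = 1 reports 1 by convention);
- a parametric bootstrap likelihood-ratio test of K vs K-1: B samples of the
  original size are drawn from the fitted (K-1) model, both models are refit
  on each (2 restarts per refit, same settings for the observed statistic),
  and p = (1 + #{LR_b >= LR_obs}) / (B + 1). B defaults to 100; the
  acceptance run uses B = 50. Note the add-one convention means the smallest
  attainable p is 1/(B+1): testing at alpha = 0.05 needs B >= 20;
- the smallest assigned-class fraction (must exceed 0.04 of patient-days);
- the minimum membership probability, operationalized as the minimum over
  classes of the *mean* max-posterior among patient-days assigned to that
  class (must exceed 0.8). The stricter per-row minimum is available by flag;
  the class-mean form is the default because a per-row minimum over thousands
  of draws from overlapping Gaussians is almost surely near 0.5 even when the
  classes are well separated.

A candidate failing any gate is disqualified. Among qualifiers, the chosen K
is the largest whose AIC improvement over K-1 exceeds 1% of the AIC range
across candidates ("stop where the decline flattens"); if every qualifier is
flat the smallest qualifier wins on parsimony. The full per-K table is always
returned so any alternative rule can be audited. On Table-calibrated
five-class synthetic cohorts (n = 2000 patients, ~7700 patient-days) the rule
returns K = 5 across seeds, with K = 6..8 disqualified jointly by the class-
size rule, the membership rule and the bootstrap LRT.

Class naming applies fixed rules in priority order to the fitted means:
highest lactate -> "critical"; then highest creatinine -> "renal
dysfunction"; then highest PaCO2 -> "respiratory failure"; then lowest age ->
"mild"; the remaining (largest) class -> "baseline". Lactate outranks
creatinine deliberately: the critical-class center has both the highest
lactate and the highest creatinine, and the priority order lets the renal
class still receive its name.

### k-means confirmation

Seven cluster-number indices (Calinski-Harabasz, Davies-Bouldin, Hartigan,
Krzanowski-Lai, Marriot, Rubin, TraceW) are computed from the within/between
scatter matrices of best-of-25 k-means partitions on *standardized* features
(the mixture itself runs on raw features — its shared per-feature variance
absorbs scale, whereas Euclidean k-means and PCA do not). Maximize-rule
indices vote their argmax (CH, KL), minimize-rule their argmin (DB), and
elbow-rule indices (Hartigan, Marriot, Rubin, TraceW) vote the K maximizing
the discrete second difference. The majority (plurality) of votes is
reported with the full tally. Two caveats are reported with every table: the
cubic clustering criterion is excluded (its hyperbox derivation is specific
to one proprietary implementation; a hook allows registering one), and the
second-difference rule is uninformative for Rubin, whose trace ratio is
increasing and concave — the vote is kept for rule uniformity and the
majority is robust to one stray index. On the synthetic cohort the elbow and
KL votes carry the five-class majority while CH and DB prefer coarser
partitions, mirroring the usual behavior of these indices under unequal
cluster sizes.

## Dosing model (dWOLS)

For each treatment separately (fluid mL/day; norepinephrine-equivalent
mcg/kg/min), the terminal hospital-death indicator Y is modeled per stage j
(ICU days 0, 1, 2, 3, 7) on the linear-probability scale as

    E(Y | x, a) = f(x_beta; beta) + a (psi0 + x_psi' psi_x) + psi2 a^2,

where x_psi contains the one-hot class labels (class 1 reference). The blip
is quadratic in the dose: a blip linear in a continuous dose has no interior
minimum, so curvature is the minimal structure under which an "optimal
volume" exists. The optimal stage dose is the vertex -(psi0 + x'psi_x) /
(2 psi2) clipped to stage bounds (the 1st-99th percentiles of observed doses,
preventing extrapolated recommendations); a non-convex stage (psi2 <= 0)
falls back to the better bound endpoint and is flagged.

Estimation is stage-wise weighted least squares with backward induction: the
pseudo-outcome at stage j subtracts every later stage's estimated regret,
Ytilde_j = Y - sum_{k>j} [gamma_k(a_k) - gamma_k(a*_k)], so patients who died
or were discharged early simply accumulate regrets over the stages they
experienced. The informative-censoring caveat this carries is documented,
not solved — it matches the observational design being emulated.

The treatment model is ordinary least squares of dose on the stage
covariates. The default weights are the stabilized inverse-density ratio
q(a) / pi(a|x) — marginal normal density over conditional normal density,
truncated at its 99.9th percentile to control weight variance. This choice
is deliberate: the familiar balancing weight |a - E(a|x)| makes the weighted
dose distribution symmetric about its conditional mean, which protects a
dose-*linear* blip against treatment-free misspecification, but the weighted
dose moments still depend on x, and with a quadratic blip a misspecified
treatment-free model then leaks bias into psi (simulation: the error in the
class-blip coefficient plateaus near 0.05-0.08 across n = 500..32000). The
density-ratio weight makes the weighted dose distribution covariate-free, so
all polynomial blip terms decouple from any treatment-free misspecification
and the bias vanishes with n (0.05 -> 0.017 over the same range). The
absolute-residual weight remains available by flag and the scheme used is
recorded on every stage fit.

Model-based Wald SEs for psi are reported per stage for flagging
(a stage whose every blip coefficient has |t| < 3 is marked
non-informative and the flag propagates to its recommendations); inference
uses a nonparametric bootstrap over patients (200 resamples by default).

Identification strength matters in practice: with the calibrated generator's
dose-outcome signal (+0.12 logit per (1 L)^2 of fluid deviation, +1.5 logit
per (mcg/kg/min)^2 of norepinephrine deviation), the fluid regime is
borderline-identified at 2000 patients (individual stages occasionally flag
non-informative or non-convex) and cleanly identified at 8000, where the
recommended per-day median fluid declines monotonically (resuscitation to
de-resuscitation). The norepinephrine blip, with far less dose variation, is
weakly identified at study scale — the flags surface this rather than hide
it.

## Dose-gap analyses

Delta = actual - optimal dose per patient-day. Fluid deltas fall into five
bins — very low (-inf, -1000], low (-1000, -500], optimal (-500, 500], high
(500, 1000], very high (1000, inf) mL — with left-open/right-closed
boundaries fixed so exact counts are reproducible. Fluid overload is delta >
1000 mL/day; norepinephrine overdosing is delta > 0.1 mcg/kg/min.
Norepinephrine delta levels use symmetric bins at +/-0.05 and +/-0.1
mcg/kg/min, a convention of this package (no published cut exists) and
labeled as such. Delta-level mortality odds ratios come from logistic
regression on category indicators with "optimal" fixed at OR = 1. The
parabola validation fits logit P(death) = b0 + b1 d + b2 d^2 and reports the
vertex -b1/(2 b2) and convexity; on (quasi-)separation the model is refit
with a small L2 penalty and flagged. Risk-factor models use greedy
stepwise-AIC logistic regression (forward or backward; a step must strictly
decrease AIC, so the final AIC never exceeds the initial; perfectly
collinear candidates are dropped before selection and logged). Analyses run
at patient-day level; within-patient correlation is acknowledged and
patient-level bootstrap is available through the DTR bootstrap utilities.

## Time-varying survival model

The labeled cohort is expanded into counting-process intervals (0,1], (1,2],
(2,3], (3,7], covariates frozen at each interval's starting day (fluid in
liters, norepinephrine in mcg/kg/min, class one-hots, plus fixed adjusters).
Death closes the interval containing the death day (a patient dying on their
only observed day contributes a half-day interval by convention — the
partial likelihood needs positive interval length); discharge censors at the
last observed interval; deaths after day 7 are censored at day 7 because no
covariates are observed beyond it. One Cox model per treatment includes
class-by-treatment interactions against the class-1 reference; fitting uses
the Efron tie approximation (many deaths share integer days). Only Efron
handling is offered; the hand-written partial likelihood appears as an
independent oracle in the test suite on a toy with distinct event times,
where all tie conventions coincide.

## Synthetic cohort generator

The generator emulates exactly the structure the analyses assume, which makes
recovery tests internally consistent:

- **Classes.** Day-0 class from the published day-0 class sizes
  (prevalence 0.264/0.080/0.503/0.056/0.096); one Markov step between
  consecutive observed days (day 7 follows day 3 in a single step — no
  hidden days 4-6). The default transition matrix is sticky (0.6 stay) with
  off-diagonal mass biased toward class 1, the class survivors drift to; no
  transition counts are published, so the matrix is a configurable
  illustration, not an estimate.
- **Features.** All 17 features are drawn per patient-day from the current
  class center with the shared diagonal dispersion — the mixture's own
  estimating assumptions. Centers are the published per-class day-0 medians
  (heart rate: means); the shared dispersion is the across-class mean of
  IQR/1.349 per feature (heart rate: mean SD), the Gaussian-consistent
  spread implied by printed quartiles. A per-class dispersion multiplier
  exists for robustness experiments. Consequences for realism: features
  that should be constant within patient (age, weight) fluctuate day to day,
  there are no within-day time series, no skewness, and no feature
  correlations beyond those induced by class mixing. Passing recovery tests
  therefore demonstrates correctness of the estimators under their own
  assumptions, not robustness to real-data violations of them.
- **Dosing policy.** Mean dose = class base x day factor + a lactate tilt,
  plus Gaussian noise, truncated at zero. Fluid bases are the published
  day-0 per-class median intakes; day factors decline toward day 7.
  Norepinephrine bases are plausible clinical magnitudes (no per-class dose
  table is published).
- **Outcome.** Terminal mortality is Bernoulli with logit equal to the
  day-0-class baseline logit plus the summed dose regrets
  psi2 (a - a*)^2 over observed days, minus an analytic per-class/day offset
  equal to the expected regret under the behavior policy. The regret form is
  the blip decomposition f + gamma with f absorbing the optimal-dose terms;
  the offset centers marginal class mortality near the published
  probabilities (0.32/0.41/0.27/0.42/0.21) so the cohort stays calibrated
  while any systematic deviation from optimal dosing still raises mortality.
  The optimal-dose tables encode resuscitation followed by de-resuscitation,
  with class 2 needing prolonged large volume with delayed norepinephrine
  and class 3 de-escalating fluid from day 1. A linear-probability outcome
  scale is available for estimator-recovery work, since the dWOLS working
  model is linear in probability and a logistic outcome attenuates psi.
- **Death timing.** Conditional on death, the hospital death day is
  1 + Poisson(7), independent of covariates, and truncates subsequent
  patient-days; roughly 40% of deaths fall inside the day 0-7 window, giving
  the survival model events to work with. Dropout (ICU discharge) removes
  each subsequent day with probability 0.12 per transition, matching a
  median ICU stay near 9 days.
- **Randomness.** All draws flow from one seed through named substreams
  (classes, dropout, features, doses, outcome, death day), so adding a
  feature never perturbs the dose draws and identical seeds give
  byte-identical tables.

## Problem sizes and test design

The study-scale runs (acceptance script and end-to-end tests) use 2000
patients (~7700 patient-days), candidate counts 2..8 and B = 50 bootstrap
LRT replicates, completing in a few minutes on one CPU; the reduced-scale
selection sweep in the unit suite uses 600 patients, K = 2..7, B = 39 over
three seeds. B = 39 rather than the spec-level default reflects the add-one
constraint above (minimum p = 0.025 < 0.05) at a fraction of the cost.
Estimator-recovery tests build their own linear-probability simulations with
doses far from zero so that the nonnegativity truncation does not
misspecify the treatment model being assumed correct.

## Known limitations

- The generator's within-patient feature independence (given the class path)
  and day-to-day redrawing of demographics are unrealistic by construction;
  see above for what passing tests do and do not show.
- Pseudo-outcome accumulation over observed stages leaves the informative-
  censoring problem of early death/discharge unaddressed, as in the
  emulated design.
- The norepinephrine regime is weakly identified at realistic signal
  strength; its recommendations should be read through the per-stage flags.
- Cox modeling censors post-day-7 deaths; hazard estimates apply to the
  first ICU week only.
- The class-number vote of the index battery is a plurality over seven
  indices, two of which (CH, DB) systematically prefer coarser partitions on
  unequal-size Gaussian classes.
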