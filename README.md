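# shockdtr

Septic shock is a heterogeneous syndrome: patients differ widely in how they
respond to fluid resuscitation and vasopressors, and one-size-fits-all dosing
targets mask subgroups that are helped or harmed by the same strategy.
`shockdtr` is an analysis pipeline for intensivists and biostatisticians that
(1) phenotypes septic-shock patient-days into latent classes from routine
clinical variables and (2) estimates an individualized optimal daily fluid
volume and norepinephrine dose per class and day, optimizing hospital
mortality. The study data it was built around are not public, so the package
ships a calibrated synthetic cohort generator that reproduces the published
class structure; every stage of the pipeline is tested against it and its
known ground truth.

## Models

**Phenotyping.** Patient-days (days 0, 1, 2, 3, 7 after ICU admission; 17
features: age, weight, HR, APACHE II, SBP, temperature, pH, HCO3, lactate,
BE, PF ratio, PaCO2, HCT, platelet, RDW-CV, creatinine, urine output) are
pooled and fit with a Gaussian finite mixture under an equal-variance,
zero-covariance constraint:

    p(x) = Σ_k w_k N(x | μ_k, diag(v)),   one shared v across classes.

The class count is chosen by a composite rule — AIC and SABIC decline,
normalized entropy, a parametric bootstrap likelihood-ratio test of K vs
K−1, a minimum class size of 4% of patient-days, and a minimum class-
membership probability of 0.8 — and confirmed by a k-means battery of
cluster-number indices (CH, DB, Hartigan, KL, Marriot, Rubin, TraceW) with a
per-index vote. Classes are named by fixed rules on the fitted centers
(critical, renal dysfunction, respiratory failure, mild, baseline).

**Dosing.** For each treatment a (fluid mL/day; norepinephrine-equivalent
mcg/kg/min, where NE-eq = norepinephrine + epinephrine + phenylephrine/10 +
dopamine/100 + metaraminol/8 + vasopressin×2.5 + angiotensin II×10), the
terminal outcome Y (hospital death) is modeled per stage as

    E(Y | x, a) = f(x^β; β) + a·(ψ0 + x^ψ'ψ_x) + ψ2·a²,

with the class labels in the blip covariates x^ψ. Stages are estimated
backward (dynamic weighted ordinary least squares with a quadratic blip and
stabilized inverse-density weights); the optimal dose is the blip vertex
clipped to stage-specific percentile bounds. Downstream analyses classify
the dose gap Δ = actual − optimal (fluid overload: Δ > 1000 mL/day; NE
overdose: Δ > 0.1 mcg/kg/min), estimate mortality odds by Δ level, validate
the optimum with a quadratic-logistic "parabola" check, and fit time-varying
Cox models with class×treatment interactions over days 0–7.

## Worked example

The analysis is a chain of numbered scripts, each a thin driver over the
library (`src/shockdtr/`), writing its tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      # calibrated 2000-patient cohort
python analysis/02_preprocess.py           # impute, screen, build matrix
python analysis/03_fit_mixture.py          # select K, fit, name, transitions
python analysis/04_validate_clusters.py    # k-means indices + PCA
python analysis/05_fit_dtr.py              # optimal dosing per day and class
python analysis/06_dose_gaps.py            # delta categories, ORs, parabola
python analysis/07_survival.py             # time-varying Cox models
```

Script 03 prints the selection table and lands on five classes:

```
 K        aic      sabic  entropy  blrt_p  min_frac  min_membership  aic_improvement  qualified
 2 973649.568 973843.821    0.971   0.032     0.145           0.983         9254.105       True
 3 966782.511 967044.005    0.957   0.032     0.122           0.973         6867.058       True
 4 964065.943 964394.678    0.847   0.032     0.115           0.880         2716.568       True
 5 962768.051 963164.028    0.820   0.032     0.115           0.834         1297.891       True
 6 962772.747 963235.965    0.818   0.742     0.003           0.682           -4.696      False
 7 962769.811 963300.270    0.798   0.903     0.006           0.639            2.937      False
 8 962758.453 963356.154    0.711   0.742     0.004           0.489           11.357      False
selected K = 5
entropy 0.820; membership stability 0.834
class names: {1: 'renal dysfunction', 2: 'mild', 3: 'respiratory failure', 4: 'critical', 5: 'baseline'}
```

Six-to-eight-class models are rejected jointly by the 4% class-size rule,
the 0.8 membership rule and a non-significant bootstrap LRT — the same
triangulation that motivates a five-class description of septic shock.
Script 04's index vote concurs (`majority K = 5`), and script 06 reproduces
the U-shaped mortality around the estimated optimum:

```
 category    or  ci_lo  ci_hi  p_value
 very low 1.337  1.155  1.547    0.000
      low 0.912  0.759  1.096    0.325
  optimal 1.000  1.000  1.000      NaN
     high 0.942  0.779  1.139    0.538
very high 1.211  1.055  1.389    0.006
quadratic-logistic check: convex=True, vertex at 316 mL from optimal
```

Both directions of dosing error raise the mortality odds, and the fitted
parabola bottoms out ~300 mL from the recommended volume. Per-stage dosing
fits carry convexity and informativeness flags; at 2000 patients the fluid
regime is borderline-identified (run `01` with `--n 8000` to see the clean
monotone decline of optimal volume from ~3.5 L on day 0 to ~1 L on day 7),
and the norepinephrine blip is weakly identified at realistic signal
strength — see `docs/methods.md`.

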