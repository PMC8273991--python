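"""Synthetic septic-shock cohort generator.

Emulates the statistical structure the downstream analyses assume: patient-days
drawn from a 5-class Gaussian mixture over 17 clinical features with a shared
diagonal covariance, Markov class transitions across ICU days 0/1/2/3/7, a
state-dependent behavior policy for daily fluid volume and
norepinephrine-equivalent dose, and a terminal hospital-mortality model with a
known treatment-free + blip structure. Class centers, dispersions and baseline
mortality are calibrated to the published day-0 class comparison table of a
1437-patient multicenter septic-shock cohort.

Every random draw flows from a single integer seed through named sub-streams,
so e.g. adding a feature does not perturb the dose draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import COHORT_COLUMNS, DEFAULT_FEATURES, OBSERVED_DAYS

__all__ = [
    "ClassProfiles",
    "BehaviorPolicy",
    "OutcomeModel",
    "GeneratorConfig",
    "default_profiles",
    "generate_cohort",
    "inject_missingness",
    "TABLE1_CLASS_N",
    "TABLE1_DEATHS",
    "TABLE1_TOTAL_N",
]

# ---------------------------------------------------------------------------
# Published day-0 calibration targets (class columns 1..5).
# Per feature: per-class (median, q1, q3); heart rate is reported mean +/- SD.
# ---------------------------------------------------------------------------

TABLE1_QUANTILES: dict[str, list[tuple[float, float, float]]] = {
    "age": [(72.5, 62.0, 82.0), (65.0, 55.0, 75.5), (67.0, 55.5, 77.0),
            (77.0, 61.0, 84.0), (42.0, 30.0, 51.0)],
    "weight": [(64.0, 54.0, 69.0), (64.0, 58.0, 70.0), (64.0, 60.0, 71.0),
               (62.0, 53.0, 65.0), (65.0, 60.0, 70.0)],
    "apacheii": [(21.0, 14.0, 26.0), (25.0, 19.0, 30.0), (22.0, 17.0, 28.0),
                 (23.0, 17.0, 26.0), (20.0, 14.0, 24.75)],
    "sbp_min": [(91.0, 77.0, 102.0), (83.0, 70.0, 98.0), (86.0, 71.0, 98.0),
                (88.0, 74.0, 98.0), (89.0, 78.0, 98.2)],
    "temp": [(37.3, 36.8, 37.8), (37.4, 36.7, 38.5), (37.6, 37.0, 38.5),
             (37.5, 37.0, 38.2), (38.5, 37.6, 39.2)],
    "ph_min": [(7.40, 7.37, 7.45), (7.24, 7.14, 7.31), (7.32, 7.26, 7.37),
               (7.38, 7.30, 7.47), (7.41, 7.37, 7.45)],
    "hco3_min": [(23.2, 21.9, 25.7), (15.3, 11.4, 18.45), (18.0, 15.6, 20.5),
                 (34.3, 32.6, 37.5), (23.1, 21.63, 25.2)],
    "lactate_max": [(1.9, 1.4, 2.5), (11.10, 9.05, 14.25), (3.4, 2.1, 5.0),
                    (1.9, 1.4, 2.9), (2.0, 1.63, 2.98)],
    "be_min": [(-0.7, -2.4, 1.6), (-11.0, -14.9, -6.75), (-6.9, -9.5, -4.44),
               (8.9, 5.0, 12.6), (-0.8, -2.68, 1.0)],
    "pf_min": [(210.0, 160.0, 280.0), (174.0, 99.5, 219.91), (187.5, 130.0, 250.0),
               (169.0, 117.83, 232.0), (210.0, 153.32, 297.79)],
    "paco2_max": [(40.0, 35.0, 44.05), (41.0, 31.5, 47.6), (36.2, 30.25, 44.0),
                  (60.0, 50.0, 77.0), (38.0, 33.0, 42.8)],
    "hct": [(27.9, 26.0, 32.9), (30.0, 26.3, 36.65), (31.4, 26.3, 37.25),
            (32.0, 26.3, 38.9), (29.0, 26.3, 36.5)],
    "platelet": [(148.0, 89.75, 214.25), (107.0, 47.0, 182.0), (131.0, 75.0, 200.0),
                 (188.0, 122.0, 267.0), (146.5, 90.5, 236.75)],
    "rdwcv": [(14.0, 13.0, 16.0), (14.0, 13.0, 15.4), (14.0, 13.0, 15.0),
              (14.0, 13.0, 15.0), (14.0, 13.0, 15.0)],
    "creatinine": [(92.05, 61.86, 134.85), (175.80, 105.65, 265.48),
                   (138.0, 87.74, 236.15), (76.0, 51.8, 121.0),
                   (79.55, 56.08, 115.84)],
    "urine_ml": [(1150.0, 646.25, 1801.25), (470.0, 206.0, 1420.0),
                 (795.0, 320.0, 1422.5), (950.0, 515.0, 1740.0),
                 (1835.0, 1092.5, 2990.0)],
}
TABLE1_HR_MEAN_SD: list[tuple[float, float]] = [
    (108.70, 21.08), (133.97, 19.78), (126.72, 22.63), (119.22, 22.20), (128.18, 21.39),
]
#: Day-0 class sizes, per-class death counts and total cohort size.
TABLE1_CLASS_N = (380, 115, 723, 81, 138)
TABLE1_DEATHS = (120, 47, 193, 34, 29)
TABLE1_TOTAL_N = 1437
#: Printed per-class mortality percentages.
TABLE1_MORTALITY = (0.32, 0.41, 0.27, 0.42, 0.21)

#: Day-0 median fluid intake by class (mL) — behavior-policy anchors.
TABLE1_INTAKE = (2480.0, 3667.0, 2962.0, 2571.0, 3448.5)

_IQR_TO_SD = 1.349  # normal-distribution IQR-to-SD factor


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named random sub-stream derived from the master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassProfiles:
    """Per-class feature centers and the shared per-feature dispersion.

    ``centers`` is (K, 17) in the order of the default feature list;
    ``dispersions`` is the length-17 standard-deviation vector shared across
    classes (the equal-variance, zero-covariance mixture the fitting procedure
    assumes). ``class_dispersion_scale``, when not all ones, multiplies the
    shared dispersion per class for robustness experiments.
    """

    centers: np.ndarray
    dispersions: np.ndarray
    feature_names: tuple[str, ...] = tuple(f.name for f in DEFAULT_FEATURES)
    class_dispersion_scale: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.centers, float)
        d = np.asarray(self.dispersions, float)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "dispersions", d)
        if c.ndim != 2 or c.shape[1] != len(self.feature_names):
            raise ValueError("centers must be (K, n_features)")
        if d.shape != (c.shape[1],):
            raise ValueError("dispersions must be length n_features")
        if not np.all(d > 0):
            raise ValueError("dispersion vector must be strictly positive")
        if self.class_dispersion_scale is not None:
            s = np.asarray(self.class_dispersion_scale, float)
            if s.shape != (c.shape[0],) or not np.all(s > 0):
                raise ValueError("class_dispersion_scale must be length K and positive")
            object.__setattr__(self, "class_dispersion_scale", s)

    @property
    def n_classes(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class BehaviorPolicy:
    """State-dependent dosing policy used by the simulated clinicians.

    Mean dose for a patient-day in class ``c`` on observed-day index ``j`` is
    ``base[c] * day_factor[j] + lactate_coef * (lactate - ref_lactate)``,
    truncated at zero after adding Gaussian noise with spread ``sd``.
    """

    fluid_base: np.ndarray
    fluid_day_factor: np.ndarray
    fluid_lactate_coef: float
    fluid_sd: float
    ne_base: np.ndarray
    ne_day_factor: np.ndarray
    ne_lactate_coef: float
    ne_sd: float
    ref_lactate: float = 2.7  # cohort median

    def mean_dose(self, treatment: str, class_idx, day_idx, lactate):
        if treatment == "fluid":
            base, fac, coef = self.fluid_base, self.fluid_day_factor, self.fluid_lactate_coef
        elif treatment == "ne":
            base, fac, coef = self.ne_base, self.ne_day_factor, self.ne_lactate_coef
        else:
            raise ValueError(f"unknown treatment {treatment!r}")
        return (np.asarray(base)[class_idx] * np.asarray(fac)[day_idx]
                + coef * (np.asarray(lactate) - self.ref_lactate))


@dataclass(frozen=True)
class OutcomeModel:
    """Known treatment-free + blip structure of the terminal mortality model.

    The per-stage blip in dose ``a`` is
    ``gamma_j(x, a) = a * (psi0_j + x_psi' psix_j) + psi2 * a**2`` with
    ``x_psi`` the one-hot class indicators (class 1 reference). The
    parameterization is stored through the class-by-day optimal-dose tables
    ``optimal_fluid``/``optimal_ne`` (vertices of the convex blip), from which
    ``blip_params`` reconstructs (psi0, psix, psi2) per stage.
    """

    psi2_fluid: float
    psi2_ne: float
    optimal_fluid: np.ndarray  # (K, n_days) mL
    optimal_ne: np.ndarray     # (K, n_days) mcg/kg/min

    def __post_init__(self):
        object.__setattr__(self, "optimal_fluid", np.asarray(self.optimal_fluid, float))
        object.__setattr__(self, "optimal_ne", np.asarray(self.optimal_ne, float))

    def blip_params(self, treatment: str, day_idx: int):
        """Return (psi0, psix, psi2) for one stage; psix has length K-1."""
        if treatment == "fluid":
            opt, psi2 = self.optimal_fluid, self.psi2_fluid
        else:
            opt, psi2 = self.optimal_ne, self.psi2_ne
        a_star = opt[:, day_idx]
        psi0 = -2.0 * psi2 * a_star[0]
        psix = -2.0 * psi2 * (a_star[1:] - a_star[0])
        return psi0, psix, psi2

    def regret(self, treatment: str, class_idx, day_idx, dose):
        """gamma(a) - gamma(a*) = psi2 * (a - a*)^2 (convex blip)."""
        opt = self.optimal_fluid if treatment == "fluid" else self.optimal_ne
        psi2 = self.psi2_fluid if treatment == "fluid" else self.psi2_ne
        a_star = opt[np.asarray(class_idx), np.asarray(day_idx)]
        return psi2 * (np.asarray(dose) - a_star) ** 2


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int
    class_prevalence: np.ndarray
    class_profiles: ClassProfiles
    transition_matrix: np.ndarray
    behavior_policy: BehaviorPolicy
    outcome_model: OutcomeModel
    mortality_link: np.ndarray   # per-class baseline hospital-mortality probability
    dropout: float               # per-transition probability of leaving the cohort
    seed: int = 0
    outcome_scale: str = "logistic"   # "logistic" (default) or "linear"
    center_mortality: bool = True     # subtract expected behavior-policy regret

    def __post_init__(self):
        prev = np.asarray(self.class_prevalence, float)
        tm = np.asarray(self.transition_matrix, float)
        mort = np.asarray(self.mortality_link, float)
        object.__setattr__(self, "class_prevalence", prev)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "mortality_link", mort)
        K = self.class_profiles.n_classes
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if prev.shape != (K,) or abs(prev.sum() - 1.0) > 1e-12 or np.any(prev < 0):
            raise ValueError("class_prevalence must be a length-K probability vector summing to 1")
        if tm.shape != (K, K) or np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix must be K x K row-stochastic")
        if mort.shape != (K,) or np.any((mort < 0) | (mort > 1)):
            raise ValueError("mortality probabilities must lie in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")
        if self.outcome_scale not in ("logistic", "linear"):
            raise ValueError("outcome_scale must be 'logistic' or 'linear'")


# ---------------------------------------------------------------------------
# Default (calibrated) configuration
# ---------------------------------------------------------------------------


def default_profiles(n_patients: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Five-class configuration calibrated to the published day-0 class table.

    Class centers are the printed per-class medians (heart rate: means); the
    shared per-feature dispersion is the across-class mean of IQR/1.349
    (heart rate: mean of the printed SDs). Baseline mortality probabilities
    are the printed per-class percentages. Day-0 prevalence follows the
    printed class sizes. Transitions default to a sticky matrix (0.6 stay,
    remainder biased toward class 1).
    """
    names = [f.name for f in DEFAULT_FEATURES]
    centers = np.empty((5, 17))
    dispersions = np.empty(17)
    for d, name in enumerate(names):
        if name == "hr_max":
            centers[:, d] = [m for m, _ in TABLE1_HR_MEAN_SD]
            dispersions[d] = float(np.mean([s for _, s in TABLE1_HR_MEAN_SD]))
        else:
            rows = TABLE1_QUANTILES[name]
            centers[:, d] = [m for m, _, _ in rows]
            dispersions[d] = float(np.mean([(q3 - q1) / _IQR_TO_SD for _, q1, q3 in rows]))
    profiles = ClassProfiles(centers=centers, dispersions=dispersions)

    prevalence = np.array(TABLE1_CLASS_N, float) / TABLE1_TOTAL_N

    # Sticky transitions, off-diagonal mass biased toward class 1 (survivors
    # drift to the baseline class); not estimated from data — configurable.
    K = 5
    tm = np.zeros((K, K))
    for i in range(K):
        others = [j for j in range(K) if j != i]
        w = np.array([2.0 if j == 0 else 1.0 for j in others])
        tm[i, others] = 0.4 * w / w.sum()
        tm[i, i] = 0.6

    policy = BehaviorPolicy(
        fluid_base=np.array(TABLE1_INTAKE),
        fluid_day_factor=np.array([1.0, 0.90, 0.80, 0.70, 0.45]),
        fluid_lactate_coef=100.0,
        fluid_sd=900.0,
        ne_base=np.array([0.30, 0.90, 0.50, 0.25, 0.20]),
        ne_day_factor=np.array([1.0, 0.90, 0.75, 0.60, 0.35]),
        ne_lactate_coef=0.02,
        ne_sd=0.15,
    )

    # Optimal-dose tables: resuscitation then de-resuscitation; class 2 needs
    # prolonged large volume with delayed norepinephrine, class 3 de-escalates
    # fluid from day 1 and benefits from early norepinephrine.
    optimal_fluid = np.array([
        [3000.0, 2600.0, 2200.0, 1500.0, 800.0],
        [4800.0, 4400.0, 3800.0, 3000.0, 1800.0],
        [3200.0, 2200.0, 1800.0, 1400.0, 900.0],
        [2400.0, 2100.0, 1800.0, 1400.0, 800.0],
        [3400.0, 2900.0, 2300.0, 1700.0, 1000.0],
    ])
    optimal_ne = np.array([
        [0.40, 0.30, 0.22, 0.15, 0.08],
        [0.60, 0.85, 0.60, 0.40, 0.20],
        [0.60, 0.45, 0.30, 0.20, 0.10],
        [0.30, 0.25, 0.20, 0.15, 0.08],
        [0.28, 0.22, 0.16, 0.10, 0.05],
    ])
    outcome = OutcomeModel(
        psi2_fluid=0.12e-6,  # logit units per mL^2: +0.12 per 1 L deviation-squared
        psi2_ne=1.5,         # logit units per (mcg/kg/min)^2
        optimal_fluid=optimal_fluid,
        optimal_ne=optimal_ne,
    )

    return GeneratorConfig(
        n_patients=n_patients,
        class_prevalence=prevalence,
        class_profiles=profiles,
        transition_matrix=tm,
        behavior_policy=policy,
        outcome_model=outcome,
        mortality_link=np.array(TABLE1_MORTALITY),
        dropout=0.12,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _expected_regret_offset(config: GeneratorConfig) -> np.ndarray:
    """Analytic E[regret] per (class, day) under the behavior policy.

    Used to center the mortality linear predictor so that class-wise marginal
    mortality stays near the configured baseline probabilities.
    """
    prof, pol, om = config.class_profiles, config.behavior_policy, config.outcome_model
    K, n_days = prof.n_classes, len(OBSERVED_DAYS)
    lac_idx = prof.feature_names.index("lactate_max")
    lac_sd = prof.dispersions[lac_idx]
    off = np.zeros((K, n_days))
    for c in range(K):
        lac_c = prof.centers[c, lac_idx]
        for j in range(n_days):
            mu_f = pol.mean_dose("fluid", c, j, lac_c)
            var_f = pol.fluid_sd**2 + (pol.fluid_lactate_coef * lac_sd) ** 2
            mu_n = pol.mean_dose("ne", c, j, lac_c)
            var_n = pol.ne_sd**2 + (pol.ne_lactate_coef * lac_sd) ** 2
            off[c, j] = (om.psi2_fluid * ((mu_f - om.optimal_fluid[c, j]) ** 2 + var_f)
                         + om.psi2_ne * ((mu_n - om.optimal_ne[c, j]) ** 2 + var_n))
    return off


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the long-format cohort table and its latent ground truth.

    Returns ``(cohort, truth)``. The cohort has one row per patient-day for
    days 0/1/2/3/7 until ICU discharge (dropout) or death; the truth table
    carries the latent class per patient-day, the optimal dose sequence under
    the configured blip parameters, and the counterfactual mortality
    probability a patient would have had under optimal dosing.
    """
    prof, pol, om = config.class_profiles, config.behavior_policy, config.outcome_model
    K, n_days = prof.n_classes, len(OBSERVED_DAYS)
    n = config.n_patients
    seed = config.seed

    rng_class = _stream(seed, "classes")
    rng_drop = _stream(seed, "dropout")
    rng_feat = _stream(seed, "features")
    rng_dose = _stream(seed, "doses")
    rng_out = _stream(seed, "outcome")
    rng_dday = _stream(seed, "deathday")
    rng_fout = _stream(seed, "fluid_out")

    # Latent class paths (n, n_days): day 0 from prevalence, then one Markov
    # step per observed-day gap (day 7 is one step after day 3).
    classes = np.empty((n, n_days), dtype=int)
    classes[:, 0] = rng_class.choice(K, size=n, p=config.class_prevalence)
    cum_tm = np.cumsum(config.transition_matrix, axis=1)
    for j in range(1, n_days):
        u = rng_class.random(n)
        classes[:, j] = (u[:, None] > cum_tm[classes[:, j - 1]]).sum(axis=1)

    # ICU discharge: survive each between-day transition with prob 1-dropout.
    stay = rng_drop.random((n, n_days - 1)) >= config.dropout
    n_obs = 1 + np.cumprod(stay, axis=1).sum(axis=1)  # observed days in 1..5

    # Features per patient-day from the current class.
    scale = (np.ones(K) if prof.class_dispersion_scale is None
             else prof.class_dispersion_scale)
    feats = (prof.centers[classes]
             + rng_feat.standard_normal((n, n_days, 17))
             * prof.dispersions[None, None, :] * scale[classes][:, :, None])

    lac_idx = prof.feature_names.index("lactate_max")
    day_idx = np.broadcast_to(np.arange(n_days), (n, n_days))
    fluid = np.maximum(
        pol.mean_dose("fluid", classes, day_idx, feats[:, :, lac_idx])
        + rng_dose.standard_normal((n, n_days)) * pol.fluid_sd, 0.0)
    ne = np.maximum(
        pol.mean_dose("ne", classes, day_idx, feats[:, :, lac_idx])
        + rng_dose.standard_normal((n, n_days)) * pol.ne_sd, 0.0)

    # Terminal mortality: baseline class logit plus accumulated blip regrets
    # over the days the patient was observed, minus the analytic offset.
    obs_mask = np.arange(n_days)[None, :] < n_obs[:, None]
    regret = (om.regret("fluid", classes, day_idx, fluid)
              + om.regret("ne", classes, day_idx, ne))
    offset = _expected_regret_offset(config)[classes, day_idx] if config.center_mortality else 0.0
    excess = ((regret - offset) * obs_mask).sum(axis=1)

    p_base = config.mortality_link[classes[:, 0]]
    if config.outcome_scale == "logistic":
        with np.errstate(divide="ignore"):
            logit = np.log(p_base) - np.log1p(-p_base)
        p_death = np.where(p_base <= 0.0, 0.0,
                           np.where(p_base >= 1.0, 1.0, 1.0 / (1.0 + np.exp(-(logit + excess)))))
    else:
        p_death = np.clip(p_base + excess, 0.0, 1.0)
    death = rng_out.random(n) < p_death

    # Hospital death day (independent of covariates given death).
    death_day = np.where(death, 1 + rng_dday.poisson(7.0, size=n), -1)

    fluid_out = np.maximum(
        feats[:, :, prof.feature_names.index("urine_ml")] * 1.15
        + rng_fout.standard_normal((n, n_days)) * 200.0, 0.0)

    # Assemble long format, truncating at discharge and at death.
    days = np.array(OBSERVED_DAYS)
    keep = obs_mask & ~(death[:, None] & (days[None, :] >= death_day[:, None]))
    keep[:, 0] = True  # day 0 always observed
    pid, jj = np.nonzero(keep)

    cohort = pd.DataFrame({"patient_id": pid, "day": days[jj]})
    for d, name in enumerate(prof.feature_names):
        cohort[name] = feats[pid, jj, d]
    cohort["fluid_in_ml"] = fluid[pid, jj]
    cohort["fluid_out_ml"] = fluid_out[pid, jj]
    cohort["ne_eq_mcgkgmin"] = ne[pid, jj]
    cohort["death_hosp"] = death[pid].astype(int)
    cohort["death_day"] = np.where(death[pid], death_day[pid], np.nan)
    cohort = cohort[COHORT_COLUMNS]

    truth = pd.DataFrame({
        "patient_id": pid,
        "day": days[jj],
        "true_class": classes[pid, jj] + 1,
        "optimal_fluid_ml": om.optimal_fluid[classes[pid, jj], jj],
        "optimal_ne_mcgkgmin": om.optimal_ne[classes[pid, jj], jj],
        "p_death_optimal": config.mortality_link[classes[pid, 0]],
        "p_death_realized": p_death[pid],
    })
    return cohort, truth


def inject_missingness(cohort: pd.DataFrame, cell_missing_rate: float,
                       seed: int = 0) -> pd.DataFrame:
    """Set each feature cell to missing independently with the given rate.

    Identifier, dose and outcome columns are never masked.
    """
    if not 0.0 <= cell_missing_rate <= 1.0:
        raise ValueError("cell_missing_rate must be in [0, 1]")
    out = cohort.copy()
    maskable = [f.name for f in DEFAULT_FEATURES if f.name in out.columns]
    rng = _stream(seed, "missingness")
    mask = rng.random((len(out), len(maskable))) < cell_missing_rate
    for k, name in enumerate(maskable):
        col = out[name].to_numpy(dtype=float, copy=True)
        col[mask[:, k]] = np.nan
        out[name] = col
    return out
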