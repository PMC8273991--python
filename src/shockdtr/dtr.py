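"""Dynamic treatment regime estimation by dynamic weighted OLS (dWOLS).

Estimates the individualized optimal daily dose of a continuous treatment
(fluid volume in mL/day, or norepinephrine-equivalent dose in mcg/kg/min)
over ICU stages 0, 1, 2, 3 and 7 by backward induction. At each stage the
expected terminal outcome is modeled as a treatment-free part plus a blip:

    E(Y | x, a) = f(x_beta; beta) + a * (psi0 + x_psi' psi_x) + psi2 * a**2

with Y the hospital-death indicator on the linear-probability scale
(predicted values are not clamped during estimation, as regression-based
dWOLS requires). The blip is quadratic in dose: a strictly linear blip in a
continuous treatment has no interior optimum, so the quadratic curvature term
is the minimal form under which an "optimal volume" is finite.

Weights come from a least-squares treatment model for the dose. The default
is the stabilized inverse-density ratio q(a) / pi(a|x) (marginal over
conditional normal density, truncated at its 99.9th percentile), which makes
the weighted dose distribution covariate-free and is what delivers double
robustness for a blip that is *quadratic* in the dose; the balancing weight
|a - E(a|x)| familiar from binary-treatment dWOLS is available by flag but
only protects a dose-linear blip against treatment-free misspecification.

Stages are estimated in reverse order; the stage-j pseudo-outcome removes the
estimated regret of every later stage:

    Ytilde_j = Y - sum_{k>j} [gamma_k(x_k, a_k) - gamma_k(x_k, a*_k)].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["StageFit", "DtrFit", "fit_stage_models", "optimal_dose", "fit_dtr",
           "recommend_doses", "bootstrap_dtr", "attach_class_labels"]

WEIGHT_SCHEMES = ("inverse_density", "abs_residual")


def attach_class_labels(cohort: pd.DataFrame, labels: pd.DataFrame,
                        n_classes: int = 5) -> pd.DataFrame:
    """Merge 1-based class labels and add one-hot columns class_2..class_K.

    Class 1 is the reference and gets no column.
    """
    out = cohort.merge(labels[["patient_id", "day", "label"]],
                       on=["patient_id", "day"], how="left", validate="1:1")
    if out["label"].isna().any():
        raise ValueError("class labels missing for some patient-days")
    for k in range(2, n_classes + 1):
        out[f"class_{k}"] = (out["label"] == k).astype(float)
    return out


@dataclass
class StageFit:
    stage: int
    psi0: float
    psix: np.ndarray
    psi2: float
    beta: np.ndarray                # intercept + x_beta coefficients
    xbeta_cols: list[str]
    xpsi_cols: list[str]
    treatment_coef: np.ndarray      # intercept + state coefficients
    treatment_resid_sd: float
    bounds: tuple[float, float]
    weight_scheme: str
    n: int
    psi_se: np.ndarray = None       # model-based SEs for (psi0, psix..., psi2)
    non_informative: bool = False

    @property
    def convex(self) -> bool:
        return self.psi2 > 0

    def blip(self, Xpsi: np.ndarray, a: np.ndarray) -> np.ndarray:
        lin = self.psi0 + (Xpsi @ self.psix if len(self.xpsi_cols) else 0.0)
        return a * lin + self.psi2 * a * a


@dataclass
class DtrFit:
    treatment: str
    outcome: str
    stages: list[int]
    stage_fits: dict[int, StageFit]
    xbeta_cols: list[str]
    xpsi_cols: list[str]
    weight_scheme: str
    skipped_stages: list[int] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        doc = {"treatment": self.treatment, "outcome": self.outcome,
               "stages": self.stages, "weight_scheme": self.weight_scheme,
               "xbeta_cols": self.xbeta_cols, "xpsi_cols": self.xpsi_cols,
               "skipped_stages": self.skipped_stages,
               "stage_fits": {str(k): {**{f: (v.tolist() if isinstance(v, np.ndarray) else v)
                                          for f, v in asdict(sf).items()}}
                              for k, sf in self.stage_fits.items()}}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _solve_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, col_names: list[str]):
    """Weighted least squares with collinearity diagnosis and model-based SEs."""
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # walk columns to name the dependent ones
        bad, cols = [], []
        for j in range(X.shape[1]):
            trial = Xw[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols) + 1:
                cols.append(j)
            else:
                bad.append(col_names[j])
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")
    coef, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return coef, se


def fit_stage_models(stage_df: pd.DataFrame, dose_col: str, pseudo_y: np.ndarray,
                     xbeta_cols: list[str], xpsi_cols: list[str],
                     weight_scheme: str = "inverse_density",
                     bounds: tuple[float, float] | None = None,
                     stage: int = 0) -> tuple[StageFit, np.ndarray]:
    """Fit the treatment model, balancing weights and the stage dWOLS regression.

    Returns ``(StageFit, weights)``. The treatment model is a least-squares
    regression of dose on the union of the stage covariates; weights default
    to the stabilized inverse-density ratio q(a)/pi(a|x), with the
    absolute-residual balancing weight |a - E(a|x)| available by flag. The
    outcome design is [1, x_beta, a, a*x_psi, a**2] fit by weighted least
    squares on the stage pseudo-outcome. The dose is scaled by its standard
    deviation internally for conditioning; reported coefficients are on the
    original dose scale.
    """
    if weight_scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"weight_scheme must be one of {WEIGHT_SCHEMES}")
    n = len(stage_df)
    state_cols = list(dict.fromkeys(xbeta_cols + xpsi_cols))
    n_coef = 2 + len(xbeta_cols) + len(xpsi_cols) + 1
    if n < 10 * n_coef:
        raise ValueError(f"stage {stage}: {n} at-risk rows < 10 x {n_coef} coefficients")
    a = stage_df[dose_col].to_numpy(float)
    if np.any(a < 0):
        raise ValueError("doses must be nonnegative")

    Xs = np.column_stack([np.ones(n)] + [stage_df[c].to_numpy(float) for c in state_cols])
    t_coef, _ = _solve_wls(Xs, a, np.ones(n), ["intercept"] + state_cols)
    a_hat = Xs @ t_coef
    resid = a - a_hat
    resid_sd = float(resid.std(ddof=max(1, len(state_cols) + 1))) or 1.0
    if weight_scheme == "abs_residual":
        w = np.abs(resid)
        w = np.maximum(w, 1e-3 * resid_sd)  # keep exactly-predicted rows in the fit
    else:  # stabilized inverse conditional density
        q = norm.pdf(a, a.mean(), a.std() or 1.0)
        dens = np.maximum(norm.pdf(resid / resid_sd) / resid_sd, 1e-300)
        w = q / dens
        w = np.minimum(w, np.quantile(w, 0.999))

    if bounds is None:
        bounds = (float(np.quantile(a, 0.01)), float(np.quantile(a, 0.99)))

    s = a.std() or 1.0
    at = a / s
    Xb = [stage_df[c].to_numpy(float) for c in xbeta_cols]
    Xp = np.column_stack([stage_df[c].to_numpy(float) for c in xpsi_cols]) \
        if xpsi_cols else np.empty((n, 0))
    design = np.column_stack([np.ones(n)] + Xb + [at] + [at * Xp[:, j] for j in range(Xp.shape[1])]
                             + [at * at])
    names = (["intercept"] + xbeta_cols + [dose_col]
             + [f"{dose_col}:{c}" for c in xpsi_cols] + [f"{dose_col}^2"])
    coef, se = _solve_wls(design, np.asarray(pseudo_y, float), w, names)

    nb = 1 + len(xbeta_cols)
    beta = coef[:nb]
    psi0 = coef[nb] / s
    psix = coef[nb + 1: nb + 1 + len(xpsi_cols)] / s
    psi2 = coef[-1] / s**2
    psi_se = np.concatenate([[se[nb] / s], se[nb + 1: nb + 1 + len(xpsi_cols)] / s,
                             [se[-1] / s**2]])
    psi_t = np.concatenate([[coef[nb]], coef[nb + 1: nb + 1 + len(xpsi_cols)], [coef[-1]]]) \
        / np.concatenate([[se[nb]], se[nb + 1: nb + 1 + len(xpsi_cols)], [se[-1]]])
    fit = StageFit(stage=stage, psi0=float(psi0), psix=np.asarray(psix, float),
                   psi2=float(psi2), beta=beta, xbeta_cols=list(xbeta_cols),
                   xpsi_cols=list(xpsi_cols), treatment_coef=t_coef,
                   treatment_resid_sd=resid_sd, bounds=bounds,
                   weight_scheme=weight_scheme, n=n, psi_se=psi_se,
                   non_informative=bool(np.all(np.abs(psi_t) < 3.0)))
    return fit, w


def optimal_dose(fit: StageFit, Xpsi) -> np.ndarray:
    """Dose minimizing the estimated blip within the stage bounds.

    With convex curvature (psi2 > 0) the vertex -(psi0 + x'psix)/(2 psi2) is
    clipped to the bounds; with psi2 <= 0 the blip is evaluated at both bound
    endpoints and the endpoint with the smaller predicted outcome contribution
    is returned (the fit carries a non-convexity flag).
    """
    Xpsi = np.atleast_2d(np.asarray(Xpsi, float))
    lo, hi = fit.bounds
    lin = fit.psi0 + (Xpsi @ fit.psix if len(fit.xpsi_cols) else np.zeros(len(Xpsi)))
    if fit.psi2 > 0:
        return np.clip(-lin / (2.0 * fit.psi2), lo, hi)
    g_lo = lo * lin + fit.psi2 * lo * lo
    g_hi = hi * lin + fit.psi2 * hi * hi
    return np.where(g_lo <= g_hi, lo, hi)


def fit_dtr(cohort: pd.DataFrame, dose_col: str, xbeta_cols: list[str],
            xpsi_cols: list[str], outcome_col: str = "death_hosp",
            stages=(0, 1, 2, 3, 7), weight_scheme: str = "inverse_density",
            ) -> DtrFit:
    """Backward-induction dWOLS over the observed ICU stages.

    The cohort is long format with class one-hot columns already attached
    (see :func:`attach_class_labels`); the terminal outcome is constant within
    patient. Patients absent from a stage (died or discharged) simply do not
    contribute to it, and their pseudo-outcomes accumulate regrets only over
    stages they experienced. A stage with no at-risk patients is skipped and
    recorded. Fluid and norepinephrine are estimated as two separate fits.
    """
    stages = sorted(stages)
    y_by_patient = cohort.groupby("patient_id")[outcome_col].first().astype(float)
    if (cohort.groupby("patient_id")[outcome_col].nunique() > 1).any():
        raise ValueError("terminal outcome must be constant within patient")
    pseudo = y_by_patient.copy()

    stage_fits: dict[int, StageFit] = {}
    skipped = []
    for day in reversed(stages):
        sub = cohort[cohort["day"] == day]
        if len(sub) == 0:
            skipped.append(day)
            continue
        sf, _ = fit_stage_models(sub, dose_col, pseudo.loc[sub["patient_id"]].to_numpy(),
                                 xbeta_cols, xpsi_cols, weight_scheme, stage=day)
        stage_fits[day] = sf
        # remove this stage's estimated regret from earlier-stage pseudo-outcomes
        Xp = sub[xpsi_cols].to_numpy(float) if xpsi_cols else np.empty((len(sub), 0))
        a = sub[dose_col].to_numpy(float)
        a_opt = optimal_dose(sf, Xp)
        regret = sf.blip(Xp, a) - sf.blip(Xp, a_opt)
        pseudo.loc[sub["patient_id"]] = (pseudo.loc[sub["patient_id"]].to_numpy()
                                         - regret)
    return DtrFit(treatment=dose_col, outcome=outcome_col, stages=list(stages),
                  stage_fits=stage_fits, xbeta_cols=list(xbeta_cols),
                  xpsi_cols=list(xpsi_cols), weight_scheme=weight_scheme,
                  skipped_stages=skipped)


def recommend_doses(dtr: DtrFit, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per patient-day actual vs optimal dose under a fitted regime.

    Returns one row per at-risk patient-day with columns ``patient_id, day,
    actual, optimal, delta`` (delta = actual - optimal) plus the stage's
    convexity and informativeness flags. Optimal doses respect the stored
    stage bounds.
    """
    rows = []
    for day, sf in sorted(dtr.stage_fits.items()):
        sub = cohort[cohort["day"] == day]
        if len(sub) == 0:
            continue
        missing = [c for c in dtr.xpsi_cols if c not in sub.columns]
        if missing:
            raise KeyError(f"cohort lacks blip covariates {missing}")
        Xp = sub[dtr.xpsi_cols].to_numpy(float) if dtr.xpsi_cols else np.empty((len(sub), 0))
        a = sub[dtr.treatment].to_numpy(float)
        opt = optimal_dose(sf, Xp)
        rows.append(pd.DataFrame({
            "patient_id": sub["patient_id"].to_numpy(),
            "day": day, "actual": a, "optimal": opt, "delta": a - opt,
            "convex": sf.convex, "non_informative": sf.non_informative,
        }))
    return pd.concat(rows, ignore_index=True)


def bootstrap_dtr(cohort: pd.DataFrame, dose_col: str, xbeta_cols, xpsi_cols,
                  outcome_col: str = "death_hosp", stages=(0, 1, 2, 3, 7),
                  weight_scheme: str = "inverse_density", n_boot: int = 200,
                  seed: int = 0) -> dict[int, pd.DataFrame]:
    """Nonparametric bootstrap (resampling patients) of the blip parameters.

    Returns, per stage, a DataFrame of bootstrap draws of
    (psi0, psix..., psi2) from which standard errors and percentile intervals
    can be read.
    """
    rng = np.random.default_rng(seed)
    cohort = cohort.reset_index(drop=True)
    groups = cohort.groupby("patient_id").indices
    patients = np.array(list(groups))
    row_idx = [groups[p] for p in patients]
    draws: dict[int, list] = {d: [] for d in stages}
    for _ in range(n_boot):
        pick = rng.integers(0, len(patients), size=len(patients))
        rows = np.concatenate([row_idx[i] for i in pick])
        boot = cohort.iloc[rows].copy()
        boot["patient_id"] = np.repeat(np.arange(len(pick)),
                                       [len(row_idx[i]) for i in pick])
        try:
            fit = fit_dtr(boot, dose_col, xbeta_cols, xpsi_cols, outcome_col,
                          stages, weight_scheme)
        except (ValueError, np.linalg.LinAlgError):
            continue
        for d, sf in fit.stage_fits.items():
            draws[d].append(np.concatenate([[sf.psi0], sf.psix, [sf.psi2]]))
    cols = ["psi0"] + [f"psix_{c}" for c in xpsi_cols] + ["psi2"]
    return {d: pd.DataFrame(v, columns=cols) for d, v in draws.items() if v}
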