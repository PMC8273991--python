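"""Time-varying-covariate proportional-hazards analysis of ICU days 0-7.

Patient-days are expanded into counting-process intervals (0,1], (1,2],
(2,3], (3,7] with covariates taken from the interval's starting day; death
closes the interval containing the death day, censoring closes the last
observed interval, and deaths after day 7 are censored at day 7 (covariates
are unobserved beyond). Two models are fit — one per treatment (daily fluid
intake in liters; norepinephrine-equivalent dose) — each with class-by-
treatment interaction terms against the class-1 reference. Ties are handled
with the Efron approximation (many deaths fall on integer days).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter

__all__ = ["to_counting_process", "fit_tv_cox", "add_interactions"]

HALF_DAY = 0.5  # degenerate single-day interval convention
MAX_FOLLOWUP_DAY = 7


def to_counting_process(cohort: pd.DataFrame, covariate_cols: list[str],
                        ) -> pd.DataFrame:
    """Expand a labeled long cohort into counting-process rows.

    ``cohort`` carries ``patient_id, day, death_hosp, death_day`` and the
    requested covariate columns. For each patient with observed days
    d_0 < ... < d_m, intervals (d_i, d_{i+1}] carry the covariates of day
    d_i. A death on day t in (d_i, d_{i+1}] (or after d_m but by day 7, via
    an appended interval) marks that interval as the event; deaths after day
    7 and discharges are censored at the last observed interval. A patient
    observed on day 0 only, dying on day 0, contributes the half-day interval
    (0, 0.5] with the event.
    """
    need = {"patient_id", "day", "death_hosp"}
    if not need <= set(cohort.columns):
        raise KeyError(f"cohort must carry columns {sorted(need)}")
    has_dday = "death_day" in cohort.columns
    rows = []
    for pid, g in cohort.sort_values(["patient_id", "day"]).groupby("patient_id"):
        days = g["day"].to_numpy()
        death = bool(g["death_hosp"].iloc[0])
        dday = float(g["death_day"].iloc[0]) if has_dday and death \
            and np.isfinite(g["death_day"].iloc[0]) else np.nan
        if death and np.isfinite(dday) and dday < days[0]:
            raise ValueError(f"patient {pid}: death day {dday} before first observed day {days[0]}")
        covs = g[covariate_cols].to_numpy()

        intervals = [(days[i], days[i + 1], covs[i]) for i in range(len(days) - 1)]
        event_idx = None
        if death and np.isfinite(dday) and dday <= MAX_FOLLOWUP_DAY:
            if dday == days[0]:
                # death on the single/first observed day: half-day interval
                intervals = [(days[0], days[0] + HALF_DAY, covs[0])]
            elif dday > days[-1]:
                intervals.append((days[-1], dday, covs[-1]))
            else:  # truncate at the interval containing the death day
                intervals = [(s, e, c) for s, e, c in intervals if s < dday]
                s, e, c = intervals[-1]
                intervals[-1] = (s, min(e, dday), c)
            event_idx = len(intervals) - 1
        for i, (s, e, c) in enumerate(intervals):
            rows.append({"patient_id": pid, "start": float(s), "stop": float(e),
                         "event": int(i == event_idx),
                         **dict(zip(covariate_cols, c))})
    out = pd.DataFrame(rows)
    if len(out) and (out.groupby("patient_id")["event"].sum() > 1).any():
        raise AssertionError("more than one event row for a patient")
    return out


def add_interactions(rows: pd.DataFrame, treatment_col: str,
                     class_cols: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Add class x treatment product columns (class 1 is the reference)."""
    out = rows.copy()
    names = []
    for c in class_cols:
        name = f"{c}:{treatment_col}"
        out[name] = out[c] * out[treatment_col]
        names.append(name)
    return out, names


def fit_tv_cox(rows: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Fit the time-varying Cox model and return a hazard-estimate table.

    ``rows`` is counting-process format from :func:`to_counting_process`.
    Returns one row per term: coefficient, hazard ratio, 95% Wald CI and
    p-value. Requires at least one event and no constant covariate;
    non-convergence or monotone-likelihood behavior surfaces as a
    lifelines convergence error/warning.
    """
    if rows["event"].sum() < 1:
        raise ValueError("no events in the counting-process table")
    const = [c for c in covariates if rows[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(rows[["patient_id", "start", "stop", "event"] + covariates],
            id_col="patient_id", start_col="start", stop_col="stop",
            event_col="event")
    s = ctv.summary
    out = pd.DataFrame({
        "term": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": np.exp(s["coef"].to_numpy()),
        "ci_lo": np.exp(s["coef lower 95%"].to_numpy()),
        "ci_hi": np.exp(s["coef upper 95%"].to_numpy()),
        "p_value": s["p"].to_numpy(),
    }).reset_index(drop=True)
    return out
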