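"""Actual-vs-optimal dosing gaps: categories, flags, validation regressions.

Delta = actual - optimal dose at patient-day level. Fluid deltas fall into
five bins — very low (-inf, -1000], low (-1000, -500], optimal (-500, 500],
high (500, 1000], very high (1000, inf) mL — with left-open/right-closed
boundaries fixed by convention. Fluid overload is delta > 1000 mL/day;
norepinephrine overdosing is delta > 0.1 mcg/kg/min. Norepinephrine delta
levels use symmetric bins at +/-0.05 and +/-0.1 mcg/kg/min; these NE bins
are a convention of this package, not a published cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["classify_deltas", "delta_level_odds", "parabola_check",
           "stepwise_risk_model", "FLUID_BINS", "NE_BINS"]

FLUID_CATEGORIES = ["very low", "low", "optimal", "high", "very high"]
FLUID_BINS = [-np.inf, -1000.0, -500.0, 500.0, 1000.0, np.inf]
NE_BINS = [-np.inf, -0.1, -0.05, 0.05, 0.1, np.inf]
FLUID_OVERLOAD_ML = 1000.0
NE_OVERDOSE = 0.1


def classify_deltas(rec_fluid: pd.DataFrame, rec_ne: pd.DataFrame,
                    fluid_bins=None, ne_bins=None,
                    fluid_overload_threshold: float = FLUID_OVERLOAD_ML,
                    ne_overdose_threshold: float = NE_OVERDOSE) -> pd.DataFrame:
    """Join fluid and norepinephrine recommendations into delta records.

    Both inputs carry ``patient_id, day, actual, optimal, delta`` (fluid in
    mL, NE in mcg/kg/min — passing one treatment's table for the other is a
    unit mismatch and is rejected on scale grounds). Categories use the
    left-open/right-closed fluid bins; ``fluid_overload`` is delta > 1000 mL
    and ``ne_overdose`` delta > 0.1 mcg/kg/min.
    """
    f = rec_fluid.rename(columns={"actual": "actual_fluid", "optimal": "optimal_fluid",
                                  "delta": "delta_fluid"})
    e = rec_ne.rename(columns={"actual": "actual_ne", "optimal": "optimal_ne",
                               "delta": "delta_ne"})
    # crude unit guard (default mL / mcg-kg-min thresholds only): optimal fluid
    # doses live on the mL scale, optimal NE on ~0-3 mcg/kg/min
    if fluid_bins is None and ne_bins is None and (
            f["optimal_fluid"].abs().max() < 50 or e["optimal_ne"].abs().max() > 50):
        raise ValueError("unit mismatch between fluid (mL) and norepinephrine (mcg/kg/min) tables")
    cols = ["patient_id", "day"]
    out = f[cols + ["actual_fluid", "optimal_fluid", "delta_fluid"]].merge(
        e[cols + ["actual_ne", "optimal_ne", "delta_ne"]], on=cols, how="inner")
    out["fluid_category"] = pd.cut(out["delta_fluid"], fluid_bins or FLUID_BINS,
                                   labels=FLUID_CATEGORIES, right=True)
    out["ne_category"] = pd.cut(out["delta_ne"], ne_bins or NE_BINS,
                                labels=FLUID_CATEGORIES, right=True)
    out["fluid_overload"] = out["delta_fluid"] > fluid_overload_threshold
    out["ne_overdose"] = out["delta_ne"] > ne_overdose_threshold
    return out


def delta_level_odds(deltas: pd.DataFrame, outcome: pd.Series | np.ndarray,
                     category_col: str = "fluid_category") -> pd.DataFrame:
    """Mortality odds ratios by delta category, with "optimal" as reference.

    Fits a logistic regression of the terminal outcome on category
    indicators. Returns one row per category with OR and 95% Wald CI; the
    reference "optimal" row has OR exactly 1.
    """
    cat = pd.Categorical(deltas[category_col], categories=FLUID_CATEGORIES)
    present = [c for c in FLUID_CATEGORIES if (np.asarray(cat) == c).any()]
    if "optimal" not in present:
        raise ValueError("reference category 'optimal' is empty")
    if len(present) < 2:
        raise ValueError("need at least two populated categories")
    y = np.asarray(outcome, float)
    dummies = pd.get_dummies(pd.Categorical(cat, categories=present), dtype=float)
    X = sm.add_constant(dummies.drop(columns="optimal"))
    res = sm.Logit(y, X).fit(disp=0)
    ci = res.conf_int()
    rows = [{"category": "optimal", "or": 1.0, "ci_lo": 1.0, "ci_hi": 1.0,
             "p_value": np.nan}]
    for c in present:
        if c == "optimal":
            continue
        rows.append({"category": c, "or": float(np.exp(res.params[c])),
                     "ci_lo": float(np.exp(ci.loc[c, 0])),
                     "ci_hi": float(np.exp(ci.loc[c, 1])),
                     "p_value": float(res.pvalues[c])})
    order = {c: i for i, c in enumerate(FLUID_CATEGORIES)}
    rows.sort(key=lambda r: order[r["category"]])
    return pd.DataFrame(rows)


def parabola_check(deltas: np.ndarray, outcome: np.ndarray,
                   ridge: float = 1e-4) -> dict:
    """Quadratic-logistic internal validation of the dosing optimum.

    Fits logit P(death) = b0 + b1 d + b2 d^2 on the deltas. A convex parabola
    (b2 > 0) with vertex -b1/(2 b2) near zero says mortality is lowest when
    dosing matches the estimated optimum. With b1 = 0 the vertex is exactly 0.
    On (quasi-)separation the model is refit with a small L2 penalty and
    flagged.
    """
    d = np.asarray(deltas, float)
    y = np.asarray(outcome, float)
    if d.size < 100:
        raise ValueError("parabola check needs at least 100 rows")
    X = sm.add_constant(np.column_stack([d, d * d]))
    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError
    except (Exception,):
        separation = True
        res = sm.Logit(y, X).fit_regularized(alpha=ridge, L1_wt=0.0, disp=0)
    b0, b1, b2 = np.asarray(res.params, float)
    vertex = 0.0 if b1 == 0 else (-b1 / (2.0 * b2) if b2 != 0 else np.inf)
    bse = np.asarray(getattr(res, "bse", [np.nan] * 3), float)
    return {"coef": (float(b0), float(b1), float(b2)), "se": tuple(bse),
            "vertex": float(vertex), "convex": bool(b2 > 0),
            "separation": separation}


def _aic_logit(y, X) -> tuple[float, object]:
    res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0, maxiter=200)
    return float(res.aic), res


def stepwise_risk_model(data: pd.DataFrame, candidates: list[str], flag_col: str,
                        direction: str = "backward") -> dict:
    """Stepwise AIC logistic model for an overdose/overload flag.

    Greedy forward selection or backward elimination; a step is accepted only
    if AIC strictly decreases, so AIC(final) <= AIC(start). Perfectly
    collinear candidates are resolved before selection by dropping the
    later-listed member (logged). Returns the fitted model, the selected
    features and the full selection path.
    """
    y = data[flag_col].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("flag column is constant")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    cands, dropped = [], []
    for c in candidates:
        X = data[cands + [c]].to_numpy(float)
        if cands and np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) \
                < X.shape[1] + 1:
            dropped.append(c)
        else:
            cands.append(c)

    current = [] if direction == "forward" else list(cands)
    aic, _ = _aic_logit(y, data[current]) if current else _aic_logit(y, pd.DataFrame(index=data.index))
    path = [{"step": 0, "action": "start", "features": list(current), "aic": aic}]
    step = 0
    while True:
        moves = ([c for c in cands if c not in current] if direction == "forward"
                 else list(current))
        best = None
        for c in moves:
            trial = current + [c] if direction == "forward" else [f for f in current if f != c]
            try:
                trial_aic, _ = _aic_logit(y, data[trial])
            except (np.linalg.LinAlgError, Exception):
                continue
            if trial_aic < aic - 1e-9 and (best is None or trial_aic < best[1]):
                best = (c, trial_aic, trial)
        if best is None:
            break
        step += 1
        current, aic = best[2], best[1]
        path.append({"step": step,
                     "action": ("add" if direction == "forward" else "drop") + f" {best[0]}",
                     "features": list(current), "aic": aic})
    final_aic, model = _aic_logit(y, data[current])
    return {"model": model, "selected": current, "aic": final_aic, "path": path,
            "pre_dropped_collinear": dropped}
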