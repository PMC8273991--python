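"""Cohort preprocessing: dose conversion, imputation, screening, scaling.

Turns the raw long-format cohort into the 17-feature analysis matrix used by
the mixture model and the cluster-validation battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import NE_EQUIVALENCE, FeatureSpec

__all__ = [
    "norepinephrine_equivalent",
    "impute_locf_nocb",
    "correlation_screen",
    "build_feature_matrix",
    "Standardizer",
]


def norepinephrine_equivalent(doses) -> float | pd.Series:
    """Convert per-drug vasopressor doses to a norepinephrine-equivalent dose.

    ``doses`` maps drug name to dose (mcg/kg/min; vasopressin in units/min),
    either a plain dict of scalars or a DataFrame with one column per drug.
    Absent drugs count as zero. The conversion is a fixed weighted sum:
    norepinephrine + epinephrine + phenylephrine/10 + dopamine/100 +
    metaraminol/8 + vasopressin*2.5 + angiotensin_ii*10.
    """
    if isinstance(doses, pd.DataFrame):
        total = pd.Series(0.0, index=doses.index)
        items = ((c, doses[c]) for c in doses.columns)
    else:
        total = 0.0
        items = doses.items()
    for drug, dose in items:
        key = drug.lower().replace(" ", "_")
        if key not in NE_EQUIVALENCE:
            raise KeyError(f"unknown vasopressor {drug!r}")
        if np.any(np.asarray(dose) < 0):
            raise ValueError(f"negative dose for {drug!r}")
        total = total + NE_EQUIVALENCE[key] * dose
    return total


def impute_locf_nocb(cohort: pd.DataFrame, feature_names: list[str] | None = None,
                     exclusion_threshold: float = 0.20,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal imputation: LOCF along days 0..7, then NOCB.

    Patients whose pre-imputation missing-cell fraction — over
    features x days actually observed for that patient — is at or above
    ``exclusion_threshold`` are excluded rather than imputed, as are patients
    left with an entirely-missing feature series after both passes.

    Returns ``(imputed cohort, exclusion report)`` where the report has
    columns ``patient_id, reason, missing_fraction``.
    """
    feats = feature_names if feature_names is not None else FeatureSpec().names
    df = cohort.sort_values(["patient_id", "day"]).reset_index(drop=True)

    cells = df.groupby("patient_id")[feats].apply(lambda g: g.isna().to_numpy().mean())
    excluded = cells[cells >= exclusion_threshold]
    report = pd.DataFrame({
        "patient_id": excluded.index,
        "reason": "missing_fraction_ge_threshold",
        "missing_fraction": excluded.to_numpy(),
    })

    keep = df[~df["patient_id"].isin(excluded.index)].copy()
    g = keep.groupby("patient_id", sort=False)
    keep[feats] = g[feats].ffill()
    keep[feats] = keep.groupby("patient_id", sort=False)[feats].bfill()

    # A feature with no observation at all for a patient survives both passes
    # as NaN: that patient is unresolvable.
    bad = keep.groupby("patient_id")[feats].apply(lambda x: x.isna().any().any())
    bad_ids = bad[bad].index
    if len(bad_ids):
        frac = cells.reindex(bad_ids).to_numpy()
        report = pd.concat([report, pd.DataFrame({
            "patient_id": bad_ids, "reason": "feature_series_all_missing",
            "missing_fraction": frac})], ignore_index=True)
        keep = keep[~keep["patient_id"].isin(bad_ids)]
    return keep.reset_index(drop=True), report.reset_index(drop=True)


def correlation_screen(matrix: pd.DataFrame, threshold: float = 0.7,
                       removal_priority: list[str] | None = None,
                       ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Flag feature pairs with Pearson |r| above threshold and drop one of each.

    ``removal_priority`` encodes domain knowledge: for a flagged pair the
    member appearing *earlier* in the list is removed. Members absent from
    the list are kept in preference to listed ones; if neither member is
    listed, the later column (in matrix order) is dropped. Pairs are resolved
    in decreasing |r|; a pair one of whose members was already removed is not
    re-resolved. Constant columns have undefined correlations: they are
    reported (r = NaN) and kept.

    Returns ``(kept, removed, pair table)`` with pair columns
    ``feature_a, feature_b, r, removed``.
    """
    priority = removal_priority or []
    cols = list(matrix.columns)
    corr = matrix.corr()
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) > threshold:
                pairs.append((a, b, r))
    pairs.sort(key=lambda t: -(abs(t[2]) if not np.isnan(t[2]) else -np.inf))

    removed: list[str] = []
    rows = []
    for a, b, r in pairs:
        victim = None
        if not np.isnan(r) and a not in removed and b not in removed:
            ia = priority.index(a) if a in priority else len(priority)
            ib = priority.index(b) if b in priority else len(priority)
            if ia < ib:
                victim = a
            elif ib < ia:
                victim = b
            else:  # neither listed: drop the later column
                victim = b if cols.index(b) > cols.index(a) else a
            removed.append(victim)
        rows.append({"feature_a": a, "feature_b": b, "r": r, "removed": victim or ""})
    kept = [c for c in cols if c not in removed]
    return kept, removed, pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "removed"])


@dataclass
class Standardizer:
    """Column-wise z-scoring with stored parameters.

    Fit once on the derivation cohort; external cohorts are projected with the
    stored means/scales, never refit.
    """

    means: pd.Series = None
    scales: pd.Series = None

    def fit(self, matrix: pd.DataFrame) -> "Standardizer":
        self.means = matrix.mean()
        sd = matrix.std(ddof=0)
        if (sd <= 0).any():
            bad = list(sd.index[sd <= 0])
            raise ValueError(f"constant columns cannot be standardized: {bad}")
        self.scales = sd
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return (matrix[self.means.index] - self.means) / self.scales

    def inverse_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix[self.means.index] * self.scales + self.means


def build_feature_matrix(cohort: pd.DataFrame, spec: FeatureSpec | None = None,
                         standardize: bool = False,
                         ) -> tuple[pd.DataFrame, Standardizer | None]:
    """Extract the 17 analysis columns (one row per patient-day) in spec order.

    With ``standardize`` the matrix is z-scored column-wise and the fitted
    :class:`Standardizer` is returned for inverse mapping and for projecting
    external cohorts with the same transform.
    """
    spec = spec or FeatureSpec()
    missing = [n for n in spec.names if n not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing required feature columns: {missing}")
    matrix = cohort[spec.names].astype(float).copy()
    if not standardize:
        return matrix, None
    sz = Standardizer().fit(matrix)
    return sz.transform(matrix), sz
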