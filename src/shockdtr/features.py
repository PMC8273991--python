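"""Feature dictionary for the septic-shock phenotyping pipeline.

The mixture model runs on 17 daily clinical features. Each feature carries a
daily aggregation tag (``min``/``max``/``as-recorded``) matching how the value
is summarized within an ICU day, and a unit for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Conversion multipliers to norepinephrine-equivalent dose (mcg/kg/min).
#: Vasopressin is entered in units/min; all other drugs in mcg/kg/min.
#: These are fixed clinical constants, never re-estimated.
NE_EQUIVALENCE: dict[str, float] = {
    "norepinephrine": 1.0,
    "epinephrine": 1.0,
    "phenylephrine": 1.0 / 10.0,
    "dopamine": 1.0 / 100.0,
    "metaraminol": 1.0 / 8.0,
    "vasopressin": 2.5,
    "angiotensin_ii": 10.0,
}

#: mg/dL -> umol/L for serum creatinine.
CREATININE_MGDL_TO_UMOL = 88.4


@dataclass(frozen=True)
class Feature:
    name: str          # column name in the cohort CSV
    aggregation: str   # daily summary: "min", "max" or "as-recorded"
    unit: str


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered list of the 17 mixture-model features."""

    features: tuple[Feature, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.features is None:
            object.__setattr__(self, "features", tuple(DEFAULT_FEATURES))
        if len(self.features) != 17:
            raise ValueError(f"FeatureSpec requires exactly 17 features, got {len(self.features)}")
        for f in self.features:
            if f.aggregation not in ("min", "max", "as-recorded"):
                raise ValueError(f"bad aggregation tag {f.aggregation!r} for {f.name}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]


DEFAULT_FEATURES: list[Feature] = [
    Feature("age", "as-recorded", "years"),
    Feature("weight", "as-recorded", "kg"),
    Feature("hr_max", "max", "/min"),
    Feature("apacheii", "as-recorded", "points"),
    Feature("sbp_min", "min", "mmHg"),
    Feature("temp", "as-recorded", "degC"),
    Feature("ph_min", "min", "pH"),
    Feature("hco3_min", "min", "mmol/L"),
    Feature("lactate_max", "max", "mmol/L"),
    Feature("be_min", "min", "mmol/L"),
    Feature("pf_min", "min", "mmHg"),
    Feature("paco2_max", "max", "mmHg"),
    Feature("hct", "as-recorded", "%"),
    Feature("platelet", "as-recorded", "1e9/L"),
    Feature("rdwcv", "as-recorded", "%"),
    Feature("creatinine", "as-recorded", "umol/L"),
    Feature("urine_ml", "as-recorded", "mL"),
]

#: Column order of the shared cohort CSV.
COHORT_COLUMNS: list[str] = (
    ["patient_id", "day"]
    + [f.name for f in DEFAULT_FEATURES]
    + ["fluid_in_ml", "fluid_out_ml", "ne_eq_mcgkgmin", "death_hosp", "death_day"]
)

#: ICU days on which variables are observed.
OBSERVED_DAYS: tuple[int, ...] = (0, 1, 2, 3, 7)


def creatinine_mgdl_to_umol(value):
    """Convert serum creatinine from mg/dL to umol/L (x 88.4)."""
    return value * CREATININE_MGDL_TO_UMOL
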