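"""Feature schema shared by the synthetic generator and the preprocessing pipeline.

The default roster mirrors the structure of an ICU stay record for an
intracerebral-hemorrhage cohort: demographic/admission descriptors, hourly
vital signs, laboratory series (with the coagulation panel PT/INR/aPTT that
drives hematoma growth risk), and medication administration flags. Hard
physiologic ranges bound what a value can plausibly be; anything outside is
an obvious recording error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str  # 'continuous' | 'categorical' | 'binary'
    lower: Optional[float] = None  # hard physiologic range (continuous only)
    upper: Optional[float] = None
    categories: Optional[Tuple[str, ...]] = None
    static: bool = False  # constant over the stay (demographics)

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"categorical feature {self.name} needs categories")


DEFAULT_SCHEMA: tuple[FeatureDef, ...] = (
    # demographics / admission (static)
    FeatureDef("gender", "categorical", categories=("F", "M"), static=True),
    FeatureDef("anchor_age", "continuous", 18, 105, static=True),
    FeatureDef(
        "admission_type",
        "categorical",
        categories=("EW EMER.", "URGENT", "ELECTIVE"),
        static=True,
    ),
    FeatureDef("insurance", "categorical", categories=("Medicare", "Other"), static=True),
    FeatureDef(
        "marital_status",
        "categorical",
        categories=("MARRIED", "SINGLE", "WIDOWED"),
        static=True,
    ),
    FeatureDef("language", "categorical", categories=("ENGLISH", "OTHER"), static=True),
    # vitals (hourly)
    FeatureDef("heart_rate", "continuous", 20, 250),
    FeatureDef("sbp", "continuous", 40, 300),
    FeatureDef("dbp", "continuous", 20, 200),
    FeatureDef("map", "continuous", 25, 250),
    FeatureDef("resp_rate", "continuous", 4, 60),
    FeatureDef("spo2", "continuous", 50, 100),
    FeatureDef("temperature", "continuous", 30, 43),
    FeatureDef("gcs", "continuous", 3, 15),
    # labs
    FeatureDef("pt", "continuous", 5, 150),
    FeatureDef("inr", "continuous", 0.5, 12),
    FeatureDef("aptt", "continuous", 10, 200),
    FeatureDef("platelets", "continuous", 5, 1000),
    FeatureDef("fibrinogen", "continuous", 30, 1000),
    FeatureDef("wbc", "continuous", 0.5, 60),
    FeatureDef("hemoglobin", "continuous", 3, 22),
    FeatureDef("glucose", "continuous", 20, 1000),
    FeatureDef("creatinine", "continuous", 0.1, 20),
    FeatureDef("sodium", "continuous", 100, 180),
    # medication flags
    FeatureDef("antihypertensive", "binary"),
    FeatureDef("mannitol", "binary"),
    FeatureDef("anticoagulant_reversal", "binary"),
    FeatureDef("sedative", "binary"),
)

SCHEMA_BY_NAME = {f.name: f for f in DEFAULT_SCHEMA}

#: The two series whose (standardized) values drive the true growth model.
SIGNAL_FEATURES = ("inr", "sbp")
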