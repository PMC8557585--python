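"""Per-patient cohort records and their tabular serialization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .ihc import Cd34Profile
from .smi import VascularizationProfile

COHORT_COLUMNS = ("patient_id", "label", "age", "bmi", "length_mm",
                  "quotient", "cd34_fraction")
LABELS = ("benign", "malignant")


@dataclass
class CohortRecord:
    """One patient: covariates, histology label, and outcome measurements.

    ``quotient`` and ``cd34_fraction`` are the scalar headline outcomes (a
    vascularization quotient and a CD34 area fraction); the full ten-parameter
    SMI profile and three-parameter CD34 profile can be attached when images
    were analyzed.
    """

    patient_id: str
    label: str
    age: float
    bmi: float
    length_mm: float
    quotient: float
    cd34_fraction: float
    profile: Optional[VascularizationProfile] = None
    cd34: Optional[Cd34Profile] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.age <= 0 or self.bmi <= 0 or self.length_mm <= 0:
            raise ValueError("age, BMI and nodule length must be positive")


def cohort_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with the standard cohort columns."""
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in COHORT_COLUMNS}
        if rec.profile is not None:
            row.update(rec.profile.as_dict())
        if rec.cd34 is not None:
            row.update(rec.cd34.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[CohortRecord]:
    """Inverse of :func:`cohort_to_frame` for the scalar columns."""
    return [CohortRecord(**{c: row[c] for c in COHORT_COLUMNS})
            for _, row in frame.iterrows()]
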