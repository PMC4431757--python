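"""Cohort feature engineering for the DEA obesity analysis.

Maps per-subject cohort variables onto DEA inputs/outputs (expenditure and
inverse intake in; inverse BMI out), classifies BMI into the standard
underweight/normal/overweight categories, and computes yearly BMI change
with the normal-baseline restriction used for the change analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .dea import DMURecord, DMUSet

__all__ = [
    "SubjectRecord",
    "BMICategory",
    "CohortValidationError",
    "build_dea_frame",
    "classify_bmi",
    "yearly_bmi_change",
    "change_analysis_filter",
    "COHORT_COLUMNS",
]

#: canonical cohort CSV columns; bmi_followup / followup_years may be empty
COHORT_COLUMNS = [
    "subject_id", "age", "sex", "bmi_baseline",
    "energy_intake_kcal", "energy_expenditure_mets_h",
    "bmi_followup", "followup_years",
]


class CohortValidationError(ValueError):
    pass


class MissingFollowupError(CohortValidationError):
    pass


class BMICategory(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: int
    sex: str                      # "M" or "F"
    bmi_baseline: float
    energy_intake: float          # kcal/day
    energy_expenditure: float     # METs-h/day
    bmi_followup: float | None = None
    followup_interval: float | None = None  # years

    def __post_init__(self) -> None:
        for name in ("bmi_baseline", "energy_intake", "energy_expenditure"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: {name} = {v} must be "
                    "strictly positive"
                )
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"subject {self.subject_id!r}: sex must be 'M' or 'F', "
                f"got {self.sex!r}"
            )
        if self.bmi_followup is not None:
            if self.followup_interval is None or self.followup_interval <= 0:
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: follow-up BMI present but "
                    "followup_interval missing or nonpositive"
                )


def subjects_from_frame(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Parse a cohort table (see COHORT_COLUMNS) into SubjectRecords."""
    subjects = []
    for _, row in frame.iterrows():
        fu_bmi = row.get("bmi_followup", np.nan)
        fu_years = row.get("followup_years", np.nan)
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            age=int(row["age"]),
            sex=str(row["sex"]),
            bmi_baseline=float(row["bmi_baseline"]),
            energy_intake=float(row["energy_intake_kcal"]),
            energy_expenditure=float(row["energy_expenditure_mets_h"]),
            bmi_followup=None if pd.isna(fu_bmi) else float(fu_bmi),
            followup_interval=None if pd.isna(fu_years) else float(fu_years),
        ))
    return subjects


def build_dea_frame(subjects: Iterable[SubjectRecord] | pd.DataFrame) -> DMUSet:
    """Per subject: inputs (expenditure, 1/intake); output 1/baseline BMI."""
    if isinstance(subjects, pd.DataFrame):
        subjects = subjects_from_frame(subjects)
    return DMUSet(
        DMURecord(
            dmu_id=s.subject_id,
            inputs=(s.energy_expenditure, 1.0 / s.energy_intake),
            outputs=(1.0 / s.bmi_baseline,),
        )
        for s in subjects
    )


def classify_bmi(bmi: float) -> BMICategory:
    """Underweight < 18.5 <= normal < 25 <= overweight (kg/m^2)."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise CohortValidationError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return BMICategory.UNDERWEIGHT
    if bmi < 25.0:
        return BMICategory.NORMAL
    return BMICategory.OVERWEIGHT


def yearly_bmi_change(subject: SubjectRecord) -> float:
    """(follow-up BMI - baseline BMI) / interval, in kg/m^2 per year."""
    if subject.bmi_followup is None or subject.followup_interval is None:
        raise MissingFollowupError(
            f"subject {subject.subject_id!r} has no follow-up BMI/interval"
        )
    return (subject.bmi_followup - subject.bmi_baseline) / subject.followup_interval


def change_analysis_filter(
    subjects: Iterable[SubjectRecord],
) -> list[SubjectRecord]:
    """Subjects eligible for the yearly-change analysis.

    Keeps subjects whose *baseline* BMI is in the normal range and who have
    follow-up values; underweight and overweight participants are excluded,
    as are those lost to follow-up.
    """
    return [
        s for s in subjects
        if s.bmi_followup is not None
        and s.followup_interval is not None
        and classify_bmi(s.bmi_baseline) is BMICategory.NORMAL
    ]


def change_analysis_mask(frame: pd.DataFrame) -> pd.Series:
    """Vectorised version of change_analysis_filter for cohort tables."""
    bmi = frame["bmi_baseline"]
    has_fu = frame["bmi_followup"].notna() & frame["followup_years"].notna()
    return has_fu & (bmi >= 18.5) & (bmi < 25.0)
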