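"""Participant-level background data.

Sex, age and measured anthropometrics are the inputs to resting-energy
expenditure prediction and to the sex x age-band median portion lookup;
``completed_recall_days`` drives the recall-day inclusion rule.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import RecordValidationError

SEXES = ("male", "female")


@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    sex: str
    age: int
    height_cm: float
    weight_kg: float
    completed_recall_days: int = 0
    n_days_scheduled: int = 6

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RecordValidationError(f"participant {self.id}: unknown sex {self.sex!r}")
        if self.age < 18:
            raise RecordValidationError(f"participant {self.id}: age {self.age} < 18")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise RecordValidationError(
                f"participant {self.id}: height and weight must be positive"
            )
        if not 0 <= self.completed_recall_days <= self.n_days_scheduled:
            raise RecordValidationError(
                f"participant {self.id}: completed_recall_days outside "
                f"[0, {self.n_days_scheduled}]"
            )

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


def participants_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame indexed by participant id."""
    rows = [
        (p.id, p.sex, p.age, p.height_cm, p.weight_kg, p.completed_recall_days)
        for p in profiles
    ]
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "sex", "age", "height_cm", "weight_kg",
                 "completed_recall_days"],
    ).set_index("participant_id")
    return df


def profiles_from_frame(df: pd.DataFrame):
    """Inverse of :func:`participants_frame`."""
    return [
        ParticipantProfile(
            id=str(idx),
            sex=row["sex"],
            age=int(row["age"]),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
            completed_recall_days=int(row["completed_recall_days"]),
        )
        for idx, row in df.iterrows()
    ]
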