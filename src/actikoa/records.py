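"""Participant records and the delimited cohort file format.

A participant is one week of wrist accelerometry reduced to 24 hourly mean
acceleration values, plus the demographic and diagnostic context needed to
build case-control datasets: month of wear, sex, age, weight, BMI, ICD-10
codes and the signed offset (in years) from the wear week to the first
qualifying knee-osteoarthritis diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOURS = 24
HOUR_COLUMNS = [f"h{h:02d}" for h in range(HOURS)]


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: diurnal activity profile plus covariates.

    Attributes
    ----------
    id : str
        Opaque participant identifier.
    profile : tuple of 24 floats
        Hourly mean acceleration (milli-gravity scale), hour 0 through 23.
    month : int
        Calendar month of the wear week, 1-12.
    sex : str
        ``"male"`` or ``"female"``.
    age : float
        Age in years at recording.
    weight : float
        Body weight in kg.
    bmi : float
        Body mass index in kg/m^2.
    icd10_codes : frozenset of str
        Diagnosis codes attached to the participant (any code system level,
        e.g. ``"M17.1"``).
    diagnosis_offset_years : float or None
        Years from the wear week to the first qualifying diagnosis; negative
        when the diagnosis preceded the recording, ``None`` when there is no
        qualifying diagnosis.
    """

    id: str
    profile: tuple[float, ...]
    month: int
    sex: str
    age: float
    weight: float
    bmi: float
    icd10_codes: frozenset[str] = field(default_factory=frozenset)
    diagnosis_offset_years: float | None = None

    def __post_init__(self) -> None:
        if len(self.profile) != HOURS:
            raise ValueError(
                f"profile must have exactly {HOURS} hourly values, got {len(self.profile)}"
            )
        if not 1 <= int(self.month) <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def profile_array(self) -> np.ndarray:
        return np.asarray(self.profile, dtype=float)

    def with_profile(self, profile: Sequence[float]) -> "ParticipantRecord":
        return replace(self, profile=tuple(float(v) for v in profile))


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Tabulate records: one row per participant, h00..h23 plus covariates."""
    rows = []
    for r in records:
        row = {"id": r.id}
        row.update({c: v for c, v in zip(HOUR_COLUMNS, r.profile)})
        row.update(
            month=r.month,
            sex=r.sex,
            age=r.age,
            weight=r.weight,
            bmi=r.bmi,
            icd10=";".join(sorted(r.icd10_codes)),
            diagnosis_offset_years=(
                "" if r.diagnosis_offset_years is None else r.diagnosis_offset_years
            ),
        )
        rows.append(row)
    columns = ["id", *HOUR_COLUMNS, "month", "sex", "age", "weight", "bmi",
               "icd10", "diagnosis_offset_years"]
    return pd.DataFrame(rows, columns=columns)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for _, row in frame.iterrows():
        offset = row["diagnosis_offset_years"]
        if offset == "" or pd.isna(offset):
            offset = None
        else:
            offset = float(offset)
        codes = row.get("icd10", "")
        if pd.isna(codes):
            codes = ""
        codes = frozenset(c for c in str(codes).split(";") if c)
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                profile=tuple(float(row[c]) for c in HOUR_COLUMNS),
                month=int(row["month"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                weight=float(row["weight"]),
                bmi=float(row["bmi"]),
                icd10_codes=codes,
                diagnosis_offset_years=offset,
            )
        )
    return records


def write_cohort(records: Iterable[ParticipantRecord], path: str | Path) -> None:
    """Write a cohort as comma-delimited text (one row per participant)."""
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[ParticipantRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    frame = pd.read_csv(path, dtype={"id": str, "icd10": str}, keep_default_na=False)
    return frame_to_records(frame)
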