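"""Eligibility filtering, disease labelling and matched undersampling.

Builds the three case-control classification scenarios from raw participant
records: (1) healthy vs any knee-osteoarthritis (KOA) case, (2) prodromal vs
already diagnosed KOA, (3) healthy vs prodromal diagnosed within five years.
Scenarios 1 and 3 are balanced 1:1 by weighted undersampling of controls on
sex, age and BMI; scenario 2 retains all eligible participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import HOURS, ParticipantRecord, records_to_frame, frame_to_records

logger = logging.getLogger(__name__)

DEFAULT_KOA_CODES = frozenset({"M17", "M17.0", "M17.1", "M17.9"})
DEFAULT_BMI_MIN = 29.0
DEFAULT_ANOMALY_MAX = 1000.0
DEFAULT_PRODROMAL_WINDOW = 10.0
DEFAULT_EARLY_WINDOW = 5.0

HEALTHY = "healthy"
DIAGNOSED = "diagnosed"
PRODROMAL = "prodromal"
# Qualifying diagnosis more than `prodromal_window` years after the wear
# week: still a case for the healthy-vs-KOA contrast, but not prodromal.
BEYOND_WINDOW = "beyond_window"


class DataIntegrityError(ValueError):
    """A qualifying diagnosis code without a diagnosis offset."""


class EmptyClassError(ValueError):
    """A scenario class has no members in the supplied cohort."""


class InfeasibleMatchingError(ValueError):
    """Fewer controls than cases; 1:1 undersampling impossible."""


@dataclass(frozen=True)
class DiseaseStatus:
    category: str  # healthy | diagnosed | prodromal | beyond_window
    within_5y: bool = False

    def __post_init__(self) -> None:
        if self.within_5y and self.category != PRODROMAL:
            raise ValueError("within_5y is only meaningful for prodromal status")


@dataclass
class ScenarioDataset:
    """A labelled two-class dataset for one classification scenario.

    Class 0 is the first-listed group of the scenario (healthy / prodromal /
    healthy), class 1 the second (any KOA / diagnosed / prodromal-within-5y).
    """

    scenario: int
    records: list[ParticipantRecord]
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels must have equal length")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Numeric arrays for model fitting; sex coded female=0, male=1."""
        return {
            "profile": np.array([r.profile for r in self.records], dtype=float),
            "month": np.array([r.month for r in self.records], dtype=int),
            "sex": np.array([1 if r.sex == "male" else 0 for r in self.records]),
            "age": np.array([r.age for r in self.records], dtype=float),
            "weight": np.array([r.weight for r in self.records], dtype=float),
            "y": self.labels.copy(),
        }

    def subset(self, indices: Sequence[int]) -> "ScenarioDataset":
        idx = np.asarray(indices, dtype=int)
        return ScenarioDataset(
            scenario=self.scenario,
            records=[self.records[i] for i in idx],
            labels=self.labels[idx],
            provenance={"parent": self.provenance, "subset_size": int(idx.size)},
        )

    def write(self, path: str | Path) -> None:
        frame = records_to_frame(self.records)
        frame["label"] = self.labels
        frame.to_csv(path, index=False)
        Path(path).with_suffix(".provenance.yaml").write_text(
            yaml.safe_dump(_plain(self.provenance), sort_keys=False)
        )

    @classmethod
    def read(cls, path: str | Path, scenario: int | None = None) -> "ScenarioDataset":
        frame = pd.read_csv(path, dtype={"id": str, "icd10": str}, keep_default_na=False)
        labels = frame.pop("label").to_numpy(dtype=int)
        prov_path = Path(path).with_suffix(".provenance.yaml")
        provenance = (
            yaml.safe_load(prov_path.read_text()) if prov_path.exists() else {}
        )
        if scenario is None:
            scenario = int(provenance.get("scenario", 0))
        return cls(scenario=scenario, records=frame_to_records(frame),
                   labels=labels, provenance=provenance)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def filter_valid(
    records: Iterable[ParticipantRecord],
    bmi_min: float = DEFAULT_BMI_MIN,
    anomaly_max: float = DEFAULT_ANOMALY_MAX,
) -> tuple[list[ParticipantRecord], list[tuple[str, str]]]:
    """Apply the eligibility rules; return survivors and a rejection log.

    Rules, in the order tested (the first failure is logged): any missing or
    non-finite hourly value; any hourly value strictly greater than
    ``anomaly_max``; BMI strictly below ``bmi_min``. Boundary semantics: an
    hourly value exactly at ``anomaly_max`` and a BMI exactly at ``bmi_min``
    are both kept.
    """
    kept: list[ParticipantRecord] = []
    rejections: list[tuple[str, str]] = []
    for r in records:
        profile = r.profile_array()
        if profile.size != HOURS or not np.all(np.isfinite(profile)):
            rejections.append((r.id, "missing_or_nonfinite_hourly_value"))
        elif np.any(profile > anomaly_max):
            rejections.append((r.id, f"hourly_value_exceeds_{anomaly_max:g}"))
        elif r.bmi < bmi_min:
            rejections.append((r.id, f"bmi_below_{bmi_min:g}"))
        else:
            kept.append(r)
    return kept, rejections


def _has_koa_code(codes: frozenset[str], koa_codes: frozenset[str]) -> bool:
    return any(any(c.startswith(k) for k in koa_codes) for c in codes)


def classify_status(
    record: ParticipantRecord,
    koa_codes: frozenset[str] = DEFAULT_KOA_CODES,
    prodromal_window: float = DEFAULT_PRODROMAL_WINDOW,
    early_window: float = DEFAULT_EARLY_WINDOW,
) -> DiseaseStatus:
    """Label one participant relative to the wear week.

    No qualifying code: healthy. Diagnosis offset <= 0 (diagnosis on or
    before the recording day): diagnosed. Offset in (0, prodromal_window]:
    prodromal, with ``within_5y`` when the offset is <= early_window.
    Offsets beyond the window are flagged ``beyond_window``.
    """
    if not 0 < early_window <= prodromal_window:
        raise ValueError("require 0 < early_window <= prodromal_window")
    if not _has_koa_code(record.icd10_codes, koa_codes):
        return DiseaseStatus(HEALTHY)
    offset = record.diagnosis_offset_years
    if offset is None:
        raise DataIntegrityError(
            f"record {record.id} carries a qualifying code but no diagnosis offset"
        )
    if offset <= 0:
        return DiseaseStatus(DIAGNOSED)
    if offset <= prodromal_window:
        return DiseaseStatus(PRODROMAL, within_5y=offset <= early_window)
    return DiseaseStatus(BEYOND_WINDOW)


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Mean difference over the pooled SD (equal-weight pooling)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def balance_summary(
    cases: Sequence[ParticipantRecord], controls: Sequence[ParticipantRecord]
) -> dict[str, float]:
    case_age = np.array([r.age for r in cases])
    ctrl_age = np.array([r.age for r in controls])
    case_bmi = np.array([r.bmi for r in cases])
    ctrl_bmi = np.array([r.bmi for r in controls])
    case_male = np.mean([r.sex == "male" for r in cases])
    ctrl_male = np.mean([r.sex == "male" for r in controls])
    return {
        "age_smd": standardized_mean_difference(case_age, ctrl_age),
        "bmi_smd": standardized_mean_difference(case_bmi, ctrl_bmi),
        "male_fraction_diff": float(case_male - ctrl_male),
    }


def _stratum_keys(
    records: Sequence[ParticipantRecord], age_bin: float, bmi_bin: float
) -> list[tuple]:
    return [
        (r.sex, int(np.floor(r.age / age_bin)), int(np.floor(r.bmi / bmi_bin)))
        for r in records
    ]


def matched_undersample(
    controls: Sequence[ParticipantRecord],
    cases: Sequence[ParticipantRecord],
    seed: int,
    age_bin: float = 5.0,
    bmi_bin: float = 2.0,
) -> list[ParticipantRecord]:
    """Select ``len(cases)`` controls with density-ratio weights on sex/age/BMI.

    Each control's sampling weight is the ratio of case to control counts in
    its (sex, 5-year age bin, 2-unit BMI bin) stratum, so the selected subset
    approximates the case distribution over the balance variables. Sampling
    is without replacement and fully determined by ``seed``. When too few
    controls fall in case-occupied strata, weights are smoothed with a small
    floor over neighbouring strata (same sex) and a warning is logged.
    """
    if len(controls) < len(cases):
        raise InfeasibleMatchingError(
            f"{len(controls)} controls cannot be undersampled to {len(cases)} cases"
        )
    if len(cases) == 0:
        raise ValueError("cases must be non-empty")

    case_keys = _stratum_keys(cases, age_bin, bmi_bin)
    ctrl_keys = _stratum_keys(controls, age_bin, bmi_bin)
    case_counts: dict[tuple, int] = {}
    for k in case_keys:
        case_counts[k] = case_counts.get(k, 0) + 1
    ctrl_counts: dict[tuple, int] = {}
    for k in ctrl_keys:
        ctrl_counts[k] = ctrl_counts.get(k, 0) + 1

    weights = np.array(
        [case_counts.get(k, 0) / ctrl_counts[k] for k in ctrl_keys], dtype=float
    )
    if int(np.count_nonzero(weights)) < len(cases):
        # Borrow mass from adjacent strata: any control sharing a sex stratum
        # with at least one case gets a small floor weight.
        case_sexes = {k[0] for k in case_keys}
        floor = (weights[weights > 0].max() if np.any(weights > 0) else 1.0) * 1e-3
        eligible = np.array([k[0] in case_sexes for k in ctrl_keys])
        if int(np.count_nonzero(weights > 0) + np.count_nonzero(eligible & (weights == 0))) < len(cases):
            eligible[:] = True  # last resort: every control is eligible
        weights = np.where(eligible & (weights == 0), floor, weights)
        logger.warning(
            "matched_undersample: sparse strata; smoothed weights with floor %.3g",
            floor,
        )

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(controls), size=len(cases), replace=False, p=weights / weights.sum())
    return [controls[i] for i in sorted(idx)]


def build_scenario(
    records: Sequence[ParticipantRecord],
    scenario: int,
    seed: int,
    koa_codes: frozenset[str] = DEFAULT_KOA_CODES,
    prodromal_window: float = DEFAULT_PRODROMAL_WINDOW,
    early_window: float = DEFAULT_EARLY_WINDOW,
) -> ScenarioDataset:
    """Compose labelling and matching into one scenario dataset.

    Scenario 1: healthy (0) vs any KOA case (1), controls undersampled 1:1.
    Scenario 2: prodromal (0) vs diagnosed (1), all eligible retained.
    Scenario 3: healthy (0) vs prodromal within 5 years (1), matched 1:1.
    Input records are assumed to have already passed :func:`filter_valid`.
    """
    if scenario not in (1, 2, 3):
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")

    statuses = [
        classify_status(r, koa_codes, prodromal_window, early_window) for r in records
    ]
    groups: dict[str, list[ParticipantRecord]] = {
        HEALTHY: [], DIAGNOSED: [], PRODROMAL: [], BEYOND_WINDOW: []
    }
    prodromal_5y: list[ParticipantRecord] = []
    for r, s in zip(records, statuses):
        groups[s.category].append(r)
        if s.within_5y:
            prodromal_5y.append(r)

    counts = {k: len(v) for k, v in groups.items()}
    counts["prodromal_within_5y"] = len(prodromal_5y)
    provenance: dict = {
        "scenario": scenario,
        "seed": seed,
        "n_input": len(records),
        "status_counts": counts,
    }

    def finish(class0, class1, matched_from=None):
        if not class1:
            raise EmptyClassError(f"scenario {scenario}: class1 is empty")
        if matched_from is not None:
            if not matched_from:
                raise EmptyClassError(f"scenario {scenario}: class0 is empty")
            provenance["balance_before"] = balance_summary(class1, matched_from)
            class0 = matched_undersample(matched_from, class1, seed)
            provenance["balance_after"] = balance_summary(class1, class0)
        elif not class0:
            raise EmptyClassError(f"scenario {scenario}: class0 is empty")
        provenance["class_sizes"] = {"class0": len(class0), "class1": len(class1)}
        labels = np.concatenate([np.zeros(len(class0), int), np.ones(len(class1), int)])
        return ScenarioDataset(scenario, list(class0) + list(class1), labels, provenance)

    if scenario == 1:
        cases = groups[DIAGNOSED] + groups[PRODROMAL] + groups[BEYOND_WINDOW]
        if groups[BEYOND_WINDOW]:
            provenance["beyond_window_as_case"] = len(groups[BEYOND_WINDOW])
        return finish([], cases, matched_from=groups[HEALTHY])
    if groups[BEYOND_WINDOW]:
        provenance["beyond_window_excluded"] = len(groups[BEYOND_WINDOW])
    if scenario == 2:
        return finish(groups[PRODROMAL], groups[DIAGNOSED])
    return finish([], prodromal_5y, matched_from=groups[HEALTHY])
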