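"""Longitudinal lesion-measurement cohorts: domain types, CSV I/O, validation.

Internal time unit is integer days from treatment start (day 0 = first dose);
baseline CT is the assessment with the largest non-positive day and must fall
within the four weeks before treatment ([-28, 0]).  Months are derived for
reporting with the 30.4375 days/month convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "BASELINE_WINDOW_DAYS",
    "TargetLesionMeasurement",
    "Assessment",
    "PatientRecord",
    "Cohort",
    "ValidationIssue",
    "SchemaError",
    "CohortValidationError",
    "DataIntegrityError",
    "months",
    "load_cohort",
    "write_cohort",
    "validate_cohort",
]

DAYS_PER_MONTH = 30.4375
BASELINE_WINDOW_DAYS = 28

MEASUREMENT_COLUMNS = [
    "patient_id",
    "day",
    "lesion_id",
    "organ",
    "diameter_mm",
    "attenuation_hu",
    "is_new",
    "nontarget_progression",
]
OUTCOME_COLUMNS = ["patient_id", "death_day", "last_followup_day"]


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


class CohortValidationError(ValueError):
    """A record violates a structural invariant (negative diameter, ...)."""


class DataIntegrityError(ValueError):
    """Internally inconsistent data discovered during analysis."""


def months(day_span: float) -> float:
    """Convert a span in days to months (30.4375 days/month).

    Raises :class:`ValueError` for negative spans.
    """
    if day_span < 0:
        raise ValueError(f"day span must be non-negative, got {day_span}")
    return day_span / DAYS_PER_MONTH


@dataclass(frozen=True)
class TargetLesionMeasurement:
    """One lesion measured on one CT: longest diameter and mean arterial HU."""

    lesion_id: str
    organ: str
    day: int
    diameter: float          # mm, >= 0
    attenuation: float | None = None   # mean HU, None when not assessable
    is_new: bool = False

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise CohortValidationError(
                f"lesion {self.lesion_id}: diameter must be >= 0, got {self.diameter}"
            )
        if self.attenuation is not None and math.isnan(self.attenuation):
            object.__setattr__(self, "attenuation", None)
        if self.is_new and self.day <= 0:
            raise CohortValidationError(
                f"lesion {self.lesion_id}: a new lesion cannot appear at baseline (day {self.day})"
            )


@dataclass
class Assessment:
    """All lesion measurements of one patient on one CT date."""

    patient_id: str
    day: int
    measurements: list[TargetLesionMeasurement]
    unequivocal_nontarget_progression: bool = False

    def __post_init__(self) -> None:
        ids = [m.lesion_id for m in self.measurements]
        if len(ids) != len(set(ids)):
            raise CohortValidationError(
                f"patient {self.patient_id}, day {self.day}: duplicate lesion ids"
            )
        for m in self.measurements:
            if m.day != self.day:
                raise CohortValidationError(
                    f"patient {self.patient_id}: measurement day {m.day} != assessment day {self.day}"
                )

    def lesion(self, lesion_id: str) -> TargetLesionMeasurement | None:
        for m in self.measurements:
            if m.lesion_id == lesion_id:
                return m
        return None


@dataclass
class PatientRecord:
    """Time-ordered assessments plus the survival outcome of one patient."""

    patient_id: str
    assessments: list[Assessment]
    death_day: int | None = None
    last_followup_day: int = 0

    def __post_init__(self) -> None:
        days = [a.day for a in self.assessments]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: assessments must be strictly increasing in day"
            )
        if days and self.last_followup_day < days[-1]:
            raise CohortValidationError(
                f"patient {self.patient_id}: last_followup_day {self.last_followup_day} "
                f"precedes last assessment day {days[-1]}"
            )
        if self.death_day is not None and self.death_day < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: death_day must be >= 0"
            )

    @property
    def baseline(self) -> Assessment | None:
        """The pre-treatment scan: largest non-positive assessment day."""
        pre = [a for a in self.assessments if a.day <= 0]
        return pre[-1] if pre else None

    @property
    def followups(self) -> list[Assessment]:
        base = self.baseline
        if base is None:
            return [a for a in self.assessments if a.day > 0]
        return [a for a in self.assessments if a.day > base.day]


@dataclass
class Cohort:
    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise CohortValidationError("duplicate patient_ids in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass(frozen=True)
class ValidationIssue:
    patient_id: str
    code: str
    message: str


def _require_columns(df: pd.DataFrame, required: list[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _as_bool(value) -> bool:
    return bool(int(value))


def load_cohort(measurements_path, outcomes_path) -> Cohort:
    """Read the measurements and outcomes CSVs into a validated :class:`Cohort`.

    Rows are grouped by patient and assessment day; ordering of the input rows
    is irrelevant.  Unparseable numerics raise :class:`SchemaError`; duplicate
    (patient, day, lesion) rows raise :class:`CohortValidationError`.
    """
    meas = pd.read_csv(measurements_path, dtype={"patient_id": str, "lesion_id": str})
    _require_columns(meas, MEASUREMENT_COLUMNS, str(measurements_path))
    out = pd.read_csv(outcomes_path, dtype={"patient_id": str})
    _require_columns(out, OUTCOME_COLUMNS, str(outcomes_path))

    for col in ("day", "diameter_mm", "attenuation_hu", "is_new", "nontarget_progression"):
        try:
            meas[col] = pd.to_numeric(meas[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{measurements_path}: column {col!r} contains unparseable values: {exc}"
            ) from exc

    dup = meas.duplicated(subset=["patient_id", "day", "lesion_id"])
    if dup.any():
        row = meas[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate measurement row for patient {row['patient_id']}, "
            f"day {int(row['day'])}, lesion {row['lesion_id']}"
        )

    outcomes = {}
    for _, row in out.iterrows():
        pid = str(row["patient_id"])
        if pid in outcomes:
            raise CohortValidationError(f"duplicate outcome row for patient {pid}")
        death = row["death_day"]
        death_day = None if pd.isna(death) else int(death)
        outcomes[pid] = (death_day, int(row["last_followup_day"]))

    patients = []
    for pid in sorted(meas["patient_id"].unique()):
        rows = meas[meas["patient_id"] == pid]
        assessments = []
        for day in sorted(rows["day"].unique()):
            at = rows[rows["day"] == day].sort_values("lesion_id")
            lesions = [
                TargetLesionMeasurement(
                    lesion_id=str(r["lesion_id"]),
                    organ=str(r["organ"]),
                    day=int(day),
                    diameter=float(r["diameter_mm"]),
                    attenuation=None if pd.isna(r["attenuation_hu"]) else float(r["attenuation_hu"]),
                    is_new=_as_bool(r["is_new"]),
                )
                for _, r in at.iterrows()
            ]
            ntp = bool(at["nontarget_progression"].astype(int).max())
            assessments.append(
                Assessment(
                    patient_id=pid,
                    day=int(day),
                    measurements=lesions,
                    unequivocal_nontarget_progression=ntp,
                )
            )
        if pid not in outcomes:
            raise SchemaError(f"patient {pid} has measurements but no outcomes row")
        death_day, last_fu = outcomes[pid]
        last_fu = max(last_fu, assessments[-1].day)
        patients.append(
            PatientRecord(
                patient_id=pid,
                assessments=assessments,
                death_day=death_day,
                last_followup_day=last_fu,
            )
        )
    return Cohort(patients=patients)


def write_cohort(cohort: Cohort, measurements_path, outcomes_path) -> None:
    """Write a cohort back to the two-CSV schema (inverse of :func:`load_cohort`)."""
    mrows = []
    orows = []
    for p in cohort.patients:
        for a in p.assessments:
            for m in a.measurements:
                mrows.append(
                    {
                        "patient_id": p.patient_id,
                        "day": a.day,
                        "lesion_id": m.lesion_id,
                        "organ": m.organ,
                        "diameter_mm": m.diameter,
                        "attenuation_hu": "" if m.attenuation is None else m.attenuation,
                        "is_new": int(m.is_new),
                        "nontarget_progression": int(a.unequivocal_nontarget_progression),
                    }
                )
        orows.append(
            {
                "patient_id": p.patient_id,
                "death_day": "" if p.death_day is None else p.death_day,
                "last_followup_day": p.last_followup_day,
            }
        )
    pd.DataFrame(mrows, columns=MEASUREMENT_COLUMNS).to_csv(measurements_path, index=False)
    pd.DataFrame(orows, columns=OUTCOME_COLUMNS).to_csv(outcomes_path, index=False)


def validate_cohort(cohort: Cohort) -> list[ValidationIssue]:
    """Flag patients unusable for response analysis (reports, never raises).

    Mirrors the protocol exclusions of imaging-based response studies:
    a baseline scan is required within the 4 weeks before treatment, it must
    show measurable disease, and at least one on-treatment scan must exist.
    """
    issues: list[ValidationIssue] = []
    for p in cohort.patients:
        base = p.baseline
        if base is None:
            issues.append(
                ValidationIssue(p.patient_id, "no_baseline", "no pre-treatment baseline assessment")
            )
        else:
            if base.day < -BASELINE_WINDOW_DAYS:
                issues.append(
                    ValidationIssue(
                        p.patient_id,
                        "baseline_outside_window",
                        f"baseline at day {base.day} outside 4-week window [-28, 0]",
                    )
                )
            if all(m.diameter == 0 for m in base.measurements):
                issues.append(
                    ValidationIssue(
                        p.patient_id, "no_measurable_disease", "no measurable baseline lesion"
                    )
                )
        if len(p.assessments) < 2:
            issues.append(
                ValidationIssue(
                    p.patient_id,
                    "insufficient_followup_imaging",
                    "fewer than two assessments (insufficient follow-up imaging)",
                )
            )
    return issues


def exclude_flagged(cohort: Cohort, issues: list[ValidationIssue]) -> Cohort:
    """Strict-mode filter: drop every patient mentioned in *issues*."""
    bad = {i.patient_id for i in issues}
    return Cohort(
        patients=[p for p in cohort.patients if p.patient_id not in bad],
        metadata=dict(cohort.metadata),
    )
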