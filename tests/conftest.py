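"""Shared builders for hand-crafted single-lesion patients and cohorts."""

from __future__ import annotations

import pytest

from respkit import Assessment, Cohort, PatientRecord, TargetLesionMeasurement


def make_patient(
    pid: str,
    series: list[tuple[int, float, float | None]],
    death_day: int | None = None,
    last_followup_day: int | None = None,
    new_lesion_days: tuple[int, ...] = (),
    organ: str = "liver",
) -> PatientRecord:
    """One-lesion patient from (day, diameter_mm, attenuation_hu) triples.

    The first triple is the baseline scan.  Days in *new_lesion_days* get an
    extra 10-mm lesion flagged as new.
    """
    assessments = []
    for day, diam, hu in series:
        lesions = [
            TargetLesionMeasurement(
                lesion_id="L1", organ=organ, day=day, diameter=diam, attenuation=hu
            )
        ]
        if day in new_lesion_days:
            lesions.append(
                TargetLesionMeasurement(
                    lesion_id="NL1", organ=organ, day=day, diameter=10.0,
                    attenuation=100.0, is_new=True,
                )
            )
        assessments.append(Assessment(patient_id=pid, day=day, measurements=lesions))
    last = last_followup_day if last_followup_day is not None else assessments[-1].day
    return PatientRecord(
        patient_id=pid,
        assessments=assessments,
        death_day=death_day,
        last_followup_day=last,
    )


@pytest.fixture
def simple_cohort() -> Cohort:
    """Three patients: a responder, a stable patient, a progressor."""
    return Cohort(
        patients=[
            make_patient("A", [(0, 100, 110), (120, 60, 80), (240, 55, 75)]),
            make_patient("B", [(0, 50, 100), (130, 51, 99), (250, 52, 98)]),
            make_patient("C", [(0, 40, 105), (125, 52, 104)], death_day=400,
                         last_followup_day=400),
        ]
    )
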