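"""Criterion-specific PFS and OS records derived from classified series.

PFS runs from treatment start to the first progression under the given
criterion or death, whichever comes first; event-free patients are censored
at their last adequate tumour assessment (not last contact), the standard
convention for imaging-based endpoints.  OS runs to death or censoring at
last follow-up.  All times are reported in months.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import DataIntegrityError, PatientRecord, months
from .response import ResponseSeries

__all__ = ["SurvivalRecord", "BivariatePair", "derive_pfs", "derive_os", "pair_endpoints"]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float            # months
    event: bool
    endpoint: str          # PFS_RECIST | PFS_CHOI | OS

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.patient_id}: survival time must be >= 0")


@dataclass
class BivariatePair:
    patient_id: str
    pfs_time: float
    pfs_event: bool
    os_time: float
    os_event: bool
    clipped: bool = False


def derive_pfs(series: ResponseSeries, patient: PatientRecord) -> SurvivalRecord:
    """Event at first PD or death (whichever first); else censored at last scan."""
    pd_day = series.first_pd_day
    candidates = [d for d in (pd_day, patient.death_day) if d is not None]
    endpoint = f"PFS_{series.criterion}"
    if candidates:
        return SurvivalRecord(
            patient_id=patient.patient_id,
            time=months(min(candidates)),
            event=True,
            endpoint=endpoint,
        )
    last_scan = patient.assessments[-1].day if patient.assessments else 0
    return SurvivalRecord(
        patient_id=patient.patient_id,
        time=months(max(last_scan, 0)),
        event=False,
        endpoint=endpoint,
    )


def derive_os(patient: PatientRecord) -> SurvivalRecord:
    if patient.death_day is not None:
        return SurvivalRecord(patient.patient_id, months(patient.death_day), True, "OS")
    return SurvivalRecord(patient.patient_id, months(patient.last_followup_day), False, "OS")


def pair_endpoints(pfs: SurvivalRecord, os: SurvivalRecord) -> BivariatePair:
    """Join one patient's PFS and OS, enforcing PFS <= OS.

    A PFS censoring time beyond OS is clipped to the OS time with the OS
    event status (a death is also a PFS event); a PFS *event* recorded after
    an OS event is inconsistent and raises.
    """
    if pfs.patient_id != os.patient_id:
        raise ValueError("records belong to different patients")
    pfs_time, pfs_event, clipped = pfs.time, pfs.event, False
    if pfs_time > os.time:
        if pfs.event and os.event:
            raise DataIntegrityError(
                f"{pfs.patient_id}: PFS event at {pfs.time:.2f} mo after OS event at {os.time:.2f} mo"
            )
        if not pfs.event:
            pfs_time, pfs_event, clipped = os.time, os.event, True
        # pfs event after an os *censoring* time: keep as recorded is impossible
        # (progression cannot be observed after follow-up ends)
        else:
            raise DataIntegrityError(
                f"{pfs.patient_id}: PFS event at {pfs.time:.2f} mo beyond follow-up {os.time:.2f} mo"
            )
    return BivariatePair(
        patient_id=pfs.patient_id,
        pfs_time=pfs_time,
        pfs_event=pfs_event,
        os_time=os.time,
        os_event=os.event,
        clipped=clipped,
    )
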