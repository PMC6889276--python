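"""RECIST v1.1 and Choi response classification from target-lesion series.

Both engines work on the sum of target-lesion longest diameters; the Choi
engine additionally uses the unweighted mean of the available target-lesion
arterial-phase attenuations (HU).  Thresholds follow the standard
definitions: RECIST PR at <= -30% vs baseline, PD at >= +20% vs nadir with a
>= 5 mm absolute increase; Choi PR at <= -10% size or <= -15% HU vs
baseline, PD at >= +10% size growth without the attenuation response.  New
lesions and unequivocal non-target progression force PD under both criteria,
and a series terminates at its first PD.

Threshold comparisons are inclusive: a -30.0% change is a RECIST PR; a
+20.0% change with a +5.0 mm increase is a RECIST PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    Assessment,
    Cohort,
    DataIntegrityError,
    PatientRecord,
)

__all__ = [
    "CriterionConfig",
    "TimepointResponse",
    "ResponseSeries",
    "TransitionTable",
    "select_target_lesions",
    "sum_of_diameters",
    "mean_attenuation",
    "classify_recist",
    "classify_choi",
    "response_at",
    "transition_table",
    "transition_table_from_marginals",
    "cohens_kappa",
]

LABELS = ("CR", "PR", "SD", "PD")
TABLE_CATEGORIES = ("PR", "SD", "PD")   # CR folded into PR for agreement tables


@dataclass(frozen=True)
class CriterionConfig:
    """Classification thresholds (percent changes) and evaluation window."""

    recist_pr_threshold: float = -30.0      # % vs baseline sum
    recist_pd_threshold: float = 20.0       # % vs nadir sum
    recist_pd_abs_mm: float = 5.0           # absolute mm increase vs nadir
    choi_size_pr_threshold: float = -10.0   # % vs baseline sum
    choi_hu_pr_threshold: float = -15.0     # % vs baseline mean HU
    choi_pd_threshold: float = 10.0         # % size increase vs reference
    reference_policy_choi_pd: str = "baseline"   # or "nadir"
    landmark_day: int = 183                 # ~6 months
    window_days: int = 60

    def __post_init__(self) -> None:
        if self.reference_policy_choi_pd not in ("baseline", "nadir"):
            raise ValueError("reference_policy_choi_pd must be 'baseline' or 'nadir'")


@dataclass
class TimepointResponse:
    day: int
    label: str
    sum_diameters: float
    mean_hu: float | None
    pct_change_size_vs_baseline: float
    pct_change_size_vs_nadir: float
    pct_change_hu_vs_baseline: float | None
    trigger: str = ""


@dataclass
class ResponseSeries:
    patient_id: str
    criterion: str                    # "RECIST" | "CHOI"
    baseline_sum: float
    baseline_hu: float | None
    responses: list[TimepointResponse] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def first_pd_day(self) -> int | None:
        for r in self.responses:
            if r.label == "PD":
                return r.day
        return None


def select_target_lesions(
    baseline: Assessment, max_total: int = 5, max_per_organ: int = 2
) -> list[str]:
    """Pick target lesions at baseline: largest diameters, capped per organ.

    Ordering is deterministic: descending diameter, ties broken by organ
    label then lesion_id (lexicographic).  Greedy selection under a
    per-organ cap plus an overall cap maximises the total selected diameter.
    """
    measurable = [m for m in baseline.measurements if m.diameter > 0]
    if not measurable:
        raise DataIntegrityError(
            f"patient {baseline.patient_id}: no measurable disease at baseline"
        )
    measurable.sort(key=lambda m: (-m.diameter, m.organ, m.lesion_id))
    chosen: list[str] = []
    per_organ: dict[str, int] = {}
    for m in measurable:
        if len(chosen) >= max_total:
            break
        if per_organ.get(m.organ, 0) >= max_per_organ:
            continue
        chosen.append(m.lesion_id)
        per_organ[m.organ] = per_organ.get(m.organ, 0) + 1
    return chosen


def sum_of_diameters(assessment: Assessment, target_ids: list[str]) -> float:
    """Sum of the target-lesion diameters at this assessment (mm).

    Every baseline target must be recorded at every follow-up (a vanished
    lesion as 0 mm); a missing row is a data-integrity error.
    """
    total = 0.0
    for lid in target_ids:
        m = assessment.lesion(lid)
        if m is None:
            raise DataIntegrityError(
                f"patient {assessment.patient_id}, day {assessment.day}: "
                f"target lesion {lid} has no measurement row"
            )
        total += m.diameter
    return total


def mean_attenuation(assessment: Assessment, target_ids: list[str]) -> float | None:
    """Unweighted mean HU over target lesions with an attenuation value."""
    values = []
    for lid in target_ids:
        m = assessment.lesion(lid)
        if m is not None and m.attenuation is not None:
            values.append(m.attenuation)
    return float(np.mean(values)) if values else None


def _pct(value: float, reference: float) -> float:
    return 100.0 * (value - reference) / reference


def _has_new_lesion(assessment: Assessment) -> bool:
    return any(m.is_new for m in assessment.measurements)


def classify_recist(patient: PatientRecord, config: CriterionConfig | None = None) -> ResponseSeries:
    """Size-only classification against baseline (PR/CR) and nadir (PD)."""
    config = config or CriterionConfig()
    base = patient.baseline
    if base is None:
        raise DataIntegrityError(f"patient {patient.patient_id}: no baseline assessment")
    targets = select_target_lesions(base)
    baseline_sum = sum_of_diameters(base, targets)
    baseline_hu = mean_attenuation(base, targets)
    series = ResponseSeries(
        patient_id=patient.patient_id,
        criterion="RECIST",
        baseline_sum=baseline_sum,
        baseline_hu=baseline_hu,
    )
    nadir = baseline_sum
    for a in patient.followups:
        s = sum_of_diameters(a, targets)
        hu = mean_attenuation(a, targets)
        vs_base = _pct(s, baseline_sum)
        vs_nadir = _pct(s, nadir) if nadir > 0 else float("inf")
        abs_vs_nadir = s - nadir
        label, trigger = "SD", ""
        if _has_new_lesion(a):
            label, trigger = "PD", "new_lesion"
        elif a.unequivocal_nontarget_progression:
            label, trigger = "PD", "nontarget_progression"
        elif vs_nadir >= config.recist_pd_threshold and abs_vs_nadir >= config.recist_pd_abs_mm:
            label, trigger = "PD", "size_increase"
        elif s == 0:
            label, trigger = "CR", "sum_zero"
        elif vs_base <= config.recist_pr_threshold:
            label, trigger = "PR", "size_drop"
        series.responses.append(
            TimepointResponse(
                day=a.day,
                label=label,
                sum_diameters=s,
                mean_hu=hu,
                pct_change_size_vs_baseline=vs_base,
                pct_change_size_vs_nadir=vs_nadir,
                pct_change_hu_vs_baseline=(
                    _pct(hu, baseline_hu) if hu is not None and baseline_hu else None
                ),
                trigger=trigger,
            )
        )
        if label == "PD":
            break
        nadir = min(nadir, s)
    return series


def classify_choi(patient: PatientRecord, config: CriterionConfig | None = None) -> ResponseSeries:
    """Size-or-attenuation classification: a >= 15% HU drop is a response.

    The PD definition deliberately excludes tumours that grow >= 10% but
    satisfy the attenuation PR clause: growth with sustained hypo-attenuation
    remains a response.  Missing follow-up HU disables the attenuation clause
    for that timepoint ("hu_unavailable"); a missing baseline HU degrades the
    whole series to size-only classification and flags the patient.
    """
    config = config or CriterionConfig()
    base = patient.baseline
    if base is None:
        raise DataIntegrityError(f"patient {patient.patient_id}: no baseline assessment")
    targets = select_target_lesions(base)
    baseline_sum = sum_of_diameters(base, targets)
    baseline_hu = mean_attenuation(base, targets)
    series = ResponseSeries(
        patient_id=patient.patient_id,
        criterion="CHOI",
        baseline_sum=baseline_sum,
        baseline_hu=baseline_hu,
    )
    if baseline_hu is None:
        series.flags.append("baseline_hu_missing:size_only")
    nadir = baseline_sum
    for a in patient.followups:
        s = sum_of_diameters(a, targets)
        hu = mean_attenuation(a, targets)
        vs_base = _pct(s, baseline_sum)
        reference = baseline_sum if config.reference_policy_choi_pd == "baseline" else nadir
        vs_ref = _pct(s, reference) if reference > 0 else float("inf")
        hu_pct = None
        if hu is not None and baseline_hu:
            hu_pct = _pct(hu, baseline_hu)
        hu_pr = hu_pct is not None and hu_pct <= config.choi_hu_pr_threshold
        size_pr = vs_base <= config.choi_size_pr_threshold
        label, trigger = "SD", ""
        if _has_new_lesion(a):
            label, trigger = "PD", "new_lesion"
        elif a.unequivocal_nontarget_progression:
            label, trigger = "PD", "nontarget_progression"
        elif s == 0:
            label, trigger = "CR", "sum_zero"
        elif hu_pr or size_pr:
            label, trigger = "PR", ("hu_drop" if hu_pr else "size_drop")
        elif vs_ref >= config.choi_pd_threshold:
            label, trigger = "PD", "size_increase"
        if hu_pct is None and baseline_hu is not None:
            trigger = (trigger + ";" if trigger else "") + "hu_unavailable"
        series.responses.append(
            TimepointResponse(
                day=a.day,
                label=label,
                sum_diameters=s,
                mean_hu=hu,
                pct_change_size_vs_baseline=vs_base,
                pct_change_size_vs_nadir=_pct(s, nadir) if nadir > 0 else float("inf"),
                pct_change_hu_vs_baseline=hu_pct,
                trigger=trigger,
            )
        )
        if label == "PD":
            break
        nadir = min(nadir, s)
    return series


def response_at(series: ResponseSeries, landmark_day: int, window_days: int) -> str | None:
    """Label at the assessment closest to *landmark_day* within the window.

    A series that terminated with PD on or before landmark + window yields
    PD (progression is carried forward); otherwise None when no assessment
    falls inside the window.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    pd_day = series.first_pd_day
    if pd_day is not None and pd_day <= landmark_day + window_days:
        return "PD"
    in_window = [r for r in series.responses if abs(r.day - landmark_day) <= window_days]
    if not in_window:
        return None
    closest = min(in_window, key=lambda r: (abs(r.day - landmark_day), r.day))
    return closest.label


@dataclass
class TransitionTable:
    """3x3 cross-tabulation, rows = RECIST {PR, SD, PD}, cols = Choi {PR, SD, PD}."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("transition table must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("transition table entries must be non-negative")
        if self.counts.sum() != self.n:
            raise ValueError("transition table entries must sum to n")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=[f"RECIST_{c}" for c in TABLE_CATEGORIES],
            columns=[f"CHOI_{c}" for c in TABLE_CATEGORIES],
        )


def _fold_cr(label: str) -> str:
    return "PR" if label == "CR" else label


def transition_table(
    cohort: Cohort,
    landmark_day: int | None = None,
    window_days: int | None = None,
    config: CriterionConfig | None = None,
) -> TransitionTable:
    """RECIST x Choi agreement at a landmark over patients with both labels."""
    config = config or CriterionConfig()
    landmark_day = config.landmark_day if landmark_day is None else landmark_day
    window_days = config.window_days if window_days is None else window_days
    counts = np.zeros((3, 3), dtype=int)
    idx = {c: i for i, c in enumerate(TABLE_CATEGORIES)}
    for p in cohort.patients:
        r = response_at(classify_recist(p, config), landmark_day, window_days)
        c = response_at(classify_choi(p, config), landmark_day, window_days)
        if r is None or c is None:
            continue
        counts[idx[_fold_cr(r)], idx[_fold_cr(c)]] += 1
    return TransitionTable(counts=counts, n=int(counts.sum()))


def transition_table_from_marginals(
    recist_pct: tuple[float, float, float],
    choi_pct: tuple[float, float, float],
    n: int,
    sd_to_pr: int,
    sd_to_pd: int,
) -> TransitionTable:
    """Reconstruct the unique 3x3 table from marginals plus two SD-row cells.

    The reconstruction uses the deterministic implication that a RECIST PR
    (>= 30% shrinkage) always satisfies the 10% Choi size criterion, so the
    RECIST-PR row has zero off-diagonal mass; the SD row is fixed by the two
    given cells, and the PD row follows from the column margins.  Percent
    marginals are converted to counts by nearest-integer rounding of pct/100*n.
    """
    recist = [round(p / 100.0 * n) for p in recist_pct]
    choi = [round(p / 100.0 * n) for p in choi_pct]
    if sum(recist) != n or sum(choi) != n:
        raise ValueError("rounded marginals do not sum to n")
    table = np.zeros((3, 3), dtype=int)
    table[0] = (recist[0], 0, 0)
    table[1] = (sd_to_pr, recist[1] - sd_to_pr - sd_to_pd, sd_to_pd)
    table[2] = np.array(choi) - table[:2].sum(axis=0)
    if (table < 0).any():
        raise ValueError("inconsistent marginals/cells: negative cell in reconstruction")
    return TransitionTable(counts=table, n=n)


def cohens_kappa(table: TransitionTable | np.ndarray) -> float:
    """Unweighted Cohen's kappa of a square agreement table.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o = trace/n
    and chance agreement p_e from the marginal products.
    """
    counts = table.counts if isinstance(table, TransitionTable) else np.asarray(table, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("kappa undefined for an empty table")
    p_o = np.trace(counts) / n
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("kappa undefined: degenerate margins with imperfect agreement")
    return float((p_o - p_e) / (1.0 - p_e))
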