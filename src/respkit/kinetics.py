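"""Tumour growth and attenuation kinetics: TG, TGR, DVR, AVR.

TG is the log-volume growth rate per month, TG = 3*ln(Dt/D0)/t, where the
factor 3 converts a diameter ratio to a volume ratio under the spherical
approximation; TGR = 100*(exp(TG) - 1) expresses it as percent volume change
per month.  DVR and AVR are the plain relative changes in summed diameter
and mean attenuation divided by the elapsed time, in percent per month.
Natural logarithm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, months
from .response import CriterionConfig, mean_attenuation, select_target_lesions, sum_of_diameters

__all__ = [
    "KineticsRecord",
    "tumor_growth",
    "tgr",
    "dvr",
    "avr",
    "variance_explained",
    "rank_correlation",
    "cohort_kinetics",
]


@dataclass(frozen=True)
class KineticsRecord:
    patient_id: str
    day_from: int
    day_to: int
    D0: float
    Dt: float
    HU0: float | None
    HUt: float | None
    TG: float | None
    TGR: float | None
    DVR: float | None
    AVR: float | None
    interval: str = "from_baseline"   # or "previous_ct"


def tumor_growth(D0: float, Dt: float, t: float) -> float:
    """TG = 3*ln(Dt/D0)/t for diameters in mm and t in months."""
    if D0 <= 0 or Dt <= 0:
        raise ValueError(f"diameters must be positive, got D0={D0}, Dt={Dt}")
    if t <= 0:
        raise ValueError(f"elapsed time must be positive, got t={t}")
    return 3.0 * math.log(Dt / D0) / t


def tgr(TG: float) -> float:
    """Percent volume change per month: 100*(exp(TG) - 1)."""
    if not math.isfinite(TG):
        raise ValueError("TG must be finite")
    return 100.0 * (math.exp(TG) - 1.0)


def _variation_rate(x0: float, xt: float, t: float, name: str) -> float:
    if x0 == 0:
        raise ValueError(f"{name}: reference value must be nonzero")
    if t <= 0:
        raise ValueError(f"{name}: elapsed time must be positive, got t={t}")
    return 100.0 * (xt - x0) / x0 / t


def dvr(D0: float, Dt: float, t: float) -> float:
    """Diameter variation rate: percent diameter change per month."""
    return _variation_rate(D0, Dt, t, "dvr")


def avr(HU0: float, HUt: float, t: float) -> float:
    """Attenuation variation rate: percent HU change per month."""
    return _variation_rate(HU0, HUt, t, "avr")


def variance_explained(x, y) -> float:
    """Squared Pearson correlation over complete (finite) pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def rank_correlation(x, y) -> float:
    """Kendall's tau-b over complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    tau, _ = stats.kendalltau(x, y)
    if not np.isfinite(tau):
        raise ValueError("Kendall's tau undefined (all ties)")
    return float(tau)


def cohort_kinetics(cohort: Cohort, config: CriterionConfig | None = None) -> pd.DataFrame:
    """Per-interval kinetics for every patient: baseline->scan and scan->scan.

    Time origin for the "from_baseline" rows is treatment start (day 0), not
    the baseline scan day; "previous_ct" rows use the preceding scan as the
    origin.  TG/TGR require positive diameters at both ends and are left
    missing otherwise, as are HU rates when attenuation is unavailable.
    """
    config = config or CriterionConfig()
    rows: list[KineticsRecord] = []
    for p in cohort.patients:
        base = p.baseline
        if base is None:
            continue
        targets = select_target_lesions(base)
        prev_day, prev_sum, prev_hu = 0, sum_of_diameters(base, targets), mean_attenuation(base, targets)
        d0, hu0 = prev_sum, prev_hu
        for a in p.followups:
            s = sum_of_diameters(a, targets)
            hu = mean_attenuation(a, targets)
            for (df, dto, x0, xt, h0, ht, kind) in (
                (0, a.day, d0, s, hu0, hu, "from_baseline"),
                (prev_day, a.day, prev_sum, s, prev_hu, hu, "previous_ct"),
            ):
                t = months(dto - df)
                tg = tumor_growth(x0, xt, t) if x0 > 0 and xt > 0 and t > 0 else None
                rows.append(
                    KineticsRecord(
                        patient_id=p.patient_id,
                        day_from=df,
                        day_to=dto,
                        D0=x0,
                        Dt=xt,
                        HU0=h0,
                        HUt=ht,
                        TG=tg,
                        TGR=tgr(tg) if tg is not None else None,
                        DVR=dvr(x0, xt, t) if x0 > 0 and t > 0 else None,
                        AVR=avr(h0, ht, t) if h0 not in (None, 0) and ht is not None and t > 0 else None,
                        interval=kind,
                    )
                )
            prev_day, prev_sum, prev_hu = a.day, s, hu
    return pd.DataFrame([r.__dict__ for r in rows])
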