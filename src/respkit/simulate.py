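"""Synthetic cohorts with the structure of slow-growing, liver-dominant,
hypervascular metastatic disease under an antiangiogenic drug.

The generator emulates the features the downstream analyses rely on: a few
target lesions per patient (liver-dominant), log-normal baseline diameters,
arterial-phase attenuation around 110 HU, a responder phenotype whose
attenuation drops early (>= 15%) while diameters barely move, a deep-shrink
subset that reaches the 30% size threshold, a discordant phenotype that
grows past +10% while hypo-attenuating (Choi PR, RECIST progression), CT
scans every ~4 months with jitter, new lesions at progression, death after
progression, and independent right-censoring.  All randomness flows from a
single seed with per-patient substreams, so output is byte-identical across
runs.

It also ships an exact Clayton-copula sampler for (PFS, OS) pairs used to
exercise the dependence estimator against its closed form tau = theta/(theta+2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import (
    Assessment,
    Cohort,
    DAYS_PER_MONTH,
    PatientRecord,
    TargetLesionMeasurement,
)
from .endpoints import BivariatePair

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_clayton_pairs"]

_ORGANS = ("liver", "lymph_node", "lung", "peritoneum", "other")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters (rates per month, days for scheduling)."""

    n_patients: int = 85
    seed: int | None = None

    # lesion geography: counts 1..6, liver-weighted
    lesion_count_probs: tuple[float, ...] = (0.20, 0.25, 0.25, 0.15, 0.10, 0.05)
    organ_probs: tuple[float, ...] = (0.70, 0.12, 0.06, 0.06, 0.06)
    liver_first_prob: float = 0.94

    # baseline marginals
    baseline_diameter_log_mean: float = math.log(25.0)   # ln mm
    baseline_diameter_log_sd: float = 0.5
    baseline_hu_mean: float = 110.0
    baseline_hu_sd: float = 15.0

    # phenotypes
    responder_fraction: float = 0.42
    deep_response_fraction: float = 0.33        # among responders
    discordant_pd_fraction: float = 0.10        # growing but hypo-attenuating

    # attenuation response (% change at first on-treatment scan, sustained)
    hu_drop_mean: float = -25.0
    hu_drop_sd: float = 8.0

    # log-diameter rates, per month
    growth_rate_mean: float = 0.020
    growth_rate_sd: float = 0.012
    discordant_growth_mean: float = 0.025
    discordant_growth_sd: float = 0.005
    shrink_rate_deep_mean: float = -0.080
    shrink_rate_deep_sd: float = 0.015
    shrink_rate_shallow_mean: float = -0.015
    shrink_rate_shallow_sd: float = 0.008
    shrink_duration_mean: float = 9.0           # months
    shrink_duration_sd: float = 2.0
    regrowth_rate_mean: float = 0.008
    regrowth_rate_sd: float = 0.004
    lesion_rate_jitter_sd: float = 0.002   # per-lesion spread around the patient rate

    # scheduling and follow-up (days)
    baseline_day_min: int = -21
    scan_interval_days: float = 120.0
    scan_jitter_days: float = 21.0
    followup_horizon_days: int = 1100

    # events
    new_lesion_fraction: float = 0.30
    post_progression_death_mean_days: float | None = 450.0
    background_death_mean_days: float | None = 2500.0
    censoring_mean_days: float | None = 1500.0

    # measurement noise
    diameter_noise_sd: float = 1.5              # mm
    hu_noise_sd: float = 5.0                    # HU

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "deep_response_fraction",
                     "discordant_pd_fraction", "new_lesion_fraction", "liver_first_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.lesion_count_probs) - 1.0) > 1e-9:
            raise ValueError("lesion_count_probs must sum to 1")
        if abs(sum(self.organ_probs) - 1.0) > 1e-9:
            raise ValueError("organ_probs must sum to 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _exp_or_none(rng: np.random.Generator, mean: float | None) -> float:
    if mean is None or not math.isfinite(mean):
        return math.inf
    return float(rng.exponential(mean))


@dataclass
class _Phenotype:
    kind: str                 # "responder" | "discordant" | "nonresponder"
    hu_drop_pct: float        # 0 when attenuation does not respond
    shrink_rate: float        # per-month log-diameter, phase 1 (responders)
    shrink_duration: float    # months
    growth_rate: float        # per-month log-diameter, growth/regrowth phase


def _draw_phenotype(rng: np.random.Generator, cfg: SimulationConfig) -> _Phenotype:
    u = rng.random()
    if u < cfg.discordant_pd_fraction:
        return _Phenotype(
            kind="discordant",
            hu_drop_pct=float(rng.normal(cfg.hu_drop_mean, cfg.hu_drop_sd)),
            shrink_rate=0.0,
            shrink_duration=0.0,
            growth_rate=max(0.001, float(rng.normal(cfg.discordant_growth_mean, cfg.discordant_growth_sd))),
        )
    if rng.random() < cfg.responder_fraction:
        deep = rng.random() < cfg.deep_response_fraction
        rate = (
            rng.normal(cfg.shrink_rate_deep_mean, cfg.shrink_rate_deep_sd)
            if deep
            else rng.normal(cfg.shrink_rate_shallow_mean, cfg.shrink_rate_shallow_sd)
        )
        return _Phenotype(
            kind="responder",
            hu_drop_pct=float(rng.normal(cfg.hu_drop_mean, cfg.hu_drop_sd)),
            shrink_rate=min(rate, 0.0),
            shrink_duration=max(1.0, float(rng.normal(cfg.shrink_duration_mean, cfg.shrink_duration_sd))),
            growth_rate=max(0.0, float(rng.normal(cfg.regrowth_rate_mean, cfg.regrowth_rate_sd))),
        )
    return _Phenotype(
        kind="nonresponder",
        hu_drop_pct=0.0,
        shrink_rate=0.0,
        shrink_duration=0.0,
        growth_rate=float(rng.normal(cfg.growth_rate_mean, cfg.growth_rate_sd)),
    )


def _log_diameter_offset(ph: _Phenotype, t_months: float) -> float:
    """Cumulative log-diameter change at t months after treatment start."""
    if t_months <= 0:
        return 0.0
    if ph.kind == "responder":
        shrink_t = min(t_months, ph.shrink_duration)
        regrow_t = max(0.0, t_months - ph.shrink_duration)
        return ph.shrink_rate * shrink_t + ph.growth_rate * regrow_t
    return ph.growth_rate * t_months


def _progression_months(ph: _Phenotype) -> float:
    """First time the true diameter sum exceeds its nadir by 20%."""
    if ph.growth_rate <= 0:
        return math.inf
    lead = math.log(1.2) / ph.growth_rate
    if ph.kind == "responder":
        return ph.shrink_duration + lead
    return lead


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a cohort (measurements and outcomes) under *config*.

    Deterministic for a fixed seed: patient i draws from an independent
    substream keyed by (seed, i).
    """
    cfg = config or SimulationConfig()
    master = np.random.default_rng(cfg.seed)
    # one fixed key per run so seed=None still yields internally consistent substreams
    run_key = int(master.integers(0, 2**31 - 1)) if cfg.seed is None else int(cfg.seed)

    patients = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng([run_key, i])
        pid = f"P{i + 1:03d}"
        ph = _draw_phenotype(rng, cfg)

        n_lesions = 1 + int(rng.choice(len(cfg.lesion_count_probs), p=cfg.lesion_count_probs))
        organs = []
        for j in range(n_lesions):
            if j == 0 and rng.random() < cfg.liver_first_prob:
                organs.append("liver")
            else:
                organs.append(str(rng.choice(_ORGANS, p=cfg.organ_probs)))
        base_diams = np.exp(
            rng.normal(cfg.baseline_diameter_log_mean, cfg.baseline_diameter_log_sd, n_lesions)
        )
        base_hus = rng.normal(cfg.baseline_hu_mean, cfg.baseline_hu_sd, n_lesions)
        lesion_jitter = rng.normal(0.0, cfg.lesion_rate_jitter_sd, n_lesions)

        baseline_day = int(rng.integers(cfg.baseline_day_min, 1))
        progression_day = _progression_months(ph) * DAYS_PER_MONTH

        death = _exp_or_none(rng, cfg.background_death_mean_days)
        if math.isfinite(progression_day) and cfg.post_progression_death_mean_days is not None:
            death = min(death, progression_day + _exp_or_none(rng, cfg.post_progression_death_mean_days))
        censor = min(_exp_or_none(rng, cfg.censoring_mean_days), cfg.followup_horizon_days)

        # scan schedule: baseline plus jittered intervals while under follow-up
        scan_days = [baseline_day]
        day = 0.0
        while True:
            day += cfg.scan_interval_days + rng.uniform(-cfg.scan_jitter_days, cfg.scan_jitter_days)
            if day > min(death, censor, cfg.followup_horizon_days):
                break
            scan_days.append(int(round(day)))
        if len(scan_days) < 2:
            # guarantee at least one on-treatment scan (protocol-conformant patient)
            first = int(round(cfg.scan_interval_days))
            scan_days.append(first)
            death = max(death, first + 1.0)
            censor = max(censor, first)

        emits_new_lesion = (
            math.isfinite(progression_day) and rng.random() < cfg.new_lesion_fraction
        )
        new_lesion_diam = float(np.exp(rng.normal(math.log(12.0), 0.4)))

        assessments = []
        new_seen = False
        for day_k in scan_days:
            t_m = max(0.0, day_k) / DAYS_PER_MONTH
            lesions = []
            for j in range(n_lesions):
                true_d = base_diams[j] * math.exp(
                    _log_diameter_offset(ph, t_m) + lesion_jitter[j] * t_m
                )
                d = max(0.0, true_d + rng.normal(0.0, cfg.diameter_noise_sd))
                hu_factor = 1.0
                if ph.hu_drop_pct != 0.0 and day_k > 0:
                    hu_factor = 1.0 + ph.hu_drop_pct / 100.0
                hu = base_hus[j] * hu_factor + rng.normal(0.0, cfg.hu_noise_sd)
                lesions.append(
                    TargetLesionMeasurement(
                        lesion_id=f"L{j + 1}",
                        organ=organs[j],
                        day=day_k,
                        diameter=round(d, 1),
                        attenuation=round(float(hu), 1),
                        is_new=False,
                    )
                )
            if emits_new_lesion and day_k >= progression_day:
                lesions.append(
                    TargetLesionMeasurement(
                        lesion_id="NL1",
                        organ="liver",
                        day=day_k,
                        diameter=round(new_lesion_diam, 1),
                        attenuation=round(cfg.baseline_hu_mean, 1),
                        is_new=not new_seen,
                    )
                )
                new_seen = True
            assessments.append(
                Assessment(
                    patient_id=pid,
                    day=day_k,
                    measurements=lesions,
                    unequivocal_nontarget_progression=False,
                )
            )

        death_day = int(round(death)) if death <= min(censor, cfg.followup_horizon_days) else None
        last_scan = assessments[-1].day
        if death_day is not None:
            death_day = max(death_day, last_scan + 1)
            last_fu = death_day
        else:
            last_fu = max(last_scan, int(round(min(censor, cfg.followup_horizon_days))))
        patients.append(
            PatientRecord(
                patient_id=pid,
                assessments=assessments,
                death_day=death_day,
                last_followup_day=last_fu,
            )
        )
    return Cohort(patients=patients, metadata={"generator": "respkit.simulate", "seed": cfg.seed})


def simulate_clayton_pairs(
    theta: float,
    n: int,
    censoring_rate: float = 0.0,
    seed: int | None = None,
    pfs_rate: float = 1.0,
    os_rate: float = 1.0 / 80.0,
) -> list[BivariatePair]:
    """Sample (PFS, OS) pairs whose latent dependence is Clayton(theta).

    (U, V) are drawn by conditional inversion, mapped through exponential
    margins to a latent progression time and a death time; PFS is the
    minimum of the two, so PFS <= OS holds by construction.  The default
    margins separate the two processes widely (fast progression, slow
    mortality) so the death-before-progression collisions of the minimum
    construction are rare (~1-2%) and the dependence of the emitted pairs
    stays at the copula's closed form tau = theta/(theta+2); this sampler
    is a test harness for the dependence estimator, not a clinical model.
    Independent exponential censoring is calibrated so that about
    *censoring_rate* of OS times are censored.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not 0.0 <= censoring_rate < 1.0:
        raise ValueError("censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    w = rng.random(n)
    if theta < 1e-9:
        v = w
    else:
        v = ((w ** (-theta / (1.0 + theta)) - 1.0) * u ** (-theta) + 1.0) ** (-1.0 / theta)
    t_prog = -np.log(u) / pfs_rate
    t_death = -np.log(v) / os_rate
    pfs = np.minimum(t_prog, t_death)
    osd = t_death

    if censoring_rate > 0:
        c_rate = os_rate * censoring_rate / (1.0 - censoring_rate)
        cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        cens = np.full(n, np.inf)

    pairs = []
    for i in range(n):
        c = cens[i]
        pfs_t, pfs_e = (pfs[i], True) if pfs[i] <= c else (c, False)
        os_t, os_e = (osd[i], True) if osd[i] <= c else (c, False)
        pairs.append(
            BivariatePair(
                patient_id=f"S{i + 1:05d}",
                pfs_time=float(pfs_t),
                pfs_event=bool(pfs_e),
                os_time=float(os_t),
                os_event=bool(os_e),
            )
        )
    return pairs
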