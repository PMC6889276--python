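"""Surrogacy battery: copula dependence of PFS and OS, landmark survival,
Mantel-Byar responder analysis and a time-dependent Cox model.

The dependence between a criterion-specific PFS and OS is summarised by
Kendall's tau under a Clayton copula, fitted in two stages: Kaplan-Meier
marginal survival functions, then maximisation of the censored-data
pseudo-likelihood over the dependence parameter theta (tau = theta/(theta+2)).
Responder/non-responder survival comparisons use the Mantel-Byar test and a
single binary time-dependent covariate in a Cox partial likelihood, both of
which let a patient change group at their response time and therefore avoid
guarantee-time bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import optimize, stats

from .endpoints import BivariatePair, SurvivalRecord

__all__ = [
    "KMCurve",
    "CopulaFit",
    "LandmarkEstimate",
    "MantelByarResult",
    "CoxTDResult",
    "km_curve",
    "clayton_tau",
    "fit_clayton",
    "landmark_survival",
    "mantel_byar",
    "cox_td",
    "paired_wilcoxon",
]


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood log-log confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median: float | None            # None = not reached
    median_ci: tuple[float | None, float | None]
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier curve, median and 95% CI for one endpoint."""
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(med_ci.iloc[0, 0]), float(med_ci.iloc[0, 1])
    return KMCurve(
        times=sf.index.to_numpy(),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        median=median,
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        n=len(records),
    )


# ------------------------------------------------------------- Clayton copula

@dataclass
class CopulaFit:
    theta: float
    tau: float
    se_tau: float | None
    n_pairs: int
    B: int
    converged: bool


def clayton_tau(theta: float) -> float:
    """Kendall's tau of a Clayton copula: theta/(theta+2)."""
    return theta / (theta + 2.0)


_THETA_BOUNDS = (1e-3, 50.0)
_U_FLOOR = 1e-6


def _clayton_neg_loglik(theta: float, u, v, e1, e2) -> float:
    """Censored-data Clayton pseudo-log-likelihood (margins held fixed).

    u, v are the marginal survival probabilities at the observed times;
    e1, e2 the event indicators.  Contributions: copula density when both
    times are events, the partial derivative of the copula when exactly one
    is censored, and the copula (joint survival) when both are censored.
    Marginal density factors do not involve theta and are dropped.
    """
    lu, lv = np.log(u), np.log(v)
    # log(phi) with phi = u^-theta + v^-theta - 1, log-sum-exp for large theta
    a, b = -theta * lu, -theta * lv
    m = np.maximum(a, b)
    lphi = m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))
    ll = np.where(
        e1 & e2,
        np.log1p(theta) - (1.0 + theta) * (lu + lv) - (2.0 + 1.0 / theta) * lphi,
        np.where(
            e1,
            -(1.0 + theta) * lu - (1.0 + 1.0 / theta) * lphi,
            np.where(
                e2,
                -(1.0 + theta) * lv - (1.0 + 1.0 / theta) * lphi,
                -(1.0 / theta) * lphi,
            ),
        ),
    )
    return -float(np.sum(ll))


def _km_survival_at_own_times(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Marginal survival plug-in: the midpoint of the KM jump at event times.

    Using (S(t-) + S(t))/2 at events rather than the right-continuous S(t)
    removes the systematic downward shift of the plug-in pseudo-observations
    (the jump assigns the whole step to one side); censored times use S(t).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    s = kmf.survival_function_at_times(times).to_numpy()
    s_left = kmf.survival_function_at_times(np.maximum(times - 1e-9, 0.0)).to_numpy()
    u = np.where(events.astype(bool), 0.5 * (s + s_left), s)
    return np.clip(u, _U_FLOOR, 1.0 - _U_FLOOR)


def _fit_theta(pfs_t, pfs_e, os_t, os_e) -> tuple[float, bool]:
    u = _km_survival_at_own_times(pfs_t, pfs_e)
    v = _km_survival_at_own_times(os_t, os_e)
    res = optimize.minimize_scalar(
        _clayton_neg_loglik,
        bounds=_THETA_BOUNDS,
        args=(u, v, pfs_e.astype(bool), os_e.astype(bool)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), bool(res.success)


def fit_clayton(pairs: list[BivariatePair], B: int = 200, seed: int | None = None) -> CopulaFit:
    """Two-stage semiparametric Clayton fit on (PFS, OS) pairs.

    Stage 1 estimates both marginal survival functions by Kaplan-Meier;
    stage 2 maximises the censored-data pseudo-likelihood over theta > 0.
    The standard error of tau comes from B nonparametric bootstrap resamples
    of the pairs (B = 0 skips the bootstrap and reports no SE).  Tied
    PFS = OS times (death-first patients) enter the both-events contribution
    as they stand, without jittering.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 bivariate pairs")
    pfs_t = np.array([p.pfs_time for p in pairs])
    pfs_e = np.array([p.pfs_event for p in pairs])
    os_t = np.array([p.os_time for p in pairs])
    os_e = np.array([p.os_event for p in pairs])
    if not (pfs_e.any() or os_e.any()):
        raise ValueError("no events in either margin: no joint information")

    theta, converged = _fit_theta(pfs_t, pfs_e, os_t, os_e)
    tau = clayton_tau(theta)

    se_tau = None
    if B > 0 and converged:
        rng = np.random.default_rng(seed)
        n = len(pairs)
        taus = []
        for _ in range(B):
            idx = rng.integers(0, n, size=n)
            if not (pfs_e[idx].any() or os_e[idx].any()):
                continue
            th_b, ok = _fit_theta(pfs_t[idx], pfs_e[idx], os_t[idx], os_e[idx])
            if ok:
                taus.append(clayton_tau(th_b))
        if len(taus) >= 2:
            se_tau = float(np.std(taus, ddof=1))
    return CopulaFit(
        theta=theta,
        tau=tau,
        se_tau=se_tau,
        n_pairs=len(pairs),
        B=B,
        converged=converged,
    )


# ----------------------------------------------------------- landmark method

@dataclass
class LandmarkEstimate:
    group: str
    landmark: float
    horizon: float
    survival: float
    ci_low: float
    ci_high: float
    n_at_risk: int


def landmark_survival(
    records: list[SurvivalRecord],
    group_at_landmark: dict[str, str | None],
    landmark: float,
    horizon: float,
) -> list[LandmarkEstimate]:
    """Conditional survival S(horizon | alive and event-free at landmark), per group.

    Only patients still at risk at the landmark (time > landmark) enter, in
    the response group they occupy at that moment; the clock restarts at the
    landmark and a Kaplan-Meier estimate with log-log 95% CI is read off at
    the horizon.  Landmark 0 reproduces the unconditional curve.
    """
    if horizon <= landmark:
        raise ValueError("horizon must exceed landmark")
    labels = sorted({g for g in group_at_landmark.values() if g is not None})
    groups: dict[str, list[SurvivalRecord]] = {g: [] for g in labels}
    for r in records:
        g = group_at_landmark.get(r.patient_id)
        if g is not None and r.time > landmark:
            groups[g].append(r)

    estimates = []
    for g in labels:
        members = groups[g]
        if not members:
            warnings.warn(f"landmark group {g!r} is empty at the landmark; estimate omitted")
            continue
        times = np.array([r.time - landmark for r in members])
        events = np.array([r.event for r in members])
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        t_eval = horizon - landmark
        s = float(kmf.survival_function_at_times(t_eval).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        idx = np.searchsorted(ci.index.to_numpy(), t_eval, side="right") - 1
        if idx < 0:
            lo, hi = 0.0, 1.0
        else:
            lo, hi = float(ci.iloc[idx, 0]), float(ci.iloc[idx, 1])
        estimates.append(
            LandmarkEstimate(
                group=g,
                landmark=landmark,
                horizon=horizon,
                survival=s,
                ci_low=lo,
                ci_high=hi,
                n_at_risk=len(members),
            )
        )
    return estimates


# ------------------------------------------------------------- Mantel-Byar

@dataclass
class MantelByarResult:
    statistic: float
    p_value: float
    n_exposed_transitions: int


def _switch_array(records: list[SurvivalRecord], switch_times: dict[str, float | None]) -> np.ndarray:
    out = np.full(len(records), np.inf)
    for i, r in enumerate(records):
        s = switch_times.get(r.patient_id)
        if s is not None:
            if s < 0:
                raise ValueError(f"{r.patient_id}: transition time must be >= 0")
            out[i] = s
    return out


def mantel_byar(
    switch_times: dict[str, float | None],
    records: list[SurvivalRecord],
) -> MantelByarResult:
    """Mantel-Byar test: log-rank with group membership changing at response.

    Each patient contributes person-time to the non-responder group until
    their transition time and to the responder group afterwards (a missing
    transition means they never respond).  Observed-minus-expected responder
    events are accumulated over event times with the hypergeometric variance;
    the statistic is chi-square with 1 d.f.  Transition times share the unit
    of the survival records.  With every transition at time 0 this is exactly
    the standard two-group log-rank test.
    """
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    switch = _switch_array(records, switch_times)

    event_times = np.unique(times[events])
    O = E = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        if n == 0:
            continue
        # state just before t: responder iff the transition happened strictly earlier
        exposed = at_risk & (switch < t)
        n1 = int(exposed.sum())
        dying = (times == t) & events
        d = int(dying.sum())
        d1 = int((dying & exposed).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return MantelByarResult(0.0, 1.0, int(np.isfinite(switch).sum()))
    stat = (O - E) ** 2 / V
    return MantelByarResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, df=1)),
        n_exposed_transitions=int(np.isfinite(switch).sum()),
    )


# ------------------------------------------------- time-dependent Cox model

@dataclass
class CoxTDResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    covariate: str = "responder"
    log_hr: float = float("nan")
    se_log_hr: float = float("nan")


def cox_td(
    records: list[SurvivalRecord],
    switch_times: dict[str, float | None],
    covariate: str = "responder",
) -> CoxTDResult:
    """Cox partial likelihood for one binary 0->1 time-dependent covariate.

    Breslow handling of ties; Newton iteration from beta = 0 to a gradient
    below 1e-8; Wald 95% CI on the log hazard ratio.  A patient's covariate
    is 0 before their switch time and 1 strictly after it (a switch at the
    exact event time still counts as unexposed for that event, matching the
    (start, stop] interval convention).
    """
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    switch = _switch_array(records, switch_times)
    if events.sum() < 2:
        raise ValueError("need at least 2 events")

    event_times = np.unique(times[events])
    rows = []
    for t in event_times:
        at_risk = times >= t
        exposed = at_risk & (switch < t)
        n1 = int(exposed.sum())
        n0 = int(at_risk.sum()) - n1
        dying = (times == t) & events
        d = int(dying.sum())
        d1 = int((dying & exposed).sum())
        rows.append((n0, n1, d, d1))
    arr = np.array(rows, dtype=float)
    n0, n1, d, d1 = arr.T
    total_d1 = d1.sum()
    total_d0 = (d - d1).sum()
    if n1.max() == 0:
        raise ValueError("HR not estimable: covariate is never 1 while at risk")
    if total_d1 == 0 or total_d0 == 0:
        raise ValueError("HR not estimable: no events in one covariate state")

    beta = 0.0
    for _ in range(100):
        eb = np.exp(beta)
        denom = n0 + n1 * eb
        p1 = n1 * eb / denom
        grad = float(np.sum(d1 - d * p1))
        hess = float(-np.sum(d * p1 * (1 - p1)))
        if abs(grad) < 1e-8:
            break
        step = -grad / hess
        # dampen huge steps far from the optimum
        beta += np.clip(step, -5.0, 5.0)
    else:
        raise RuntimeError("Newton iteration did not converge")
    eb = np.exp(beta)
    info = float(np.sum(d * (n1 * eb / (n0 + n1 * eb)) * (1 - n1 * eb / (n0 + n1 * eb))))
    se = 1.0 / np.sqrt(info)
    z = beta / se
    return CoxTDResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        covariate=covariate,
        log_hr=float(beta),
        se_log_hr=float(se),
    )


# --------------------------------------------------------- paired Wilcoxon

def paired_wilcoxon(before, after) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired series (zero differences dropped).

    Exact null distribution for up to 25 non-zero differences, normal
    approximation with continuity correction above; returns (W, p).
    All-zero differences are degenerate: (0, 1).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired series must have equal length")
    diffs = after - before
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 0.0, 1.0
    method = "exact" if nonzero.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(nonzero, method=method, correction=(method == "approx"))
    except ValueError:
        res = stats.wilcoxon(nonzero, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)
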