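# Methods

## Setting and data model

The package analyses cohorts of patients with measurable, typically
slow-growing, hypervascular metastatic disease followed by serial
contrast-enhanced CT. Each assessment records, per target lesion, the
longest diameter (mm) and the mean arterial-phase attenuation (HU); an
assessment-level flag marks unequivocal non-target progression. Time is
kept internally as integer days from treatment start (day 0); the baseline
scan is the assessment with the largest non-positive day and must fall in
the four weeks before treatment ([−28, 0] days). Months are derived for
reporting with the 30.4375 days/month convention. Rate calculations use
day 0, not the baseline scan day, as the origin — the elapsed time that
matters clinically is time on drug — while the baseline scan day is kept on
record.

Validation mirrors the protocol exclusions of imaging-based response
studies: patients without a window-conformant baseline, without measurable
baseline disease, or with fewer than two assessments are flagged; strict
mode drops them from analysis rather than aborting the run.

## Response criteria

Both engines operate on the sum of target-lesion diameters (targets chosen
at baseline: descending diameter, at most two per organ, five overall;
greedy selection under these caps maximises the selected total). Attenuation
enters as the unweighted mean of the available target-lesion HU values — no
diameter or area weighting, since the measure is a per-lesion ROI mean.

- RECIST v1.1: CR when the sum is 0; PR when the change vs baseline is
  ≤ −30%; PD when the change vs nadir (smallest sum so far, baseline
  included) is ≥ +20% **and** ≥ +5 mm, or on new lesions / non-target
  progression; SD otherwise.
- Choi: PR when size falls ≥ 10% vs baseline **or** mean HU falls ≥ 15% vs
  baseline (no new lesions); PD when size grows ≥ 10% vs its reference and
  the attenuation-PR clause is *not* met, or on new lesions / non-target
  progression. Growth with sustained hypo-attenuation therefore stays PR —
  the defining asymmetry of the criterion.

Threshold comparisons are inclusive (−30.0% is PR; +20.0% with +5.0 mm is
PD). A series terminates at its first PD under either criterion; labels at
a landmark are read from the assessment closest to the landmark inside a
±window (default day 183 ± 60), with an earlier PD carried forward.

Choices where the published operational definitions are not fully
specified, exposed in `CriterionConfig` rather than hard-coded:

- The Choi PD size reference defaults to **baseline** (configurable to
  nadir), and the PR clauses always reference baseline; "against baseline
  values" is the first-named convention in the source material for this
  family of criteria. When both a baseline-referenced size-PR and a
  nadir-referenced PD condition hold, PR wins (the PR clause is evaluated
  first, consistent with the growth-with-hypoattenuation rule).
- Missing follow-up HU disables the attenuation clause for that timepoint
  and tags it `hu_unavailable`; a missing baseline HU degrades the whole
  series to size-only classification and flags the patient.
- CR requires a target-lesion sum of exactly 0; lymph-node short-axis
  normalisation is omitted because the schema carries longest diameters
  only.

Agreement between criteria is summarised by a 3×3 transition table
(PR/SD/PD, CR folded into PR) and unweighted Cohen's
κ = (p_o − p_e)/(1 − p_e). A published table known only through its
marginals can be reconstructed with `transition_table_from_marginals`,
which is exact when the PR row is forced to the diagonal (a ≥30% shrinkage
always meets the 10% Choi size criterion) and two cells of the SD row are
given.

## Kinetics

TG = 3·ln(Dₜ/D₀)/t converts a diameter ratio to a log-volume rate per
month under the spherical approximation; TGR = 100·(e^TG − 1) is its
percent-per-month transform. The logarithm is natural — the e-based
inverse transform fixes the base. DVR and AVR divide the plain relative
change in summed diameter and mean HU by the elapsed months. Kinetics are
emitted both from baseline (origin day 0) and per scan-to-scan interval,
flagged by `interval`. TG requires positive diameters at both ends and is
left missing otherwise (vanished lesions); AVR requires a nonzero baseline
HU.

## Endpoints and surrogacy

PFS runs from treatment start to the first criterion-specific PD or death,
whichever comes first; event-free patients are censored at the last
adequate tumour assessment (not last contact). OS runs to death or
censoring at last follow-up. Pairing enforces the semi-competing structure
PFS ≤ OS: a PFS censoring time beyond a death is clipped to the death time
and becomes an event; a recorded PFS *event* after the OS time raises a
data-integrity error.

**Clayton copula.** Dependence between PFS and OS is summarised by
Kendall's τ = θ/(θ+2) under a Clayton copula fitted in two stages:
Kaplan–Meier marginal survival estimates, then maximisation of the
censored-data pseudo-likelihood over θ (copula density for double events,
the copula's partial derivative for singly censored pairs, the copula
itself for doubly censored pairs; marginal density factors drop out). The
pseudo-observations use the midpoint of the KM jump, (S(t−)+S(t))/2, at
event times — the right-continuous value alone shifts all pseudo-
observations down and biases θ̂. θ is optimised on [10⁻³, 50] by bounded
scalar minimisation (τ from 0.0005 to 0.96); ties PFS = OS enter the
double-event term without jittering. The SE of τ comes from B = 200
nonparametric bootstrap resamples (configurable; B = 0 skips it). Two-stage
semiparametric estimation was chosen over a joint parametric fit because it
makes no assumption about the margins and is directly testable by parameter
recovery on simulated pairs.

**Landmark analysis.** Conditional survival S(horizon | at risk at
landmark) per response group: patients event-free and under follow-up at
the landmark enter the group their label occupies there (same ±window as
the transition table), the clock restarts, and a KM estimate with log-log
95% CI is read at the horizon (defaults: landmark 6, horizon 24 months).
With landmark 0 this reproduces the unconditional curve.

**Mantel–Byar.** A log-rank-type comparison in which each patient
contributes person-time to the non-responder group until their response
and to the responder group after it, removing guarantee-time bias.
Observed-minus-expected responder events are accumulated over event times
with hypergeometric variance; the statistic is χ² with 1 d.f. State at an
event time uses transitions strictly before it; with all transitions at
time 0 the test is exactly the two-group log-rank.

**Time-dependent Cox.** A single binary 0→1 covariate in the Cox partial
likelihood with Breslow tie handling, Newton-Raphson from β = 0 to a
gradient below 10⁻⁸, Wald 95% CI. The covariate follows the (start, stop]
convention (a switch at the exact event time counts as unexposed for that
event). Monotone-likelihood configurations (no events in one state, or a
covariate never 1 at risk) raise "HR not estimable" instead of returning a
diverging estimate.

**Wilcoxon signed-rank** (paired size/HU changes between consecutive
scans): exact null distribution up to 25 non-zero differences, normal
approximation with continuity correction above; zero differences are
dropped, an all-zero vector is degenerate (p = 1). No multiplicity
adjustment is applied anywhere in the battery.

## Synthetic cohorts

`simulate_cohort` draws, per patient: 1–6 lesions (liver-dominant: the
first lesion is hepatic with probability 0.94), log-normal baseline
diameters (median 25 mm), normal baseline attenuation (110 ± 15 HU), and a
phenotype — *responder* (42%: early sustained HU drop of −25 ± 8% from the
first on-treatment scan, slow diameter shrinkage, with a deep-shrink subset
of 33% that reaches the RECIST −30% threshold, then regrowth), *discordant*
(10%: grows ~2.5%/month in log-diameter yet hypo-attenuates — Choi PR,
eventual RECIST PD), or *non-responder* (slow exponential growth,
2 ± 1.2%/month log-diameter). Scans occur every ~120 ± 21 days; measurement
noise is 1.5 mm and 5 HU; progression (latent +20% over the nadir) can
spawn a new lesion (30%), death follows progression with an exponential lag
(mean 450 days) on top of a slow background hazard, and censoring is
independent exponential truncated at a ~36-month horizon. All randomness
derives from one seed with per-patient substreams, so output is
byte-identical across runs. These defaults qualitatively reproduce the
structure the analyses assume — a ~6-month Choi PR fraction near 0.45
against a RECIST PR fraction near 0.13, liver-dominant anatomy, slow
growth, early attenuation response — but they are not a fit to any real
cohort: simulated medians, hazard ratios and copula τ values are
emergent, not calibrated. What passing tests show is that the estimators
recover known truths under this generative structure; they say nothing
about inter-reader variability, non-exponential hazards, lesion
segmentation error, or scan-interval informativeness, none of which the
generator models.

`simulate_clayton_pairs` is a separate harness for the dependence
estimator: exact Clayton(θ) sampling by conditional inversion, exponential
margins, PFS = min(latent progression, death) so PFS ≤ OS by construction.
Its default margins separate the two processes widely (progression scale 1
month, mortality scale 80 months) so that death-before-progression
collisions of the minimum construction stay near 1–2% and the emitted
pairs keep the copula's closed-form τ; censoring is exponential with rate
λ_c = λ_OS·c/(1−c) so a fraction ≈ c of OS times is censored.

## Numerical and testing notes

- Problem sizes in the test suite were chosen to make each stochastic check
  decisive at comfortable margins: copula recovery at n = 500 pairs with
  200 bootstrap replicates, Mantel–Byar null calibration over 1000
  simulations of n = 80, Cox HR recovery at n = 1000.
- The Mantel–Byar and time-dependent Cox routines are validated against
  independent reference implementations (lifelines' log-rank on the
  all-transitions-at-zero reduction, `CoxPHFitter`/`CoxTimeVaryingFitter`
  on time-fixed and switch covariates); Cohen's κ is cross-checked against
  statsmodels. Reference ties are only oracles — the shipped code paths are
  the package's own.
- Known limitations: the Clayton fit treats the KM margins as fixed, so
  its bootstrap SE absorbs but does not decompose marginal-estimation
  noise; only one copula family is offered; the Cox model handles a single
  binary covariate; non-target disease is a single boolean; no
  interval-censoring correction for scan spacing is attempted.
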