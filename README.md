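# respkit

Radiological tumour-response analysis for slow-growing hypervascular
tumours (the motivating setting is pancreatic neuroendocrine tumours on
antiangiogenic therapy, where lesions hypo-attenuate on CT long before they
shrink). The package classifies responses under **RECIST v1.1** and the
**Choi criteria**, computes growth/attenuation kinetics, and evaluates
which criterion's progression-free survival (PFS) better surrogates overall
survival (OS).

## What it computes

Given longitudinal target-lesion measurements (longest diameter in mm,
mean arterial-phase attenuation in HU) and survival outcomes:

- **Response classification.** Per patient, the sum of target-lesion
  diameters *S* (up to five lesions, at most two per organ) and mean HU are
  tracked against baseline and nadir.
  RECIST: PR if ΔS ≤ −30% vs baseline, PD if ΔS ≥ +20% **and** ≥ +5 mm vs
  nadir (or new lesions / unequivocal non-target progression), CR if S = 0.
  Choi: PR if ΔS ≤ −10% **or** ΔHU ≤ −15% vs baseline; PD if ΔS ≥ +10%
  without the attenuation response — a tumour that grows but hypo-attenuates
  remains a responder.
- **Kinetics.** Tumour growth rate on the volume scale,
  TG = 3·ln(Dₜ/D₀)/t and TGR = 100·(e^TG − 1) %/month, plus the plain
  diameter and attenuation variation rates DVR, AVR (%/month).
- **Agreement.** RECIST×Choi transition tables at a landmark (default 6
  months ± 60 days) and unweighted Cohen's κ.
- **Surrogacy.** Criterion-specific PFS and OS as a bivariate censored
  pair; Kendall's τ under a Clayton copula (two-stage: Kaplan–Meier
  margins, censored-data pseudo-likelihood over θ; τ = θ/(θ+2); bootstrap
  SE), landmark conditional survival with log-log CIs, the Mantel–Byar
  test, and a single-covariate time-dependent Cox model.
- **Synthetic cohorts.** A generator that emulates the target setting
  (liver-dominant multi-lesion disease, early attenuation responders,
  discordant growing-but-hypoattenuating patients, interval CT scheduling,
  right-censoring), so the whole pipeline runs without patient data.

## Worked example

```bash
respkit simulate --seed 5 --n-patients 40 --outdir run
respkit classify run/measurements.csv run/outcomes.csv --outdir run/cls
respkit surrogacy run/cls/survival.csv \
    --measurements run/measurements.csv --outcomes run/outcomes.csv \
    -B 30 --outdir run/sur
```

prints

```
classified 40 patients; 6-month agreement kappa = 0.148
PFS_RECIST: Kendall tau = 0.445 (SE 0.119)
PFS_CHOI: Kendall tau = 0.365 (SE 0.119)
```

i.e. on this small simulated cohort the two criteria agree only weakly at
six months (κ = 0.15, mostly RECIST-SD patients reclassified by Choi), and
each criterion's PFS shows moderate Clayton-copula dependence with OS
(τ ≈ 0.4, bootstrap SE ≈ 0.12 at n = 40). `run/cls/` holds the per-patient
response and survival tables, `run/sur/` the copula/landmark/Mantel–Byar
report, and `respkit report` emits tidy spider- and waterfall-plot tables.

The same operations are available as a library:

```python
from respkit import (simulate_cohort, SimulationConfig, classify_choi,
                     transition_table, cohens_kappa)
cohort = simulate_cohort(SimulationConfig(n_patients=85, seed=1))
table = transition_table(cohort)          # 6-month RECIST x Choi counts
kappa = cohens_kappa(table)
```

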