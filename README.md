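# pgsrisk

Joint analysis of polygenic scores (PGS) and socioeconomic status (SES)
on complex-disease risk, packaged as a tested, reusable pipeline for
epidemiologists and statistical geneticists working with registry-linked
biobank cohorts.

Real cohorts of this kind are access-controlled, so the package includes a
first-class synthetic multi-study cohort generator with known ground
truth; every stage of the analysis is validated against that ground truth
and against closed-form oracles.

## What it computes

* **Cox model battery** on the age time scale (follow-up from birth to the
  first of diagnosis, death, or age 80; Efron ties): per-SD PGS effects,
  education effects (ISCED dichotomized low ≤ 4 / high ≥ 5), their joint
  model, their interaction, and PGS fits stratified by education —
  adjusted for sex, birth decade, and genetic PCs (10 with a PGS term,
  5 without). Scaled-Schoenfeld proportional-hazards diagnostics and a
  Fine–Gray subdistribution sensitivity analysis under administrative
  censoring. Occupation class (upper vs lower level, with iterative
  census backfill) as an alternative SES measure.
* **Fixed-effect meta-analysis** of log hazard ratios across studies with
  inverse-variance weights w_i = 1/se_i², Cochran's Q = Σw_i(β_i − β̂)²
  on k−1 df, two-sided Wald attenuation tests between nested models, and
  a Bonferroni threshold α/m.
* **PGS-stratified lifetime risk**: population rate tables (GBD-style
  5-year age × sex incidence/prevalence/mortality) converted to
  piecewise-constant hazards; cumulative incidence to age 80 under
  competing mortality,
  CIF = Σ_k S_k · λ_k/(λ_k+μ_k) · (1 − e^{−(λ_k+μ_k)Δ_k});
  hazard ratios for the five PGS groups (<20%, 20–40%, 40–60% reference,
  60–95%, >95%) applied to the calibrated baseline with per-bin
  renormalization so the group mixture reproduces the population hazard;
  log-linear age interpolation of quartile HRs; bootstrap percentile
  bands.
* **Prediction increments**: nested logistic models (covariates ± PGS ±
  education ± interaction) on a stratified 80/20 split, compared with
  Mann–Whitney AUC, DeLong's correlated-AUC test, continuous net
  reclassification (NRI) and integrated discrimination (IDI) indices.

See `docs/methods.md` for the model, assumptions, parameter defaults, and
numerical choices.

## Worked example

```python
import numpy as np
from pgsrisk import (
    SimConfig, StratumSpec, ModelSpec,
    generate_cohort, generate_rate_table,
    fit_cox, fit_cox_stratified, fixed_effect_meta,
    rates_to_hazards, stratified_cif,
)
from pgsrisk.survival import estimate_stratum_hrs

# three studies of 20k people; per-SD PGS HR 1.4, high education HR 0.8,
# PGS x education interaction HR 1.1, mild between-study heterogeneity
cfg = SimConfig(n_per_study=20_000, n_studies=3, seed=1, tau_study=0.02)
cohort = generate_cohort(cfg)

per_study = []
for study, sub in cohort.groupby("study_id"):
    ests = fit_cox(sub, ModelSpec(model_id="joint"), study_id=study)
    per_study.append([e for e in ests if e.term == "pgs"][0])
pooled = fixed_effect_meta(per_study)
print(f"PGS HR per SD (fixed-effect, k={pooled.k}): "
      f"{pooled.pooled_hr:.2f} (95% CI {pooled.ci95[0]:.2f}-{pooled.ci95[1]:.2f}); "
      f"Cochran's Q = {pooled.q_stat:.2f}, p = {pooled.q_p:.2f}")

strat = fit_cox_stratified(cohort, ModelSpec(model_id="joint"))
for level in ("low", "high"):
    e = [x for x in strat[level] if x.term == "pgs"][0]
    print(f"PGS HR per SD, {level} education: {e.hr:.2f} "
          f"(95% CI {e.ci95[0]:.2f}-{e.ci95[1]:.2f})")

strata = StratumSpec()
hrs = {e.stratum: e.hr for e in estimate_stratum_hrs(cohort, strata, engine="fast")}
hazards = rates_to_hazards(generate_rate_table(cfg), sex="female")
curves = stratified_cif(hazards, hrs, strata)
print(f"Cumulative incidence by 80: top 5% of PGS "
      f"{100 * curves['>95%'].at(80.0):.1f}%, "
      f"bottom 20% {100 * curves['<20%'].at(80.0):.1f}%")
```

prints

```
PGS HR per SD (fixed-effect, k=3): 1.48 (95% CI 1.45-1.51); Cochran's Q = 4.83, p = 0.09
PGS HR per SD, low education: 1.42 (95% CI 1.38-1.46)
PGS HR per SD, high education: 1.57 (95% CI 1.52-1.62)
Cumulative incidence by 80: top 5% of PGS 31.8%, bottom 20% 10.3%
```

The pooled per-SD hazard ratio of 1.48 recovers the generative marginal
effect (1.4 plus the interaction's contribution among the 45% highly
educated); the education-stratified HRs (1.42 vs 1.57) reflect the
generative interaction HR of 1.1; Q on 2 df is unremarkable under the
small simulated heterogeneity (τ = 0.02); and the calibrated lifetime
risks show the ~3× spread between the top 5% and bottom 20% of the PGS
distribution implied by those hazard ratios.

The same analysis runs end-to-end from a YAML config via the CLI:

```sh
pgsrisk all --out runs/demo --seed 7          # or: pgsrisk simulate / cox / meta / cif / predict
pgsrisk validate --cohort runs/demo/synthetic_disease.cohort.tsv \
                 --rates  runs/demo/synthetic_disease.rates.csv
```

All result files are plain delimiter-separated text with a header comment
carrying the config hash and seed; reruns are byte-identical.

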