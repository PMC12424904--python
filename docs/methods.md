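# Methods

`pgsrisk` analyses the joint contribution of a disease-specific polygenic
score (PGS) and socioeconomic status (SES, proxied by educational
attainment or occupation class) to complex-disease risk. Because the
registry-linked biobank data this kind of analysis is run on are
access-controlled, the package ships a synthetic multi-study cohort
generator with known ground truth; every analytic stage is exercised and
validated against that ground truth and against closed-form oracles.

## Generative model (synthetic_cohort)

Each of `n_studies` studies contains `n_per_study` individuals with:

* **PGS** `Z` — standard normal, re-standardized to mean 0, SD 1 within
  each study (SD uses the *n−1* denominator; this is a convention choice,
  recorded because either denominator is defensible).
* **Education** — a latent standard-normal propensity `L` with
  `corr(Z, L) = rho_pgs_edu`, thresholded at the `(1 − p_high_edu)` normal
  quantile: a Gaussian copula that controls the PGS–SES dependence with a
  single parameter. The default `rho_pgs_edu = 0` reflects the working
  hypothesis of largely independent genetic and socioeconomic
  contributions; it is a free parameter, not an empirical claim.
* **Disease onset** — proportional hazards on the age time scale,

      h(a | Z, E) = λ(a) · exp(β_pgs,s Z + β_edu E + β_inter Z·E),

  with λ(a) piecewise constant on 5-year bins [a, a+5) covering [0, 80).
  Event ages are drawn by exact inverse transform on the piecewise-constant
  cumulative hazard (no discretization error), which is what makes the
  closed-form exponential oracles in the tests exact.
* **Competing mortality** — an independent piecewise-exponential death age
  with hazard μ(a); whichever of disease/death comes first is the event,
  administratively censored at age 80.
* **Between-study heterogeneity** — each study's PGS log hazard ratio is
  `β_pgs + N(0, τ²)`; this is the signal Cochran's Q detects.
* **Entry** — entry age uniform on [35, 80]; individuals whose diagnosis
  predates entry are retained, mirroring registry data where follow-up
  runs from birth. Sex and ten genetic PCs are simulated independently of
  all effects so adjusted models are estimable without encoding
  confounding.

Default parameters emulate a common late-onset disease with a strong PGS
(per-SD HR 1.4), protective high education (HR 0.8), and a modest positive
PGS×education interaction (HR 1.1, i.e. a stronger PGS effect among the
highly educated — the interaction pattern of substantive interest).
Baseline disease hazard rises from ~10⁻⁵/yr below age 30 to 0.018/yr at
70–80 (cumulative incidence by 80 around 17% after competing mortality);
mortality is Gompertz-like, 2·10⁻⁴·e^{0.075a}, giving ~55–60% death by 80.

The matching population rate table reports, per 5-year bin and sex, the
population-average incidence λ(a)·E[exp(β_pgs Z + (β_edu + β_inter Z)E)]
(Gauss–Hermite quadrature over the copula), prevalence accumulated from
incidence, all-cause mortality equal to the generative μ, and zero
cause-specific mortality (the generator's mortality is disease-free by
construction). The static marginalization deliberately ignores the
selective depletion of high-risk individuals at older ages; the bias this
induces downstream is small at these hazard levels and is compensated by
age-varying hazard ratios (below).

**What the generator does not emulate:** genotypes and LD, PGS weight
construction, ICD-coded endpoint curation, informative censoring,
SES-dependent mortality, calendar effects, and ancestry structure. Passing
tests therefore demonstrate the *statistical machinery* is correct under
the stated model, not that real registry data satisfy that model.

## Harmonization (harmonize)

Education is dichotomized at ISCED ≤ 4 (low) vs ≥ 5 (high); out-of-range
or missing values raise so callers can flag the record (missing ISCED
excludes a record from education analyses but not PGS-only analyses).
Occupation histories (census year → class 1–9) are resolved by picking the
census closest to the event year (cases) or end of follow-up (controls),
ties to the earlier census, then stepping backwards through earlier
censuses while the class is uninformative (students, pensioners, other,
unknown, missing); classes map to upper-level, lower-level (clerical and
manual combined) or self-employed, and records with no informative class
at or before the selected census are excluded. Stepping *forward* to a
later census is never done. The default census-year set (1970, 1975,
1980, 1990, 1993, 1995, 2000, 2004–2020 annually) is configurable.
Endpoint filters drop entry ages outside [35, 80], the disallowed sex for
sex-restricted endpoints, and whole excluded studies; follow-up beyond the
endpoint's maximum analysis age is recoded as censoring at that age.

## Survival analysis (survival)

Cox proportional-hazards regression with attained age as analysis time,
origin at birth (no delayed entry — registry diagnoses predate
enrollment), exit at the first of disease, death (treated as censoring in
the cause-specific fits) or age 80. Ties are handled with the Efron
approximation. Adjustment covariates: sex, birth decade as categorical
indicators, and genetic PCs — 10 whenever a PGS term is in the model, 5
otherwise. Constant covariates are dropped with a warning. The model
battery: PGS only, education only, both ("joint"), both plus interaction,
and PGS fits stratified by education level (PGS is *not* re-standardized
within stratum; stratified fits keep 10 PCs).

Proportional hazards are tested with the Grambsch–Therneau correlation of
scaled Schoenfeld residuals against a transform of event time
(Kaplan–Meier by default; rank and identity selectable), per term plus a
global chi-square. The per-term statistic is validated against lifelines'
implementation; calibration (~5% rejection under exact PH) and power
(sign-reversing effect) are verified by simulation.

PGS-group hazard ratios use the five groups <20%, 20–40%, 40–60%
(reference), 60–95%, >95%, with cut points computed once on the full
analysis sample (cases and controls combined — a recorded choice; the
alternative of control-only cuts changes little at these case fractions)
and indicator coding against the middle group. Optional age-resolved fits
restrict risk sets to age-at-event quartile windows via left truncation
and tag each estimate with the window midpoint for interpolation.

The Fine–Gray sensitivity analysis models the subdistribution hazard.
Scope is deliberately restricted to purely administrative censoring at a
known age, where the Fine–Gray inverse-probability-of-censoring weights
are identically 1 and the estimator reduces *exactly* to a Cox fit in
which competing-event subjects stay in the risk set until the
administrative age. Inputs with earlier (random) censoring are rejected
rather than approximated; IPCW estimation is out of scope.

Numerical notes: lifelines (Efron ties, Newton precision 1e−9) performs
all user-facing fits; an in-package vectorized Newton solver implementing
the same Efron partial likelihood (optionally left-truncated) backs the
bootstrap and replicate-heavy simulations, where a ~30× per-fit speedup is
the difference between seconds and hours. The two agree to 5e−6
(lifelines' stopping rule is the binding constraint) and the partial
likelihood itself is anchored to a hand-written score-equation oracle on a
30-person fixture at 1e−8.

## Meta-analysis (meta)

Inverse-variance fixed-effect pooling of log hazard ratios: weights
1/se², pooled SE (Σw)^{−1/2}, Cochran's Q = Σw(β−β̂)² on k−1 df with an
upper-tail chi-square p (reported even at k = 2). A single study passes
through with Q undefined. Attenuation between nested models (e.g. PGS
effect before vs after education adjustment) is a two-sided Wald z on the
coefficient difference treating the two fits as independent — the
same-sample covariance is ignored, which need not be conservative; a
proper correction would need the joint influence functions and is not
attempted. Multiplicity control is Bonferroni, α/m with m = 19 outcomes
by default. Only fixed-effect pooling is provided; no between-study
variance is estimated.

## Lifetime risk (lifetime_risk)

Population rate tables are converted to hazards (λ = incidence, optionally
/(1−prevalence) to refer to the susceptible pool — off by default and
exposed as a flag, since the role of prevalence in the conversion is a
modelling choice; μ = all-cause minus cause-specific mortality, floored at
0, or all-cause by option). The cumulative incidence function under
competing mortality is accumulated per bin as

    CIF += S_k · λ_k/(λ_k+μ_k) · (1 − e^{−(λ_k+μ_k)Δ_k}),
    S_{k+1} = S_k · e^{−(λ_k+μ_k)Δ_k},

which is exact for piecewise-constant hazards (bin refinement is a no-op;
zero-hazard bins contribute nothing). Bins are half-open [a, a+5); age 80
itself belongs to no bin.

Group-specific hazards apply the estimated HRs to the calibrated baseline
with per-bin renormalization c_k such that Σ_g w̃_{gk}·HR_g(k)·c_k = 1,
where w̃_{gk} are the stratum weights re-weighted by each group's
probability of being alive and disease-free at the bin start. Without any
renormalization, applying HRs to population-average rates double-counts
the high-risk strata; with *static* birth-cohort weights the correction is
right at age 0 but drifts as high-risk groups are depleted (≈3·10⁻³ CIF
error by age 80 under the default rates). Survivor re-weighting keeps the
group mixture equal to the population hazard among those actually at risk,
and the stratum-weight mixture of group CIFs then reproduces the
population CIF to within the within-bin exponential nonlinearity
(< 10⁻³ at every knot; first-bin hazard identity exact to 1e−12).

Age-varying HRs from the quartile fits are interpolated linearly on the
log-HR scale between quartile midpoints with constant extension beyond the
first/last midpoint; a single input yields a constant. Bootstrap bands
resample individuals with replacement (default B = 1000; pipeline default
200), re-estimate the group HRs with cut points recomputed per resample,
recompute all curves, and take 2.5/97.5 percentiles per knot; percentile
intervals are used throughout. All resampling is seeded.

## Prediction (prediction)

The outcome switches from time-to-event to lifetime case status
(ever-diagnosed within follow-up). On a seeded, case-stratified 80/20
split, six maximum-likelihood logistic models are fitted: covariates only
with 5 and with 10 PCs, plus PGS, plus education, plus both, plus both
with interaction; birth year enters continuously here (unlike the decade
indicators of the Cox stage). Baseline pairing follows the PC rule: the
5-PC covariate model is the comparator for the education model, the 10-PC
one for every PGS-containing model; the full model is additionally
compared against each single-factor model and the interaction model
against the full model. Discrimination: Mann–Whitney AUC with ties
counted ½ and a DeLong-variance CI; correlated-AUC comparison by DeLong's
placement-value test; continuous NRI (ties contribute zero movement) and
IDI. External validation is represented by scoring an independently
generated cohort with train-fitted scorers.

## Pipeline (cli)

One YAML configuration drives `simulate → harmonize → cox → meta → cif →
predict`; each stage reads and writes plain-text interchange tables (TSV
cohorts/estimates/CIF/prediction, CSV rates) whose header comments carry
the config hash and seed, so stage-wise reruns are byte-identical to the
end-to-end run. One global seed fans out deterministically (SeedSequence)
to per-stage child seeds. The meta summary flags terms passing the
Bonferroni threshold.

## Problem sizes used in the validation suite

Closed-form oracles run at trivial size. Simulation checks use: parameter
coverage 100 cohorts of 20k; null-term type-I error 500 cohorts of 1.5k;
interaction recovery 100 cohorts of 10k (both the interaction coefficient
and the stratified difference, each within twice its average standard
error); Q calibration 500 draws of 3 simulated study estimates; PH-test
calibration 120 cohorts of 600; end-to-end lifetime-risk calibration one
100k estimation cohort against a fresh 200k cohort (agreement within 2
percentage points of cumulative incidence, with age-quartile HR
interpolation absorbing most of the age-aggregation bias). These sizes
were chosen so each check's Monte-Carlo error is small against its
tolerance.

## Known limitations

* The Wald attenuation test ignores the correlation between nested fits
  on the same data.
* Fine–Gray supports administrative censoring only.
* The rate-table generator's static marginalization slightly overstates
  late-age population incidence under strong effects.
* Education analyses assume the dichotomy is exogenous; the generator
  cannot speak to SES causality.
* Remaining-lifetime risk conditional on an attained age, random-effects
  meta-analysis, categorical NRI and survival-time AUC are out of scope.
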