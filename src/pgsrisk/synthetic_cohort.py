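"""Synthetic multi-study cohort and population rate-table generator.

Real biobank registry data of the kind this pipeline analyses are
access-controlled, so every downstream stage is exercised on cohorts drawn
from a generative model with known parameters:

* PGS: standard normal, re-standardized (mean 0, SD 1) within each study.
* Education: a standard-normal latent propensity with correlation
  ``rho_pgs_edu`` to the PGS, thresholded at the (1 - p_high_edu) normal
  quantile (Gaussian-copula control of the PGS-SES dependence).
* Disease onset: proportional hazards on the age time scale with a
  piecewise-constant baseline on 5-year bins; event ages are drawn by exact
  inverse transform on the piecewise-constant cumulative hazard.
* Competing mortality: an independent piecewise-exponential death age.
* Observation: event type is whichever of disease/death comes first, with
  administrative censoring at ``admin_censor_age``; entry age is uniform on
  ``entry_age_range`` (diagnoses may predate entry, as in registry data).
* Between-study heterogeneity: each study's PGS log hazard ratio is
  perturbed by N(0, tau_study^2).

Sex and genetic principal components are generated independently of all
effects; they exist so that adjusted models are estimable, not to encode
confounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_BIN_WIDTH, ConfigurationError, SimConfig

__all__ = [
    "generate_cohort",
    "generate_rate_table",
    "standardize_pgs",
    "population_hazard_multiplier",
    "DegenerateInputError",
    "COHORT_COLUMNS",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]
COHORT_COLUMNS = [
    "person_id", "study_id", "sex", "birth_year", "pgs", "isced", "education",
    "occupation_history", "entry_age", "event_age", "event_type", *PC_COLUMNS,
]

CENSUS_YEARS = (1970, 1975, 1980, 1990, 1993, 1995, 2000, *range(2004, 2021))


def _sample_piecewise_exponential(
    u: np.ndarray, multiplier: np.ndarray, rates: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Exact inverse-transform event ages under a piecewise-constant hazard.

    Individual hazard is ``multiplier * rates[k]`` on bin k.  Returns +inf
    where the total cumulative hazard is exhausted before the last bin edge.
    """
    widths = np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(rates * widths)])
    # baseline cumulative hazard each individual must accumulate
    target = -np.log(u) / multiplier
    k = np.searchsorted(cum, target, side="right") - 1
    n_bins = rates.size
    out = np.full(u.shape, np.inf)
    inside = k < n_bins
    kk = k[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = edges[kk] + (target[inside] - cum[kk]) / rates[kk]
    # zero-rate bins cannot host an event; searchsorted already skips them
    out[inside] = t
    return out


def _correlated_latent(rng: np.random.Generator, pgs: np.ndarray, rho: float) -> np.ndarray:
    noise = rng.standard_normal(pgs.size)
    return rho * pgs + np.sqrt(max(0.0, 1.0 - rho * rho)) * noise


def _occupation_histories(rng: np.random.Generator, n: int) -> list[dict[int, int]]:
    """Sparse census occupation records; codes 1-4 informative, 5-9 not."""
    histories = []
    years = np.asarray(CENSUS_YEARS)
    for _ in range(n):
        k = int(rng.integers(1, 5))
        yrs = sorted(rng.choice(years, size=k, replace=False).tolist())
        classes = rng.choice(
            np.arange(1, 10), size=k,
            p=[0.10, 0.25, 0.20, 0.25, 0.04, 0.08, 0.04, 0.02, 0.02],
        )
        histories.append({int(y): int(c) for y, c in zip(yrs, classes)})
    return histories


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a multi-study cohort table with known ground truth.

    Returns one record per person with the columns in :data:`COHORT_COLUMNS`.
    event_type is 0 (administratively censored at ``admin_censor_age``),
    1 (disease) or 2 (death without prior disease).  Identical configs
    (including seed) produce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    edges = config.age_edges
    lam = np.asarray(config.baseline_hazard)
    mu = np.asarray(config.mortality_hazard)

    frames = []
    for s in range(config.n_studies):
        n = config.n_per_study
        study_id = f"study_{s + 1}"
        beta_pgs_s = config.beta_pgs + (
            config.tau_study * rng.standard_normal() if config.tau_study > 0 else 0.0
        )

        pgs_raw = rng.standard_normal(n)
        # standardize before computing hazards so the stored column carries
        # exactly the per-SD effect the config declares
        pgs = (pgs_raw - pgs_raw.mean()) / pgs_raw.std(ddof=1)
        latent = _correlated_latent(rng, pgs, config.rho_pgs_edu)
        threshold = stats.norm.ppf(1.0 - config.p_high_edu)
        high_edu = latent > threshold

        log_mult = (
            beta_pgs_s * pgs
            + config.beta_edu * high_edu
            + config.beta_inter * pgs * high_edu
        )
        t_disease = _sample_piecewise_exponential(
            rng.uniform(size=n), np.exp(log_mult), lam, edges
        )
        t_death = _sample_piecewise_exponential(
            rng.uniform(size=n), np.ones(n), mu, edges
        )

        event_age = np.minimum(
            np.minimum(t_disease, t_death), config.admin_censor_age
        )
        event_type = np.zeros(n, dtype=int)
        event_type[(t_disease <= t_death) & (t_disease < config.admin_censor_age)] = 1
        event_type[(t_death < t_disease) & (t_death < config.admin_censor_age)] = 2

        isced = np.where(
            high_edu, rng.integers(5, 9, size=n), rng.integers(0, 5, size=n)
        )
        sex = np.where(rng.uniform(size=n) < config.sex_ratio, "female", "male")
        lo, hi = config.entry_age_range
        entry_age = rng.uniform(lo, hi, size=n)
        y0, y1 = config.birth_year_range
        birth_year = rng.integers(y0, y1 + 1, size=n)

        df = pd.DataFrame(
            {
                "person_id": [f"{study_id}_{i:07d}" for i in range(n)],
                "study_id": study_id,
                "sex": sex,
                "birth_year": birth_year,
                "pgs": pgs,
                "isced": isced,
                "education": np.where(high_edu, "high", "low"),
                "occupation_history": (
                    _occupation_histories(rng, n)
                    if config.simulate_occupation
                    else [None] * n
                ),
                "entry_age": entry_age,
                "event_age": event_age,
                "event_type": event_type,
            }
        )
        pcs = rng.standard_normal((n, 10))
        for j, col in enumerate(PC_COLUMNS):
            df[col] = pcs[:, j]
        frames.append(df)

    return pd.concat(frames, ignore_index=True)


def population_hazard_multiplier(config: SimConfig, n_nodes: int = 201) -> float:
    """E[exp(b_p Z + (b_e + b_i Z) E)] over the generative PGS/education law.

    Gauss-Hermite quadrature over the standard-normal PGS, with the
    conditional education probability implied by the Gaussian copula.
    With all betas zero this is 1; with only beta_pgs = b it is exp(b^2/2).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / np.sqrt(2.0 * np.pi)
    z = nodes
    c = stats.norm.ppf(1.0 - config.p_high_edu)
    rho = config.rho_pgs_edu
    if abs(rho) < 1.0:
        p_high = stats.norm.sf((c - rho * z) / np.sqrt(1.0 - rho * rho))
    else:
        p_high = (np.sign(rho) * z > c).astype(float)
    f = np.exp(config.beta_pgs * z) * (
        (1.0 - p_high)
        + p_high * np.exp(config.beta_edu + config.beta_inter * z)
    )
    return float(np.sum(w * f))


def generate_rate_table(config: SimConfig) -> pd.DataFrame:
    """Population rate table matching the generative model, GBD-style.

    One row per (5-year age bin, sex) with per-person-year disease incidence
    (the population-average hazard, i.e. baseline times the marginal
    multiplier over the PGS/education distribution), prevalence accumulated
    from incidence, all-cause mortality and cause-specific mortality.  The
    generator's mortality is independent of disease, so the cause-specific
    column is zero and all-cause mortality equals the generative mortality
    hazard.
    """
    lam = np.asarray(config.baseline_hazard)
    mu = np.asarray(config.mortality_hazard)
    edges = config.age_edges
    mult = population_hazard_multiplier(config)
    incidence = lam * mult
    cum = np.concatenate([[0.0], np.cumsum(incidence * np.diff(edges))])[:-1]
    prevalence = 1.0 - np.exp(-cum)

    rows = []
    for sex in ("female", "male"):
        rows.append(
            pd.DataFrame(
                {
                    "age_lo": edges[:-1],
                    "age_hi": edges[1:],
                    "sex": sex,
                    "incidence": incidence,
                    "prevalence": prevalence,
                    "mort_all": mu,
                    "mort_cause": 0.0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def standardize_pgs(cohort: pd.DataFrame) -> pd.DataFrame:
    """Re-standardize the pgs column to mean 0, SD 1 within each study.

    SD uses the n-1 denominator.  Idempotent on already-standardized input.
    Raises :class:`DegenerateInputError` for a study with fewer than two
    individuals or a constant PGS.
    """
    out = cohort.copy()
    for study, idx in cohort.groupby("study_id").groups.items():
        x = cohort.loc[idx, "pgs"].to_numpy(dtype=float)
        if x.size < 2:
            raise DegenerateInputError(
                f"study {study!r} has fewer than two individuals"
            )
        sd = x.std(ddof=1)
        if sd == 0.0:
            raise DegenerateInputError(f"study {study!r} has constant PGS")
        out.loc[idx, "pgs"] = (x - x.mean()) / sd
    return out
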