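"""Lifetime cumulative incidence calibrated to population rates.

Population rate tables (GBD-style: 5-year age bin x sex rows with disease
incidence, prevalence, all-cause and cause-specific mortality, all per
person-year) are converted to a piecewise-constant hazard schedule; the
cumulative incidence function (CIF) to age 80 accounts for the competing
risk of death through the disease-free mortality hazard.  Hazard ratios
for PGS groups (optionally education-specific and age-varying) are applied
to the calibrated baseline with a per-bin renormalization so that the
stratum-weight mixture of group hazards reproduces the population-average
hazard; confidence bands come from bootstrap resampling of the cohort used
to estimate the group HRs.

Within bin k of width D_k with disease hazard l_k and competing mortality
m_k, the CIF increment is

    S_k * l_k / (l_k + m_k) * (1 - exp(-(l_k + m_k) D_k)),

with S_k the probability of being alive and disease-free at the bin start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._coxfast import fit_cox_fast
from .config import StratumSpec
from .survival import HazardEstimate, assign_pgs_groups

__all__ = [
    "RateTableError",
    "HazardSchedule",
    "CifCurve",
    "rates_to_hazards",
    "baseline_cif",
    "stratified_cif",
    "interpolate_age_hrs",
    "bootstrap_cif_ci",
]


class RateTableError(ValueError):
    pass


@dataclass
class HazardSchedule:
    """Piecewise-constant disease (lambda) and competing-mortality (mu) hazards."""

    age_edges: np.ndarray  # length n_bins + 1, starting at 0
    lam: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = self.lam.size
        if self.mu.size != n or self.age_edges.size != n + 1:
            raise RateTableError("inconsistent schedule shapes")
        if np.any(self.lam < 0) or np.any(self.mu < 0):
            raise RateTableError("hazards must be non-negative")
        if np.any(np.diff(self.age_edges) <= 0):
            raise RateTableError("age bins must be increasing")


@dataclass
class CifCurve:
    """Cumulative incidence on an age grid, with optional bootstrap bands."""

    age_grid: np.ndarray
    cif: np.ndarray
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None
    stratum: str = ""
    education: str = ""

    def at(self, age: float) -> float:
        """CIF at an exact grid age."""
        idx = np.flatnonzero(np.isclose(self.age_grid, age))
        if idx.size == 0:
            raise KeyError(f"age {age} is not a grid knot")
        return float(self.cif[idx[0]])


def rates_to_hazards(
    rates: pd.DataFrame,
    sex: Optional[str] = None,
    adjust_susceptible: bool = False,
    mortality: str = "cause_removed",
) -> HazardSchedule:
    """Convert a population rate table to a piecewise-constant schedule.

    The disease hazard is the incidence rate, optionally divided by
    (1 - prevalence) to refer it to the still-susceptible pool.  The
    competing mortality hazard is all-cause minus cause-specific mortality
    (floored at zero); set ``mortality='all'`` to use all-cause mortality
    unchanged.
    """
    tab = rates
    if "sex" in tab.columns:
        levels = tab["sex"].unique()
        if sex is not None:
            tab = tab[tab["sex"] == sex]
            if len(tab) == 0:
                raise RateTableError(f"no rows for sex {sex!r}")
        elif len(levels) > 1:
            raise RateTableError(
                "rate table contains multiple sexes; pass sex= to select one"
            )
    tab = tab.sort_values("age_lo").reset_index(drop=True)
    lo = tab["age_lo"].to_numpy(dtype=float)
    hi = tab["age_hi"].to_numpy(dtype=float)
    if not np.allclose(lo[1:], hi[:-1]) or lo[0] != 0.0:
        raise RateTableError("age bins must be contiguous and start at 0")
    lam = tab["incidence"].to_numpy(dtype=float)
    if adjust_susceptible:
        prev = tab["prevalence"].to_numpy(dtype=float)
        if np.any(prev >= 1.0):
            raise RateTableError("prevalence of 1 leaves no susceptible pool")
        lam = lam / (1.0 - prev)
    if mortality == "cause_removed":
        mu = np.maximum(
            tab["mort_all"].to_numpy(dtype=float)
            - tab["mort_cause"].to_numpy(dtype=float),
            0.0,
        )
    elif mortality == "all":
        mu = tab["mort_all"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mortality option {mortality!r}")
    return HazardSchedule(
        age_edges=np.concatenate([lo, hi[-1:]]), lam=lam, mu=mu
    )


def _cif_knots(
    edges: np.ndarray, lam: np.ndarray, mu: np.ndarray, max_age: float
) -> tuple[np.ndarray, np.ndarray]:
    """CIF evaluated at every bin edge <= max_age (plus max_age if interior)."""
    if max_age > edges[-1] + 1e-12:
        raise RateTableError(
            f"max_age {max_age} exceeds rate coverage (up to {edges[-1]})"
        )
    knots = [0.0]
    cif = [0.0]
    surv = 1.0
    acc = 0.0
    for k in range(lam.size):
        a0, a1 = edges[k], edges[k + 1]
        if a0 >= max_age:
            break
        width = min(a1, max_age) - a0
        total = lam[k] + mu[k]
        if total > 0:
            inc = surv * (lam[k] / total) * (1.0 - np.exp(-total * width))
            surv *= np.exp(-total * width)
        else:
            inc = 0.0
        acc += inc
        knots.append(a0 + width)
        cif.append(acc)
    return np.asarray(knots), np.asarray(cif)


def baseline_cif(hazards: HazardSchedule, max_age: float = 80.0) -> CifCurve:
    """Population cumulative incidence accounting for competing death."""
    knots, cif = _cif_knots(hazards.age_edges, hazards.lam, hazards.mu, max_age)
    return CifCurve(age_grid=knots, cif=cif, stratum="population")


def _group_hr_array(
    hr, n_bins: int, edges: np.ndarray
) -> np.ndarray:
    """Normalize a group HR spec (scalar, array, or interpolator) to per-bin."""
    if np.isscalar(hr):
        arr = np.full(n_bins, float(hr))
    else:
        arr = np.asarray(hr, dtype=float)
        if arr.size != n_bins:
            raise RateTableError("per-bin HR array has wrong length")
    if np.any(arr <= 0):
        raise RateTableError("hazard ratios must be positive")
    return arr


def stratified_cif(
    hazards: HazardSchedule,
    group_hrs: Mapping[str, float | np.ndarray],
    strata: StratumSpec,
    renormalize: bool = True,
    max_age: float = 80.0,
) -> dict[str, CifCurve]:
    """Per-PGS-group cumulative incidence from population hazards and HRs.

    Group hazards are ``c_k * HR_g(k) * lambda_k``.  With renormalization
    (the default) the per-bin constant c_k solves

        sum_g wtilde_gk * HR_g(k) * c_k = 1,

    where ``wtilde_gk`` are the stratum weights re-weighted by each group's
    probability of still being alive and disease-free at the bin start.
    Applying hazard ratios to population-average rates without this
    correction double-counts the high-risk strata; weighting by survivors
    (rather than the birth-cohort weights) keeps the group mixture equal to
    the population-average hazard among those actually at risk, so the
    stratum-weight mixture of the group CIF curves reproduces the
    population CIF to within the within-bin exponential nonlinearity.
    Without renormalization c_k = 1 and the reference group carries the
    baseline hazard unchanged.
    """
    n_bins = hazards.lam.size
    hrs = {
        g: _group_hr_array(group_hrs[g], n_bins, hazards.age_edges)
        for g in strata.group_labels
        if g in group_hrs
    }
    missing = [g for g in strata.group_labels if g not in hrs]
    if missing:
        raise RateTableError(f"missing HRs for groups: {missing}")
    labels = list(strata.group_labels)
    w0 = np.asarray(strata.weights, dtype=float)
    edges = hazards.age_edges
    if max_age > edges[-1] + 1e-12:
        raise RateTableError(
            f"max_age {max_age} exceeds rate coverage (up to {edges[-1]})"
        )

    n_groups = len(labels)
    surv = np.ones(n_groups)             # alive and disease-free, per group
    cif = np.zeros(n_groups)
    knots = [0.0]
    curves_cif = [cif.copy()]
    for k in range(n_bins):
        a0, a1 = edges[k], edges[k + 1]
        if a0 >= max_age:
            break
        width = min(a1, max_age) - a0
        hr_k = np.array([hrs[g][k] for g in labels])
        if renormalize:
            wt = w0 * surv
            total_wt = wt.sum()
            c = total_wt / float(wt @ hr_k) if total_wt > 0 else 1.0
        else:
            c = 1.0
        lam_g = c * hr_k * hazards.lam[k]
        total = lam_g + hazards.mu[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total > 0, lam_g / np.where(total > 0, total, 1.0), 0.0)
        cif = cif + surv * frac * (1.0 - np.exp(-total * width))
        surv = surv * np.exp(-total * width)
        knots.append(a0 + width)
        curves_cif.append(cif.copy())
    grid = np.asarray(knots)
    stacked = np.vstack(curves_cif)
    return {
        g: CifCurve(age_grid=grid, cif=stacked[:, j].copy(), stratum=g)
        for j, g in enumerate(labels)
    }


def interpolate_age_hrs(
    quartile_hrs: Sequence[tuple[float, float]],
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Interpolate age-quartile HRs to per-bin values on the log scale.

    ``quartile_hrs`` is a sequence of (midpoint age, HR) pairs.  Linear
    interpolation on log HR between midpoints, constant extension beyond
    the first and last midpoint; a single input yields a constant function.
    """
    if not len(quartile_hrs):
        raise RateTableError("need at least one quartile HR")
    pts = sorted(quartile_hrs)
    ages = np.array([a for a, _ in pts], dtype=float)
    hrs = np.array([h for _, h in pts], dtype=float)
    if np.any(hrs <= 0):
        raise RateTableError("hazard ratios must be positive")
    edges = np.asarray(bin_edges, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return np.exp(np.interp(mids, ages, np.log(hrs)))


def _stratum_hrs_fast(
    table: pd.DataFrame, strata: StratumSpec
) -> dict[str, float]:
    """Unadjusted PGS-group HRs via the internal Newton solver."""
    groups = assign_pgs_groups(table, strata)
    ref = strata.reference
    non_ref = [g for g in strata.group_labels if g != ref]
    X = np.column_stack([(groups.to_numpy() == g).astype(float) for g in non_ref])
    res = fit_cox_fast(
        X,
        table["event_age"].to_numpy(dtype=float),
        (table["event_type"].to_numpy() == 1).astype(int),
    )
    out = {ref: 1.0}
    out.update({g: float(np.exp(b)) for g, b in zip(non_ref, res.beta)})
    return out


def bootstrap_cif_ci(
    cohort: pd.DataFrame,
    rates: pd.DataFrame,
    strata: StratumSpec,
    B: int = 1000,
    seed: int = 0,
    sex: Optional[str] = "female",
    renormalize: bool = True,
    max_age: float = 80.0,
) -> dict[str, CifCurve]:
    """Percentile bootstrap bands for the PGS-stratified CIF curves.

    Resamples individuals with replacement ``B`` times, re-estimates the
    group HRs (unadjusted indicator Cox fits, cut points recomputed per
    resample) and recomputes the stratified curves; bands are the 2.5/97.5
    percentiles at each knot.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    hazards = rates_to_hazards(rates, sex=sex)
    point_hrs = _stratum_hrs_fast(cohort, strata)
    curves = stratified_cif(
        hazards, point_hrs, strata, renormalize=renormalize, max_age=max_age
    )
    rng = np.random.default_rng(seed)
    n = len(cohort)
    samples = {g: [] for g in strata.group_labels}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        hrs_b = _stratum_hrs_fast(boot, strata)
        curves_b = stratified_cif(
            hazards, hrs_b, strata, renormalize=renormalize, max_age=max_age
        )
        for g in strata.group_labels:
            samples[g].append(curves_b[g].cif)
    for g, curve in curves.items():
        arr = np.vstack(samples[g])
        curve.ci_low = np.percentile(arr, 2.5, axis=0)
        curve.ci_high = np.percentile(arr, 97.5, axis=0)
    return curves


def cif_frame(curves: Mapping[str, CifCurve], disease: str = "") -> pd.DataFrame:
    """Flatten CIF curves into the tab-separated interchange layout."""
    rows = []
    for g, c in curves.items():
        for i, age in enumerate(c.age_grid):
            rows.append(
                {
                    "disease": disease,
                    "education": c.education,
                    "stratum": g,
                    "age": float(age),
                    "cif": float(c.cif[i]),
                    "ci_low": float(c.ci_low[i]) if c.ci_low is not None else np.nan,
                    "ci_high": float(c.ci_high[i]) if c.ci_high is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
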