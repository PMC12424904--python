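"""Cox proportional-hazards battery on the age time scale.

Analysis time is attained age with origin at birth (diagnoses predate
study enrollment in registry data, so there is no delayed entry by
default); follow-up ends at the earliest of disease, death, or the
administrative limit.  Competing deaths are treated as censoring in the
cause-specific fits and kept in the risk set until the administrative
censoring age in the Fine-Gray subdistribution fits.

Models are adjusted for sex, birth decade (categorical indicators) and
genetic principal components: 10 PCs whenever a PGS term is present, 5
otherwise.  Ties are handled with the Efron approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from ._coxfast import CoxConvergenceError, fit_cox_fast
from .config import ModelSpec, StratumSpec

__all__ = [
    "FitError",
    "DegenerateDataError",
    "UnsupportedInputError",
    "HazardEstimate",
    "CoxModelFit",
    "fit_cox",
    "fit_cox_model",
    "fit_cox_stratified",
    "test_proportional_hazards",
    "assign_pgs_groups",
    "estimate_stratum_hrs",
    "fit_fine_gray",
    "estimates_to_frame",
]

DURATION_COL = "event_age"
EVENT_COL = "_disease_event"


class FitError(RuntimeError):
    pass


class DegenerateDataError(ValueError):
    pass


class UnsupportedInputError(ValueError):
    pass


@dataclass
class HazardEstimate:
    """One fitted coefficient on the log hazard-ratio scale with provenance."""

    term: str
    log_hr: float
    se: Optional[float]
    n_cases: int = 0
    n_controls: int = 0
    study_id: str = ""
    stratum: str = ""
    model_id: str = ""
    disease: str = ""
    age_mid: Optional[float] = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def z(self) -> Optional[float]:
        if self.se is None:
            return None
        return self.log_hr / self.se

    @property
    def p(self) -> Optional[float]:
        z = self.z
        if z is None:
            return None
        return float(2.0 * stats.norm.sf(abs(z)))

    @property
    def ci95(self) -> Optional[tuple[float, float]]:
        if self.se is None:
            return None
        return (
            float(np.exp(self.log_hr - 1.96 * self.se)),
            float(np.exp(self.log_hr + 1.96 * self.se)),
        )


@dataclass
class CoxModelFit:
    """A fitted Cox model plus the design it was fitted on."""

    estimates: list[HazardEstimate]
    design: pd.DataFrame
    spec: ModelSpec
    fitter: Optional[CoxPHFitter] = None
    term_names: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return int(self.design[EVENT_COL].sum())


def build_design(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Assemble the regression design for one model of the battery.

    Returns a frame with the duration/event columns plus covariates; constant
    covariates are dropped with a warning (they carry no information under
    the partial likelihood).
    """
    design = pd.DataFrame(
        {
            DURATION_COL: table["event_age"].to_numpy(dtype=float),
            EVENT_COL: (table["event_type"].to_numpy() == 1).astype(int),
        }
    )
    if spec.has_pgs:
        design["pgs"] = table["pgs"].to_numpy(dtype=float)
    if spec.has_education or spec.model_id == "interaction":
        edu = (table["education"].to_numpy() == "high").astype(float)
        design["education"] = edu
    if spec.model_id == "interaction":
        design["pgs_x_education"] = design["pgs"] * design["education"]
    if spec.adjust:
        if "sex" in table.columns:
            design["is_female"] = (table["sex"].to_numpy() == "female").astype(float)
        if "birth_year" in table.columns:
            decade = (table["birth_year"].to_numpy(dtype=float) // 10 * 10).astype(int)
            dummies = pd.get_dummies(
                pd.Categorical(decade), prefix="decade", drop_first=True
            ).astype(float)
            for col in dummies.columns:
                design[col] = dummies[col].to_numpy()
        for j in range(1, spec.effective_n_pcs + 1):
            col = f"pc{j}"
            if col in table.columns:
                design[col] = table[col].to_numpy(dtype=float)

    for col in [c for c in design.columns if c not in (DURATION_COL, EVENT_COL)]:
        if design[col].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {col!r}", stacklevel=2)
            design = design.drop(columns=col)
    return design


def _check_cases_controls(design: pd.DataFrame) -> tuple[int, int]:
    n_cases = int(design[EVENT_COL].sum())
    n_controls = int(len(design) - n_cases)
    if n_cases == 0 or n_controls == 0:
        raise DegenerateDataError(
            f"need at least one case and one control (cases={n_cases}, "
            f"controls={n_controls})"
        )
    return n_cases, n_controls


def fit_cox_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    study_id: str = "",
    stratum: str = "",
    disease: str = "",
) -> CoxModelFit:
    """Fit one Cox model of the battery and return the full fit object."""
    design = build_design(table, spec)
    n_cases, n_controls = _check_cases_controls(design)
    terms = [c for c in design.columns if c not in (DURATION_COL, EVENT_COL)]
    if not terms:
        raise DegenerateDataError("no non-constant covariates to fit")
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                design,
                duration_col=DURATION_COL,
                event_col=EVENT_COL,
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError as exc:
        raise FitError(
            f"Cox fit failed to converge for terms {terms} "
            f"(model {spec.model_id!r}): {exc}"
        ) from exc
    estimates = [
        HazardEstimate(
            term=t,
            log_hr=float(cph.params_[t]),
            se=float(cph.standard_errors_[t]),
            n_cases=n_cases,
            n_controls=n_controls,
            study_id=study_id,
            stratum=stratum,
            model_id=spec.model_id,
            disease=disease,
        )
        for t in terms
    ]
    return CoxModelFit(
        estimates=estimates, design=design, spec=spec, fitter=cph, term_names=terms
    )


def fit_cox(
    table: pd.DataFrame,
    spec: ModelSpec,
    study_id: str = "",
    disease: str = "",
) -> list[HazardEstimate]:
    """Partial-likelihood estimates (Efron ties) for one model of the battery."""
    return fit_cox_model(table, spec, study_id=study_id, disease=disease).estimates


def fit_cox_stratified(
    table: pd.DataFrame,
    spec: ModelSpec,
    study_id: str = "",
    disease: str = "",
) -> dict[str, list[HazardEstimate]]:
    """Independent fits of the same model within each education level.

    The education term itself is removed from the within-stratum design.
    """
    inner = ModelSpec(
        model_id="pgs_only" if spec.has_pgs else spec.model_id,
        adjust=spec.adjust,
        n_pcs=spec.n_pcs if spec.n_pcs is not None else spec.effective_n_pcs,
    )
    out: dict[str, list[HazardEstimate]] = {}
    for level in ("low", "high"):
        sub = table[table["education"] == level]
        if len(sub) == 0 or (sub["event_type"] == 1).sum() == 0 or (
            sub["event_type"] != 1
        ).sum() == 0:
            raise DegenerateDataError(
                f"education stratum {level!r} lacks cases or controls"
            )
        out[level] = fit_cox_model(
            sub, inner, study_id=study_id, stratum=level, disease=disease
        ).estimates
    return out


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics (scaled Schoenfeld residuals)
# ---------------------------------------------------------------------------

def _time_transform(times: np.ndarray, durations, events, transform: str) -> np.ndarray:
    if transform == "identity":
        return times.astype(float)
    if transform == "rank":
        return stats.rankdata(times).astype(float)
    if transform == "km":
        km = KaplanMeierFitter()
        km.fit(durations, events)
        surv = km.survival_function_at_times(times).to_numpy()
        return 1.0 - surv
    raise ValueError(f"unknown time transform {transform!r}")


def test_proportional_hazards(
    fit: CoxModelFit, transform: str = "km"
) -> pd.DataFrame:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Correlates each term's scaled Schoenfeld residuals with a transform of
    event time (Kaplan-Meier by default; ``rank`` and ``identity``
    selectable) and adds a global chi-square test across all terms.
    Returns a frame indexed by term (plus ``GLOBAL``) with columns
    ``statistic``, ``df`` and ``p``.
    """
    if fit.n_events < 2:
        raise DegenerateDataError("proportional-hazards test needs >= 2 events")
    cph = fit.fitter
    design = fit.design
    resid = cph.compute_residuals(design, kind="schoenfeld")
    # residual rows correspond to event rows of the design, in design order
    ev_rows = design.loc[resid.index]
    times = ev_rows[DURATION_COL].to_numpy(dtype=float)
    order = np.argsort(times)
    r = resid[fit.term_names].to_numpy(dtype=float)[order]
    g = _time_transform(
        times[order],
        design[DURATION_COL].to_numpy(),
        design[EVENT_COL].to_numpy(),
        transform,
    )
    c = g - g.mean()
    d = len(times)
    v_inv = cph.variance_matrix_.loc[fit.term_names, fit.term_names].to_numpy()
    css = float(c @ c)

    rows = []
    scaled_num = c @ (r @ v_inv) * d          # per-term numerators, scaled
    for j, term in enumerate(fit.term_names):
        chi2 = scaled_num[j] ** 2 / (d * v_inv[j, j] * css)
        rows.append((term, chi2, 1, float(stats.chi2.sf(chi2, 1))))
    q = c @ r
    global_chi2 = float(d * q @ v_inv @ q / css)
    rows.append(
        ("GLOBAL", global_chi2, len(fit.term_names),
         float(stats.chi2.sf(global_chi2, len(fit.term_names))))
    )
    return pd.DataFrame(rows, columns=["term", "statistic", "df", "p"]).set_index(
        "term"
    )


# ---------------------------------------------------------------------------
# PGS-group hazard ratios
# ---------------------------------------------------------------------------

def assign_pgs_groups(table: pd.DataFrame, strata: StratumSpec) -> pd.Series:
    """Label each row with its PGS group; cuts from the full analysis sample."""
    cuts = np.quantile(table["pgs"].to_numpy(dtype=float), strata.quantile_cuts)
    idx = np.searchsorted(cuts, table["pgs"].to_numpy(dtype=float), side="right")
    return pd.Series(
        np.asarray(strata.group_labels, dtype=object)[idx], index=table.index
    )


def _fit_group_indicators(
    table: pd.DataFrame,
    groups: pd.Series,
    strata: StratumSpec,
    engine: str,
    study_id: str,
    disease: str,
    education: str = "",
    age_mid: Optional[float] = None,
    entry_age: Optional[np.ndarray] = None,
    exit_age: Optional[np.ndarray] = None,
    events: Optional[np.ndarray] = None,
) -> list[HazardEstimate]:
    ref = strata.reference
    non_ref = [g for g in strata.group_labels if g != ref]
    X = np.column_stack(
        [(groups.to_numpy() == g).astype(float) for g in non_ref]
    )
    durations = (
        exit_age if exit_age is not None else table["event_age"].to_numpy(dtype=float)
    )
    ev = (
        events if events is not None else (table["event_type"].to_numpy() == 1)
    ).astype(int)
    for g in strata.group_labels:
        if ev[groups.to_numpy() == g].sum() == 0:
            cell = f"group {g!r}" + (f", education {education!r}" if education else "")
            raise DegenerateDataError(f"no cases in cell: {cell}")

    n_cases = int(ev.sum())
    n_controls = int(len(ev) - n_cases)
    if engine == "fast":
        res = fit_cox_fast(X, durations, ev, entry=entry_age)
        params = dict(zip(non_ref, res.beta))
        ses = dict(zip(non_ref, res.se))
    else:
        df = pd.DataFrame({DURATION_COL: durations, EVENT_COL: ev})
        for j, g in enumerate(non_ref):
            df[f"g{j}"] = X[:, j]
        cph = CoxPHFitter(penalizer=0.0)
        kwargs = {}
        if entry_age is not None:
            df["_entry"] = entry_age
            kwargs["entry_col"] = "_entry"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=DURATION_COL, event_col=EVENT_COL, **kwargs)
        except ConvergenceError as exc:
            raise FitError(f"stratum HR fit failed: {exc}") from exc
        params = {g: float(cph.params_[f"g{j}"]) for j, g in enumerate(non_ref)}
        ses = {g: float(cph.standard_errors_[f"g{j}"]) for j, g in enumerate(non_ref)}

    out = []
    for g in strata.group_labels:
        if g == ref:
            est = HazardEstimate(
                term="pgs_group", log_hr=0.0, se=None,
                n_cases=n_cases, n_controls=n_controls,
                study_id=study_id, stratum=g, model_id="pgs_groups",
                disease=disease, age_mid=age_mid,
            )
        else:
            est = HazardEstimate(
                term="pgs_group", log_hr=params[g], se=ses[g],
                n_cases=n_cases, n_controls=n_controls,
                study_id=study_id, stratum=g, model_id="pgs_groups",
                disease=disease, age_mid=age_mid,
            )
        if education:
            est.stratum = g
            est.model_id = f"pgs_groups|edu={education}"
        out.append(est)
    return out


def estimate_stratum_hrs(
    table: pd.DataFrame,
    strata: StratumSpec,
    by_education: bool = False,
    by_age_quartile: bool = False,
    engine: str = "lifelines",
    study_id: str = "",
    disease: str = "",
):
    """Hazard ratios for PGS groups against the middle (40-60%) reference.

    Quantile cut points are computed once on the full analysis sample
    (cases and controls combined) and reused in every stratified cell.
    Returns a list of :class:`HazardEstimate` (one per group, reference HR
    = 1 with no SE), or a dict keyed by education level and/or age-quartile
    label when the corresponding flags are set.  Age-quartile fits restrict
    the risk sets to the quartile's age window (left truncation at the
    window start) and tag each estimate with the window midpoint for HR
    interpolation.
    """
    groups = assign_pgs_groups(table, strata)

    def cells(sub: pd.DataFrame, sub_groups: pd.Series, education: str = ""):
        if not by_age_quartile:
            return _fit_group_indicators(
                sub, sub_groups, strata, engine, study_id, disease, education
            )
        event_ages = sub.loc[sub["event_type"] == 1, "event_age"].to_numpy()
        if event_ages.size < 4:
            raise DegenerateDataError("too few events for age quartiles")
        qs = np.quantile(event_ages, [0.0, 0.25, 0.5, 0.75, 1.0])
        out = {}
        for k in range(4):
            lo, hi = qs[k], qs[k + 1]
            at_risk = sub["event_age"].to_numpy() > lo
            win = sub[at_risk]
            win_groups = sub_groups[at_risk]
            exit_age = np.minimum(win["event_age"].to_numpy(dtype=float), hi)
            ev = (
                (win["event_type"].to_numpy() == 1)
                & (win["event_age"].to_numpy() <= hi)
            )
            out[f"Q{k + 1}"] = _fit_group_indicators(
                win, win_groups, strata, engine, study_id, disease,
                education, age_mid=float((lo + hi) / 2.0),
                entry_age=np.full(len(win), lo), exit_age=exit_age,
                events=ev.astype(int),
            )
        return out

    if not by_education:
        return cells(table, groups)
    out = {}
    for level in ("low", "high"):
        mask = table["education"] == level
        out[level] = cells(table[mask], groups[mask], education=level)
    return out


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazards under administrative censoring
# ---------------------------------------------------------------------------

def fit_fine_gray(
    table: pd.DataFrame,
    spec: ModelSpec,
    admin_censor_age: float = 80.0,
    study_id: str = "",
    disease: str = "",
) -> list[HazardEstimate]:
    """Subdistribution-hazard coefficients for the disease endpoint.

    Supported only under purely administrative censoring at a known age
    (the censoring-complete case, where the Fine-Gray inverse-probability
    weights are identically 1): individuals with a competing death remain
    in the risk set until ``admin_censor_age``.  Output shape matches
    :func:`fit_cox`.
    """
    censored = table[table["event_type"] == 0]
    if len(censored) and (
        censored["event_age"] < admin_censor_age - 1e-9
    ).any():
        raise UnsupportedInputError(
            "non-administrative censoring detected: Fine-Gray fits here "
            "require all censoring at the administrative age "
            f"{admin_censor_age}"
        )
    mod = table.copy()
    deaths = mod["event_type"] == 2
    mod.loc[deaths, "event_age"] = admin_censor_age
    mod.loc[deaths, "event_type"] = 0
    ests = fit_cox(mod, spec, study_id=study_id, disease=disease)
    for e in ests:
        e.model_id = f"fine_gray_{spec.model_id}"
    return ests


def estimates_to_frame(estimates: list[HazardEstimate]) -> pd.DataFrame:
    """Flatten estimates into the tab-separated interchange layout."""
    rows = []
    for e in estimates:
        ci = e.ci95
        rows.append(
            {
                "disease": e.disease,
                "study": e.study_id,
                "model_id": e.model_id,
                "stratum": e.stratum,
                "term": e.term,
                "log_hr": e.log_hr,
                "se": e.se if e.se is not None else np.nan,
                "z": e.z if e.z is not None else np.nan,
                "p": e.p if e.p is not None else np.nan,
                "hr": e.hr,
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
                "n_cases": e.n_cases,
                "n_controls": e.n_controls,
            }
        )
    return pd.DataFrame(rows)
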