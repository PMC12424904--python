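"""Cox battery: hand-written partial-likelihood oracle, stratified and
interaction fits, Schoenfeld diagnostics, PGS-group HRs, Fine-Gray."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import make_survival_table
from pgsrisk.config import ModelSpec, SimConfig, StratumSpec
from pgsrisk.survival import (
    DegenerateDataError,
    UnsupportedInputError,
    assign_pgs_groups,
    estimate_stratum_hrs,
    estimates_to_frame,
    fit_cox,
    fit_cox_model,
    fit_cox_stratified,
    fit_fine_gray,
)
from pgsrisk.survival import test_proportional_hazards as schoenfeld_test
from pgsrisk.synthetic_cohort import generate_cohort


def brute_force_cox_mle(x: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Root of the hand-written partial-likelihood score function.

    Valid for distinct event times (no ties): the log partial likelihood is
    sum over events i of x_i*b - log sum_{j: t_j >= t_i} exp(x_j*b); its
    derivative is solved by bisection to machine precision.
    """
    def score(b):
        u = 0.0
        for i in np.flatnonzero(e):
            risk = t >= t[i]
            w = np.exp(x[risk] * b)
            u += x[i] - np.sum(x[risk] * w) / np.sum(w)
        return u

    return float(optimize.brentq(score, -10.0, 10.0, xtol=1e-13))


def test_partial_likelihood_oracle_30_person_fixture():
    rng = np.random.default_rng(30)
    n = 30
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = np.sort(rng.uniform(1.0, 70.0, size=n))  # distinct by construction
    e = rng.uniform(size=n) < 0.7
    e[:2] = True  # ensure events
    tab = make_survival_table(t, e.astype(int), pgs=x)
    est = fit_cox(tab, ModelSpec(model_id="pgs_only", adjust=False))[0]
    oracle = brute_force_cox_mle(x, t, e)
    assert abs(est.log_hr - oracle) < 1e-8


def test_hr_and_ci_reproduce_from_log_hr_and_se():
    tab = make_survival_table(
        np.linspace(10, 70, 40), [1, 0] * 20, pgs=np.random.default_rng(0).normal(size=40)
    )
    est = fit_cox(tab, ModelSpec(model_id="pgs_only", adjust=False))[0]
    assert est.hr == pytest.approx(np.exp(est.log_hr))
    lo, hi = est.ci95
    assert lo == pytest.approx(np.exp(est.log_hr - 1.96 * est.se))
    assert hi == pytest.approx(np.exp(est.log_hr + 1.96 * est.se))
    assert lo < est.hr < hi


def test_zero_events_raises():
    tab = make_survival_table([10.0, 20.0, 30.0], [0, 0, 0], pgs=[0.1, 0.5, -1.0])
    with pytest.raises(DegenerateDataError):
        fit_cox(tab, ModelSpec(model_id="pgs_only", adjust=False))


def test_constant_covariate_dropped_with_warning():
    rng = np.random.default_rng(2)
    tab = make_survival_table(
        np.linspace(5, 75, 60), rng.integers(0, 2, 60), pgs=rng.normal(size=60),
        education=["low"] * 60,
    )
    with pytest.warns(UserWarning, match="constant covariate"):
        ests = fit_cox(tab, ModelSpec(model_id="joint", adjust=False))
    assert [e.term for e in ests] == ["pgs"]


def test_stratified_fit_on_identical_strata_gives_identical_estimates():
    rng = np.random.default_rng(3)
    n = 400
    half = make_survival_table(
        rng.uniform(20, 80, n), rng.integers(0, 2, n), pgs=rng.normal(size=n)
    )
    low = half.assign(education="low")
    high = half.assign(education="high")
    tab = pd.concat([low, high], ignore_index=True)
    out = fit_cox_stratified(tab, ModelSpec(model_id="joint", adjust=False))
    b_low = [e for e in out["low"] if e.term == "pgs"][0]
    b_high = [e for e in out["high"] if e.term == "pgs"][0]
    assert b_low.log_hr == pytest.approx(b_high.log_hr, abs=1e-10)
    assert b_low.se == pytest.approx(b_high.se, abs=1e-10)


def test_interaction_coefficient_equals_stratified_difference_large_n():
    cfg = SimConfig(
        n_per_study=100_000, n_studies=1, seed=19,
        beta_pgs=np.log(1.5), beta_edu=np.log(0.8), beta_inter=np.log(1.1),
    )
    c = generate_cohort(cfg)
    inter = [
        e for e in fit_cox(c, ModelSpec(model_id="interaction", adjust=False))
        if e.term == "pgs_x_education"
    ][0]
    strat = fit_cox_stratified(c, ModelSpec(model_id="joint", adjust=False))
    diff = (
        [e for e in strat["high"] if e.term == "pgs"][0].log_hr
        - [e for e in strat["low"] if e.term == "pgs"][0].log_hr
    )
    assert abs(inter.log_hr - diff) < 0.02


def test_empty_education_stratum_is_an_error():
    tab = make_survival_table(
        np.linspace(10, 70, 30), [1] * 15 + [0] * 15,
        pgs=np.random.default_rng(1).normal(size=30), education=["low"] * 30,
    )
    with pytest.raises(DegenerateDataError, match="high"):
        fit_cox_stratified(tab, ModelSpec(model_id="joint", adjust=False))


class TestProportionalHazardsDiagnostics:
    def _null_table(self, seed, n=600):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.3 * x)))
        e = t < 60
        return make_survival_table(np.minimum(t, 60), e.astype(int), pgs=x)

    def test_matches_lifelines_per_term(self):
        from lifelines.statistics import proportional_hazard_test

        tab = self._null_table(8)
        fit = fit_cox_model(tab, ModelSpec(model_id="pgs_only", adjust=False))
        mine = schoenfeld_test(fit, transform="rank")
        theirs = proportional_hazard_test(
            fit.fitter, fit.design, time_transform="rank"
        )
        assert mine.loc["pgs", "p"] == pytest.approx(
            float(theirs.summary["p"].iloc[0]), abs=1e-6
        )

    def test_calibrated_under_exact_proportional_hazards(self):
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            tab = self._null_table(5000 + rep)
            fit = fit_cox_model(tab, ModelSpec(model_id="pgs_only", adjust=False))
            p = schoenfeld_test(fit).loc["pgs", "p"]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_reps <= 0.10

    def test_detects_sign_reversing_effect(self):
        rng = np.random.default_rng(55)
        n = 10_000
        x = rng.normal(size=n)
        t1 = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x)))
        t = np.where(t1 < 40, t1, 40 + rng.exponential(1.0 / (0.02 * np.exp(-0.5 * x))))
        e = t < 80
        tab = make_survival_table(np.minimum(t, 80), e.astype(int), pgs=x)
        fit = fit_cox_model(tab, ModelSpec(model_id="pgs_only", adjust=False))
        res = schoenfeld_test(fit)
        assert res.loc["GLOBAL", "p"] < 1e-6

    def test_too_few_events_rejected(self):
        tab = make_survival_table([10.0, 20.0, 30.0], [1, 0, 0], pgs=[0.2, -0.1, 0.4])
        fit = fit_cox_model(tab, ModelSpec(model_id="pgs_only", adjust=False))
        with pytest.raises(DegenerateDataError):
            schoenfeld_test(fit)


class TestStratumHRs:
    def test_reference_group_has_unit_hr_and_no_se(self, strata):
        c = generate_cohort(SimConfig(n_per_study=5000, n_studies=1, seed=29))
        ests = estimate_stratum_hrs(c, strata)
        ref = [e for e in ests if e.stratum == strata.reference][0]
        assert ref.hr == 1.0 and ref.se is None
        assert len(ests) == 5

    def test_top5_matches_truncated_normal_oracle(self, strata):
        # linear PGS effect beta: group HR vs the 40-60% reference is
        # exp(beta * E[Z | group]); for Z > z_0.95, E = phi(1.645)/0.05 = 2.063
        b = np.log(1.5)
        cfg = SimConfig(
            n_per_study=200_000, n_studies=1, seed=31,
            beta_pgs=b, beta_edu=0.0, beta_inter=0.0,
        )
        ests = estimate_stratum_hrs(generate_cohort(cfg), strata, engine="fast")
        top = [e for e in ests if e.stratum == ">95%"][0]
        expected = np.exp(b * stats.norm.pdf(stats.norm.ppf(0.95)) / 0.05)
        assert abs(top.hr - expected) < 0.15

    def test_null_effects_give_unit_hrs(self, strata):
        cfg = SimConfig(
            n_per_study=200_000, n_studies=1, seed=37,
            beta_pgs=0.0, beta_edu=0.0, beta_inter=0.0,
        )
        ests = estimate_stratum_hrs(generate_cohort(cfg), strata, engine="fast")
        for e in ests:
            assert 0.9 < e.hr < 1.1

    def test_age_quartile_fits_tag_midpoints(self, strata):
        c = generate_cohort(SimConfig(n_per_study=20_000, n_studies=1, seed=41))
        out = estimate_stratum_hrs(c, strata, by_age_quartile=True, engine="fast")
        assert set(out) == {"Q1", "Q2", "Q3", "Q4"}
        mids = [out[q][0].age_mid for q in ("Q1", "Q2", "Q3", "Q4")]
        assert all(m is not None for m in mids)
        assert mids == sorted(mids)

    def test_empty_cell_raises_named_error(self, strata):
        c = generate_cohort(SimConfig(n_per_study=2000, n_studies=1, seed=43))
        c = c.copy()
        groups = assign_pgs_groups(c, strata)
        c.loc[(groups == ">95%") & (c["event_type"] == 1), "event_type"] = 0
        with pytest.raises(DegenerateDataError, match=">95%"):
            estimate_stratum_hrs(c, strata)


class TestFineGray:
    def test_equals_cause_specific_without_competing_deaths(self):
        cfg = SimConfig(
            n_per_study=5000, n_studies=1, seed=47,
            mortality_hazard=[0.0] * 16,
        )
        c = generate_cohort(cfg)
        spec = ModelSpec(model_id="pgs_only", adjust=False)
        cs = fit_cox(c, spec)[0]
        fg = fit_fine_gray(c, spec)[0]
        assert abs(fg.log_hr - cs.log_hr) < 1e-6
        assert abs(fg.se - cs.se) < 1e-6

    def test_mortality_covariate_gets_subdistribution_hr_below_one(self):
        # disease hazard independent of x, mortality strongly increasing in x:
        # high-x subjects die early without disease, depressing the disease CIF
        rng = np.random.default_rng(49)
        n = 20_000
        x = rng.normal(size=n)
        t_dis = rng.exponential(1.0 / 0.003, size=n)
        t_die = rng.exponential(1.0 / (0.03 * np.exp(0.8 * x)), size=n)
        age = np.minimum(np.minimum(t_dis, t_die), 80.0)
        ev = np.zeros(n, dtype=int)
        ev[(t_dis <= t_die) & (t_dis < 80)] = 1
        ev[(t_die < t_dis) & (t_die < 80)] = 2
        tab = make_survival_table(age, ev, pgs=x)
        fg = fit_fine_gray(tab, ModelSpec(model_id="pgs_only", adjust=False))[0]
        assert fg.hr < 1.0
        assert fg.p < 0.01

    def test_attenuated_but_same_sign_as_cause_specific(self):
        agree = 0
        for rep in range(20):
            cfg = SimConfig(
                n_per_study=4000, n_studies=1, seed=6000 + rep,
                beta_pgs=np.log(1.5), beta_edu=0.0, beta_inter=0.0,
            )
            c = generate_cohort(cfg)
            spec = ModelSpec(model_id="pgs_only", adjust=False)
            cs = fit_cox(c, spec)[0]
            fg = fit_fine_gray(c, spec)[0]
            if fg.log_hr > 0 and fg.log_hr < cs.log_hr:
                agree += 1
        assert agree >= 18

    def test_random_censoring_rejected(self):
        tab = make_survival_table([10.0, 30.0, 50.0], [1, 0, 2], pgs=[0.1, -0.2, 0.3])
        with pytest.raises(UnsupportedInputError):
            fit_fine_gray(tab, ModelSpec(model_id="pgs_only", adjust=False))


def test_estimates_frame_layout():
    c = generate_cohort(SimConfig(n_per_study=2000, n_studies=1, seed=51))
    ests = fit_cox(c, ModelSpec(model_id="joint", adjust=False), study_id="study_1",
                   disease="d")
    frame = estimates_to_frame(ests)
    assert list(frame.columns) == [
        "disease", "study", "model_id", "stratum", "term", "log_hr", "se", "z",
        "p", "hr", "ci_low", "ci_high", "n_cases", "n_controls",
    ]
    assert set(frame["term"]) == {"pgs", "education"}
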