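"""Cockcroft-Gault, power-law covariate effects, screening and the
inclusion rule's constants."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from pmxnpag import (CHI2_1DF_P01, Cohort, CovariateEffect, CovariateModel,
                     CovariateSet, DoseEvent, Observation, PKParameters,
                     Subject, apply_covariates, cockcroft_gault,
                     screen_covariates)
from pmxnpag.covariates import ALB_REFERENCE, AGE_REFERENCE, final_covariate_model


@pytest.mark.parametrize("age, wt, scr, sex, expected", [
    (40, 72, 88.4, "M", 100.0),
    (68, 60, 75.0, "M", 70.72),
    (68, 60, 75.0, "F", 60.11),
])
def test_cockcroft_gault_values(age, wt, scr, sex, expected):
    assert cockcroft_gault(age, wt, scr, sex) == pytest.approx(expected,
                                                               abs=0.005)


def test_cockcroft_gault_domain():
    with pytest.raises(ValueError):
        cockcroft_gault(141, 60, 75, "M")
    with pytest.raises(ValueError):
        cockcroft_gault(50, -1, 75, "M")


def test_ccr_derived_on_covariate_set():
    cov = CovariateSet(age=68, wt=60, sex="M", scr=75, alb=30, apache2=20)
    assert cov.ccr == pytest.approx(70.72, abs=0.005)


def test_chi2_inclusion_constant_matches_distribution():
    assert CHI2_1DF_P01 == pytest.approx(chi2.ppf(0.99, df=1), abs=0.005)


def _cov(alb=ALB_REFERENCE, age=AGE_REFERENCE):
    return CovariateSet(age=age, wt=60, sex="M", scr=75, alb=alb, apache2=21.5)


def test_apply_covariates_identity_at_reference(table_params):
    out = apply_covariates(table_params, _cov(), final_covariate_model())
    assert out.CL == pytest.approx(table_params.CL, rel=1e-14)
    assert out.Vc == pytest.approx(table_params.Vc, rel=1e-14)
    assert out.Q == table_params.Q and out.Vp == table_params.Vp


def test_apply_covariates_low_albumin_raises_cl(table_params):
    out = apply_covariates(table_params, _cov(alb=23.1), final_covariate_model())
    assert out.CL == pytest.approx(1.24 * (23.1 / 31.45) ** (-0.95), rel=1e-12)
    assert out.CL == pytest.approx(1.662, abs=0.001)


def test_cl_monotone_decreasing_in_albumin(table_params):
    model = final_covariate_model()
    albs = np.linspace(21.3, 41.5, 30)
    cls = [apply_covariates(table_params, _cov(alb=a), model).CL for a in albs]
    assert np.all(np.diff(cls) < 0)
    ages = np.linspace(31, 94, 30)
    vs = [apply_covariates(table_params, _cov(age=a), model).Vc for a in ages]
    assert np.all(np.diff(vs) > 0)


def test_duplicate_effect_pair_rejected():
    e = CovariateEffect("CL", "alb", 31.45, -0.95)
    with pytest.raises(ValueError, match="duplicate"):
        CovariateModel((e, CovariateEffect("CL", "alb", 30.0, 0.5)))


def _screen_cohort(n=10, seed=0):
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        cov = CovariateSet(age=float(rng.uniform(30, 90)), wt=60.0, sex="M",
                           scr=75.0, alb=float(rng.uniform(23, 41)),
                           apache2=21.0)
        subjects.append(Subject(
            id=f"s{i}", covariates=cov, doses=[DoseEvent(0.0, 100.0, 1.0)],
            observations=[Observation(1.0, 2.0)]))
    return Cohort(subjects)


def test_screen_exact_linear_relation_gives_r2_one():
    cohort = _screen_cohort()
    post = pd.DataFrame({
        "CL": [2.0 + 0.05 * s.covariates.age for s in cohort],
        "Vc": [10.0 - 0.1 * s.covariates.alb for s in cohort],
    }, index=[s.id for s in cohort])
    tab = screen_covariates(post, cohort, covariate_names=("age", "alb"))
    r2 = tab.set_index(["parameter", "covariate"])["r2"]
    assert r2.loc[("CL", "age")] == pytest.approx(1.0, abs=1e-12)
    assert r2.loc[("Vc", "alb")] == pytest.approx(1.0, abs=1e-12)


def test_screen_constant_covariate_flagged_r2_zero():
    cohort = _screen_cohort()
    post = pd.DataFrame({"CL": np.linspace(1, 2, len(cohort))},
                        index=[s.id for s in cohort])
    tab = screen_covariates(post, cohort, covariate_names=("wt",))
    assert tab["r2"].iloc[0] == 0.0
    assert tab["flag"].iloc[0] == "zero-variance"


def test_screen_matches_correlation_oracle(rng):
    cohort = _screen_cohort(12, seed=3)
    y = rng.normal(2, 0.5, size=12)
    post = pd.DataFrame({"CL": y}, index=[s.id for s in cohort])
    tab = screen_covariates(post, cohort, covariate_names=("alb",))
    x = np.array([s.covariates.alb for s in cohort])
    assert tab["r2"].iloc[0] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                              rel=1e-12)


def test_stepwise_trivial_cases():
    """No candidates returns the base model unchanged; a candidate
    duplicating an included effect is rejected as such."""
    from pmxnpag import (CohortDesign, ModelSpec, NpagConfig, default_space,
                         generate_cohort, run_npag)
    from pmxnpag.covariates import final_covariate_model, stepwise_select

    design = CohortDesign(n_subjects=5, total_samples=20)
    cohort, _ = generate_cohort(design, seed=12)
    cfg = NpagConfig(n_initial=64, max_cycles=5, seed=0)
    alb_eff = CovariateEffect("CL", "alb", 31.45, -0.95)
    base_model = ModelSpec(compartments=2,
                           covariates=CovariateModel((alb_eff,)))
    fit = run_npag(cohort, base_model, default_space(2), cfg)

    final, table = stepwise_select(cohort, fit, base_model, default_space(2),
                                   cfg, [])
    assert final == base_model.covariates
    assert len(table) == 1

    dup = CovariateEffect("CL", "alb", 30.0, -0.5)   # same (target, covariate)
    final, table = stepwise_select(cohort, fit, base_model, default_space(2),
                                   cfg, [dup])
    assert final == base_model.covariates
    assert table["model"].iloc[1].startswith("duplicate")
    assert not table["accepted"].iloc[1]
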