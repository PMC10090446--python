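"""Nonparametric estimator building blocks: EM weights, likelihood matrix,
posteriors, fit indices, and the adaptive-grid driver on small problems."""

import numpy as np
import pytest

from pmxnpag import (Cohort, CohortDesign, CovariateModel, CovariateSet,
                     DoseEvent, ErrorSpec, ModelSpec, NpagConfig, Observation,
                     SupportSet, Subject, default_space, fit_metrics,
                     generate_cohort, information_criteria, likelihood_matrix,
                     log_likelihood_subject, optimize_weights,
                     posterior_subject, run_npag, PKParameters)


# ---------------------------------------------------------------------- EM

def _brute_force_two_point(P, n_grid=200001):
    """Exhaustive search over the 1-simplex for K=2."""
    a = np.linspace(0.0, 1.0, n_grid)
    w = np.column_stack([a, 1 - a])
    obj = np.log(P @ w.T).sum(axis=0)
    best = np.argmax(obj)
    return w[best], obj[best]


def test_em_single_point_gets_weight_one():
    w, _ = optimize_weights(np.array([[0.3], [0.9]]))
    assert w == pytest.approx([1.0])


def test_em_matches_brute_force_on_two_point_problems(rng):
    for _ in range(10):
        P = rng.uniform(0.05, 1.0, size=(rng.integers(1, 6), 2))
        w_em, obj_em = optimize_weights(P)
        w_bf, obj_bf = _brute_force_two_point(P)
        assert obj_em >= obj_bf - 1e-8
        assert np.allclose(w_em, w_bf, atol=2e-4)


def test_em_single_subject_prefers_dominant_point():
    w, _ = optimize_weights(np.array([[0.2, 0.8]]))
    assert w[1] == pytest.approx(1.0, abs=1e-6)


def test_em_symmetric_matrix_gives_equal_weights():
    P = np.array([[0.2, 0.7], [0.7, 0.2]])
    w, _ = optimize_weights(P)
    assert w == pytest.approx([0.5, 0.5], abs=1e-8)


def test_em_objective_nondecreasing(rng):
    P = rng.uniform(0.01, 1.0, size=(8, 5))
    objs = []
    w = np.full(5, 0.2)
    for _ in range(50):
        objs.append(np.log(P @ w).sum())
        w = w * (P.T @ (1.0 / (P @ w))) / P.shape[0]
        w /= w.sum()
    assert np.all(np.diff(objs) >= -1e-12)


def test_em_rejects_zero_row():
    with pytest.raises(ValueError, match="unexplainable"):
        optimize_weights(np.array([[0.0, 0.0], [0.5, 0.5]]))


# ------------------------------------------------------- likelihood matrix

def _tiny_cohort():
    cov = CovariateSet(age=68, wt=60, sex="M", scr=75, alb=31.45, apache2=21)
    subs = []
    for i, c in enumerate([2.5, 1.4, 3.2]):
        subs.append(Subject(
            id=f"s{i}", covariates=cov,
            doses=[DoseEvent(0.0, 100.0, 1.0)],
            observations=[Observation(1.0, c), Observation(8.0, c / 2)]))
    return Cohort(subs)


def test_likelihood_matrix_matches_naive_evaluation():
    cohort = _tiny_cohort()
    model = ModelSpec(compartments=2, error=ErrorSpec(gamma=1.0))
    pts = np.array([[1.24, 16.64, 3.04, 66.2], [2.0, 30.0, 5.0, 50.0]])
    P, off = likelihood_matrix(cohort, pts, model)
    for i, s in enumerate(cohort):
        for j in range(2):
            ll = log_likelihood_subject(PKParameters(*pts[j]), s, model.error)
            assert P[i, j] * np.exp(off[i]) == pytest.approx(np.exp(ll),
                                                             rel=1e-10)
    assert P.max(axis=1) == pytest.approx(np.ones(3))


def test_likelihood_matrix_duplicate_point_gives_identical_columns():
    cohort = _tiny_cohort()
    model = ModelSpec(compartments=2)
    pts = np.array([[1.24, 16.64, 3.04, 66.2]] * 2)
    P, _ = likelihood_matrix(cohort, pts, model)
    np.testing.assert_array_equal(P[:, 0], P[:, 1])


# ----------------------------------------------------------- fit indices

@pytest.mark.parametrize("neg2ll, k, expected_aicc, expected_bic", [
    (188.6, 3, 195.0, 201.0),
    (145.6, 5, 156.6, 166.4),
])
def test_information_criteria_two_compartment_convention(neg2ll, k,
                                                         expected_aicc,
                                                         expected_bic):
    aicc, bic = information_criteria(neg2ll, k, n=64)
    assert aicc == pytest.approx(expected_aicc, abs=0.1)
    assert bic == pytest.approx(expected_bic, abs=0.1)


def test_information_criteria_small_n_flagged():
    with pytest.raises(ValueError, match="AICc undefined"):
        information_criteria(100.0, k=5, n=6)


# ----------------------------------------------------------- posteriors

def _fit_small(cohort, seed=3, **kw):
    cfg = NpagConfig(n_initial=128, max_cycles=25, seed=seed, **kw)
    model = ModelSpec(compartments=2)
    return run_npag(cohort, model, default_space(2), cfg), model


def test_posterior_single_support_point(rich_cohort_small):
    cohort, _ = rich_cohort_small
    fit, model = _fit_small(Cohort(cohort.subjects[:4]))
    # collapse the result to one point by hand
    fit.support = SupportSet(fit.support.points[:1], np.array([1.0]))
    pw, pm = posterior_subject(fit, cohort.subjects[0])
    assert pw == pytest.approx([1.0])
    np.testing.assert_allclose(pm.as_array(), fit.support.points[0])


def test_posterior_without_observations_recovers_prior(rich_cohort_small):
    cohort, _ = rich_cohort_small
    fit, model = _fit_small(Cohort(cohort.subjects[:4]))
    s = cohort.subjects[0]
    empty = Subject(id="empty", covariates=s.covariates, doses=s.doses,
                    observations=[])
    pw, _ = posterior_subject(fit, empty)
    np.testing.assert_allclose(pw, fit.support.weights, atol=1e-12)


def test_posterior_two_point_bayes_ratio():
    cohort = _tiny_cohort()
    model = ModelSpec(compartments=2, error=ErrorSpec(gamma=1.0))
    pts = np.array([[1.24, 16.64, 3.04, 66.2], [2.0, 30.0, 5.0, 50.0]])
    prior = np.array([0.3, 0.7])
    P, _ = likelihood_matrix(cohort, pts, model)
    from pmxnpag.npag import NPAGResult
    fit = NPAGResult(support=SupportSet(pts, prior), gamma_final=1.0,
                     neg2ll=0.0, cycle_log=[], converged=True, model=model,
                     space=default_space(2), seed=0)
    pw, _ = posterior_subject(fit, cohort.subjects[0])
    expected = prior * P[0]
    expected /= expected.sum()
    np.testing.assert_allclose(pw, expected, rtol=1e-9)


# --------------------------------------------------------------- driver

def test_npag_neg2ll_nonincreasing_and_deterministic(rich_cohort_small):
    cohort, _ = rich_cohort_small
    small = Cohort(cohort.subjects[:6])
    fit1, _ = _fit_small(small, seed=9)
    fit2, _ = _fit_small(small, seed=9)
    trace = [c[1] for c in fit1.cycle_log]
    assert np.all(np.diff(trace) <= 1e-9)
    assert fit1.neg2ll == pytest.approx(fit2.neg2ll, abs=1e-9)
    assert fit1.neg2ll <= trace[0] + 1e-9
    # simplex invariants
    assert fit1.support.weights.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(fit1.support.weights >= 0)


def test_npag_degenerate_cohort_collapses_to_truth():
    """All subjects share one parameter vector and noise is tiny: the
    fitted support must concentrate within 5% of the truth."""
    truth_err = ErrorSpec(c0=0.005, c1=0.005, gamma=1.0)
    design = CohortDesign(n_subjects=10, sampling_mode="rich",
                          truth_covariates=CovariateModel(),
                          truth_cv_pct={"CL": 0.01, "Vc": 0.01,
                                        "Q": 0.01, "Vp": 0.01},
                          truth_error=truth_err)
    cohort, truth = generate_cohort(design, seed=3)
    # start gamma high: the early inflated error variance anneals the
    # likelihood surface while the grid is still coarse
    model = ModelSpec(compartments=2, error=truth_err.with_gamma(5.0))
    cfg = NpagConfig(n_initial=2048, max_cycles=150, seed=5)
    fit = run_npag(cohort, model, default_space(2), cfg)
    true_vec = truth[["CL", "Vc", "Q", "Vp"]].iloc[0].to_numpy()
    within = np.all(np.abs(fit.support.points / true_vec - 1.0) < 0.05,
                    axis=1)
    assert fit.support.weights[within].sum() >= 0.99
    np.testing.assert_allclose(fit.support.mean(), true_vec, rtol=0.05)


def test_fit_metrics_r2_and_param_table(rich_cohort_small):
    cohort, _ = rich_cohort_small
    small = Cohort(cohort.subjects[:6])
    fit, model = _fit_small(small, seed=2)
    m = fit_metrics(fit, small, model)
    assert 0.0 <= m.r2_pop <= 1.0
    assert m.r2_post >= m.r2_pop - 0.05   # posterior fit at least as good
    assert m.k == 5 and m.n_obs == small.n_obs_quantified
    aicc, bic = information_criteria(m.neg2ll, m.k, m.n_obs)
    assert m.aicc == pytest.approx(aicc) and m.bic == pytest.approx(bic)
    tab = m.params
    np.testing.assert_allclose(tab["cv_pct"],
                               100 * tab["sd"] / tab["mean"], rtol=1e-12)
    assert set(tab.index) == {"CL", "Vc", "Q", "Vp"}
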