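"""Structural model: closed-form propagation vs ODE oracle, superposition,
mass balance, steady-state AUC."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pmxnpag import (DoseEvent, PKParameters, Regimen, predict_concentrations,
                     predict_concentrations_many, predict_one_compartment,
                     regimen_doses, steady_state_auc24)


def _ode_oracle(p: PKParameters, doses, times, rtol=1e-11):
    """Adaptive-integration reference for the infusion model."""

    def rate(t):
        return sum(d.rate for d in doses if d.time <= t < d.end)

    def rhs(t, x):
        if p.Q is None:
            return [rate(t) - p.CL / p.Vc * x[0]]
        return [rate(t) - (p.CL / p.Vc + p.Q / p.Vc) * x[0] + p.Q / p.Vp * x[1],
                p.Q / p.Vc * x[0] - p.Q / p.Vp * x[1]]

    x0 = [0.0] if p.Q is None else [0.0, 0.0]
    breaks = sorted({0.0, *[d.time for d in doses], *[d.end for d in doses],
                     max(times)})
    sol_t, sol_y = [], []
    x = x0
    for a, b in zip(breaks[:-1], breaks[1:]):
        s = solve_ivp(rhs, [a, b], x, rtol=rtol, atol=1e-13,
                      dense_output=True)
        for t in times:
            if a < t <= b:
                sol_t.append(t)
                sol_y.append(s.sol(t)[0])
        x = s.y[:, -1]
    for t in times:            # queries at or before the first breakpoint
        if t <= breaks[0]:
            sol_t.append(t)
            sol_y.append(0.0)
    order = np.argsort(sol_t)
    return np.array(sol_y)[order] / p.Vc


def test_no_doses_gives_zero(table_params):
    out = predict_concentrations(table_params, [], [1.0, 5.0, 10.0])
    np.testing.assert_array_equal(out, 0.0)


def test_single_infusion_matches_ode_oracle(table_params):
    doses = [DoseEvent(0.0, 75.0, 1.0)]
    times = np.array([0.5, 1.0, 1.5, 3.0, 8.0, 24.0])
    pred = predict_concentrations(table_params, doses, times)
    oracle = _ode_oracle(table_params, doses, times)
    np.testing.assert_allclose(pred, oracle, rtol=1e-6)


def test_random_draws_match_ode_oracle(rng):
    """Closed form vs adaptive integration on 100 random parameter/regimen
    draws, to 1e-6 relative."""
    for _ in range(100):
        p = PKParameters(CL=rng.uniform(0.1, 6), Vc=rng.uniform(2, 100),
                         Q=rng.uniform(0.1, 20), Vp=rng.uniform(2, 200))
        dur = rng.uniform(0.5, 2.0)
        doses = [DoseEvent(12.0 * k, rng.uniform(40, 150), dur)
                 for k in range(3)]
        times = np.sort(rng.uniform(0.0, 40.0, size=5))
        pred = predict_concentrations(p, doses, times)
        oracle = _ode_oracle(p, doses, times)
        np.testing.assert_allclose(pred, oracle, rtol=1e-6, atol=1e-12)


def test_superposition_of_two_doses(rng):
    """Linearity: the two-dose response equals the sum of time-shifted
    single-dose responses."""
    for _ in range(20):
        p = PKParameters(CL=rng.uniform(0.2, 5), Vc=rng.uniform(3, 80),
                         Q=rng.uniform(0.1, 15), Vp=rng.uniform(5, 150))
        d1 = DoseEvent(0.0, rng.uniform(50, 150), rng.uniform(0.5, 2))
        d2 = DoseEvent(rng.uniform(6, 18), rng.uniform(40, 100),
                       rng.uniform(0.5, 2))
        times = np.sort(rng.uniform(0, 48, size=8))
        both = predict_concentrations(p, [d1, d2], times)
        single = (predict_concentrations(p, [d1], times)
                  + predict_concentrations(p, [d2], times))
        np.testing.assert_allclose(both, single, rtol=1e-9, atol=1e-12)


def test_mass_balance(table_params):
    """X1 + X2 + CL * integral of C equals the administered amount."""
    p = table_params
    doses = regimen_doses(Regimen(75.0, loading_dose=125.0), 6)
    t_end = 70.0
    tt = np.linspace(0, t_end, 20001)
    c = predict_concentrations(p, doses, tt)
    eliminated = p.CL * np.trapezoid(c, tt)
    x1 = c[-1] * p.Vc
    # X2 by integrating dX2/dt = Q/Vc X1 - Q/Vp X2 on the fine grid
    x2 = 0.0
    for i in range(1, len(tt)):
        dt = tt[i] - tt[i - 1]
        x1a = c[i - 1] * p.Vc
        x1b = c[i] * p.Vc
        # trapezoidal step of the linear ODE (fine grid)
        x2 = ((x2 * (1 - 0.5 * dt * p.Q / p.Vp)
               + 0.5 * dt * p.Q / p.Vc * (x1a + x1b))
              / (1 + 0.5 * dt * p.Q / p.Vp))
    given = sum(d.amount for d in doses if d.time < t_end)
    assert (x1 + x2 + eliminated) == pytest.approx(given, rel=1e-5)


def test_continuity_across_infusion_boundaries(table_params):
    doses = [DoseEvent(0.0, 100.0, 1.0)]
    eps = 1e-7
    t = np.array([1.0 - eps, 1.0, 1.0 + eps])
    c = predict_concentrations(table_params, doses, t)
    assert np.all(c > 0)
    assert abs(c[2] - c[0]) < 1e-4
    assert np.all(np.isfinite(c))


def test_one_compartment_plateau_is_rate_over_cl():
    p = PKParameters(CL=2.0, Vc=20.0)
    doses = [DoseEvent(0.0, 10000.0, 1000.0)]   # 10 mg/h for ~6 weeks
    c = predict_one_compartment(p, doses, [900.0])
    assert c[0] == pytest.approx(10.0 / 2.0, rel=1e-4)


def test_one_compartment_limit_of_two_compartment():
    p1 = PKParameters(CL=1.5, Vc=25.0)
    p2 = PKParameters(CL=1.5, Vc=25.0, Q=1e-8, Vp=10.0)
    doses = [DoseEvent(0.0, 100.0, 1.0), DoseEvent(12.0, 75.0, 1.0)]
    t = np.linspace(0.5, 24, 20)
    np.testing.assert_allclose(predict_one_compartment(p1, doses, t),
                               predict_concentrations(p2, doses, t), rtol=1e-5)


def test_monoexponential_terminal_slope():
    p = PKParameters(CL=2.0, Vc=20.0)
    doses = [DoseEvent(0.0, 100.0, 0.1)]
    t = np.linspace(2, 30, 50)
    c = predict_one_compartment(p, doses, t)
    slope = np.polyfit(t, np.log(c), 1)[0]
    assert slope == pytest.approx(-p.CL / p.Vc, rel=1e-6)


def test_auc24_closed_form_values(table_params):
    assert steady_state_auc24(PKParameters(2.0, 10.0), Regimen(100.0)) \
        == pytest.approx(100.0)
    assert steady_state_auc24(table_params, Regimen(75.0)) \
        == pytest.approx(120.97, abs=0.005)
    assert steady_state_auc24(table_params, Regimen(0.0)) == 0.0


def test_auc24_matches_trapezoidal_integration(table_params):
    """Closed form vs numeric integration of one steady-state interval."""
    reg = Regimen(75.0, loading_dose=100.0)
    # terminal half-life is ~2 days here, so run far past ten intervals
    n_int = 60
    doses = regimen_doses(reg, n_int)
    t = np.linspace((n_int - 2) * 12.0, (n_int - 1) * 12.0, 4001)
    c = predict_concentrations(table_params, doses, t)
    auc24 = 2.0 * np.trapezoid(c, t)
    assert auc24 == pytest.approx(steady_state_auc24(table_params, reg),
                                  rel=5e-3)


def test_vectorized_prediction_agrees_with_scalar(rng, table_params):
    theta = np.abs(rng.normal(1, 0.3, size=(7, 4))) * \
        np.array([1.24, 16.64, 3.04, 66.2])
    doses = [DoseEvent(0.0, 100.0, 1.0), DoseEvent(12.0, 75.0, 1.5)]
    t = np.linspace(0.5, 24, 10)
    many = predict_concentrations_many(theta, doses, t)
    for k in range(theta.shape[0]):
        single = predict_concentrations(PKParameters(*theta[k]), doses, t)
        np.testing.assert_allclose(many[k], single, rtol=1e-12)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        PKParameters(CL=-1.0, Vc=10.0)
    with pytest.raises(ValueError):
        PKParameters(CL=1.0, Vc=10.0, Q=2.0)   # Q without Vp
    with pytest.raises(ValueError):
        Regimen(75.0, interval=1.0, infusion_duration=2.0)
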