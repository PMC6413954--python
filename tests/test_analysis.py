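"""Tests for the closed-form equilibrium theory."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gonogo import (
    ActionSpec,
    LearningParams,
    PathwayWeights,
    ScheduleSpec,
    apply_update,
    balanced_epsilon,
    check_conditions,
    coefficients,
    deterministic_fixed_point,
    detuned_weights,
    discrete_equilibrium,
    effective_rates,
    prediction_error,
    solve_parameters,
    stochastic_equilibrium,
    thalamic_detuned,
)


@pytest.mark.parametrize(
    "alpha, epsilon, expected",
    [
        (0.3, 1.0, (0.3, 0.0)),
        (0.3, 0.0, (0.15, 0.15)),
        (0.3, 0.443, (0.21645, 0.08355)),
    ],
)
def test_effective_rates(alpha, epsilon, expected):
    rates = effective_rates(LearningParams(alpha, epsilon, 0.01))
    assert rates.alpha_Q == pytest.approx(expected[0], abs=1e-12)
    assert rates.alpha_S == pytest.approx(expected[1], abs=1e-12)
    assert rates.alpha_Q + rates.alpha_S == pytest.approx(alpha, abs=1e-15)


def test_coefficients_near_published_values():
    coef = coefficients(LearningParams(0.3, 0.443, 0.093))
    assert coef.c_Q == pytest.approx(0.6995, abs=1e-4)
    assert coef.c_S == pytest.approx(0.8984, abs=1e-4)


def test_coefficients_zero_decay_flagged():
    coef = coefficients(LearningParams(0.3, 0.5, 0.0))
    assert coef.c_Q == 1.0
    assert coef.c_S is None and not coef.c_S_defined


def test_coefficients_linear_slope_gives_zero_spread_coefficient():
    assert coefficients(LearningParams(0.3, 1.0, 0.05)).c_S == 0.0


@pytest.mark.parametrize(
    "alpha, c_Q, c_S, eps_expected, lam_expected",
    [
        (0.3, 0.7, 0.9, 0.443, 0.093),
        (0.1, 0.8, 0.9, 0.6327, 0.0204),
    ],
)
def test_solve_parameters_reference_settings(alpha, c_Q, c_S, eps_expected, lam_expected):
    epsilon, lam = solve_parameters(alpha, c_Q, c_S)
    assert round(epsilon, 3) == pytest.approx(round(eps_expected, 3))
    assert round(lam, 3) == pytest.approx(round(lam_expected, 3))
    assert epsilon == pytest.approx(eps_expected, abs=5e-4)
    assert lam == pytest.approx(lam_expected, abs=5e-4)


@given(
    alpha=st.floats(0.01, 1.0),
    c_Q=st.floats(0.3, 0.99),
    c_S=st.floats(0.05, 2.0),
)
def test_solve_parameters_roundtrip(alpha, c_Q, c_S):
    t = c_S * (1.0 / c_Q - 1.0)
    if t >= 1.0:
        with pytest.raises(ValueError):
            solve_parameters(alpha, c_Q, c_S)
        return
    epsilon, lam = solve_parameters(alpha, c_Q, c_S)
    coef = coefficients(LearningParams(alpha, epsilon, lam))
    assert coef.c_Q == pytest.approx(c_Q, abs=1e-12)
    assert coef.c_S == pytest.approx(c_S, abs=1e-12)


def test_solve_parameters_domain_errors():
    with pytest.raises(ValueError):
        solve_parameters(0.3, 1.0, 0.9)  # c_Q >= 1 would force lam <= 0
    with pytest.raises(ValueError):
        solve_parameters(0.3, 0.3, 0.9)  # epsilon would leave [0, 1]


def test_check_conditions_residual():
    report = check_conditions(LearningParams(0.3, 0.443, 0.093))
    assert abs(report.spread_residual) == pytest.approx(0.0189, abs=1e-4)
    assert report.weak_decay_ratio == pytest.approx(
        2 * 0.093 / (0.3 * 1.443), abs=1e-12
    )
    assert report.c_S_defined


def test_check_conditions_degenerate_cases():
    no_decay = check_conditions(LearningParams(0.3, 0.5, 0.0))
    assert no_decay.weak_decay_ratio == 0.0
    assert no_decay.spread_residual == pytest.approx(-0.15)
    assert not no_decay.c_S_defined
    linear = check_conditions(LearningParams(0.1, 1.0, 0.0))
    assert linear.weak_decay_ok and linear.spread_ok and not linear.c_S_defined


def test_balanced_epsilon_limits_and_value():
    assert balanced_epsilon(0.4, 0.0) == 1.0
    assert balanced_epsilon(0.01, 50.0) < 1e-3  # strong decay drives eps -> 0
    assert balanced_epsilon(0.3, 0.03) == pytest.approx(0.819804, abs=1e-6)


@given(alpha=st.floats(0.01, 1.0), lam=st.floats(1e-4, 0.5))
def test_balanced_epsilon_equalizes_coefficients(alpha, lam):
    eps = balanced_epsilon(alpha, lam)
    coef = coefficients(LearningParams(alpha, eps, lam))
    assert coef.c_Q == pytest.approx(coef.c_S, abs=1e-12)


def test_detuned_weights_reduce_to_payoff_and_cost_at_unit_coefficients():
    g, n = detuned_weights(ActionSpec(17.0, 4.0), 1.0, 1.0)
    assert g == pytest.approx(17.0)
    assert n == pytest.approx(4.0)


@pytest.mark.parametrize(
    "c, D, expected",
    [
        (1.0, 1.0, 20.0),  # full dopamine weights the payoff only
        (1.0, 0.0, -5.0),  # no dopamine weights the cost only
    ],
)
def test_thalamic_detuned_extremes(c, D, expected):
    a = ActionSpec(20.0, 5.0)
    assert thalamic_detuned(a, D, c_Q=c, c_S=c) == pytest.approx(expected)


def test_thalamic_detuned_baseline_scaling():
    a = ActionSpec(20.0, 5.0)
    t = thalamic_detuned(a, 0.5, c_Q=0.8, c_S=0.8)
    assert t == pytest.approx(0.8 * (20.0 - 5.0) / 2.0)


def test_stochastic_equilibrium_two_point(alternating_params):
    spec = ScheduleSpec("two_point", 20.0, 20.0)
    eq = stochastic_equilibrium(spec, alternating_params)
    c_S = coefficients(alternating_params).c_S
    assert eq.Q_star == pytest.approx(0.0, abs=1e-12)
    assert eq.S_star == pytest.approx(c_S * 20.0, abs=1e-9)
    assert eq.G_star == pytest.approx(eq.S_star)
    assert eq.N_star == pytest.approx(eq.S_star)


def test_stochastic_equilibrium_point_mass(alternating_params):
    coef = coefficients(alternating_params)
    q = 7.0
    eq = discrete_equilibrium([q], [1.0], alternating_params)
    assert eq.Q_star == pytest.approx(coef.c_Q * q)
    assert eq.S_star == pytest.approx(coef.c_S * q * (1 - coef.c_Q), abs=1e-12)


def test_stochastic_equilibrium_quadrature_matches_closed_form(alternating_params):
    """A frozen normal distribution through quadrature must agree with the
    gaussian schedule's closed-form folded-normal expression."""
    spec = ScheduleSpec("gaussian", 20.0, 10.0)
    closed = stochastic_equilibrium(spec, alternating_params)
    frozen = stats.norm(spec.gaussian_mu, spec.gaussian_sigma)
    quad = stochastic_equilibrium(frozen, alternating_params)
    assert quad.Q_star == pytest.approx(closed.Q_star, abs=1e-8)
    assert quad.S_star == pytest.approx(closed.S_star, abs=1e-8)


def test_stochastic_equilibrium_requires_decay():
    with pytest.raises(ValueError):
        stochastic_equilibrium(
            ScheduleSpec("two_point", 20.0, 20.0), LearningParams(0.3, 0.5, 0.0)
        )


def test_deterministic_fixed_point_printed_and_exact(alternating_params):
    fp = deterministic_fixed_point(ActionSpec(20.0, 20.0), alternating_params)
    assert fp.Q_star_printed == pytest.approx(3.661, abs=1e-3)
    coef = coefficients(alternating_params)
    # the printed one-line formula omits exactly a factor c_Q
    assert fp.Q_star_exact == pytest.approx(fp.Q_star_printed * coef.c_Q, abs=1e-9)
    assert fp.G_star == pytest.approx(fp.S_star_exact + fp.Q_star_exact)
    assert fp.N_star == pytest.approx(fp.S_star_exact - fp.Q_star_exact)


def test_deterministic_fixed_point_matches_iterated_updates(alternating_params):
    """Independent oracle: iterate the raw G/N updates on the alternating
    schedule until convergence and compare with the closed-form point."""
    a = ActionSpec(20.0, 20.0)
    fp = deterministic_fixed_point(a, alternating_params)
    w = PathwayWeights(0.0, 0.0)
    for _ in range(400):
        for r in (-a.n, a.p):
            w = apply_update(w, prediction_error(r, w), alternating_params)
    assert 0.5 * (w.G - w.N) == pytest.approx(fp.Q_star_exact, abs=1e-9)
    assert 0.5 * (w.G + w.N) == pytest.approx(fp.S_star_exact, abs=1e-9)


def test_deterministic_fixed_point_small_rate_limit():
    """As alpha_Q + lam -> 0 the mean estimate approaches (p - n)/2."""
    p = LearningParams(1e-6, 0.5, 1e-8)
    fp = deterministic_fixed_point(ActionSpec(20.0, 4.0), p)
    assert fp.Q_star_printed == pytest.approx((20.0 - 4.0) / 2.0, rel=1e-4)


def test_fixed_cost_equilibrium_consistent_with_simulation(alternating_params):
    """The folded-normal correction for the fixed-cost/stochastic-payoff
    schedule must match a long Monte-Carlo average of E|R - c|."""
    spec = ScheduleSpec("fixed_cost_stochastic_payoff", 20.0, 10.0, payoff_sd=5.0)
    from gonogo.schedules import schedule_mean_abs

    rng = np.random.default_rng(5)
    draws = np.concatenate(
        [np.full(200_000, -10.0), rng.normal(20.0, 5.0, 200_000)]
    )
    center = 3.0
    mc = np.abs(draws - center).mean()
    assert schedule_mean_abs(spec, center) == pytest.approx(mc, abs=3 * 0.02)
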