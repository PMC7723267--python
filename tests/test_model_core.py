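import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evostab import (
    DomainError,
    DoseSchedule,
    ModelParams,
    dose_response,
    growth_rate_from_doubling_time,
    simulate,
    vector_field,
)
from evostab.model_core import AffineLaw, jacobian


@pytest.mark.parametrize(
    "lam, ktp, mu",
    [(0.0, 10000.0, 1.5), (1.0, 100.0, 0.5), (0.4, 6040.0, 1.1)],
)
def test_dose_response_endpoints_and_midpoint(lam, ktp, mu):
    got_ktp, got_mu = dose_response(lam)
    assert got_ktp == pytest.approx(ktp)
    assert got_mu == pytest.approx(mu)


@pytest.mark.parametrize("lam", [-0.1, 1.01, 2.0])
def test_dose_response_domain(lam):
    with pytest.raises(DomainError):
        dose_response(lam)


@pytest.mark.parametrize(
    "hours, scale, rate",
    [(60.0, 1.0, 0.27726), (48.0, 1.0, 0.34657), (25.0, 1.0, 0.66542),
     (48.0, 0.01, 3.4657e-3)],
)
def test_growth_rate_from_doubling_time(hours, scale, rate):
    assert growth_rate_from_doubling_time(hours, scale) == pytest.approx(rate, abs=1e-5)


def test_growth_rate_domain():
    with pytest.raises(DomainError):
        growth_rate_from_doubling_time(-1.0)
    with pytest.raises(DomainError):
        growth_rate_from_doubling_time(24.0, scale=0.0)


def test_vector_field_vanishes_on_zero_or_capacity_components(params):
    # extinct types have zero rate; T- at carrying capacity has zero rate
    f = vector_field((0.0, 0.0, 10000.0), 0.7, params)
    assert np.allclose(f, 0.0)


def test_vector_field_near_zero_at_reported_equilibrium(params):
    # the two-decimal rounded equilibrium leaves only a rounding-level residual
    f = vector_field((2082.76, 5206.90, 0.0), 0.4, params)
    assert np.all(np.abs(f) < 1e-4)
    # the exact branch value has residual at machine precision
    x_tp = (10000 - 9900 * 0.4) / 1.16
    f = vector_field((0.4 * x_tp, x_tp, 0.0), 0.4, params)
    assert np.all(np.abs(f) < 1e-6)


def test_tplus_collapses_without_tp(params):
    # T+ lives off the TP testosterone supply: vanishing TP means a vanishing
    # T+ carrying capacity and a strongly negative growth rate
    f = vector_field((100.0, params.tp_floor / 2, 0.0), 0.0, params)
    assert f[0] < -1e3


def test_jacobian_matches_finite_differences(params):
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.uniform(10.0, 8000.0, 3)
        lam = rng.uniform(0, 1)
        J = jacobian(x, lam, params)
        J_fd = np.empty((3, 3))
        for j in range(3):
            h = 1e-5 * max(1.0, x[j])
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J_fd[:, j] = (vector_field(xp, lam, params) - vector_field(xm, lam, params)) / (2 * h)
        assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-10)


def test_equilibrium_is_fixed_point_of_flow(params, two_species_target):
    x_star, lam = two_species_target
    traj = simulate(x_star, lam, tf=10000.0)
    assert traj.breach_time is None
    assert np.max(np.abs(np.asarray(traj.final_state) - x_star)) < 0.1


def test_tminus_alone_follows_logistic_curve(params):
    r, K = params.r[2], params.K_Tminus
    x0 = 100.0
    traj = simulate((0.0, 0.0, x0), 0.0, tf=10000.0)
    closed = K / (1.0 + (K / x0 - 1.0) * np.exp(-r * traj.t))
    assert np.max(np.abs(traj.states[:, 2] - closed) / closed) < 1e-4
    # breach when the logistic curve crosses the viability cap
    t_star = math.log((K / x0 - 1.0) / (K / params.viability_cap - 1.0)) / r
    assert traj.breach_time == pytest.approx(t_star, rel=0.01)


def test_full_dose_releases_resistant_clone(params):
    traj = simulate((3000.0, 3000.0, 2900.0), 1.0, tf=10000.0, stop_on_breach=True)
    assert traj.breach_time is not None
    xf = np.asarray(traj.final_state)
    assert xf[2] / xf.sum() > 0.8


def test_adaptive_integrator_agrees_with_rk4(params):
    sched = DoseSchedule(np.array([0.0, 300.0, 700.0]), np.array([0.0, 1.0, 0.3]))
    a = simulate((2000.0, 3000.0, 500.0), sched, tf=1000.0)
    b = simulate((2000.0, 3000.0, 500.0), sched, tf=1000.0, method="adaptive")
    assert np.allclose(a.states, b.states, rtol=1e-5, atol=1e-4)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(0.0, 4500.0), min_size=3, max_size=3),
    doses=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=4),
)
def test_densities_stay_non_negative(x, doses):
    times = np.arange(len(doses)) * 100.0
    sched = DoseSchedule(times, np.array(doses))
    traj = simulate(x, sched, tf=500.0, dt=1.0)
    assert np.all(traj.states >= 0.0)


def test_dose_laws_strictly_decreasing(params):
    lams = np.linspace(0, 1, 101)
    assert np.all(np.diff(params.K_TP_law(lams)) < 0)
    assert np.all(np.diff(params.mu_law(lams)) < 0)


def test_params_validation():
    with pytest.raises(DomainError):
        ModelParams(r=(0.0, 1e-3, 1e-3))
    with pytest.raises(DomainError):
        ModelParams(K_TP_law=AffineLaw(10000.0, -10001.0))  # K_TP(1) < 0


@pytest.mark.parametrize("suffix", [".json", ".yaml"])
def test_params_roundtrip(tmp_path, suffix):
    p = ModelParams().with_alpha(2, 1, 5.0)
    path = tmp_path / f"params{suffix}"
    p.save(path)
    assert ModelParams.load(path) == p


def test_trajectory_csv_export(tmp_path, params):
    import pandas as pd

    traj = simulate((100.0, 200.0, 300.0), 0.5, tf=50.0)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["t", "x_Tplus", "x_TP", "x_Tminus", "dose", "total_volume"]
    assert len(df) == 51


def test_dose_schedule_validation():
    with pytest.raises(DomainError):
        DoseSchedule(np.array([0.0, 0.0]), np.array([0.1, 0.2]))
    with pytest.raises(DomainError):
        DoseSchedule(np.array([0.0]), np.array([1.5]))
    with pytest.raises(DomainError):
        simulate((1.0, 1.0, 1.0), 0.5, t0=10.0, tf=5.0)
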