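import math

import numpy as np
import pytest
import scipy.linalg

from kaiabc import (integrate, detect_period, amplitude, wavepacket_velocity,
                    orbit_area, default_initial_state, build_state_space,
                    build_rate_matrix, uniform_state, get_preset,
                    NoOscillationError, NotConvergedError, IntegrationError,
                    numeric_fixed_point, stability_report)
from kaiabc.dynamics import Trajectory


def test_equilibrium_network_stays_uniform(eq):
    space = build_state_space(eq)
    traj = integrate(eq, uniform_state(space), t_end=50.0, n_out=200)
    assert np.abs(traj.states - 1.0 / space.n).max() < 1e-8


def test_integrator_agrees_with_matrix_exponential(s1):
    """With the KaiA pool effectively infinite the master equation is
    linear and frozen; the integrator must track expm(W t) p0 to 1e-6."""
    p = s1.replace(k_Af=1e-6, A_T=1e6)       # a = k_Af*A_f = 1, frozen
    space = build_state_space(p)
    p0 = default_initial_state(space)
    W = build_rate_matrix(p, p0, space)
    traj = integrate(p, p0, t_end=20.0, n_out=9)
    for i, t in enumerate(traj.times):
        exact = scipy.linalg.expm(W * t) @ p0
        assert np.abs(traj.states[i] - exact).max() < 1e-6


def test_probability_is_conserved_and_nonnegative(osc):
    space = build_state_space(osc)
    traj = integrate(osc, default_initial_state(space), t_end=500.0,
                     n_out=500)
    assert np.abs(traj.states.sum(axis=1) - 1.0).max() <= 1e-8
    assert traj.states.min() >= 0.0


def test_integrate_rejects_bad_inputs(s1):
    space = build_state_space(s1)
    with pytest.raises(IntegrationError):
        integrate(s1, default_initial_state(space), t_end=-1.0)
    bad = np.full(space.n, 0.5)
    with pytest.raises(IntegrationError):
        integrate(s1, bad, t_end=1.0)


def _sinusoid_trajectory(s1, period=24.0, amp=0.2, dt=0.1, n_cycles=12):
    """A synthetic trajectory whose phosphorylation signal is
    0.5 + amp*sin(2*pi*t/period): mass split between P1(0) and P1(N)."""
    space = build_state_space(s1)
    t = np.arange(0.0, n_cycles * period, dt)
    level = 0.5 + amp * np.sin(2 * math.pi * t / period)
    states = np.zeros((len(t), space.n))
    states[:, space.idx_p1(s1.N)] = level       # weight 1
    states[:, space.idx_p1(0)] = 1.0 - level    # weight 0
    return Trajectory(times=t, states=states, params=s1)


def test_period_detection_on_synthetic_sinusoid(s1):
    traj = _sinusoid_trajectory(s1)
    summary = detect_period(traj, transient_fraction=0.1)
    assert summary.oscillating
    assert summary.period == pytest.approx(24.0, abs=0.1)
    assert amplitude(traj, 0.1) == pytest.approx(0.4, rel=1e-3)


def test_constant_signal_is_not_oscillating(s1):
    space = build_state_space(s1)
    t = np.linspace(0, 100, 500)
    states = np.tile(uniform_state(space), (len(t), 1))
    traj = Trajectory(times=t, states=states, params=s1)
    summary = detect_period(traj)
    assert not summary.oscillating
    assert summary.amplitude == 0.0
    with pytest.raises(NoOscillationError):
        wavepacket_velocity(traj)


def test_drifting_period_raises_not_converged(s1):
    space = build_state_space(s1)
    t = np.arange(0, 200, 0.1)
    # chirped signal: instantaneous period drifts by ~40%
    phase = 2 * math.pi * (t / 20.0 + 0.005 * (t / 20.0) ** 2)
    level = 0.5 + 0.2 * np.sin(phase)
    states = np.zeros((len(t), space.n))
    states[:, space.idx_p1(s1.N)] = level
    states[:, space.idx_p1(0)] = 1.0 - level
    with pytest.raises(NotConvergedError):
        detect_period(Trajectory(times=t, states=states, params=s1),
                      transient_fraction=0.1)


def test_velocity_of_uniformly_drifting_packet(s1):
    """A wavepacket rotating rigidly at angular velocity w0 must yield a
    flat (phase, velocity) orbit at w0 — the analytic drift oracle."""
    space = build_state_space(s1)
    w0 = 2 * math.pi / 50.0
    t = np.arange(0.0, 500.0, 0.25)
    kappa = 8.0
    # single uniform cover of the ring: P1 (0..pi) plus P2 (pi..2pi), with
    # half weight at the duplicated seam phases (pi and 0/2pi)
    cover = np.zeros(space.n)
    cover[space.p1_slice] = 1.0
    cover[space.p2_slice] = 1.0
    for i in (space.idx_p1(0), space.idx_p1(s1.N),
              space.idx_p2(s1.N), space.idx_p2(2 * s1.N)):
        cover[i] = 0.5
    states = np.empty((len(t), space.n))
    for i, ti in enumerate(t):
        w = cover * np.exp(kappa * np.cos(space.phi - w0 * ti))
        states[i] = w / w.sum()
    traj = Trajectory(times=t, states=states, params=s1)
    phase, vel = wavepacket_velocity(traj)
    assert np.abs(vel - w0).max() < 0.02 * w0


def test_limit_cycle_period_is_initial_condition_independent(osc):
    rep = stability_report(osc)
    space = build_state_space(osc)
    t_end = 50 * rep.predicted_period
    periods = []
    for p0 in (default_initial_state(space),
               0.8 * rep.fixed_point.p + 0.2 * default_initial_state(space)):
        traj = integrate(osc, p0, t_end=t_end, n_out=3000)
        periods.append(detect_period(traj, 0.5).period)
    assert abs(periods[0] - periods[1]) <= 0.01 * periods[0]


def test_metabolic_compensation_flat_period_varying_amplitude(s2):
    """Raising K_d0 (lower %ATP) changes the oscillation amplitude far
    more than the period: the hallmark of metabolic compensation."""
    results = []
    for K in (1.0, 8.0):
        p = s2.replace(K_d0=K, k1=0.05)
        rep = stability_report(p)
        space = build_state_space(p)
        p0 = 0.9 * rep.fixed_point.p + 0.1 * default_initial_state(space)
        traj = integrate(p, p0, t_end=80 * rep.predicted_period, n_out=3200)
        summary = detect_period(traj, 0.5)
        results.append(summary)
    t_lo, t_hi = results[0].period, results[1].period
    a_lo, a_hi = results[0].amplitude, results[1].amplitude
    period_change = abs(t_hi - t_lo) / t_lo
    amplitude_change = abs(a_hi - a_lo) / max(a_lo, a_hi)
    assert period_change < 0.12
    assert amplitude_change > 2 * period_change


def test_orbit_area_grows_at_lower_K_d0(s2):
    """Smaller K_d0 (more ATP) lets the wave traverse a larger orbit in
    the angle-angular-velocity plane."""
    areas = {}
    for K in (2.0, 8.0):
        p = s2.replace(K_d0=K, k1=0.05)
        rep = stability_report(p)
        space = build_state_space(p)
        p0 = 0.9 * rep.fixed_point.p + 0.1 * default_initial_state(space)
        traj = integrate(p, p0, t_end=80 * rep.predicted_period, n_out=6400)
        areas[K] = orbit_area(*wavepacket_velocity(traj))
    assert areas[2.0] > areas[8.0]
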