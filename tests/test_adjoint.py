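"""Adjoint solver and gradient assembly.

The module's defining property — adjoint gradient equals finite
differences of the discretized cost — is asserted per cost functional in
the acceptance suite; here the structural contracts are covered on small
instances.
"""

import numpy as np
import pytest

from oscontrol.adjoint import (assemble_gradient, cost_gradient,
                               solve_adjoint)
from oscontrol.costs import CostSpec, evaluate
from oscontrol.model import (ControlSignal, NetworkConfig, NodeParams,
                             simulate)


def _total_cost(config, u, proto, spec, x0):
    ctl = ControlSignal(dt=proto.dt, u=u, t0C=proto.t0C, t1C=proto.t1C)
    traj = simulate(config, ctl, initial_state=x0)
    return evaluate(traj, ctl, spec).total


def test_zero_source_gives_zero_adjoint(two_node_random, rng):
    traj = simulate(two_node_random, duration=20.0,
                    initial_state=rng.random(4))
    adj = solve_adjoint(traj, np.zeros_like(traj.E), two_node_random)
    assert not adj.lam_E.any() and not adj.lam_I.any()


def test_final_condition_is_exactly_zero(two_node_random, rng):
    spec = CostSpec("variance", 3.0, t0=5.0, T=20.0)
    ctl = ControlSignal.zero(2, 20.0)
    traj = simulate(two_node_random, ctl, initial_state=rng.random(4))
    bd = evaluate(traj, ctl, spec)
    adj = solve_adjoint(traj, bd.g_series, two_node_random, ctl)
    assert not adj.lam_E[:, -1].any() and not adj.lam_I[:, -1].any()


def test_energy_only_gradient_is_control(two_node_random, rng):
    """With zero adjoint source the gradient reduces to u exactly."""
    ctl = ControlSignal.zero(2, 20.0, t0C=2.0, t1C=18.0)
    ctl.u[:] = rng.standard_normal(ctl.u.shape)
    ctl = ctl.masked()
    traj = simulate(two_node_random, ctl, initial_state=rng.random(4))
    adj = solve_adjoint(traj, np.zeros_like(traj.E), two_node_random, ctl)
    grad = assemble_gradient(adj, ctl, traj, two_node_random)
    np.testing.assert_array_equal(grad.grad, ctl.u)


def test_gradient_masked_outside_control_interval(two_node_random, rng):
    spec = CostSpec("fourier_osc", 5.0, t0=5.0, T=20.0, omega=0.5)
    ctl = ControlSignal.zero(2, 20.0, t0C=5.0, t1C=15.0)
    ctl.u[:] = 0.1 * rng.standard_normal(ctl.u.shape)
    grad, _, _ = cost_gradient(two_node_random, ctl.masked(), spec,
                               initial_state=rng.random(4))
    mask = ctl.mask()
    assert not grad.grad[:, ~mask].any()
    assert grad.grad[:, mask].any()


def test_gradient_linear_in_cost_combination(two_node_random, rng):
    """Gradient of w1*F1 + w2*F2 equals the sum of the single gradients
    (all sharing one energy term, which is subtracted once)."""
    x0 = rng.random(4)
    ctl = ControlSignal.zero(2, 20.0)
    ctl.u[:] = 0.2 * rng.standard_normal(ctl.u.shape)
    traj = simulate(two_node_random, ctl, initial_state=x0)
    s1 = CostSpec("variance", 2.0, t0=5.0, T=20.0)
    s2 = CostSpec("fourier_sync", -3.0, t0=5.0, T=20.0, omega=0.4)
    b1 = evaluate(traj, ctl, s1)
    b2 = evaluate(traj, ctl, s2)
    g_comb = solve_adjoint(traj, b1.g_series + b2.g_series,
                           two_node_random, ctl)
    g1 = solve_adjoint(traj, b1.g_series, two_node_random, ctl)
    g2 = solve_adjoint(traj, b2.g_series, two_node_random, ctl)
    np.testing.assert_allclose(g_comb.lam_E, g1.lam_E + g2.lam_E,
                               rtol=1e-10, atol=1e-14)


def test_no_delay_matches_dense_one_step_oracle(rng):
    """With D = 0 the adjoint equals plain reverse accumulation through
    numerically differentiated one-step maps."""
    N = 2
    C = np.array([[0.0, 1.0], [1.0, 0.0]])
    cfg = NetworkConfig(N=N, params=NodeParams(), C=C, D=np.zeros((2, 2)),
                        c_gl=0.8, E_ext=[0.8, 1.1], I_ext=[0.4, 0.6])
    dt, T = 0.1, 8.0
    NT = int(T / dt)
    x0 = rng.random(2 * N)
    ctl = ControlSignal.zero(N, T)
    traj = simulate(cfg, ctl, initial_state=x0)
    spec = CostSpec("variance", 2.0, t0=2.0, T=T)
    bd = evaluate(traj, ctl, spec)
    adj = solve_adjoint(traj, bd.g_series, cfg, ctl)

    def step(x):
        """One Euler step computed through simulate (independent path)."""
        t1 = simulate(cfg, duration=dt, dt=dt, initial_state=x)
        return t1.final_state()

    G = dt * bd.g_series  # discrete source acting on E components
    lam = np.zeros((NT + 1, 2 * N))
    lam[NT, :N] = G[:, NT]
    eps = 1e-7
    for k in range(NT - 1, -1, -1):
        x = np.concatenate([traj.E[:, k], traj.I[:, k]])
        J = np.empty((2 * N, 2 * N))
        for j in range(2 * N):
            xp, xm = x.copy(), x.copy()
            xp[j] = min(xp[j] + eps, 1.0)
            xm[j] = max(xm[j] - eps, 0.0)
            J[:, j] = (step(xp) - step(xm)) / (xp[j] - xm[j])
        lam[k] = J.T @ lam[k + 1]
        lam[k, :N] += G[:, k]
    np.testing.assert_allclose(adj.lam_E.T, lam[:, :N], rtol=2e-5, atol=1e-10)
    np.testing.assert_allclose(adj.lam_I.T, lam[:, N:], rtol=2e-5, atol=1e-10)


def test_delayed_gradient_matches_finite_differences(two_node_random, rng):
    """Spot-check of the defining FD property on the delayed network."""
    spec = CostSpec("cross_correlation", 3.0, t0=5.0, T=20.0)
    x0 = rng.random(4)
    u0 = 0.3 * rng.standard_normal((2, 201))
    ctl = ControlSignal(dt=0.1, u=u0.copy(), t0C=0.0, t1C=20.0)
    grad, _, _ = cost_gradient(two_node_random, ctl, spec, initial_state=x0)
    eps = 1e-6
    for _ in range(10):
        n, k = rng.integers(2), rng.integers(200)
        up, um = u0.copy(), u0.copy()
        up[n, k] += eps
        um[n, k] -= eps
        fd = (_total_cost(two_node_random, up, ctl, spec, x0)
              - _total_cost(two_node_random, um, ctl, spec, x0)) / (2 * eps)
        assert grad.grad[n, k] * 0.1 == pytest.approx(fd, rel=1e-4, abs=1e-12)
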