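"""Cost functionals: analytic values, derivative series, sign and scaling
contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oscontrol.costs import (CostSpec, DegenerateInputError,
                             cross_correlation_cost, energy_cost,
                             fourier_osc_cost, fourier_sync_cost,
                             precision_cost, variance_cost)
from oscontrol.model import ControlSignal

DT = 0.1


def _grid(T=60.0):
    NT = int(round(T / DT))
    return np.arange(NT + 1) * DT


def _random_series(rng, N=2, T=60.0):
    """Smooth random multi-node series (band-limited noise)."""
    t = _grid(T)
    x = np.zeros((N, len(t)))
    for n in range(N):
        for f, a, p in zip(rng.uniform(0.02, 0.2, 4),
                           rng.uniform(0.1, 1.0, 4),
                           rng.uniform(0, 2 * np.pi, 4)):
            x[n] += a * np.sin(2 * np.pi * f * t + p)
    return x


def _fd_check(fun, x, g, rng, n_probes=25, rel_tol=1e-6):
    """Central finite differences of the discretized value vs dt * g."""
    eps = 1e-6
    worst = 0.0
    for _ in range(n_probes):
        n = rng.integers(x.shape[0])
        k = rng.integers(x.shape[1])
        xp, xm = x.copy(), x.copy()
        xp[n, k] += eps
        xm[n, k] -= eps
        fd = (fun(xp) - fun(xm)) / (2 * eps)
        an = DT * g[n, k]
        denom = max(abs(fd), abs(an))
        if denom > 1e-14:
            worst = max(worst, abs(fd - an) / denom)
    assert worst < rel_tol


class TestEnergy:
    def test_zero_control(self):
        ctl = ControlSignal.zero(1, 10.0, DT)
        value, du = energy_cost(ctl)
        assert value == 0.0 and not du.any()

    def test_unit_control_half_T(self):
        ctl = ControlSignal.zero(1, 10.0, DT)
        ctl.u[:] = 1.0
        value, _ = energy_cost(ctl)
        assert value == pytest.approx(5.0)

    def test_matches_summation_oracle(self, rng):
        ctl = ControlSignal.zero(3, 20.0, DT)
        ctl.u[:] = rng.standard_normal(ctl.u.shape)
        value, du = energy_cost(ctl)
        oracle = 0.5 * sum(ctl.u[n, k] ** 2 * DT
                           for n in range(3) for k in range(ctl.u.shape[1] - 1))
        assert value == pytest.approx(oracle, rel=1e-12)
        # derivative series equals u on its support; the final grid point
        # lies outside the half-open integration window
        np.testing.assert_array_equal(du[:, :-1], ctl.u[:, :-1])
        np.testing.assert_array_equal(du[:, -1], 0.0)


class TestPrecision:
    def test_zero_at_reference(self, rng):
        x = _random_series(rng)
        value, g = precision_cost(x, x, 2.0, DT, 0.0, 60.0)
        assert value == 0.0 and not g.any()

    def test_constant_offset_closed_form(self):
        t0, T, w_P, delta, K = 10.0, 50.0, 3.0, 0.2, 2
        x = np.zeros((K, len(_grid(60.0))))
        ref = x - delta
        value, _ = precision_cost(x, ref, w_P, DT, t0, T)
        assert value == pytest.approx(w_P * K * delta ** 2 / 2, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            precision_cost(np.zeros((2, 10)), np.zeros((3, 10)), 1.0,
                           DT, 0.0, 0.5)

    def test_g_matches_finite_differences(self, rng):
        x = _random_series(rng)
        ref = _random_series(rng)
        w_P = 2.5
        _, g = precision_cost(x, ref, w_P, DT, 10.0, 50.0)
        _fd_check(lambda xx: precision_cost(xx, ref, w_P, DT, 10.0, 50.0)[0],
                  x, g, rng)


class TestFourier:
    # omega with period 20 = 200 grid steps; windows of whole periods
    OMEGA = 2 * np.pi / 20.0

    def test_inphase_cosines_give_minus_quarter(self):
        t = _grid(100.0)
        x = np.vstack([np.cos(self.OMEGA * t)] * 3)
        v_sync, _ = fourier_sync_cost(x, self.OMEGA, DT, 0.0, 100.0)
        v_osc, _ = fourier_osc_cost(x, self.OMEGA, DT, 0.0, 100.0)
        assert v_sync == pytest.approx(-0.25, abs=1e-6)
        assert v_osc == pytest.approx(-0.25, abs=1e-6)

    def test_antiphase_sync_zero_but_osc_minus_quarter(self):
        t = _grid(100.0)
        x = np.vstack([np.cos(self.OMEGA * t), -np.cos(self.OMEGA * t)])
        v_sync, _ = fourier_sync_cost(x, self.OMEGA, DT, 0.0, 100.0)
        v_osc, _ = fourier_osc_cost(x, self.OMEGA, DT, 0.0, 100.0)
        assert v_sync == pytest.approx(0.0, abs=1e-12)
        assert v_osc == pytest.approx(-0.25, abs=1e-6)

    def test_single_node_costs_identical(self, rng):
        x = _random_series(rng, N=1)
        v_sync, g_sync = fourier_sync_cost(x, self.OMEGA, DT, 5.0, 55.0)
        v_osc, g_osc = fourier_osc_cost(x, self.OMEGA, DT, 5.0, 55.0)
        assert v_sync == pytest.approx(v_osc, rel=1e-12)
        np.testing.assert_allclose(g_sync, g_osc, rtol=1e-12)

    @pytest.mark.parametrize("fun", [fourier_sync_cost, fourier_osc_cost])
    def test_g_matches_finite_differences(self, fun, rng):
        x = _random_series(rng)
        _, g = fun(x, self.OMEGA, DT, 10.0, 50.0)
        _fd_check(lambda xx: fun(xx, self.OMEGA, DT, 10.0, 50.0)[0],
                  x, g, rng, rel_tol=1e-5)


class TestCrossCorrelation:
    def test_identical_nodes_give_minus_one(self, rng):
        x = np.vstack([_random_series(rng, N=1)] * 3)
        value, _ = cross_correlation_cost(x, DT, 0.0, 60.0)
        assert value == pytest.approx(-1.0, rel=1e-12)

    def test_sign_flipped_give_plus_one(self, rng):
        base = _random_series(rng, N=1)
        base -= base.mean()
        x = np.vstack([base, -base])
        value, _ = cross_correlation_cost(x, DT, 0.0, 60.0)
        assert value == pytest.approx(1.0, rel=1e-12)

    def test_orthogonal_sin_cos_give_zero(self):
        t = _grid(100.0)
        om = 2 * np.pi / 20.0
        x = np.vstack([np.sin(om * t), np.cos(om * t)])
        value, _ = cross_correlation_cost(x, DT, 0.0, 100.0)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_node_raises(self, rng):
        x = _random_series(rng)
        x[1] = 0.42
        with pytest.raises(DegenerateInputError):
            cross_correlation_cost(x, DT, 0.0, 60.0)

    def test_g_matches_finite_differences(self, rng):
        x = _random_series(rng, N=3)
        _, g = cross_correlation_cost(x, DT, 10.0, 50.0)
        _fd_check(lambda xx: cross_correlation_cost(xx, DT, 10.0, 50.0)[0],
                  x, g, rng, rel_tol=1e-5)


class TestVariance:
    def test_identical_nodes_give_zero(self, rng):
        x = np.vstack([_random_series(rng, N=1)] * 4)
        value, g = variance_cost(x, DT, 0.0, 60.0)
        assert value == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_symmetric_constants_closed_form(self):
        a = 0.3
        x = np.vstack([np.full(601, a), np.full(601, -a)])
        value, _ = variance_cost(x, DT, 0.0, 60.0)
        assert value == pytest.approx(a ** 2, rel=1e-12)

    def test_g_sums_to_zero_across_nodes(self, rng):
        x = _random_series(rng, N=4)
        _, g = variance_cost(x, DT, 10.0, 50.0)
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-15)

    def test_g_matches_finite_differences(self, rng):
        x = _random_series(rng, N=3)
        _, g = variance_cost(x, DT, 10.0, 50.0)
        _fd_check(lambda xx: variance_cost(xx, DT, 10.0, 50.0)[0], x, g, rng)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), amp=st.floats(0.1, 5.0))
def test_cost_contracts_on_random_series(seed, amp):
    """Sign contracts, Cauchy-Schwarz ordering, and amplitude scaling."""
    rng = np.random.default_rng(seed)
    x = _random_series(rng, N=3)
    om = 2 * np.pi / 20.0
    v_sync, _ = fourier_sync_cost(x, om, DT, 0.0, 60.0)
    v_osc, _ = fourier_osc_cost(x, om, DT, 0.0, 60.0)
    v_var, _ = variance_cost(x, DT, 0.0, 60.0)
    v_cc, _ = cross_correlation_cost(x, DT, 0.0, 60.0)
    assert v_sync <= 0 and v_osc <= 0
    assert v_var >= 0
    assert -1.0 - 1e-9 <= v_cc <= 1.0 + 1e-9
    # |sum_n z_n|^2 <= N sum_n |z_n|^2
    assert v_sync >= v_osc - 1e-12
    # quadratic amplitude scaling of Fourier and variance costs
    v_sync_a, _ = fourier_sync_cost(amp * x, om, DT, 0.0, 60.0)
    v_var_a, _ = variance_cost(amp * x, DT, 0.0, 60.0)
    assert v_sync_a == pytest.approx(amp ** 2 * v_sync, rel=1e-9)
    assert v_var_a == pytest.approx(amp ** 2 * v_var, rel=1e-9)
    # cross-correlation invariant under per-node positive affine maps
    scale = rng.uniform(0.5, 2.0, (3, 1))
    shift = rng.uniform(-1.0, 1.0, (3, 1))
    v_cc_a, _ = cross_correlation_cost(scale * x + shift, DT, 0.0, 60.0)
    assert v_cc_a == pytest.approx(v_cc, rel=1e-9, abs=1e-9)


def test_cost_spec_validation():
    with pytest.raises(ValueError):
        CostSpec("fourier_sync", 1.0, t0=10.0, T=5.0, omega=1.0)
    with pytest.raises(ValueError):
        CostSpec("fourier_sync", 1.0, t0=0.0, T=5.0)  # missing omega
    with pytest.raises(ValueError):
        CostSpec("variance", 0.0, t0=0.0, T=5.0)      # zero weight
    with pytest.raises(ValueError):
        CostSpec("precision", 1.0, t0=0.0, T=5.0)     # missing reference
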