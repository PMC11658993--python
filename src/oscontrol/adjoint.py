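"""Adjoint state and cost gradient for the controlled Wilson-Cowan network.

The gradient of the total cost with respect to the control is assembled
from a single backward sweep of the adjoint state — one simulation's worth
of work regardless of how many control degrees of freedom there are.

The sweep is the exact reverse-mode differentiation of the explicit-Euler
forward map, i.e. the discrete counterpart of the delayed adjoint equation:
the adjoint is integrated backwards from lambda(T) = 0, with each coupling
delay d feeding the future value lambda(t + d) back into the present,
gated so that look-ups beyond T vanish.  Because forward and backward
sweeps discretize the same map, the assembled gradient matches finite
differences of the discretized cost to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .costs import CostBreakdown, CostSpec, evaluate
from .model import (ControlSignal, NetworkConfig, StateTrajectory,
                    synaptic_inputs)

__all__ = ["AdjointState", "GradientSeries", "solve_adjoint",
           "assemble_gradient", "cost_gradient"]


@dataclass
class AdjointState:
    """Adjoint trajectory lambda, split into E- and I-components.

    ``lam_E[n, k]`` is the sensitivity of the accuracy cost to a
    perturbation of E_n at grid time k (and likewise ``lam_I``); the final
    column is exactly zero.
    """

    dt: float
    lam_E: np.ndarray
    lam_I: np.ndarray


@dataclass
class GradientSeries:
    """Cost gradient d F / d u_n(t) on the grid, zero outside the control
    interval."""

    dt: float
    grad: np.ndarray

    def masked_norm(self) -> float:
        return float(np.sqrt((self.grad ** 2).sum() * self.dt))


def solve_adjoint(trajectory: StateTrajectory, g_series: np.ndarray,
                  config: NetworkConfig, control: ControlSignal | None = None,
                  observable: str = "E") -> AdjointState:
    """Backward sweep of the adjoint system along a stored trajectory.

    Parameters
    ----------
    g_series
        Weighted accuracy-cost derivative w_X * dF_X/dx(t) on the grid
        (shape (N, NT + 1), zero outside the measurement window) acting on
        the chosen observable.
    control
        The control under which ``trajectory`` was produced (needed to
        reconstruct synaptic arguments; ``None`` means u = 0).

    With g identically zero the homogeneous system yields lambda = 0.
    """
    if g_series.shape != trajectory.E.shape:
        raise ValueError("g_series must match the trajectory grid")
    if not np.isfinite(g_series).all():
        raise ValueError("non-finite g_series")
    a, b = synaptic_inputs(trajectory, control, config)
    p = config.params
    # discrete-scale source: dPhi/dx_n[k] = dt * g(t_k)
    GE = np.zeros_like(g_series)
    GI = np.zeros_like(g_series)
    if observable == "E":
        GE = trajectory.dt * g_series
    else:
        GI = trajectory.dt * g_series
    lam_E, lam_I = _kernels.adjoint(
        trajectory.E, trajectory.I, a, b, GE, GI,
        config.c_gl * config.C, config.delay_steps(trajectory.dt),
        p.tau_E, p.tau_I, p.gamma, p.mu, p.c_EE, p.c_EI, p.c_IE, p.c_II,
        trajectory.dt)
    if not (np.isfinite(lam_E).all() and np.isfinite(lam_I).all()):
        raise FloatingPointError("non-finite adjoint state")
    return AdjointState(dt=trajectory.dt, lam_E=lam_E, lam_I=lam_I)


def assemble_gradient(adjoint: AdjointState, control: ControlSignal,
                      trajectory: StateTrajectory,
                      config: NetworkConfig) -> GradientSeries:
    """Combine energy term and adjoint state into the cost gradient.

    grad_n(t_k) = u_n(t_k) + lambda-projection of dh/du at t_k, masked to
    the control interval.  For an energy-only problem (zero adjoint) the
    gradient is exactly u.
    """
    if adjoint.lam_E.shape != control.u.shape:
        raise ValueError("adjoint and control grids differ")
    p = config.params
    a, _ = synaptic_inputs(trajectory, control, config)
    from .model import _sigmoid_deriv
    dSa = _sigmoid_deriv(a, p.gamma, p.mu)
    sens = (1.0 - trajectory.E) * dSa / p.tau_E   # d rhs_E / d u on the grid
    grad = control.masked().u.copy()
    grad[:, :-1] += adjoint.lam_E[:, 1:] * sens[:, :-1]
    grad[:, ~control.mask()] = 0.0
    return GradientSeries(dt=control.dt, grad=grad)


def cost_gradient(config: NetworkConfig, control: ControlSignal,
                  spec: CostSpec, trajectory: StateTrajectory | None = None,
                  initial_state: np.ndarray | None = None,
                  ) -> tuple[GradientSeries, CostBreakdown, StateTrajectory]:
    """Forward simulation + cost evaluation + adjoint sweep in one call."""
    from .model import simulate
    if trajectory is None:
        trajectory = simulate(config, control, initial_state=initial_state)
    breakdown = evaluate(trajectory, control, spec)
    adj = solve_adjoint(trajectory, breakdown.g_series, config, control,
                        observable=spec.observable)
    grad = assemble_gradient(adj, control, trajectory, config)
    return grad, breakdown, trajectory
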