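"""Cost functionals for oscillation and synchrony control, and their
state-derivatives.

Every accuracy functional ``F_X`` comes with the series ``g = dF_X/dx(t)``
that the adjoint method needs.  All time integrals use the left-rectangle
rule on the simulation grid over the half-open measurement window
[t0, T); this makes each ``g`` the *exact* derivative of the discretized
value (up to roundoff), which is the property the gradient tests assert.

Cost kinds
----------
precision
    Classical tracking cost: mean squared distance to a reference.
fourier_sync
    Negative squared Fourier component at the target frequency of the
    *summed* network activity; rewards coherent network power.
fourier_osc
    Negative sum of node-wise squared Fourier components; phase-indifferent.
cross_correlation
    Negative mean pairwise Pearson correlation of the node observables.
variance
    Time-averaged across-node variance; zero iff all nodes move together.

Negative weights flip the direction of each functional, e.g. a negative
fourier weight suppresses the target mode and a negative cross-correlation
weight drives desynchronization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import ControlSignal, StateTrajectory, interval_indices

__all__ = [
    "CostSpec",
    "CostBreakdown",
    "DegenerateInputError",
    "energy_cost",
    "precision_cost",
    "fourier_sync_cost",
    "fourier_osc_cost",
    "cross_correlation_cost",
    "variance_cost",
    "evaluate",
    "ACCURACY_COSTS",
]

CostKind = Literal["precision", "fourier_sync", "fourier_osc",
                   "cross_correlation", "variance"]

#: node variance below which the Pearson correlation is undefined
_VARIANCE_FLOOR = 1e-12


class DegenerateInputError(ValueError):
    """A cost functional was evaluated on an input where it is undefined."""


@dataclass(frozen=True)
class CostSpec:
    """Which accuracy functional to optimize, and on what window.

    Parameters
    ----------
    kind
        One of the five cost kinds.
    weight
        Signed weight w_X multiplying the accuracy term.  Sign selects
        enforcement vs suppression, see module docstring.
    t0, T
        Measurement interval; the functional is evaluated on [t0, T).
    omega
        Target angular frequency (fourier kinds only), omega = 2 pi f with
        f in cycles per time unit.
    reference
        Target trajectory (precision only), shape (N, NT + 1).
    observable
        Which per-node state component the functional sees; the excitatory
        activity by default.
    """

    kind: CostKind
    weight: float
    t0: float
    T: float
    omega: float | None = None
    reference: np.ndarray | None = None
    observable: Literal["E", "I"] = "E"

    def __post_init__(self):
        if self.t0 >= self.T:
            raise ValueError("t0 must be smaller than T")
        if self.weight == 0:
            raise ValueError("weight must be non-zero")
        if self.kind in ("fourier_sync", "fourier_osc"):
            if self.omega is None or self.omega <= 0:
                raise ValueError(f"{self.kind} requires omega > 0")
        if self.kind == "precision" and self.reference is None:
            raise ValueError("precision cost requires a reference trajectory")

    def with_weight(self, w: float) -> "CostSpec":
        from dataclasses import replace
        return replace(self, weight=w)


@dataclass
class CostBreakdown:
    """Evaluated cost terms: total = weight * F_X + F_E.

    ``g_series`` is the weighted derivative w_X * dF_X/dx(t), zero outside
    the measurement window — the source term of the adjoint equation.
    """

    F_E: float
    F_X: float
    weight: float
    g_series: np.ndarray

    @property
    def total(self) -> float:
        return self.weight * self.F_X + self.F_E


def _window(x: np.ndarray, dt: float, t0: float, T: float):
    n_steps = x.shape[-1] - 1
    sl = interval_indices(t0, T, dt, n_steps)
    length = (sl.stop - sl.start) * dt
    if length <= 0:
        raise ValueError("empty measurement window")
    return sl, length


def energy_cost(control: ControlSignal) -> tuple[float, np.ndarray]:
    """Energy term 0.5 * integral u^2 dt over [0, T) and its u-derivative.

    The derivative series is simply ``u`` itself.
    """
    u = control.masked().u
    value = 0.5 * float((u[:, :-1] ** 2).sum()) * control.dt
    return value, u.copy()


def precision_cost(x: np.ndarray, x_ref: np.ndarray, w_P: float,
                   dt: float, t0: float, T: float) -> tuple[float, np.ndarray]:
    """Weighted mean squared deviation from a reference trajectory.

    value = w_P / (2 (T - t0)) * integral (x - x_ref)^2 dt, with
    g = w_P (x - x_ref) / (T - t0) on the window.  Unlike the other
    functionals the weight is folded in here, matching the classical
    definition of the tracking term.
    """
    x = np.asarray(x, float)
    x_ref = np.asarray(x_ref, float)
    if x.shape != x_ref.shape:
        raise ValueError("x and x_ref must have the same shape")
    sl, Tm = _window(x, dt, t0, T)
    diff = x[:, sl] - x_ref[:, sl]
    value = w_P / (2.0 * Tm) * float((diff ** 2).sum()) * dt
    g = np.zeros_like(x)
    g[:, sl] = w_P * diff / Tm
    return value, g


def _fourier_components(x, dt, sl, omega):
    t = np.arange(x.shape[1]) * dt
    phase = np.exp(-1j * omega * t[sl])
    z = (x[:, sl] * phase).sum(axis=1) * dt   # per-node integral of x e^{-iwt}
    return z, t


def fourier_sync_cost(x: np.ndarray, omega: float, dt: float,
                      t0: float, T: float) -> tuple[float, np.ndarray]:
    """Synchronization Fourier cost of the summed observables.

    value = -|integral sum_n x_n(t) e^{-i omega t} dt|^2 / (N^2 (T-t0)^2),
    always <= 0.  Its derivative g is identical for every node.
    """
    x = np.asarray(x, float)
    N = x.shape[0]
    sl, Tm = _window(x, dt, t0, T)
    z, t = _fourier_components(x, dt, sl, omega)
    zsum = z.sum()
    value = -abs(zsum) ** 2 / (N ** 2 * Tm ** 2)
    g = np.zeros_like(x)
    g[:, sl] = -2.0 / (N ** 2 * Tm ** 2) * np.real(
        zsum * np.exp(1j * omega * t[sl]))
    return value, g


def fourier_osc_cost(x: np.ndarray, omega: float, dt: float,
                     t0: float, T: float) -> tuple[float, np.ndarray]:
    """Oscillation Fourier cost: node-wise power at the target frequency.

    value = -sum_n |integral x_n e^{-i omega t} dt|^2 / (N (T-t0)^2).
    Each node's g depends on that node's series only, so relative phases
    are not rewarded.  For N = 1 this equals :func:`fourier_sync_cost`.
    """
    x = np.asarray(x, float)
    N = x.shape[0]
    sl, Tm = _window(x, dt, t0, T)
    z, t = _fourier_components(x, dt, sl, omega)
    value = -float((np.abs(z) ** 2).sum()) / (N * Tm ** 2)
    g = np.zeros_like(x)
    g[:, sl] = -2.0 / (N * Tm ** 2) * np.real(
        z[:, None] * np.exp(1j * omega * t[sl])[None, :])
    return value, g


def cross_correlation_cost(x: np.ndarray, dt: float,
                           t0: float, T: float) -> tuple[float, np.ndarray]:
    """Negative mean pairwise Pearson correlation of the node observables.

    value in [-1, 1]: -1 for identical (perfectly correlated) nodes, +1 for
    perfectly anti-correlated pairs.  Requires N >= 2 and non-degenerate
    per-node variance on the window.
    """
    x = np.asarray(x, float)
    N = x.shape[0]
    if N < 2:
        raise ValueError("cross-correlation cost requires N >= 2")
    sl, Tm = _window(x, dt, t0, T)
    xw = x[:, sl]
    y = xw - xw.mean(axis=1, keepdims=True)
    var = (y ** 2).sum(axis=1) * dt / Tm
    if (var < _VARIANCE_FLOOR).any():
        bad = int(np.argmin(var))
        raise DegenerateInputError(
            f"node {bad} has (near-)zero variance on the measurement window; "
            "the Pearson correlation is undefined")
    sig = np.sqrt(var)
    Ikl = (y @ y.T) * dt                       # integral of y_k y_l
    corr = Ikl / (Tm * np.outer(sig, sig))
    pair_sum = (corr.sum() - np.trace(corr)) / 2.0
    value = -2.0 / (N * (N - 1)) * pair_sum

    # g_k(t) = dF/dx_k(t): differentiate -2/(N(N-1)Tm) sum_{n<l} I_nl/(s_n s_l)
    inv = 1.0 / sig
    sum_yl = (inv[:, None] * y).sum(axis=0)[None, :] - inv[:, None] * y
    Isum = ((Ikl * inv[None, :]).sum(axis=1)
            - np.diag(Ikl) * inv)              # sum_{l != k} I_kl / s_l
    g = np.zeros_like(x)
    g[:, sl] = (-2.0 / (N * (N - 1) * Tm)) * (
        inv[:, None] * sum_yl
        - y * (Isum / (Tm * sig ** 3))[:, None])
    return value, g


def variance_cost(x: np.ndarray, dt: float,
                  t0: float, T: float) -> tuple[float, np.ndarray]:
    """Time-averaged across-node variance of the observables.

    value = 1/(N (T-t0)) * integral sum_n (x_n(t) - xbar(t))^2 dt >= 0,
    where xbar(t) is the network mean; zero iff all nodes coincide on the
    window.  The g-series sums to zero across nodes at every time.
    """
    x = np.asarray(x, float)
    N = x.shape[0]
    if N < 2:
        raise ValueError("variance cost requires N >= 2")
    sl, Tm = _window(x, dt, t0, T)
    dev = x[:, sl] - x[:, sl].mean(axis=0, keepdims=True)
    value = float((dev ** 2).sum()) * dt / (N * Tm)
    g = np.zeros_like(x)
    g[:, sl] = 2.0 * dev / (N * Tm)
    return value, g


ACCURACY_COSTS = ("precision", "fourier_sync", "fourier_osc",
                  "cross_correlation", "variance")


def evaluate(trajectory: StateTrajectory, control: ControlSignal,
             spec: CostSpec) -> CostBreakdown:
    """Evaluate total cost w_X * F_X + F_E on a trajectory.

    Returns the breakdown including the weighted g-series used as the
    adjoint source term.
    """
    x = trajectory.E if spec.observable == "E" else trajectory.I
    dt = trajectory.dt
    if spec.kind == "precision":
        # weight handled inside the classical definition; report F_X
        # unweighted for a uniform breakdown
        value, g = precision_cost(x, spec.reference, 1.0, dt, spec.t0, spec.T)
    elif spec.kind == "fourier_sync":
        value, g = fourier_sync_cost(x, spec.omega, dt, spec.t0, spec.T)
    elif spec.kind == "fourier_osc":
        value, g = fourier_osc_cost(x, spec.omega, dt, spec.t0, spec.T)
    elif spec.kind == "cross_correlation":
        value, g = cross_correlation_cost(x, dt, spec.t0, spec.T)
    elif spec.kind == "variance":
        value, g = variance_cost(x, dt, spec.t0, spec.T)
    else:
        raise ValueError(f"unknown cost kind: {spec.kind!r}")
    F_E, _ = energy_cost(control)
    return CostBreakdown(F_E=F_E, F_X=value, weight=spec.weight,
                         g_series=spec.weight * g)
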