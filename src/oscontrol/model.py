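"""Delay-coupled Wilson-Cowan networks: forward simulation and linearization.

The Wilson-Cowan model describes each network node by the fractions
``E_n(t)``, ``I_n(t)`` of active excitatory and inhibitory neurons,

.. math::

    \\tau_E \\dot E_n = -E_n + (1 - E_n)\\,
        S(c_{EE} E_n - c_{EI} I_n + E^{ext} + u_n
          + c_{gl} \\sum_m C_{nm} E_m(t - D_{nm}))

    \\tau_I \\dot I_n = -I_n + (1 - I_n)\\,
        S(c_{IE} E_n - c_{II} I_n + I^{ext})

with the sigmoid transfer ``S(x) = (1 + exp(-gamma (x - mu)))**-1``.  Nodes
couple through their excitatory populations with weight matrix ``C`` (row =
receiving node), delay matrix ``D``, and global gain ``c_gl``; the additive
control ``u_n(t)`` enters the excitatory synaptic argument only.

Time units are dimensionless; for frequencies quoted in Hz the package
convention is 1 time unit = 1 ms.

Integration is explicit Euler on the uniform grid ``t_k = k * dt`` with
delays rounded to grid steps and constant pre-simulation history.  The
``(1 - x) S(...) - x`` form keeps activities in [0, 1] for any admissible
control as long as ``dt <= min(tau_E, tau_I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from . import _kernels

__all__ = [
    "NodeParams",
    "NetworkConfig",
    "StateTrajectory",
    "ControlSignal",
    "IntegrationError",
    "sigmoid",
    "simulate",
    "jacobians",
    "classify_regime",
    "single_node",
    "interval_indices",
]

#: default integration step, in model time units
DEFAULT_DT = 0.1


class IntegrationError(RuntimeError):
    """Raised when the forward integration produces a non-finite state."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(f"non-finite state at step {step} (t = {time:g})")


@dataclass(frozen=True)
class NodeParams:
    """Single-node Wilson-Cowan parameters (shared by all nodes).

    Defaults are the standard parameter set used throughout the package:
    tau_E = 2.5, tau_I = 3.75, gamma = 1.5, mu = 3.0 and intra-node
    couplings (c_EE, c_EI, c_IE, c_II) = (16, 12, 15, 3).
    """

    tau_E: float = 2.5
    tau_I: float = 3.75
    gamma: float = 1.5
    mu: float = 3.0
    c_EE: float = 16.0
    c_EI: float = 12.0
    c_IE: float = 15.0
    c_II: float = 3.0

    def __post_init__(self):
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in ("c_EE", "c_EI", "c_IE", "c_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Static description of a delay-coupled Wilson-Cowan network."""

    N: int
    params: NodeParams
    C: np.ndarray          # (N, N) coupling weights, row = receiver
    D: np.ndarray          # (N, N) delays in time units
    c_gl: float = 0.0
    E_ext: np.ndarray | float = 0.0
    I_ext: np.ndarray | float = 0.0

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if C.shape != (self.N, self.N) or D.shape != (self.N, self.N):
            raise ValueError(f"C and D must have shape ({self.N}, {self.N})")
        if (C < 0).any():
            raise ValueError("C entries must be non-negative")
        if (D < 0).any():
            raise ValueError("D entries must be non-negative")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "E_ext", np.broadcast_to(
            np.asarray(self.E_ext, dtype=float), (self.N,)).copy())
        object.__setattr__(self, "I_ext", np.broadcast_to(
            np.asarray(self.I_ext, dtype=float), (self.N,)).copy())

    def delay_steps(self, dt: float) -> np.ndarray:
        """Delays rounded to the nearest integer number of grid steps."""
        return np.rint(self.D / dt).astype(np.int64)

    def with_inputs(self, E_ext, I_ext) -> "NetworkConfig":
        return replace(self, E_ext=E_ext, I_ext=I_ext)

    def permuted(self, perm: np.ndarray) -> "NetworkConfig":
        """Relabel nodes by permutation array ``perm`` (new index <- old)."""
        p = np.asarray(perm)
        return replace(self, C=self.C[np.ix_(p, p)], D=self.D[np.ix_(p, p)],
                       E_ext=self.E_ext[p], I_ext=self.I_ext[p])


def single_node(E_ext: float = 0.0, I_ext: float = 0.0,
                params: NodeParams | None = None) -> NetworkConfig:
    """Convenience constructor for an uncoupled single-node configuration."""
    z = np.zeros((1, 1))
    return NetworkConfig(N=1, params=params or NodeParams(), C=z, D=z,
                         c_gl=0.0, E_ext=E_ext, I_ext=I_ext)


@dataclass
class StateTrajectory:
    """Time-gridded network state ``E``, ``I`` of shape (N, NT + 1)."""

    dt: float
    E: np.ndarray
    I: np.ndarray

    @property
    def N(self) -> int:
        return self.E.shape[0]

    @property
    def n_steps(self) -> int:
        return self.E.shape[1] - 1

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.E.shape[1]) * self.dt

    def final_state(self) -> np.ndarray:
        """Stacked (E_0..E_{N-1}, I_0..I_{N-1}) at the final grid point."""
        return np.concatenate([self.E[:, -1], self.I[:, -1]])


def interval_indices(t0: float, t1: float, dt: float, n_steps: int) -> slice:
    """Grid indices k with t0 <= t_k < t1 (half-open, the package-wide rule)."""
    i0 = int(round(t0 / dt))
    i1 = int(round(t1 / dt))
    return slice(max(i0, 0), min(i1, n_steps + 1))


@dataclass
class ControlSignal:
    """Additive control of the excitatory synaptic argument.

    ``u`` has shape (N, NT + 1); entries outside the control interval
    [t0C, t1C) are zero (enforced by :meth:`masked`).
    """

    dt: float
    u: np.ndarray
    t0C: float = 0.0
    t1C: float = np.inf

    @classmethod
    def zero(cls, N: int, duration: float, dt: float = DEFAULT_DT,
             t0C: float = 0.0, t1C: float = np.inf) -> "ControlSignal":
        NT = int(round(duration / dt))
        return cls(dt=dt, u=np.zeros((N, NT + 1)), t0C=t0C, t1C=t1C)

    @property
    def n_steps(self) -> int:
        return self.u.shape[1] - 1

    def support(self) -> slice:
        t1 = min(self.t1C, self.n_steps * self.dt)
        return interval_indices(self.t0C, t1, self.dt, self.n_steps)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.u.shape[1], dtype=bool)
        m[self.support()] = True
        return m

    def masked(self) -> "ControlSignal":
        u = np.zeros_like(self.u)
        s = self.support()
        u[:, s] = self.u[:, s]
        return ControlSignal(dt=self.dt, u=u, t0C=self.t0C, t1C=self.t1C)

    def energy(self) -> float:
        """The energy cost 0.5 * integral of u^2 (left-rectangle rule)."""
        return 0.5 * float((self.u[:, :-1] ** 2).sum()) * self.dt


def sigmoid(x, gamma: float = 1.5, mu: float = 3.0):
    """Sigmoidal transfer S(x) = 1 / (1 + exp(-gamma (x - mu))).

    Strictly increasing with S(mu) = 1/2; the exponent is clipped so the
    function saturates instead of overflowing.
    """
    z = np.clip(gamma * (np.asarray(x, dtype=float) - mu),
                -_kernels._EXP_CLIP, _kernels._EXP_CLIP)
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(x) else out


def _sigmoid_deriv(x, gamma: float, mu: float):
    s = sigmoid(x, gamma, mu)
    return gamma * s * (1.0 - s)


def simulate(config: NetworkConfig, control: ControlSignal | None = None,
             duration: float | None = None, dt: float = DEFAULT_DT,
             initial_state: np.ndarray | None = None) -> StateTrajectory:
    """Integrate the network with explicit Euler steps of size ``dt``.

    Parameters
    ----------
    config
        Network description.
    control
        Control signal; ``None`` means no control.  When given, its grid
        defines ``duration`` and ``dt`` unless stated explicitly.
    duration
        Simulated time span T; the trajectory has ``T/dt + 1`` grid points.
    initial_state
        Stacked ``(E_0..E_{N-1}, I_0..I_{N-1})`` in [0, 1]; defaults to
        all zeros.  The state for t < 0 is held constant at this value.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite (reports the failure time).
    """
    N = config.N
    if control is not None:
        dt = control.dt
        if duration is None:
            duration = control.n_steps * control.dt
    if duration is None:
        raise ValueError("duration is required when no control is given")
    NT = int(round(duration / dt))
    if control is None:
        u = np.zeros((N, NT + 1))
    else:
        if control.u.shape != (N, NT + 1):
            raise ValueError("control grid does not match network/duration")
        u = control.masked().u
    E = np.zeros((N, NT + 1))
    I = np.zeros((N, NT + 1))
    if initial_state is not None:
        x0 = np.asarray(initial_state, dtype=float)
        if x0.shape != (2 * N,):
            raise ValueError(f"initial_state must have shape ({2 * N},)")
        if (x0 < 0).any() or (x0 > 1).any():
            raise ValueError("initial_state must lie in [0, 1]")
        E[:, 0] = x0[:N]
        I[:, 0] = x0[N:]
    p = config.params
    fail = _kernels.forward(
        E, I, u, config.c_gl * config.C, config.delay_steps(dt),
        config.E_ext, config.I_ext,
        p.tau_E, p.tau_I, p.gamma, p.mu, p.c_EE, p.c_EI, p.c_IE, p.c_II, dt)
    if fail >= 0:
        raise IntegrationError(fail, fail * dt)
    return StateTrajectory(dt=dt, E=E, I=I)


def synaptic_inputs(trajectory: StateTrajectory, control: ControlSignal | None,
                    config: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    """Synaptic arguments (a, b) of the E- and I-equations along a trajectory."""
    p = config.params
    N = config.N
    u = control.masked().u if control is not None else np.zeros_like(trajectory.E)
    return _kernels.synaptic_inputs(
        trajectory.E, trajectory.I, u, config.c_gl * config.C,
        config.delay_steps(trajectory.dt), config.E_ext, config.I_ext,
        p.c_EE, p.c_EI, p.c_IE, p.c_II)


def jacobians(trajectory: StateTrajectory, control: ControlSignal | None,
              config: NetworkConfig, t_index: int):
    """Analytic Jacobians of h = xdot - rhs at one grid time.

    State ordering is ``(E_0..E_{N-1}, I_0..I_{N-1})``.  Returns

    - ``dh_dx_local``: (2N, 2N) partials w.r.t. the undelayed state,
    - ``dh_dx_delayed``: dict mapping delay steps d > 0 to (2N, 2N) blocks
      of partials w.r.t. the state delayed by d,
    - ``dh_du``: (2N, N) partials w.r.t. the control (inhibitory rows zero).

    With ``h = xdot - rhs`` the entries are the negated rhs derivatives; the
    sign convention is fixed package-wide and verified against
    finite differences of the discretized rhs.
    """
    p = config.params
    N = config.N
    a, b = synaptic_inputs(trajectory, control, config)
    a = a[:, t_index]
    b = b[:, t_index]
    E = trajectory.E[:, t_index]
    I = trajectory.I[:, t_index]
    Sa, Sb = sigmoid(a, p.gamma, p.mu), sigmoid(b, p.gamma, p.mu)
    dSa, dSb = _sigmoid_deriv(a, p.gamma, p.mu), _sigmoid_deriv(b, p.gamma, p.mu)

    local = np.zeros((2 * N, 2 * N))
    # E-row: d rhs_E / dE_n (undelayed, intra-node), d rhs_E / dI_n
    dEdE = (-1.0 - Sa + (1.0 - E) * dSa * p.c_EE) / p.tau_E
    dEdI = (1.0 - E) * dSa * (-p.c_EI) / p.tau_E
    dIdE = (1.0 - I) * dSb * p.c_IE / p.tau_I
    dIdI = (-1.0 - Sb + (1.0 - I) * dSb * (-p.c_II)) / p.tau_I
    idx = np.arange(N)
    local[idx, idx] = -dEdE
    local[idx, N + idx] = -dEdI
    local[N + idx, idx] = -dIdE
    local[N + idx, N + idx] = -dIdI

    dsteps = config.delay_steps(trajectory.dt)
    delayed: dict[int, np.ndarray] = {}
    Cw = config.c_gl * config.C
    for n in range(N):
        for m in range(N):
            if Cw[n, m] == 0.0:
                continue
            val = -(1.0 - E[n]) * dSa[n] * Cw[n, m] / p.tau_E
            d = int(dsteps[n, m])
            if d == 0:
                local[n, m] += val
            else:
                delayed.setdefault(d, np.zeros((2 * N, 2 * N)))[n, m] = val

    dh_du = np.zeros((2 * N, N))
    dh_du[idx, idx] = -(1.0 - E) * dSa / p.tau_E
    return local, delayed, dh_du


RegimeLabel = Literal["down", "up", "oscillatory", "bistable", "unclassified"]

#: peak-to-peak amplitude above which a post-transient E series counts as
#: oscillating; well above the Euler noise floor, well below physiological
#: oscillation amplitudes (~0.2-0.5)
OSCILLATION_AMPLITUDE_THRESHOLD = 1e-3

#: stationary E levels separating "down" from "up"; fixed points of the
#: standard parameter set sit near 0.01 (down) and above 0.3 (up)
_UP_LEVEL = 0.15
#: two stationary branches further apart than this count as distinct
_BISTABLE_GAP = 0.05


def classify_regime(E_ext: float, I_ext: float,
                    config: NetworkConfig | None = None,
                    duration: float = 500.0, transient: float = 300.0,
                    dt: float = DEFAULT_DT,
                    seeds: tuple[np.ndarray, ...] | None = None) -> RegimeLabel:
    """Classify the long-run regime at external inputs (E_ext, I_ext).

    Simulates from a low-activity and a high-activity initial condition,
    discards ``transient``, and inspects the remaining E series: peak-to-peak
    amplitude above :data:`OSCILLATION_AMPLITUDE_THRESHOLD` means
    oscillatory; two distinct stationary levels mean bistable; otherwise the
    common stationary level is labelled down or up.  Amplitudes within a
    factor of two of the threshold are reported as "unclassified" rather
    than silently guessed.
    """
    if config is None:
        config = single_node()
    config = config.with_inputs(E_ext, I_ext)
    N = config.N
    if seeds is None:
        # corners of the (E, I) square: low/high activity seeds plus the
        # mixed corners, which catch bistable basins that exclude the
        # diagonal corners
        lo, hi = 0.02, 0.98
        seeds = tuple(
            np.concatenate([np.full(N, e), np.full(N, i)])
            for e, i in ((lo, lo), (hi, hi), (lo, hi), (hi, lo)))
    finals, amps = [], []
    for x0 in seeds:
        traj = simulate(config, duration=duration, dt=dt, initial_state=x0)
        tail = traj.E[:, interval_indices(transient, duration, dt, traj.n_steps)]
        amps.append(float(np.ptp(tail, axis=1).max()))
        finals.append(float(tail[:, -1].mean()))
    amp = max(amps)
    if amp > 2.0 * OSCILLATION_AMPLITUDE_THRESHOLD:
        return "oscillatory"
    if amp > 0.5 * OSCILLATION_AMPLITUDE_THRESHOLD:
        return "unclassified"
    if max(finals) - min(finals) > _BISTABLE_GAP:
        return "bistable"
    return "up" if finals[0] > _UP_LEVEL else "down"
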