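"""Gradient-descent optimal control with weight annealing.

The optimal control u* minimizes F = w_X F_X + F_E.  Each iteration runs
one forward simulation, one adjoint sweep, and a backtracking (Armijo)
line search along the negative gradient, so every accepted step strictly
decreases the total cost.  For minimum-energy problems the accuracy weight
is annealed: after each inner convergence the weight magnitude shrinks by
a fixed factor, until the control collapses to zero (at which point the
last non-collapsed stage is returned) or the weight floor is reached.

The descent hyperparameters live in :class:`DescentParams`; none of them
change the optimum, only how fast it is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adjoint import assemble_gradient, solve_adjoint
from .costs import CostSpec, evaluate
from .model import (ControlSignal, IntegrationError, NetworkConfig,
                    StateTrajectory, simulate)

__all__ = [
    "minimum_energy_switch",
    "DescentParams",
    "WeightSchedule",
    "InitSpec",
    "OptimizationProblem",
    "OptimizationResult",
    "optimize",
    "anneal_weight",
    "init_control",
    "shift_control",
]


@dataclass(frozen=True)
class DescentParams:
    """Backtracking gradient-descent hyperparameters."""

    init_step: float = 1.0
    armijo_c1: float = 1e-4
    shrink: float = 0.5
    grow: float = 2.0
    min_step: float = 1e-14
    max_iter: int = 5000
    tol: float = 1e-6        # relative total-cost decrease
    patience: int = 10       # consecutive below-tol iterations to stop


@dataclass(frozen=True)
class WeightSchedule:
    """Multiplicative weight-annealing schedule.

    ``factor`` in (0, 1) scales |w| after each stage; a stage ends after
    ``period`` iterations or at inner convergence, whichever comes first;
    annealing stops when |w| would drop below ``floor`` or when the control
    collapses to (numerically) zero — the minimum-energy limit — in which
    case the last non-collapsed control is returned.
    """

    factor: float = 0.7
    period: int = 500
    floor: float = 1e-6
    max_stages: int = 50
    collapse_tol: float = 1e-6   # sup-norm of u counting as collapsed

    def __post_init__(self):
        if not 0.0 < self.factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")


def anneal_weight(weight: float, schedule: WeightSchedule) -> float:
    """One annealing step: shrink |weight| by the factor, keep the sign.

    Returns the unchanged weight if shrinking would cross the floor.
    """
    w = weight * schedule.factor
    if abs(w) < schedule.floor:
        return weight
    return w


@dataclass(frozen=True)
class InitSpec:
    """Initial control guess: zero, a sinusoid at the target frequency, or
    small seeded uniform noise.

    ``antiphase`` flips the sinusoid's sign on every other node — the
    educated guess for tasks whose target state is an anti-phase pattern.
    """

    kind: str = "zero"          # zero | sinusoid | noise
    amplitude: float = 0.0
    frequency: float = 0.0      # cycles per time unit (sinusoid only)
    seed: int = 0
    antiphase: bool = False


def init_control(init: InitSpec, N: int, duration: float, dt: float,
                 t0C: float, t1C: float) -> ControlSignal:
    """Build the initial control on the grid, supported on [t0C, t1C)."""
    ctl = ControlSignal.zero(N, duration, dt, t0C=t0C, t1C=t1C)
    if init.kind == "zero":
        return ctl
    t = np.arange(ctl.u.shape[1]) * dt
    if init.kind == "sinusoid":
        wave = init.amplitude * np.sin(2 * np.pi * init.frequency * t)
        signs = ((-1.0) ** np.arange(N) if init.antiphase
                 else np.ones(N))
        ctl.u[:] = signs[:, None] * wave[None, :]
    elif init.kind == "noise":
        rng = np.random.default_rng(init.seed)
        ctl.u[:] = init.amplitude * rng.uniform(-1.0, 1.0, ctl.u.shape)
    else:
        raise ValueError(f"unknown init kind: {init.kind!r}")
    return ctl.masked()


def shift_control(control: ControlSignal, shift: float,
                  period: float | None = None) -> ControlSignal:
    """Time-translate a control signal on the grid (zero-fill outside).

    A negative ``shift`` moves the signal earlier.  For oscillatory initial
    states a state-switching control stays valid only under shifts by whole
    oscillation periods; pass ``period`` to have that checked.  The energy
    cost is exactly invariant under the shift.

    Raises
    ------
    ValueError
        If nonzero samples would be pushed outside the grid, or the shift
        is not a whole number of periods when ``period`` is given.
    """
    if period is not None:
        ratio = shift / period
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                f"shift {shift} is not an integer multiple of the period {period}")
    steps = int(round(shift / control.dt))
    u = control.masked().u
    out = np.zeros_like(u)
    if steps >= 0:
        if steps > 0 and np.abs(u[:, u.shape[1] - steps:]).max(initial=0.0) > 0:
            raise ValueError("shift pushes control support beyond the grid")
        out[:, steps:] = u[:, :u.shape[1] - steps]
    else:
        if np.abs(u[:, :-steps]).max(initial=0.0) > 0:
            raise ValueError("shift pushes control support before t = 0")
        out[:, :steps] = u[:, -steps:]
    T = control.n_steps * control.dt
    return ControlSignal(dt=control.dt, u=out,
                         t0C=max(control.t0C + shift, 0.0),
                         t1C=min(control.t1C + shift, T) if np.isfinite(control.t1C) else T)


@dataclass
class OptimizationProblem:
    """Complete description of one optimal-control run."""

    config: NetworkConfig
    cost: CostSpec
    duration: float
    t0C: float = 0.0
    t1C: float = np.inf
    dt: float = 0.1
    initial_state: np.ndarray | None = None
    init: InitSpec = field(default_factory=InitSpec)
    descent: DescentParams = field(default_factory=DescentParams)
    anneal: WeightSchedule | None = None
    seed: int = 0

    def __post_init__(self):
        if self.cost.t0 < self.t0C:
            raise ValueError(
                "measurement may not start before the control interval "
                f"(t0 = {self.cost.t0} < t0C = {self.t0C})")


@dataclass
class OptimizationResult:
    control: ControlSignal
    trajectory: StateTrajectory
    history: list[dict]
    termination: str
    final_weight: float
    seed: int
    F_E: float = 0.0       # energy of the returned control
    F_X: float = 0.0       # accuracy term of the returned control
    total_cost: float = 0.0


def _evaluate_total(config, u_arr, proto: ControlSignal, spec, x0):
    ctl = ControlSignal(dt=proto.dt, u=u_arr, t0C=proto.t0C, t1C=proto.t1C)
    traj = simulate(config, ctl, initial_state=x0)
    return evaluate(traj, ctl, spec), traj, ctl


def _descend(config, control, spec, x0, descent, max_iter, history,
             stage, verbose=False):
    """Inner gradient-descent loop at fixed weight.

    Returns (control, trajectory, breakdown, converged, termination).
    """
    bd, traj, control = _evaluate_total(config, control.masked().u, control,
                                        spec, x0)
    step = descent.init_step
    calm = 0
    for it in range(max_iter):
        adj = solve_adjoint(traj, bd.g_series, config, control,
                            observable=spec.observable)
        grad = assemble_gradient(adj, control, traj, config)
        gnorm2 = float((grad.grad ** 2).sum()) * control.dt
        if gnorm2 == 0.0:
            return control, traj, bd, True, "zero_gradient"
        def try_step(s):
            try:
                out = _evaluate_total(config, control.u - s * grad.grad,
                                      control, spec, x0)
            except IntegrationError:
                return None
            if out[0].total <= bd.total - descent.armijo_c1 * s * gnorm2:
                return out
            return None

        # backtracking-and-forward-tracking line search: shrink until the
        # Armijo condition holds, then keep doubling while it still helps
        # (the cost scale varies over many orders of magnitude between
        # tasks, so a fixed step scale cannot work)
        accepted = None
        while step >= descent.min_step:
            accepted = try_step(step)
            if accepted is not None:
                break
            step *= descent.shrink
        if accepted is None:
            return control, traj, bd, True, "step_underflow"
        while True:
            bigger = try_step(step * descent.grow)
            if bigger is None or bigger[0].total >= accepted[0].total:
                break
            accepted = bigger
            step *= descent.grow
        bd_try, traj_try, ctl_try = accepted
        rel = (bd.total - bd_try.total) / max(abs(bd.total), 1e-12)
        control, traj, bd = ctl_try, traj_try, bd_try
        history.append({"stage": stage, "iter": it, "F_E": bd.F_E,
                        "F_X": bd.F_X, "weight": spec.weight,
                        "total": bd.total, "step": step})
        if verbose:
            print(f"stage {stage} it {it}: total={bd.total:.6g} "
                  f"F_E={bd.F_E:.4g} F_X={bd.F_X:.4g} step={step:.2g}")
        calm = calm + 1 if rel < descent.tol else 0
        if calm >= descent.patience:
            return control, traj, bd, True, "converged"
    return control, traj, bd, False, "max_iter"


def optimize(problem: OptimizationProblem, verbose: bool = False
             ) -> OptimizationResult:
    """Run the full optimal-control loop (with annealing if configured).

    The recorded total cost is non-increasing over accepted steps within
    each weight stage.  Simulation failures under trial controls reject the
    step and halve the step size; persistent failure terminates with the
    last accepted control.
    """
    cfg, spec, descent = problem.config, problem.cost, problem.descent
    control = init_control(problem.init, cfg.N, problem.duration,
                           problem.dt, problem.t0C, problem.t1C)
    history: list[dict] = []
    x0 = problem.initial_state

    if problem.anneal is None:
        control, traj, bd, _, term = _descend(
            cfg, control, spec, x0, descent, descent.max_iter, history, 0,
            verbose)
        return OptimizationResult(control, traj, history, term,
                                  spec.weight, problem.seed,
                                  F_E=bd.F_E, F_X=bd.F_X, total_cost=bd.total)

    sched = problem.anneal
    best = None
    term = "anneal_floor"
    for stage in range(sched.max_stages):
        control, traj, bd, _, _ = _descend(
            cfg, control, spec, x0, descent,
            min(sched.period, descent.max_iter), history, stage, verbose)
        sup = float(np.abs(control.u).max())
        if sup < sched.collapse_tol:
            # control collapsed: the previous stage was the minimum-energy
            # limit; revert to it
            term = "collapsed"
            break
        best = (control, traj, bd, spec.weight)
        new_w = anneal_weight(spec.weight, sched)
        if new_w == spec.weight:
            term = "anneal_floor"
            break
        spec = spec.with_weight(new_w)
    if best is None:
        # collapsed already in the first stage: the weight was below the
        # task's threshold and the optimal control is zero
        return OptimizationResult(control, traj, history, "collapsed",
                                  spec.weight, problem.seed,
                                  F_E=bd.F_E, F_X=bd.F_X, total_cost=bd.total)
    control, traj, bd, w = best
    return OptimizationResult(control, traj, history, term, w, problem.seed,
                              F_E=bd.F_E, F_X=bd.F_X, total_cost=bd.total)


def minimum_energy_switch(problem: OptimizationProblem, success,
                          initial_control: ControlSignal | None = None,
                          verbose: bool = False) -> OptimizationResult:
    """Weight-annealed optimization of a state-switching task.

    Runs the annealing schedule stage by stage and keeps the
    lowest-energy control for which ``success(control, trajectory)`` is
    true — typically a persistence check that the target attractor
    survives after the control is switched off.  Annealing stops once a
    stage loses the switch after at least one success (shrinking the
    weight further only removes incentive) or the control collapses.

    Returns the best successful stage; ``termination`` is "failed" if no
    stage achieved the task.
    """
    cfg, spec, descent = problem.config, problem.cost, problem.descent
    sched = problem.anneal if problem.anneal is not None else WeightSchedule()
    if initial_control is not None:
        control = initial_control.masked()
    else:
        control = init_control(problem.init, cfg.N, problem.duration,
                               problem.dt, problem.t0C, problem.t1C)
    history: list[dict] = []
    x0 = problem.initial_state
    best = None
    term = "anneal_floor"
    bd = None
    w_lost = None
    for stage in range(sched.max_stages):
        control, traj, bd, _, _ = _descend(
            cfg, control, spec, x0, descent,
            min(sched.period, descent.max_iter), history, stage, verbose)
        ok = bool(success(control, traj))
        if verbose:
            print(f"stage {stage}: w={spec.weight:.4g} F_E={bd.F_E:.4g} "
                  f"switch={'yes' if ok else 'no'}")
        if ok and (best is None or bd.F_E < best[2].F_E):
            best = (control, traj, bd, spec.weight)
        if not ok and best is not None:
            term = "switch_lost"
            w_lost = spec.weight
            break
        if float(np.abs(control.u).max()) < sched.collapse_tol:
            term = "collapsed"
            break
        new_w = anneal_weight(spec.weight, sched)
        if new_w == spec.weight:
            break
        spec = spec.with_weight(new_w)
    if best is not None and w_lost is not None:
        # the switch threshold lies between the best weight and the weight
        # at which the switch was lost; bisect toward it so the returned
        # control approaches the true minimum-energy limit
        w_hi = best[3]
        w_lo = w_lost
        for _ in range(3):
            w_mid = np.sign(w_hi) * np.sqrt(abs(w_hi) * abs(w_lo))
            control, traj, bd, _, _ = _descend(
                cfg, best[0], spec.with_weight(w_mid), x0, descent,
                min(sched.period, descent.max_iter), history, -2, verbose)
            if success(control, traj):
                if bd.F_E < best[2].F_E:
                    best = (control, traj, bd, w_mid)
                w_hi = w_mid
            else:
                w_lo = w_mid
    if best is None:
        return OptimizationResult(control, traj, history, "failed",
                                  spec.weight, problem.seed,
                                  F_E=bd.F_E, F_X=bd.F_X, total_cost=bd.total)
    control, traj, bd, w = best
    # polish: converge tightly at the best stage's weight so the reported
    # control is the minimum-energy solution, not a mid-descent iterate
    polish = replace(descent, max_iter=2 * sched.period,
                     tol=descent.tol * 1e-2, patience=2 * descent.patience)
    c2, t2, b2, _, _ = _descend(cfg, control, spec.with_weight(w), x0,
                                polish, polish.max_iter, history, -1, verbose)
    if success(c2, t2) and b2.F_E <= bd.F_E:
        control, traj, bd = c2, t2, b2
    return OptimizationResult(control, traj, history, term, w, problem.seed,
                              F_E=bd.F_E, F_X=bd.F_X, total_cost=bd.total)
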