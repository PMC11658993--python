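"""Ready-made control tasks on the standard study networks.

Each task function builds its problem from the named fixtures, runs the
optimizer (with multi-start over initial controls where the cost
landscape is known to have local optima), and verifies the outcome the
way the corresponding experiment is judged:

- oscillation induction: dominant frequency of the controlled window;
- state switches: the target attractor must persist for at least ten
  natural periods after the control is switched off;
- network (de)synchronization: temporal-mean Kuramoto order parameter
  against the uncontrolled baseline.
"""

from __future__ import annotations

import numpy as np

from .analysis import kuramoto_mean, power_spectrum
from .config import F_IP, F_OOP, fixture
from .costs import CostSpec
from .model import ControlSignal, NetworkConfig, simulate
from .optimize import (DescentParams, InitSpec, OptimizationResult,
                       WeightSchedule, minimum_energy_switch, optimize)

__all__ = [
    "classify_two_node_attractor",
    "switch_persists",
    "two_node_switch",
    "two_node_switch_suite",
    "induce_oscillation",
    "six_node_synchrony_task",
    "aligned_l2_distance",
]

#: persistence horizon after control off, in units of the slower (OOP)
#: period — ten natural periods
PERSISTENCE_PERIODS = 10
_OOP_PERIOD = 1.0 / F_OOP


def classify_two_node_attractor(network: NetworkConfig,
                                control: ControlSignal | None,
                                x0: np.ndarray,
                                horizon: float = 250.0) -> str:
    """Run past the control window and label the surviving attractor.

    The in-phase orbit lives on the exact symmetry manifold E_0 = E_1, so
    the label follows from whether the late-time node difference has
    collapsed.
    """
    dt = 0.1 if control is None else control.dt
    T_ctl = 0.0 if control is None else control.u.shape[1] * dt
    total = T_ctl + horizon
    NT = int(round(total / dt))
    u_ext = np.zeros((network.N, NT + 1))
    if control is not None:
        u_ext[:, :control.u.shape[1]] = control.masked().u
        ctl = ControlSignal(dt=dt, u=u_ext, t0C=control.t0C, t1C=control.t1C)
    else:
        ctl = ControlSignal(dt=dt, u=u_ext)
    traj = simulate(network, ctl, initial_state=x0)
    tail = slice(int((total - horizon / 2) / dt), None)
    gap = float(np.abs(traj.E[0, tail] - traj.E[1, tail]).max())
    return "IP" if gap < 1e-6 else "OOP"


def switch_persists(network: NetworkConfig, control: ControlSignal,
                    x0: np.ndarray, target: str) -> bool:
    """Does the target attractor survive >= 10 periods beyond control off?"""
    horizon = PERSISTENCE_PERIODS * _OOP_PERIOD + 20.0
    return classify_two_node_attractor(network, control, x0,
                                       horizon=horizon) == target


_SWITCH_SETUP = {
    # direction -> (fixture, target, fourier kind, fourier frequency)
    "OOP_to_IP": ("switch_OOP_to_IP", "IP", "fourier_sync", F_IP),
    "IP_to_OOP": ("switch_IP_to_OOP", "OOP", "fourier_osc", F_OOP),
}


def two_node_switch(direction: str, kind: str,
                    weight: float | None = None,
                    anneal: WeightSchedule | None = None,
                    descent: DescentParams | None = None,
                    noise_seeds: tuple[int, ...] = (1, 2),
                    ) -> OptimizationResult:
    """Minimum-energy switch between the two-node IP and OOP attractors.

    ``kind`` is one of "fourier", "cross_correlation", "variance"; the
    weight defaults to the fixture's task weight.  The Fourier costs are
    started from a sinusoidal guess at the target attractor's frequency
    (in-phase or anti-phase as appropriate); the correlation and variance
    costs, whose gradients vanish on the symmetric start state, use
    multi-start over small noise controls and keep the lowest-energy
    successful run.
    """
    fix_name, target, fourier_kind, f_target = _SWITCH_SETUP[direction]
    cfg = fixture(fix_name)
    cost_kind = fourier_kind if kind == "fourier" else kind
    w = weight if weight is not None else cfg.task_weights[kind]
    spec = CostSpec(cost_kind, w, t0=200.0, T=600.0,
                    omega=(2 * np.pi * f_target
                           if cost_kind.startswith("fourier") else None))
    cfg.anneal = anneal or WeightSchedule(factor=0.7, period=400,
                                          floor=abs(w) * 1e-5, max_stages=24)
    cfg.descent = descent or DescentParams(max_iter=3000, patience=15)
    x0 = cfg.prepared_initial_state()

    # shared sinusoidal guess at the target attractor's frequency for all
    # functionals; the symmetry-breaking noise starts additionally hedge
    # the correlation/variance landscapes' local optima
    inits = [InitSpec("sinusoid", 0.5, f_target,
                      antiphase=(target == "OOP"))]
    if kind != "fourier":
        inits += [InitSpec("noise", 1.0, seed=s) for s in noise_seeds]

    def success(control, trajectory):
        return switch_persists(cfg.network, control, x0, target)

    best = None
    for init in inits:
        cfg.init = init
        res = minimum_energy_switch(cfg.problem(spec), success)
        if res.termination == "failed":
            continue
        if best is None or res.F_E < best.F_E:
            best = res
    return best if best is not None else res


def two_node_switch_suite(direction: str,
                          kinds=("fourier", "cross_correlation", "variance"),
                          ) -> dict[str, OptimizationResult]:
    """Minimum-energy switches for several cost functionals, with
    incumbent exchange.

    Round one optimizes each functional from its own initializations.
    Round two re-runs each functional warm-started from the overall
    lowest-energy successful control (the incumbent): a functional keeps
    that solution only if its own annealed descent independently
    preserves it at lower or equal energy.  This is the multi-start
    scheme under which the minimum-energy limits of different
    functionals can be compared: without it each functional tends to
    stall in its own local optimum.
    """
    results = {k: two_node_switch(direction, k) for k in kinds}
    successful = {k: r for k, r in results.items()
                  if r.termination != "failed"}
    if len(successful) < 2:
        return results
    fix_name, target, fourier_kind, f_target = _SWITCH_SETUP[direction]
    for _ in range(2):                     # exchange until stable
        incumbent_kind = min(successful, key=lambda k: successful[k].F_E)
        incumbent = successful[incumbent_kind].control
        improved = _exchange_round(results, successful, kinds,
                                   incumbent_kind, incumbent,
                                   fix_name, target, fourier_kind, f_target)
        if not improved:
            break
    return results


def _exchange_round(results, successful, kinds, incumbent_kind, incumbent,
                    fix_name, target, fourier_kind, f_target) -> bool:
    """Offer the incumbent control to every other functional.

    Each functional re-descends from the incumbent at a ladder of fixed
    weights stepping down from its own threshold; a rung counts only if
    the functional's own descent keeps the switch at lower energy.
    Returns whether any functional improved.
    """
    from .optimize import _descend
    improved = False
    for kind in kinds:
        if kind == incumbent_kind or kind not in successful:
            continue
        cfg = fixture(fix_name)
        cost_kind = fourier_kind if kind == "fourier" else kind
        x0 = cfg.prepared_initial_state()
        descent = DescentParams(max_iter=800, patience=30)
        w_top = results[kind].final_weight
        for k in range(4):
            w = w_top * 0.7 ** k
            spec = CostSpec(cost_kind, w, t0=200.0, T=600.0,
                            omega=(2 * np.pi * f_target
                                   if cost_kind.startswith("fourier")
                                   else None))
            warm = ControlSignal(dt=cfg.dt, u=incumbent.masked().u.copy(),
                                 t0C=cfg.t0C, t1C=cfg.t1C)
            hist: list[dict] = []
            ctl, traj, bd, _, _ = _descend(cfg.network, warm, spec, x0,
                                           descent, descent.max_iter,
                                           hist, -3)
            if (switch_persists(cfg.network, ctl, x0, target)
                    and bd.F_E < results[kind].F_E):
                results[kind] = OptimizationResult(
                    ctl, traj, hist, "incumbent_adopted", w,
                    results[kind].seed, F_E=bd.F_E, F_X=bd.F_X,
                    total_cost=bd.total)
                successful[kind] = results[kind]
                improved = True
        if results[kind].termination == "incumbent_adopted":
            continue
        # fallback: full annealing path warm-started from the incumbent
        w = (np.sign(results[kind].final_weight)
             * abs(cfg.task_weights[kind]))
        spec = CostSpec(cost_kind, w, t0=200.0, T=600.0,
                        omega=(2 * np.pi * f_target
                               if cost_kind.startswith("fourier") else None))
        cfg.anneal = WeightSchedule(factor=0.7, period=400,
                                    floor=abs(w) * 1e-5, max_stages=24)
        cfg.descent = DescentParams(max_iter=3000, patience=15)
        warm = ControlSignal(dt=cfg.dt, u=incumbent.masked().u.copy(),
                             t0C=cfg.t0C, t1C=cfg.t1C)

        def success(control, trajectory):
            return switch_persists(cfg.network, control, x0, target)

        res = minimum_energy_switch(cfg.problem(spec), success,
                                    initial_control=warm)
        if res.termination != "failed" and res.F_E < results[kind].F_E:
            results[kind] = res
            successful[kind] = res
            improved = True
    return improved


def induce_oscillation(weight: float | None = None,
                       descent: DescentParams | None = None,
                       ) -> tuple[OptimizationResult, float, float]:
    """Drive a 30 Hz oscillation from the single-node down state.

    Returns (result, dominant frequency of the controlled window,
    zero-control Fourier cost for comparison).
    """
    cfg = fixture("induce_osc_A")
    if weight is not None:
        cfg.cost = cfg.cost.with_weight(weight)
    if descent is not None:
        cfg.descent = descent
    res = optimize(cfg.problem())
    spec = power_spectrum(res.trajectory.E, cfg.dt, cfg.cost.t0, cfg.cost.T)
    from .costs import evaluate
    zero = ControlSignal.zero(1, cfg.duration, cfg.dt, cfg.t0C, cfg.t1C)
    bd0 = evaluate(simulate(cfg.network, zero), zero, cfg.cost)
    return res, float(spec.dominant[0]), bd0.F_X


def six_node_synchrony_task(task: str, kind: str,
                            descent: DescentParams | None = None,
                            ) -> tuple[OptimizationResult, float, float]:
    """Synchronize ("sync", point D) or desynchronize ("desync", point E)
    the six-node network with one cost functional.

    The Fourier target frequency is the spectral peak of the uncontrolled
    network mean, as measured on the baseline run.  Returns
    (result, controlled Kuramoto mean, uncontrolled Kuramoto mean).
    """
    cfg = fixture(f"six_node_sync" if task == "sync" else "six_node_desync")
    baseline = simulate(cfg.network, duration=cfg.duration, dt=cfg.dt,
                        initial_state=cfg.initial_state)
    R0 = kuramoto_mean(baseline.E, cfg.dt, 100.0, 600.0)
    f_peak = power_spectrum(baseline.E.mean(0, keepdims=True), cfg.dt,
                            100.0, 600.0, interpolate=False).dominant[0]
    cost_kind = "fourier_sync" if kind == "fourier" else kind
    w = cfg.task_weights[kind]
    spec = CostSpec(cost_kind, w, t0=100.0, T=600.0,
                    omega=(2 * np.pi * f_peak if cost_kind == "fourier_sync"
                           else None))
    cfg.init = InitSpec("noise", 0.05, seed=1)
    cfg.descent = descent or DescentParams(max_iter=1000, patience=15)
    res = optimize(cfg.problem(spec))
    R = kuramoto_mean(res.trajectory.E, cfg.dt, 100.0, 600.0)
    return res, float(R), float(R0)


#: external inputs of the single-node bistable point used for the
#: stationary state-switch task (located with the regime classifier)
BISTABLE_POINT = (2.8, 1.8)


def _bistable_fixed_points():
    """Down and up fixed points of the single node at the bistable point."""
    from scipy.optimize import fsolve
    from .model import NodeParams, sigmoid
    p = NodeParams()
    E_ext, I_ext = BISTABLE_POINT

    def rhs(x):
        E, I = x
        a = p.c_EE * E - p.c_EI * I + E_ext
        b = p.c_IE * E - p.c_II * I + I_ext
        return [-E + (1 - E) * sigmoid(a, p.gamma, p.mu),
                -I + (1 - I) * sigmoid(b, p.gamma, p.mu)]

    down = fsolve(rhs, [0.01, 0.01], xtol=1e-13)
    up = fsolve(rhs, [0.5, 0.5], xtol=1e-13)
    return np.asarray(down), np.asarray(up)


def single_node_state_switch(direction: str = "down_to_up",
                             weight: float = 1000.0,
                             descent: DescentParams | None = None,
                             ) -> tuple[OptimizationResult, bool]:
    """Switch the bistable single node between its down and up states.

    Uses the precision cost toward the target fixed point on a
    measurement window [200, 400) disjoint from the control window
    [50, 150).  The down-to-up direction starts from a positive half-wave
    pulse (the up basin requires a net excitatory kick); the reverse
    direction starts from small noise.  Returns the result and whether
    the target state persists after the control is off.
    """
    from .model import single_node
    from .optimize import OptimizationProblem
    down, up = _bistable_fixed_points()
    if direction == "down_to_up":
        start, target = down, up
        init = InitSpec("sinusoid", 1.0, 0.0025)   # half-wave pulse > 0
    elif direction == "up_to_down":
        start, target = up, down
        init = InitSpec("noise", 0.2, seed=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    network = single_node(*BISTABLE_POINT)
    T = 400.0
    NT = int(round(T / 0.1))
    ref = np.full((1, NT + 1), target[0])
    prob = OptimizationProblem(
        config=network,
        cost=CostSpec("precision", weight, t0=200.0, T=T, reference=ref),
        duration=T, t0C=50.0, t1C=150.0,
        initial_state=start,
        init=init,
        descent=descent or DescentParams(max_iter=800, patience=15))
    res = optimize(prob)
    # persistence: continue 250 units with u = 0 and compare to the target
    u_ext = np.zeros((1, NT + 2500 + 1))
    u_ext[:, :NT + 1] = res.control.masked().u
    ctl = ControlSignal(dt=0.1, u=u_ext, t0C=50.0, t1C=150.0)
    tail = simulate(network, ctl, initial_state=start)
    reached = bool(abs(tail.E[0, -1] - target[0]) < 0.01
                   and abs(np.ptp(tail.E[0, -500:])) < 1e-6)
    return res, reached


def aligned_l2_distance(u_a: np.ndarray, u_b: np.ndarray,
                        max_shift_steps: int = 600,
                        allow_node_swap: bool = True) -> float:
    """Normalized L2 distance between two control signals after optimal
    time alignment (and node relabeling, for symmetric networks).

    Distance = min over shifts of ||u_a - shift(u_b)|| / max(||u_a||,
    ||u_b||); 0 means identical shapes.
    """
    na, nb = np.linalg.norm(u_a), np.linalg.norm(u_b)
    denom = max(na, nb)
    if denom == 0:
        return 0.0
    best = np.inf
    variants = [u_b] + ([u_b[::-1]] if allow_node_swap else [])
    for v in variants:
        for s in range(-max_shift_steps, max_shift_steps + 1):
            shifted = np.zeros_like(v)
            if s >= 0:
                shifted[:, s:] = v[:, :v.shape[1] - s]
            else:
                shifted[:, :s] = v[:, -s:]
            d = np.linalg.norm(u_a - shifted)
            if d < best:
                best = d
    return float(best / denom)
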