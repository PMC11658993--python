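"""Run configuration, fixtures for the standard study setups, and
serialization of trajectories and results.

A :class:`RunConfig` bundles everything one optimal-control run needs:
the network, the cost functional, the control/measurement intervals, the
initial-control guess, descent and annealing parameters, and the seeding
of the initial state.  Configs round-trip through JSON or YAML; unknown
keys are rejected by name so typos cannot silently change a run.

:func:`fixture` returns ready-made configs for the standard setups: the
five single-node state-space points A-E, the bistable two-node network,
the six-node network in its asynchronous (D) and synchronous (E) states,
and the oscillation-induction, state-switch and (de)synchronization tasks.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .costs import CostSpec
from .model import ControlSignal, NetworkConfig, NodeParams, StateTrajectory, simulate
from .optimize import DescentParams, InitSpec, WeightSchedule

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "fixture",
    "FIXTURE_NAMES",
    "STATE_SPACE_POINTS",
    "TWO_NODE_C",
    "TWO_NODE_D",
    "SIX_NODE_C",
    "SIX_NODE_D",
    "write_timeseries",
    "read_timeseries",
    "config_hash",
]

# ---------------------------------------------------------------------------
# printed study parameters

#: external-input coordinates (E_ext, I_ext) of the single-node state-space
#: points at which control tasks are studied
STATE_SPACE_POINTS = {
    "A": (1.0, 1.0),      # down state
    "B": (3.0, 1.0),      # up state
    "C": (1.8, 0.8),      # two-node network: bistable IP / OOP oscillations
    "D": (1.6, 0.4),      # six-node network: asynchronous oscillation
    "E": (1.0, 0.4),      # six-node network: synchronous oscillation
}

TWO_NODE_C = np.array([[0.0, 1.0],
                       [1.0, 0.0]])
TWO_NODE_D = np.array([[0.0, 9.5],
                       [9.5, 0.0]])
TWO_NODE_CGL = 1.8

SIX_NODE_C = np.array([
    [0, 1, 0, 0, 0, 1],
    [1, 0, 1, 0, 1, 0],
    [0, 0, 0, 0, 0, 1],
    [0, 0, 1, 0, 0, 1],
    [1, 1, 0, 1, 0, 1],
    [0, 1, 1, 0, 0, 0]], dtype=float)
SIX_NODE_D = np.array([
    [0, 12, 0, 0, 0, 8],
    [8, 0, 13, 0, 1, 0],
    [0, 0, 0, 0, 0, 9],
    [0, 0, 4, 0, 0, 11],
    [15, 17, 0, 14, 0, 18],
    [0, 0, 3, 0, 0, 0]], dtype=float)
SIX_NODE_CGL = 0.8

#: spectral-readout frequencies of the two coexisting two-node attractors
#: (inverse periods 13.89 and 22.72)
F_IP = 0.072
F_OOP = 0.044

#: deterministic weakly-perturbed initial state used to seed the six-node
#: network: a small per-node ramp breaking the permutation symmetry
def ramp_initial_state(N: int, scale: float = 0.01) -> np.ndarray:
    ramp = scale * (np.arange(N) + 1)
    return np.concatenate([ramp, ramp])


# ---------------------------------------------------------------------------
# run configuration


class ConfigError(ValueError):
    """A run configuration violated the schema."""


@dataclass
class RunConfig:
    """Declarative description of a simulation or optimization run."""

    network: NetworkConfig
    duration: float
    dt: float = 0.1
    cost: CostSpec | None = None
    t0C: float = 0.0
    t1C: float = np.inf
    init: InitSpec = field(default_factory=InitSpec)
    descent: DescentParams = field(default_factory=DescentParams)
    anneal: WeightSchedule | None = None
    seed: int = 0
    initial_state: np.ndarray | None = None
    settle: float = 0.0      # uncontrolled pre-run; its final state becomes t=0
    task_weights: dict = field(default_factory=dict)
    label: str = ""

    def prepared_initial_state(self) -> np.ndarray | None:
        """Initial state after the settle pre-run (if any)."""
        if self.settle <= 0:
            return self.initial_state
        traj = simulate(self.network, duration=self.settle, dt=self.dt,
                        initial_state=self.initial_state)
        return traj.final_state()

    def problem(self, cost: CostSpec | None = None):
        """Build the optimization problem (optionally overriding the cost)."""
        from .optimize import OptimizationProblem
        c = cost if cost is not None else self.cost
        if c is None:
            raise ConfigError("run config has no cost block")
        return OptimizationProblem(
            config=self.network, cost=c, duration=self.duration,
            t0C=self.t0C, t1C=self.t1C, dt=self.dt,
            initial_state=self.prepared_initial_state(),
            init=self.init, descent=self.descent, anneal=self.anneal,
            seed=self.seed)


# ---------------------------------------------------------------------------
# (de)serialization

_NETWORK_KEYS = {"N", "params", "C", "D", "c_gl", "E_ext", "I_ext"}
_PARAM_KEYS = {"tau_E", "tau_I", "gamma", "mu", "c_EE", "c_EI", "c_IE", "c_II"}
_COST_KEYS = {"kind", "weight", "t0", "T", "omega", "reference", "observable"}
_TOP_KEYS = {"network", "duration", "dt", "cost", "t0C", "t1C", "init",
             "descent", "anneal", "seed", "initial_state", "settle",
             "task_weights", "label"}
_INIT_KEYS = {"kind", "amplitude", "frequency", "seed", "antiphase"}
_DESCENT_KEYS = {"init_step", "armijo_c1", "shrink", "grow", "min_step",
                 "max_iter", "tol", "patience"}
_ANNEAL_KEYS = {"factor", "period", "floor", "max_stages", "collapse_tol"}


def _check_keys(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where} block")


def _network_from_dict(d: dict) -> NetworkConfig:
    _check_keys(d, _NETWORK_KEYS, "network")
    try:
        N = int(d["N"])
    except KeyError:
        raise ConfigError("network block requires 'N'")
    pd = d.get("params", {})
    _check_keys(pd, _PARAM_KEYS, "network.params")
    params = NodeParams(**pd)
    C = np.asarray(d.get("C", np.zeros((N, N))), dtype=float)
    D = np.asarray(d.get("D", np.zeros((N, N))), dtype=float)
    for name, M in (("C", C), ("D", D)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ConfigError(f"network matrix '{name}' must be square, "
                              f"got shape {M.shape}")
        if M.shape != (N, N):
            raise ConfigError(f"network matrix '{name}' has shape {M.shape}, "
                              f"expected ({N}, {N})")
    return NetworkConfig(N=N, params=params, C=C, D=D,
                         c_gl=float(d.get("c_gl", 0.0)),
                         E_ext=d.get("E_ext", 0.0), I_ext=d.get("I_ext", 0.0))


def _cost_from_dict(d: dict) -> CostSpec:
    _check_keys(d, _COST_KEYS, "cost")
    ref = d.get("reference")
    return CostSpec(kind=d["kind"], weight=float(d["weight"]),
                    t0=float(d["t0"]), T=float(d["T"]),
                    omega=None if d.get("omega") is None else float(d["omega"]),
                    reference=None if ref is None else np.asarray(ref, float),
                    observable=d.get("observable", "E"))


def from_dict(d: dict) -> RunConfig:
    _check_keys(d, _TOP_KEYS, "top-level")
    if "network" not in d:
        raise ConfigError("config requires a 'network' block")
    if "duration" not in d:
        raise ConfigError("config requires 'duration'")
    init_d = d.get("init", {})
    _check_keys(init_d, _INIT_KEYS, "init")
    desc_d = d.get("descent", {})
    _check_keys(desc_d, _DESCENT_KEYS, "descent")
    ann = d.get("anneal")
    if ann is not None:
        _check_keys(ann, _ANNEAL_KEYS, "anneal")
    x0 = d.get("initial_state")
    t1C = d.get("t1C", np.inf)
    return RunConfig(
        network=_network_from_dict(d["network"]),
        duration=float(d["duration"]),
        dt=float(d.get("dt", 0.1)),
        cost=None if d.get("cost") is None else _cost_from_dict(d["cost"]),
        t0C=float(d.get("t0C", 0.0)),
        t1C=np.inf if t1C in (None, "inf") else float(t1C),
        init=InitSpec(**init_d),
        descent=DescentParams(**desc_d),
        anneal=None if ann is None else WeightSchedule(**ann),
        seed=int(d.get("seed", 0)),
        initial_state=None if x0 is None else np.asarray(x0, float),
        settle=float(d.get("settle", 0.0)),
        task_weights=dict(d.get("task_weights", {})),
        label=str(d.get("label", "")))


def to_dict(cfg: RunConfig) -> dict:
    net = cfg.network
    d = {
        "label": cfg.label,
        "network": {
            "N": net.N,
            "params": asdict(net.params),
            "C": net.C.tolist(),
            "D": net.D.tolist(),
            "c_gl": net.c_gl,
            "E_ext": net.E_ext.tolist(),
            "I_ext": net.I_ext.tolist(),
        },
        "duration": cfg.duration,
        "dt": cfg.dt,
        "cost": None,
        "t0C": cfg.t0C,
        "t1C": "inf" if np.isinf(cfg.t1C) else cfg.t1C,
        "init": asdict(cfg.init),
        "descent": asdict(cfg.descent),
        "anneal": None if cfg.anneal is None else asdict(cfg.anneal),
        "seed": cfg.seed,
        "initial_state": None if cfg.initial_state is None
        else np.asarray(cfg.initial_state).tolist(),
        "settle": cfg.settle,
        "task_weights": dict(cfg.task_weights),
    }
    if cfg.cost is not None:
        c = cfg.cost
        d["cost"] = {"kind": c.kind, "weight": c.weight, "t0": c.t0, "T": c.T,
                     "omega": c.omega,
                     "reference": None if c.reference is None
                     else np.asarray(c.reference).tolist(),
                     "observable": c.observable}
    return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run config from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a run configuration."""
    blob = json.dumps(to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# fixtures


def _single_node_cfg(point: str) -> NetworkConfig:
    E_ext, I_ext = STATE_SPACE_POINTS[point]
    z = np.zeros((1, 1))
    return NetworkConfig(N=1, params=NodeParams(), C=z, D=z, c_gl=0.0,
                         E_ext=E_ext, I_ext=I_ext)


def _two_node_cfg() -> NetworkConfig:
    E_ext, I_ext = STATE_SPACE_POINTS["C"]
    return NetworkConfig(N=2, params=NodeParams(), C=TWO_NODE_C,
                         D=TWO_NODE_D, c_gl=TWO_NODE_CGL,
                         E_ext=E_ext, I_ext=I_ext)


def _six_node_cfg(point: str) -> NetworkConfig:
    E_ext, I_ext = STATE_SPACE_POINTS[point]
    return NetworkConfig(N=6, params=NodeParams(), C=SIX_NODE_C,
                         D=SIX_NODE_D, c_gl=SIX_NODE_CGL,
                         E_ext=E_ext, I_ext=I_ext)


def _fixture_builders():
    b = {}
    for pt in "ABCDE":
        b[f"wc_point_{pt}"] = lambda pt=pt: RunConfig(
            network=_single_node_cfg(pt), duration=500.0,
            label=f"single node at point {pt}")

    b["two_node_C"] = lambda: RunConfig(
        network=_two_node_cfg(), duration=700.0,
        initial_state=np.array([0.1, 0.1, 0.1, 0.1]),
        label="two-node network, bistable IP/OOP point")

    for pt in "DE":
        b[f"six_node_{pt}"] = lambda pt=pt: RunConfig(
            network=_six_node_cfg(pt), duration=600.0,
            initial_state=ramp_initial_state(6),
            label=f"six-node network at point {pt}")

    # oscillation induction from the down state (30 Hz target); the down
    # state's flat cost landscape needs an oscillatory initial kick to
    # escape the zero-control local minimum
    b["induce_osc_A"] = lambda: RunConfig(
        network=_single_node_cfg("A"), duration=400.0,
        cost=CostSpec("fourier_sync", 8e4, t0=50.0, T=350.0,
                      omega=2 * np.pi * 0.03),
        t0C=50.0, t1C=350.0,
        init=InitSpec("sinusoid", amplitude=0.5, frequency=0.03),
        label="induce 30 Hz oscillation at point A, w_F = 8e4")

    # two-node state switches; control on [50, 350), cost measured on
    # [200, 600); initial state settled onto the start attractor
    def _fig7(start, weights, omega):
        return RunConfig(
            network=_two_node_cfg(), duration=600.0,
            cost=CostSpec("fourier_sync" if start == "OOP" else "fourier_osc",
                          weights["fourier"], t0=200.0, T=600.0, omega=omega),
            t0C=50.0, t1C=350.0,
            initial_state=(np.array([0.9, 0.0, 0.0, 0.0]) if start == "OOP"
                           else np.array([0.1, 0.1, 0.1, 0.1])),
            settle=200.0,
            anneal=WeightSchedule(),
            task_weights=weights,
            label=f"two-node switch starting from {start}")

    b["switch_OOP_to_IP"] = lambda: _fig7(
        "OOP", {"fourier": 4000.0, "cross_correlation": 250.0,
                "variance": 30000.0}, omega=2 * np.pi * F_IP)
    b["switch_IP_to_OOP"] = lambda: _fig7(
        "IP", {"fourier": 2000.0, "cross_correlation": -500.0,
               "variance": -1000.0}, omega=2 * np.pi * F_OOP)

    # six-node (de)synchronization; control and measurement on [100, 600);
    # omega is set at run time to the uncontrolled spectral peak
    def _fig8(point, weights):
        return RunConfig(
            network=_six_node_cfg(point), duration=700.0,
            cost=CostSpec("fourier_sync", weights["fourier"],
                          t0=100.0, T=600.0, omega=2 * np.pi * 0.06),
            t0C=100.0, t1C=600.0,
            initial_state=ramp_initial_state(6),
            task_weights=weights,
            label=f"six-node network at point {point}")

    b["six_node_sync"] = lambda: _fig8(
        "D", {"fourier": 18600.0, "cross_correlation": 4711.0,
              "variance": 45000.0})
    b["six_node_desync"] = lambda: _fig8(
        "E", {"fourier": -1000.0, "cross_correlation": -500.0,
              "variance": -2000.0})
    return b


_BUILDERS = _fixture_builders()
FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def fixture(name: str) -> RunConfig:
    """Return the ready-made run configuration for a named study setup."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(FIXTURE_NAMES)}") from None


# ---------------------------------------------------------------------------
# time-series serialization


def write_timeseries(path: str | Path, dt: float, arrays: dict[str, np.ndarray],
                     meta: dict | None = None) -> None:
    """Write time series as CSV (column t plus one column per node series),
    with an optional JSON metadata sidecar next to it."""
    path = Path(path)
    cols, names = [], []
    n_t = None
    for prefix, arr in arrays.items():
        arr = np.atleast_2d(arr)
        n_t = arr.shape[1]
        for n in range(arr.shape[0]):
            names.append(f"{prefix}_{n}")
            cols.append(arr[n])
    t = np.arange(n_t) * dt
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t"] + names)
        for k in range(n_t):
            w.writerow([repr(float(t[k]))] + [repr(float(c[k])) for c in cols])
    if meta is not None:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps({"dt": dt, **meta}, indent=1))


def read_timeseries(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a CSV written by :func:`write_timeseries`.

    Returns (t, {prefix: array of shape (N, n_t)}).
    """
    data = np.genfromtxt(path, delimiter=",", names=True)
    t = data["t"]
    groups: dict[str, list] = {}
    for name in data.dtype.names[1:]:
        prefix, _, idx = name.rpartition("_")
        groups.setdefault(prefix, []).append((int(idx), data[name]))
    out = {p: np.array([s for _, s in sorted(rows)]) for p, rows in groups.items()}
    return t, out


def save_trajectory(path: str | Path, traj: StateTrajectory,
                    cfg: RunConfig | None = None) -> None:
    meta = {"kind": "trajectory"}
    if cfg is not None:
        meta["config_hash"] = config_hash(cfg)
    write_timeseries(path, traj.dt, {"E": traj.E, "I": traj.I}, meta)


def save_control(path: str | Path, control: ControlSignal,
                 cfg: RunConfig | None = None) -> None:
    meta = {"kind": "control", "t0C": control.t0C,
            "t1C": None if np.isinf(control.t1C) else control.t1C}
    if cfg is not None:
        meta["config_hash"] = config_hash(cfg)
    write_timeseries(path, control.dt, {"u": control.u}, meta)
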