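# oscontrol

Optimal control of oscillations and network synchrony in delay-coupled
Wilson-Cowan neural population models, computed with the adjoint method.

## The problem

Classical optimal control theory asks a dynamical system to track a
prescribed reference trajectory.  For oscillatory targets this is overly
rigid: one usually cares that a neural population oscillates *at some
frequency*, or that network nodes oscillate *together* (or apart) — not
about the exact waveform, amplitude or phase.  `oscontrol` implements
cost functionals that capture these goals directly and differentiates
them with the adjoint method, so that the full gradient of

    F = w_X * F_X  +  1/2 ∫ u(t)² dt

with respect to every control sample `u_n(t_k)` costs one backward sweep,
whatever the dimension of the control.  The accuracy term `F_X` is one of

| kind | definition | targets |
|---|---|---|
| `precision` | mean squared distance to a reference | classical tracking |
| `fourier_sync` | −&#124;Fourier component at ω of the summed activity&#124;² | coherent network power at a frequency |
| `fourier_osc` | −Σₙ &#124;node-wise Fourier component at ω&#124;² | oscillation per node, any phases |
| `cross_correlation` | − mean pairwise Pearson correlation | phase synchrony (any frequency) |
| `variance` | across-node variance of activity | synchrony (small = together) |

A negative weight `w_X` flips each goal (suppress a mode, desynchronize).
The plant is a network of Wilson-Cowan nodes — excitatory/inhibitory
population pairs with sigmoid transfer — coupled through their excitatory
populations with per-edge delays; the control enters the excitatory
input additively.  Gradient descent with backtracking line search and
optional weight annealing finds minimum-energy controls.

Intended users: computational neuroscientists studying stimulation
strategies (frequency entrainment, attractor switching, network
(de)synchronization) on firing-rate network models.

## A worked example

Drive a 30 Hz oscillation from a stable low-activity state
(`examples/03_induce_oscillation.py`):

```
termination: converged after 312 iterations
energy cost F_E           =     241.72
Fourier cost w*F_F        =   -1658.62   (zero control: -5.22e-13)
dominant frequency        =     0.0300 cycles/unit (target 0.03 = 30 Hz)
```

The node rests in a down state with essentially zero spectral power at
the 30 Hz target (1 time unit = 1 ms).  The optimized control spends
energy `F_E = 241.7` to earn a weighted Fourier reward of `−1658.6`, and
the controlled activity oscillates exactly at the target frequency —
`0.0300` is within one spectral bin (1/300) of the target.

Desynchronizing a six-node network
(`examples/05_desynchronize_network.py`):

```
uncontrolled Kuramoto mean R = 0.753
controlled   Kuramoto mean R = 0.240
control energy F_E           = 80.5
```

The Kuramoto order parameter `R ∈ [0, 1]` (1 = perfect phase alignment)
drops to a third of its uncontrolled value when the cross-correlation
cost is minimized with a negative weight.

The other scripts in `examples/` cover the bistable two-node network and
its attractor periods, the single-node regime map, minimum-energy
switches between in-phase and out-of-phase oscillations, and a
finite-difference verification of the adjoint gradient.

A thin CLI wraps the same functionality:

```sh
oscontrol simulate --fixture two_node_C --out run/
oscontrol analyze run/trajectory.csv --t0 200
oscontrol optimize --fixture induce_osc_A --out opt/
oscontrol scan --grid 20 --out regimes.csv
```

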