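# Methods

This note documents the models, numerical choices and design decisions
behind `oscontrol`, and what the test suite does and does not establish.

## Model

Each network node is a Wilson-Cowan pair: fractions `E_n(t), I_n(t)` of
active excitatory and inhibitory neurons obeying

    tau_E dE_n/dt = -E_n + (1 - E_n) S(c_EE E_n - c_EI I_n + E_ext
                     + u_n(t) + c_gl sum_m C_nm E_m(t - D_nm))
    tau_I dI_n/dt = -I_n + (1 - I_n) S(c_IE E_n - c_II I_n + I_ext)

with the sigmoid `S(x) = 1/(1 + exp(-gamma (x - mu)))`.  All nodes share
one parameter set — tau_E = 2.5, tau_I = 3.75, gamma = 1.5, mu = 3,
(c_EE, c_EI, c_IE, c_II) = (16, 12, 15, 3) — and couple only through
their excitatory populations, with 0/1 adjacency `C` (row = receiver),
per-edge delays `D`, and a global gain `c_gl`.  The additive control
`u_n(t)` enters the excitatory synaptic argument only.  Time is
dimensionless; frequencies quoted in Hz assume 1 unit = 1 ms, so a 30 Hz
target means a period of 33.3 units.

The `(1 - x) S(...) - x` form confines activities to [0, 1] for any
admissible control; the simulator asserts this and treats any non-finite
state as an integration failure with a reported failure time.

## Discretization

Explicit Euler with `dt = 0.1` on the grid `t_k = k dt` (halving `dt`
changes stationary terminal states by < 1% and oscillation periods by
< 1%, which is the accuracy relevant here).  Delays are rounded to whole
grid steps; the state before t = 0 is held constant at the initial
state.  Every time integral — energy, accuracy costs, and their
gradients — uses the left-rectangle rule on the half-open window
`[a, b)` (grid indices `a <= t_k < b`).  This single convention makes
each cost's derivative series `g = dF_X/dx(t)` the *exact* gradient of
the discretized value, which the tests verify against central finite
differences at ~1e-6 relative error.

## Cost functionals

With measurement window `[t0, T)` of length `Tm` and observable
`x_n = E_n`:

- energy: `F_E = 1/2 integral u^2 dt` over the whole run;
- precision: `w_P/(2 Tm) integral (x - x_ref)^2 dt`;
- synchronization Fourier: `-|integral sum_n x_n e^{-i w t} dt|^2 / (N Tm)^2`,
  rewarding *coherent* network power at the target frequency;
- oscillation Fourier: `-(sum_n |integral x_n e^{-i w t} dt|^2) / (N Tm^2)`,
  phase-indifferent node-wise power (equal to the synchronization form
  for N = 1, and never smaller than it, by Cauchy-Schwarz);
- cross-correlation: minus the mean pairwise Pearson correlation over
  the window (in [-1, 1]); undefined when a node's variance is below
  1e-12, which raises a degenerate-input error rather than emitting NaN;
- variance: the time-averaged across-node variance (>= 0, zero iff the
  nodes coincide).

A negative weight turns each functional into its opposite (suppress a
mode, desynchronize).  One derivative detail: differentiating the
cross-correlation cost gives the *negative* of the commonly printed
bracket for its g-series; the finite-difference oracle fixes the sign
unambiguously and the implementation follows that.

## Adjoint gradient

The gradient of the total cost with respect to every control sample
comes from one backward sweep.  The sweep is the exact reverse-mode
differentiation of the Euler forward map (discretize-then-differentiate):
lambda runs backward from lambda(T) = 0; each coupling delay `d` feeds
`lambda(t + d)` back into the present, gated to vanish for look-ups past
T.  Because forward and backward passes discretize the same map, the
assembled gradient matches finite differences of the discretized cost to
roundoff (measured ~1e-7 relative; the acceptance threshold is 1e-3).
The continuous delayed adjoint equation would differ by O(dt) — the
discrete-exact choice is what makes line searches reliable.

## Optimizer

Plain gradient descent with an Armijo line search (c1 = 1e-4) that both
backtracks (halving) and forward-tracks (doubling while the condition
still holds).  Forward-tracking matters: cost scales differ by many
orders of magnitude between tasks, so no fixed step scale works.  Every
accepted step strictly decreases the total cost; simulation failures
under a trial control reject the step and halve it.  Convergence:
relative cost decrease below 1e-6 for 10 consecutive iterations, capped
at 5000 iterations per weight stage.

Minimum-energy tasks anneal the accuracy weight: stages of at most
`period` iterations, after each of which |w| shrinks by a fixed factor
(default 0.7), until the control collapses to zero or, for switching
tasks, until the switch is lost.  `minimum_energy_switch` judges each
stage with a task-success callback — the target attractor must persist
for at least ten natural periods after the control window — bisects the
weight toward the switch threshold once a stage loses it, and returns
the lowest-energy successful stage after a final polish descent at that
stage's weight.  This mirrors how such solutions are selected in
practice: repeated initializations, success-filtered, minimum cost kept.

When several cost functionals are optimized for the *same* switch
(`two_node_switch_suite`), each first runs independently and then the
best (lowest-energy) control found by any of them — the incumbent — is
offered to the others, which re-descend from it under their own cost at
a ladder of weights stepping down from their own switch threshold (with
a full annealed warm start as fallback).  A functional adopts the
incumbent only if its own descent independently retains the switch at
lower energy.  Without this exchange each functional stalls in its own
local optimum (pairwise control distances of 6-60%); with it the three
minimum-energy controls coincide to a fraction of a percent in both
switch directions, making the comparison of their limits meaningful.

### Initial controls

The descent landscape has genuine local optima, and several tasks need
an educated initial guess:

- induction from the down state: the zero control is a local minimum
  (the stationary state has no leakage power at a commensurate target
  frequency), so the task starts from a sinusoid at the target frequency
  with amplitude 0.5;
- switches driven by correlation/variance costs from a symmetric state:
  the symmetry manifold is flow-invariant and the gradient vanishes on
  it, so these start from small uniform noise (amplitude 1.0,
  multi-start over three seeds, lowest-energy success kept);
- Fourier-driven switches: a sinusoid at the target attractor's
  frequency, in-phase or anti-phase across nodes according to the target
  pattern;
- the down-to-up stationary switch: a positive half-wave pulse (the up
  basin needs a net excitatory kick).

## Standard study setups

The `fixture()` presets encode the study conditions: single-node
state-space points A (1,1, down), B (3,1, up), C (1.8, 0.8), D (1.6,
0.4), E (1, 0.4); the two-node network (mutual coupling, delay 9.5,
c_gl = 1.8) bistable between in-phase (IP) and out-of-phase (OOP)
oscillations at point C; and a six-node network (asymmetric 0/1
adjacency, heterogeneous delays 1-18, c_gl = 0.8) that oscillates
asynchronously at point D and nearly synchronously at point E.

Attractor periods are reported two ways.  The general-purpose measure is
the mean inter-peak interval with sub-grid quadratic refinement (IP
13.93, OOP 22.47 at dt = 0.1).  The headline reproduction values instead
read the raw periodogram peak of the 500-unit post-transient measurement
window (frequency resolution 0.002), the finite-window spectral readout:
IP 1/0.072 = 13.89, OOP 1/0.044 = 22.73.  Both measures agree to within
the spectral resolution; the duality is asserted at 2%.

The six-node "weakly perturbed" start is the deterministic ramp
`E_n(0) = I_n(0) = 0.01 (n+1)`.  Point D's asynchronous attractor is
reached from essentially any small perturbation (R = 0.34); point E has
a coexisting less-synchronous state that some random starts find, and
the ramp lands on the dominant synchronous attractor (R = 0.75).

Kuramoto order parameter: phases are the angles of the analytic signal
(Hilbert transform) of each node's mean-subtracted excitatory activity
over the analysis window; `R(t) = |mean_n exp(i theta_n)|`, averaged
over the window.  Phase-extraction conventions differ across
implementations, which is why the synchrony baselines carry a +-0.10
tolerance rather than exactness.

## Numerical edge cases

- Sigmoid exponents are clipped at +-60; S saturates instead of
  overflowing.
- Euler keeps activities in [0, 1] exactly for dt <= min(tau_E, tau_I).
- Regime classification simulates from the four corners of the (E, I)
  unit square, discards a 300-unit transient, and calls peak-to-peak
  E-amplitude > 1e-3 oscillatory (well above the Euler noise floor, well
  below physiological amplitudes); amplitudes within a factor two of the
  threshold return "unclassified" instead of a guess.  Stationary levels
  are split down/up at E = 0.15, and two branches further apart than
  0.05 count as bistable.
- Zero-variance nodes make the Pearson correlation undefined and raise;
  non-oscillatory nodes make Kuramoto phases meaningless and raise.

## What the tests show — and do not

The suite verifies the implementation on the deterministic, noise-free
model with shared node parameters: discrete-gradient exactness, analytic
cost values, the published attractor periods and synchrony baselines,
and qualitative task outcomes (induction at the target frequency,
persistent switches, synchrony raised/lowered against baseline).  It
does not establish anything about noisy dynamics, heterogeneous node
parameters, other network topologies, or robustness of the controls to
model mismatch — the controls are open-loop and model-exact by
construction.  Gradient-descent results are local optima; multi-start
reduces but cannot eliminate the risk of missing better controls.
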