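"""Numba kernels for the forward Euler sweep and the discrete adjoint sweep.

All kernels work on plain float64 arrays. State arrays are shaped
``(N, NT + 1)`` with column ``k`` holding the state at time ``t_k = k * dt``.
Delays are given in integer grid steps; a delayed index ``k - d < 0`` reads
column 0 (the pre-simulation history is held constant at the initial state).
"""

import numpy as np
from numba import njit

#: clip bound for the sigmoid exponent; exp(60) ~ 1e26 is far beyond any
#: attainable synaptic input but safely inside float64 range.
_EXP_CLIP = 60.0


@njit(cache=True)
def _sig(x, gamma, mu):
    z = gamma * (x - mu)
    if z > _EXP_CLIP:
        z = _EXP_CLIP
    elif z < -_EXP_CLIP:
        z = -_EXP_CLIP
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def forward(E, I, u, Cw, dsteps, Eext, Iext,
            tauE, tauI, gamma, mu, cEE, cEI, cIE, cII, dt):
    """Explicit-Euler integration of the delay-coupled Wilson-Cowan network.

    Fills ``E`` and ``I`` in place starting from their column 0.
    Returns -1 on success, or the first step index at which the state
    became non-finite.
    """
    N, NT1 = E.shape
    NT = NT1 - 1
    for k in range(NT):
        for n in range(N):
            s = 0.0
            for m in range(N):
                c = Cw[n, m]
                if c != 0.0:
                    j = k - dsteps[n, m]
                    if j < 0:
                        j = 0
                    s += c * E[m, j]
            a = cEE * E[n, k] - cEI * I[n, k] + Eext[n] + u[n, k] + s
            b = cIE * E[n, k] - cII * I[n, k] + Iext[n]
            En = E[n, k] + dt / tauE * (-E[n, k] + (1.0 - E[n, k]) * _sig(a, gamma, mu))
            In = I[n, k] + dt / tauI * (-I[n, k] + (1.0 - I[n, k]) * _sig(b, gamma, mu))
            if not (np.isfinite(En) and np.isfinite(In)):
                return k
            E[n, k + 1] = En
            I[n, k + 1] = In
    return -1


@njit(cache=True)
def synaptic_inputs(E, I, u, Cw, dsteps, Eext, Iext,
                    cEE, cEI, cIE, cII):
    """Synaptic arguments a (excitatory) and b (inhibitory) along a trajectory."""
    N, NT1 = E.shape
    a = np.empty((N, NT1))
    b = np.empty((N, NT1))
    for k in range(NT1):
        for n in range(N):
            s = 0.0
            for m in range(N):
                c = Cw[n, m]
                if c != 0.0:
                    j = k - dsteps[n, m]
                    if j < 0:
                        j = 0
                    s += c * E[m, j]
            a[n, k] = cEE * E[n, k] - cEI * I[n, k] + Eext[n] + u[n, k] + s
            b[n, k] = cIE * E[n, k] - cII * I[n, k] + Iext[n]
    return a, b


@njit(cache=True)
def adjoint(E, I, a, b, GE, GI, Cw, dsteps,
            tauE, tauI, gamma, mu, cEE, cEI, cIE, cII, dt):
    """Backward sweep of the discrete adjoint system.

    ``GE``/``GI`` hold the cost derivative dPhi/dE_n[k], dPhi/dI_n[k] of the
    discretized accuracy cost (zero outside the measurement window).  The
    returned ``lamE``/``lamI`` satisfy lam_n[k] = dF_X/dx_n[k] (total
    derivative through the discrete dynamics), with lam[NT] = G[NT] = 0.

    Delayed couplings feed back through the indicator-gated future terms,
    mirroring the delayed adjoint equation of the continuous formulation.
    """
    N, NT1 = E.shape
    NT = NT1 - 1
    lamE = np.zeros((N, NT1))
    lamI = np.zeros((N, NT1))
    # pre-compute local linearization factors
    beta = np.empty((N, NT1))    # d E[k+1] / d (synaptic argument a[k])
    alpha = np.empty((N, NT1))
    SA = np.empty((N, NT1))
    SB = np.empty((N, NT1))
    for k in range(NT1):
        for n in range(N):
            sa = _sig(a[n, k], gamma, mu)
            sb = _sig(b[n, k], gamma, mu)
            SA[n, k] = sa
            SB[n, k] = sb
            beta[n, k] = dt / tauE * (1.0 - E[n, k]) * gamma * sa * (1.0 - sa)
            alpha[n, k] = dt / tauI * (1.0 - I[n, k]) * gamma * sb * (1.0 - sb)
    for n in range(N):
        lamE[n, NT] = GE[n, NT]
        lamI[n, NT] = GI[n, NT]
    for k in range(NT - 1, -1, -1):
        for n in range(N):
            accE = GE[n, k]
            # local couplings into step k+1
            accE += (1.0 - dt / tauE * (1.0 + SA[n, k]) + beta[n, k] * cEE) * lamE[n, k + 1]
            accE += alpha[n, k] * cIE * lamI[n, k + 1]
            # delayed couplings: E_n[k] enters node p's excitatory input at
            # step j = k + d[p, n]; gated by j + 1 <= NT
            for p in range(N):
                c = Cw[p, n]
                if c != 0.0:
                    j = k + dsteps[p, n]
                    if j < NT:
                        accE += beta[p, j] * c * lamE[p, j + 1]
            lamE[n, k] = accE
            accI = GI[n, k]
            accI -= beta[n, k] * cEI * lamE[n, k + 1]
            accI += (1.0 - dt / tauI * (1.0 + SB[n, k]) - alpha[n, k] * cII) * lamI[n, k + 1]
            lamI[n, k] = accI
    return lamE, lamI
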