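"""Post-hoc quantification of simulated activity: oscillation periods,
spectra, phases, and the Kuramoto order parameter.

Phases are extracted as the angle of the analytic signal (Hilbert
transform) of the mean-subtracted observable; the Kuramoto order parameter

    R(t) = | (1/N) sum_n exp(i theta_n(t)) |

then ranges from 0 (no phase synchrony) to 1 (full synchrony) and its
temporal mean over a measurement window is the package's scalar synchrony
measure.  Spectra are plain (untapered) periodograms of the
mean-subtracted window, matching the finite-window Fourier integrals used
by the cost functionals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, hilbert

from .model import interval_indices

__all__ = [
    "NotOscillatoryError",
    "SpectrumResult",
    "SynchronyReport",
    "oscillation_period",
    "extract_phase",
    "kuramoto",
    "kuramoto_mean",
    "power_spectrum",
    "dominant_period",
    "hz",
]

#: transient discarded by default before measuring attractor properties
DEFAULT_TRANSIENT = 100.0


def hz(f_hz: float) -> float:
    """Convert a frequency in Hz to cycles per model time unit (1 unit = 1 ms)."""
    return f_hz / 1000.0


class NotOscillatoryError(ValueError):
    """A series did not contain enough oscillation cycles to analyze."""


def oscillation_period(x: np.ndarray, dt: float,
                       transient: float = DEFAULT_TRANSIENT,
                       min_peaks: int = 5) -> float:
    """Mean inter-peak interval of a single oscillatory series.

    Peaks are located after discarding ``transient`` and refined to
    sub-grid precision with a quadratic fit through the three samples
    around each maximum.

    Raises
    ------
    NotOscillatoryError
        If fewer than ``min_peaks`` peaks remain after the transient.
    """
    x = np.asarray(x, float)
    tail = x[int(round(transient / dt)):]
    amp = float(np.ptp(tail))
    peaks, _ = find_peaks(tail, prominence=0.1 * amp if amp > 0 else None)
    peaks = peaks[(peaks > 0) & (peaks < len(tail) - 1)]
    if len(peaks) < min_peaks:
        raise NotOscillatoryError(
            f"found {len(peaks)} peaks, need {min_peaks}")
    y0, y1, y2 = tail[peaks - 1], tail[peaks], tail[peaks + 1]
    denom = y0 - 2 * y1 + y2
    offset = np.where(denom != 0, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    times = (peaks + offset) * dt
    return float(np.diff(times).mean())


def extract_phase(x: np.ndarray, dt: float, t0: float, T: float) -> np.ndarray:
    """Unwrapped instantaneous phase of the analytic signal on [t0, T).

    The series is mean-subtracted over the window first.  A (numerically)
    constant series has no phase and raises ``ValueError``.
    """
    x = np.asarray(x, float)
    sl = interval_indices(t0, T, dt, x.shape[-1] - 1)
    y = x[sl] - x[sl].mean()
    if float(np.ptp(y)) < 1e-12:
        raise ValueError("constant series has no well-defined phase")
    return np.unwrap(np.angle(hilbert(y)))


@dataclass
class SynchronyReport:
    """Kuramoto order parameter R(t) and pairwise correlations on a window."""

    dt: float
    t0: float
    kuramoto_t: np.ndarray       # R(t) on the window grid
    kuramoto_mean: float
    pairwise_corr: np.ndarray    # (N, N) Pearson correlations


def kuramoto(E: np.ndarray, dt: float, t0: float, T: float,
             min_amplitude: float = 1e-3) -> SynchronyReport:
    """Phase-synchrony report for an N-node activity array (N, NT + 1).

    Every node must oscillate (peak-to-peak above ``min_amplitude`` on the
    window); a flat node makes the phase, and hence R, meaningless and
    raises ``ValueError``.
    """
    E = np.asarray(E, float)
    N = E.shape[0]
    if N < 2:
        raise ValueError("synchrony measures need N >= 2 nodes")
    sl = interval_indices(t0, T, dt, E.shape[-1] - 1)
    flat = [n for n in range(N) if float(np.ptp(E[n, sl])) < min_amplitude]
    if flat:
        raise ValueError(f"nodes {flat} are not oscillatory on the window")
    theta = np.array([extract_phase(E[n], dt, t0, T) for n in range(N)])
    R = np.abs(np.exp(1j * theta).mean(axis=0))
    corr = np.corrcoef(E[:, sl])
    return SynchronyReport(dt=dt, t0=t0, kuramoto_t=R,
                           kuramoto_mean=float(R.mean()),
                           pairwise_corr=corr)


def kuramoto_mean(E: np.ndarray, dt: float, t0: float, T: float) -> float:
    """Temporal mean of the Kuramoto order parameter over [t0, T)."""
    return kuramoto(E, dt, t0, T).kuramoto_mean


@dataclass
class SpectrumResult:
    """One-sided periodogram; ``power`` rows sum to the windowed variance."""

    frequencies: np.ndarray      # cycles per time unit
    power: np.ndarray            # (N, n_freq)
    dominant: np.ndarray         # (N,) dominant frequency per node


def power_spectrum(x: np.ndarray, dt: float, t0: float, T: float,
                   interpolate: bool = True) -> SpectrumResult:
    """Untapered periodogram of the mean-subtracted window [t0, T).

    ``interpolate=True`` refines each node's dominant frequency with a
    quadratic fit through the three bins around the maximum;
    ``interpolate=False`` reports the raw argmax bin — the finite-window
    readout whose resolution is 1/(T - t0).
    """
    x = np.atleast_2d(np.asarray(x, float))
    sl = interval_indices(t0, T, dt, x.shape[-1] - 1)
    y = x[:, sl] - x[:, sl].mean(axis=1, keepdims=True)
    K = y.shape[1]
    if K < 2:
        raise ValueError("window must contain at least 2 samples")
    X = np.fft.rfft(y, axis=1)
    freqs = np.fft.rfftfreq(K, dt)
    # one-sided normalization: sum of power equals the time-domain variance
    power = np.abs(X) ** 2 / K ** 2
    power[:, 1:] *= 2.0
    if K % 2 == 0:
        power[:, -1] /= 2.0
    dominant = np.empty(x.shape[0])
    for n in range(x.shape[0]):
        j = int(np.argmax(power[n, 1:])) + 1
        f = freqs[j]
        if interpolate and 1 <= j < len(freqs) - 1:
            p0, p1, p2 = power[n, j - 1:j + 2]
            denom = p0 - 2 * p1 + p2
            if denom != 0:
                f = freqs[j] + 0.5 * (p0 - p2) / denom * (freqs[1] - freqs[0])
        dominant[n] = f
    return SpectrumResult(frequencies=freqs, power=power, dominant=dominant)


def dominant_period(x: np.ndarray, dt: float, t0: float, T: float,
                    interpolate: bool = False) -> float:
    """Oscillation period read off the periodogram peak of one series.

    With ``interpolate=False`` this is the inverse of the raw peak bin —
    the finite-window spectral readout with resolution 1/(T - t0), the
    procedure used for reporting attractor periods.
    """
    spec = power_spectrum(np.atleast_2d(x), dt, t0, T, interpolate=interpolate)
    f = float(spec.dominant[0])
    if f <= 0:
        raise NotOscillatoryError("no nonzero dominant frequency")
    return 1.0 / f
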