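"""Time-domain grounding of the angle-basis model.

The model treats the bandpass-filtered BOLD signal at region ``c`` as a single
sinusoid with region-specific phase, plus a jitter term that decorrelates the
region from everything else.  This module generates such signals, computes
Pearson FC from them, and computes phase-locking value (PLV) connectivity from
the discrete analytic signal, so the central identity can be demonstrated
numerically: for unit jitters the Pearson correlation of two sinusoids at a
common frequency converges to cos(theta_c - theta_d), and with jitter mixing
to j_c * j_d * cos(theta_c - theta_d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import FCMatrix

__all__ = [
    "TimeSeriesMatrix",
    "generate_sine_signals",
    "pearson_fc",
    "analytic_signal",
    "plv",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """R regions x T samples of a real-valued signal with sampling step dt (s)."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("time series must be 2-D (regions x samples)")
        if arr.shape[1] < 4:
            raise ValueError(f"need at least 4 samples, got {arr.shape[1]}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def generate_sine_signals(
    phases: np.ndarray,
    jitters: np.ndarray,
    omega: float,
    n_samples: int,
    dt: float,
    seed: int = 0,
) -> TimeSeriesMatrix:
    """Sinusoid-plus-jitter signals whose FC realizes the single-basis model.

    Region c gets ``x_c(t) = j_c sin(omega t + theta_c) + sqrt(1 - j_c^2) e_c(t)``
    with e_c independent white Gaussian noise scaled to the sample variance of
    that region's sinusoid, so that for large T

        corr(x_c, x_d) ~= j_c * j_d * cos(theta_c - theta_d).

    The jitter mixture keeps unit (sinusoid-scale) variance and has this exact
    closed-form expected correlation, which is what makes it testable against
    the model algebra.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    jitters = np.asarray(jitters, dtype=float).ravel()
    if phases.shape != jitters.shape:
        raise ValueError("phases and jitters must have the same length")
    if jitters.min() < 0.0 or jitters.max() > 1.0:
        raise ValueError("jitters must lie in [0, 1]")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if omega * n_samples * dt < 2 * (2 * np.pi):
        raise ValueError("signal must span at least 2 full periods")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * dt
    sines = np.sin(omega * t[None, :] + phases[:, None])
    sine_sd = sines.std(axis=1, ddof=0, keepdims=True)
    noise = rng.standard_normal(sines.shape) * sine_sd
    x = jitters[:, None] * sines + np.sqrt(1.0 - jitters[:, None] ** 2) * noise
    return TimeSeriesMatrix(values=x, dt=dt)


def pearson_fc(ts: TimeSeriesMatrix) -> FCMatrix:
    """Pearson correlation matrix of the region time series."""
    x = ts.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        region = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region {region} has zero variance")
    corr = np.corrcoef(x)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(corr)


def analytic_signal(ts: TimeSeriesMatrix) -> np.ndarray:
    """Discrete analytic signal (frequency-domain Hilbert construction).

    Negative frequencies are zeroed and positive ones doubled; the real part
    equals the input up to FFT round-off and the imaginary part is the
    Hilbert transform.
    """
    return scipy.signal.hilbert(ts.values, axis=1)


def plv(ts: TimeSeriesMatrix, edge_fraction: float = 0.05) -> np.ndarray:
    """Phase-locking value matrix.

    ``PLV_cd = |mean_t exp(i (phi_c(t) - phi_d(t)))|`` with phi the analytic
    phase.  A fraction of samples at each end (default 5%) is discarded to
    avoid the FFT edge artifacts of the analytic-signal construction.
    Symmetric, unit diagonal, entries in [0, 1].
    """
    if not 0.0 <= edge_fraction < 0.5:
        raise ValueError("edge_fraction must be in [0, 0.5)")
    xa = analytic_signal(ts)
    cut = int(edge_fraction * ts.n_samples)
    if cut:
        xa = xa[:, cut:-cut]
    mag = np.abs(xa)
    if np.any(mag == 0):
        raise ValueError("zero analytic magnitude: phase undefined at some sample")
    phasor = xa / mag
    # mean of exp(i(phi_c - phi_d)) over time = (1/T) * phasor @ conj(phasor).T
    t_eff = phasor.shape[1]
    out = np.abs(phasor @ phasor.conj().T) / t_eff
    out = np.clip(0.5 * (out + out.T), 0.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out
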