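"""Nonlinear waveform features: Katz fractal dimension and entropies.

Katz fractal dimension treats the waveform as a planar curve of points
``(i * dt, x_i)``.  With total curve length ``L`` (sum of distances between
successive points), diameter ``d`` (largest distance from the first point),
and average step ``a = L / n_steps``, the dimension is

    D = log10(n) / (log10(n) + log10(d / L)),   n = L / a.

Renyi entropy of order ``alpha`` is computed on an equal-width amplitude
histogram: ``(1 / (1 - alpha)) * log(sum p_i^alpha)``; it tends to the
Shannon entropy as ``alpha -> 1``.

Wavelet entropies pool the coefficients ``s_i`` of an orthogonal discrete
wavelet decomposition and evaluate, with ``0 * log 0 := 0``:

    shannon    = -sum s_i^2 * ln(s_i^2)
    log_energy =  sum ln(s_i^2)          (zero coefficients skipped)
    norm       =  sum |s_i|^p

All entropies use natural logarithms (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pywt


@dataclass(frozen=True)
class KatzMeasures:
    L: float  # total curve length
    d: float  # diameter: max distance from the first point
    a: float  # average step length L / n_steps
    n_steps: int
    D: float  # Katz fractal dimension


def katz_measures(waveform: np.ndarray, dt: float = 1.0) -> KatzMeasures:
    """Katz curve measures of a waveform embedded as ``(i * dt, x_i)``."""
    x = np.asarray(waveform, dtype=float)
    if x.size < 3:
        raise ValueError("Katz FD requires at least 3 points")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(x.size) * dt
    steps = np.hypot(np.diff(t), np.diff(x))
    L = float(np.sum(steps))
    d = float(np.max(np.hypot(t - t[0], x - x[0])))
    if d == 0 or L == 0:
        raise ValueError("degenerate curve: all points identical")
    n_steps = x.size - 1
    a = L / n_steps
    n = L / a
    D = np.log10(n) / (np.log10(n) + np.log10(d / L))
    return KatzMeasures(L=L, d=d, a=a, n_steps=n_steps, D=float(D))


def katz_fd(waveform: np.ndarray, dt: float = 1.0) -> float:
    """Katz fractal dimension of a waveform (1.0 for a straight line)."""
    return katz_measures(waveform, dt).D


def renyi_entropy(signal: np.ndarray, alpha: float = 2.0, n_bins: int = 100) -> float:
    """Renyi entropy (nats) of the amplitude distribution.

    The distribution is an equal-width histogram with ``n_bins`` bins over
    the signal's own [min, max] range.  A constant signal (single occupied
    bin) has zero entropy.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if alpha == 1:
        raise ValueError(
            "alpha = 1 is the Shannon limit; use a value near 1 or shannon directly"
        )
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


@dataclass(frozen=True)
class WaveletEntropies:
    shannon: float
    log_energy: float
    norm: float


def coefficient_entropies(coeffs: np.ndarray, p: float = 1.1) -> WaveletEntropies:
    """Entropy functionals of a pooled coefficient vector."""
    s = np.asarray(coeffs, dtype=float)
    if p <= 0:
        raise ValueError("norm exponent p must be > 0")
    e = s**2
    pos = e[e > 0]
    shannon = float(-np.sum(pos * np.log(pos)))
    log_energy = float(np.sum(np.log(pos)))
    norm = float(np.sum(np.abs(s) ** p))
    return WaveletEntropies(shannon=shannon, log_energy=log_energy, norm=norm)


def wavelet_decompose(
    signal: np.ndarray, wavelet: str = "db4", level: int = 5
) -> np.ndarray:
    """Pooled coefficients of an orthogonal DWT (periodized boundary)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2**level:
        raise ValueError(
            f"signal of length {x.size} too short for a level-{level} decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    return np.concatenate(coeffs)


def wavelet_entropies(
    signal: np.ndarray, wavelet: str = "db4", level: int = 5, p: float = 1.1
) -> WaveletEntropies:
    """Shannon, log-energy and norm entropies of the wavelet coefficients."""
    return coefficient_entropies(wavelet_decompose(signal, wavelet, level), p=p)


def nonlinear_features(
    window: np.ndarray,
    alpha: float = 2.0,
    n_bins: int = 100,
    wavelet: str = "db4",
    level: int = 5,
    p: float = 1.1,
    dt: float = 1.0,
) -> Tuple[float, float, float, float, float]:
    """The five-feature nonlinear panel for one analysis window.

    Returns ``(katz_fd, renyi, w_shannon, w_logenergy, w_norm)``.  ``dt`` is
    the Katz embedding step; pass the sampling interval in seconds so the
    time axis (s) and amplitude axis (mV) are on comparable scales.
    """
    went = wavelet_entropies(window, wavelet=wavelet, level=level, p=p)
    return (
        katz_fd(window, dt=dt),
        renyi_entropy(window, alpha=alpha, n_bins=n_bins),
        went.shannon,
        went.log_energy,
        went.norm,
    )
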