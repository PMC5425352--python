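"""Frequency-domain HRV features from the NN tachogram.

The unevenly sampled NN series is cubic-interpolated onto a uniform 4 Hz
grid, mean-detrended, and a Welch PSD (Hann window, 150 s segments, 50%
overlap) is estimated.  Band powers are trapezoid integrals of the density
over the conventional HRV bands — ULF (<0.003 Hz), VLF (0.003-0.04), LF
(0.04-0.15), HF (0.15-0.4) — which partition total power exactly because the
integration grid is augmented with the band edges.  LF/HF is the
sympathovagal balance index.

A band whose lower edge is below 1/span of the record cannot be resolved
from that record; its power is still computed but flagged unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import interpolate, signal

from .core import NNSeries


@dataclass(frozen=True)
class BandSpec:
    ulf: Tuple[float, float] = (0.0, 0.003)
    vlf: Tuple[float, float] = (0.003, 0.04)
    lf: Tuple[float, float] = (0.04, 0.15)
    hf: Tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.ulf, *self.vlf, *self.lf, *self.hf]
        seq = [self.ulf[0], self.ulf[1], self.vlf[1], self.lf[1], self.hf[1]]
        if any(not np.isfinite(e) for e in edges) or any(np.diff(seq) <= 0):
            raise ValueError("bands must be contiguous, non-overlapping, increasing")
        if (self.ulf[1], self.vlf[1]) != (self.vlf[0], self.lf[0]) or self.lf[1] != self.hf[0]:
            raise ValueError("bands must be contiguous")

    @property
    def upper_edge(self) -> float:
        return self.hf[1]


@dataclass
class PSD:
    """One-sided power spectral density of the tachogram (ms^2 per Hz)."""

    freqs: np.ndarray
    density: np.ndarray
    span: float  # tachogram span in s (sets the resolvable lower edge)

    def __post_init__(self) -> None:
        if self.freqs.shape != self.density.shape:
            raise ValueError("frequency grid / density shape mismatch")


@dataclass(frozen=True)
class SpectralFeatures:
    total_power: float  # ms^2, integral over (0, upper_edge]
    ulf_power: float
    vlf_power: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float  # NaN marks undefined (hf_power == 0)
    unresolved_bands: Tuple[str, ...] = field(default=())


def tachogram_psd(
    nn: NNSeries,
    resample_rate: float = 4.0,
    segment_seconds: float = 150.0,
    min_intervals: int = 8,
    min_span: float = 30.0,
    nyquist_edge: float = 0.4,
) -> PSD:
    """Welch PSD of the NN tachogram.

    The accepted intervals, located at the time of their ending beat, are
    cubic-interpolated to ``resample_rate`` (default 4 Hz) and
    mean-detrended before the Welch estimate.
    """
    if resample_rate <= 2 * nyquist_edge:
        raise ValueError(
            f"resample_rate {resample_rate} Hz must exceed twice the upper band "
            f"edge ({nyquist_edge} Hz)"
        )
    times = nn.beat_times[1:][nn.accepted]
    values = nn.accepted_nn
    if values.size < min_intervals:
        raise ValueError(f"need >= {min_intervals} accepted NN intervals")
    span = float(times[-1] - times[0])
    if span < min_span:
        raise ValueError(f"tachogram span {span:.1f} s shorter than {min_span} s")

    grid = np.arange(times[0], times[-1], 1.0 / resample_rate)
    tach = interpolate.interp1d(times, values, kind="cubic")(grid)
    tach = tach - np.mean(tach)

    nperseg = min(len(tach), int(round(segment_seconds * resample_rate)))
    freqs, density = signal.welch(
        tach,
        fs=resample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PSD(freqs=freqs, density=density, span=span)


def _band_integral(freqs: np.ndarray, density: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of the piecewise-linear density over [lo, hi]."""
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, density)
    return float(np.trapezoid(vals, grid))


def band_powers(psd: PSD, bands: BandSpec = BandSpec()) -> SpectralFeatures:
    """Integrate the PSD over the HRV bands; ratio computed last.

    The integration grid is augmented with the exact band edges, so the four
    band powers partition the total exactly.
    """
    f, d = psd.freqs, psd.density
    if f[-1] < bands.upper_edge:
        raise ValueError("PSD grid does not cover the HF band")
    ulf = _band_integral(f, d, *bands.ulf)
    vlf = _band_integral(f, d, *bands.vlf)
    lf = _band_integral(f, d, *bands.lf)
    hf = _band_integral(f, d, *bands.hf)
    total = _band_integral(f, d, bands.ulf[0], bands.upper_edge)
    ratio = lf / hf if hf > 0 else float("nan")
    # a band is unresolved when the record is shorter than one cycle of its
    # slowest estimable frequency (for ULF, whose lower edge is 0, the band
    # only has content below its upper edge)
    unresolved = tuple(
        name
        for name, (lo, hi_) in (("ulf", bands.ulf), ("vlf", bands.vlf),
                                ("lf", bands.lf), ("hf", bands.hf))
        if psd.span < 1.0 / (lo if lo > 0 else hi_)
    )
    return SpectralFeatures(
        total_power=total,
        ulf_power=ulf,
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=ratio,
        unresolved_bands=unresolved,
    )


def spectral_features(nn: NNSeries, bands: BandSpec = BandSpec(), **psd_kwargs) -> SpectralFeatures:
    """Convenience: PSD estimation followed by band integration."""
    return band_powers(tachogram_psd(nn, **psd_kwargs), bands)
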