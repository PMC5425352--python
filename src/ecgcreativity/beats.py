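"""R-peak detection and NN-series construction.

A Pan-Tompkins-style detector: band-pass the QRS energy band, differentiate,
square, integrate over a moving window, pick peaks above an adaptive
(scale-proportional) threshold with a 200 ms refractory period, then refine
each detection to the argmax of the input signal within +-50 ms.  The
detector is invariant to positive rescaling of the signal.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import ECGRecord, NNSeries

REFRACTORY_S = 0.2
REFINE_HALF_S = 0.05
_INTEG_WIN_S = 0.15
_QRS_BAND = (5.0, 15.0)


def detect_r_peaks(record: ECGRecord, threshold_frac: float = 0.25) -> np.ndarray:
    """Detect R-peak times (s) in a filtered single-lead ECG.

    Returns an empty array for a flat (zero-variance) signal.  The adaptive
    threshold is ``threshold_frac`` times a high quantile of the integrated
    detection function, which makes detection amplitude-scale invariant.
    """
    fs = record.sampling_rate
    x = record.samples
    if len(x) < 2 * fs:
        raise ValueError("record shorter than 2 s")
    if np.ptp(x) == 0:
        return np.array([])

    sos = sps.butter(2, _QRS_BAND, btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    det = np.gradient(band) ** 2
    win = max(int(round(_INTEG_WIN_S * fs)), 1)
    integ = np.convolve(det, np.ones(win) / win, mode="same")

    thr = threshold_frac * np.quantile(integ, 0.995)
    if thr <= 0:
        return np.array([])
    peaks, _ = sps.find_peaks(
        integ, height=thr, distance=max(int(round(REFRACTORY_S * fs)), 1)
    )
    if peaks.size == 0:
        return np.array([])

    # refine to the raw-signal argmax within +-50 ms
    half = int(round(REFINE_HALF_S * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)

    # enforce the refractory period post-refinement, keeping the taller peak
    keep: list[int] = []
    min_gap = REFRACTORY_S * fs
    for p in refined:
        if keep and p - keep[-1] < min_gap:
            if x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep) / fs


def to_nn_series(beat_times: np.ndarray, sampling_rate: float | None = None) -> NNSeries:
    """Successive beat-time differences in ms, with the physiologic gate.

    Intervals outside 250-3000 ms are flagged abnormal (``accepted=False``)
    and excluded from NN statistics downstream.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValueError("need at least 2 beat times to form NN intervals")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return NNSeries(beat_times=beat_times, sampling_rate=sampling_rate)
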