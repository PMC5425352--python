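"""Time-domain HRV feature panel.

Statistics of the accepted NN intervals: mean, SD (SDNN), RMSSD, NN50,
pNN50, min/max/median/range and mean heart rate.  An amplitude variant
(order statistics of raw window samples) is provided as an optional
alternative reading of the "mean of the ECG signal" family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NNSeries

NN50_THRESHOLD_MS = 50.0


@dataclass(frozen=True)
class TimeFeatures:
    mean_nn: float  # ms
    mean_hr: float  # beats/min, 60000 / mean_nn
    sdnn: float  # ms
    rmssd: float  # ms
    nn50: int
    pnn50: float  # percent of successive differences
    min_nn: float
    max_nn: float
    median_nn: float
    range_nn: float


def time_domain_features(nn: NNSeries, ddof: int = 1) -> TimeFeatures:
    """Compute the time-domain panel over the accepted NN intervals.

    ``ddof=1`` gives the sample SD (default); set 0 for population SD.
    RMSSD / NN50 / pNN50 are computed over successive differences of the
    accepted interval sequence.
    """
    x = nn.accepted_nn
    if x.size < 2:
        raise ValueError(
            f"mean/SDNN require >= 2 accepted NN intervals, got {x.size}"
        )
    diffs = np.diff(x)
    nn50 = int(np.sum(np.abs(diffs) > NN50_THRESHOLD_MS))
    mean_nn = float(np.mean(x))
    return TimeFeatures(
        mean_nn=mean_nn,
        mean_hr=60000.0 / mean_nn,
        sdnn=float(np.std(x, ddof=ddof)),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        nn50=nn50,
        pnn50=100.0 * nn50 / diffs.size,
        min_nn=float(np.min(x)),
        max_nn=float(np.max(x)),
        median_nn=float(np.median(x)),
        range_nn=float(np.max(x) - np.min(x)),
    )


@dataclass(frozen=True)
class AmplitudeFeatures:
    mean: float
    min: float
    max: float
    median: float
    rms: float


def amplitude_features(window: np.ndarray) -> AmplitudeFeatures:
    """Order statistics and moments of raw sample values (mV) in a window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return AmplitudeFeatures(
        mean=float(np.mean(window)),
        min=float(np.min(window)),
        max=float(np.max(window)),
        median=float(np.median(window)),
        rms=float(np.sqrt(np.mean(window**2))),
    )
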