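import numpy as np
import pytest

from ecgcreativity.core import NNSeries
from ecgcreativity.ecgsim import SimConfig, simulate_rr_tachogram, synthesize_ecg


def nn_from_intervals(intervals_ms) -> NNSeries:
    """Build an NNSeries whose interval sequence equals the given values."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    beat_times = np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
    return NNSeries(beat_times=beat_times, nn_intervals=intervals_ms)


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 60 bpm, 60 s synthetic ECG with known beat times."""
    nn = simulate_rr_tachogram(60, 0, 2.0, 60)
    cfg = SimConfig(duration=60, powerline_amp=0, baseline_amp=0,
                    broadband_sd=0, seed=3)
    return synthesize_ecg(nn, cfg), nn


@pytest.fixture(scope="session")
def study_table():
    """Window-level feature table of a 20-subject synthetic cohort."""
    from ecgcreativity.ecgsim import simulate_cohort
    from ecgcreativity.pipeline import extract_features

    records = simulate_cohort(20, seed=11)
    return extract_features(records)
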