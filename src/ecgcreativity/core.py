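"""Core containers shared across the pipeline.

The analysis substrate is a single-lead ECG trace (`ECGRecord`) recorded in
one of four conditions — rest or one of the three figural creativity tasks —
and the normal-to-normal (NN) inter-beat interval series (`NNSeries`)
derived from it, on which all HRV features are computed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# NN intervals outside this physiologic gate are flagged abnormal and
# excluded from NN statistics (guards against detector errors / ectopy).
NN_GATE_MS = (250.0, 3000.0)


class Condition(str, enum.Enum):
    """Recording condition: rest or one of the three creativity tasks."""

    REST = "rest"
    TASK1 = "task1"
    TASK2 = "task2"
    TASK3 = "task3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONDITIONS = (Condition.REST, Condition.TASK1, Condition.TASK2, Condition.TASK3)

#: The six pairwise contrasts reported by the statistics and classifiers.
CONDITION_PAIRS = (
    (Condition.REST, Condition.TASK1),
    (Condition.REST, Condition.TASK2),
    (Condition.REST, Condition.TASK3),
    (Condition.TASK1, Condition.TASK2),
    (Condition.TASK1, Condition.TASK3),
    (Condition.TASK2, Condition.TASK3),
)


@dataclass
class ECGRecord:
    """One labeled single-lead ECG trace.

    Parameters
    ----------
    samples : ndarray
        Signal in mV.
    sampling_rate : float
        Samples per second (Hz).
    condition : Condition
        Recording condition label.
    subject_id : str
        Opaque subject identifier.
    creativity_score : float, optional
        Normalized creativity score on a 0-100 scale, if available.
    """

    samples: np.ndarray
    sampling_rate: float
    condition: Condition = Condition.REST
    subject_id: str = "S000"
    creativity_score: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECGRecord.samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECGRecord.samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.condition = Condition(self.condition)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of this record with new samples and identical metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class NNSeries:
    """Beat times and the normal-to-normal interval sequence.

    ``nn_intervals[i]`` is the interval ending at ``beat_times[i + 1]`` in
    milliseconds.  Intervals outside the physiologic gate (250-3000 ms) are
    kept in the sequence but flagged ``accepted=False`` and excluded from
    NN statistics downstream.
    """

    beat_times: np.ndarray  # seconds, strictly increasing
    nn_intervals: np.ndarray = field(default=None)  # ms
    accepted: np.ndarray = field(default=None)  # bool per interval
    sampling_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size < 2:
            raise ValueError("NNSeries requires at least 2 beat times")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        expected = np.diff(self.beat_times) * 1000.0
        if self.nn_intervals is None:
            self.nn_intervals = expected
        else:
            self.nn_intervals = np.asarray(self.nn_intervals, dtype=float)
            if not np.allclose(self.nn_intervals, expected, rtol=0, atol=1e-6):
                raise ValueError("nn_intervals inconsistent with beat_times")
        if self.accepted is None:
            lo, hi = NN_GATE_MS
            self.accepted = (self.nn_intervals >= lo) & (self.nn_intervals <= hi)
        else:
            self.accepted = np.asarray(self.accepted, dtype=bool)
            if self.accepted.shape != self.nn_intervals.shape:
                raise ValueError("accepted mask shape mismatch")

    @property
    def accepted_nn(self) -> np.ndarray:
        """NN intervals inside the physiologic gate, in ms."""
        return self.nn_intervals[self.accepted]

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)
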