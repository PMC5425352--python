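"""Synthetic multi-condition ECG cohorts.

Generates lead-II-like ECG with controllable mean heart rate, HRV spectral
structure (LF and HF band power with a target LF/HF ratio), 50 Hz powerline
contamination, baseline wander and broadband noise, plus a per-subject
creativity score on a 0-100 scale.  The RR tachogram is produced by a
modulated-interval model — mean interval plus narrowband LF and HF tone
mixtures plus white jitter, scaled to a target SDNN — which gives analytic
control over the band-power ratio.  The waveform is rendered as one fixed
P-QRS-T template (sum of Gaussian bumps) per beat.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .core import CONDITIONS, Condition, ECGRecord, NNSeries

# LF / HF HRV bands (Hz) used to place modulation tones.
_LF_BAND = (0.04, 0.15)
_HF_BAND = (0.15, 0.4)

# P-QRS-T template: (time offset from R in s, amplitude in mV, width in s).
PQRST_TEMPLATE = (
    (-0.18, 0.12, 0.022),   # P
    (-0.025, -0.10, 0.010),  # Q
    (0.0, 1.00, 0.012),      # R
    (0.025, -0.15, 0.010),   # S
    (0.26, 0.35, 0.050),     # T
)

#: Shortest inter-beat interval (s) the template renderer accepts; below
#: this, successive QRS cores would merge.
MIN_RENDER_INTERVAL_S = 0.30


@dataclass(frozen=True)
class SimConfig:
    """Per-record simulation parameters.

    ``sdnn_target`` (ms) sets total interval variability; ``lf_hf_target``
    sets the ratio of LF to HF modulation power.  Noise terms are in mV.
    """

    sampling_rate: float = 1000.0
    duration: float = 126.0
    mean_hr: float = 65.0
    sdnn_target: float = 40.0
    lf_hf_target: float = 1.5
    lf_center: float = 0.1
    hf_center: float = 0.25
    powerline_amp: float = 0.05
    baseline_amp: float = 0.10
    broadband_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 50.0:
            raise ValueError("sampling_rate must exceed twice the powerline frequency")
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValueError("mean_hr must lie in [30, 220] beats/min")
        if self.sdnn_target < 0:
            raise ValueError("sdnn_target must be >= 0")
        if self.lf_hf_target <= 0:
            raise ValueError("lf_hf_target must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def simulate_rr_tachogram(
    mean_hr: float,
    sdnn_target: float,
    lf_hf_target: float,
    duration: float,
    seed: int = 0,
    n_tones: int = 24,
    jitter_frac: float = 0.05,
    start_offset: float = 0.4,
) -> NNSeries:
    """Simulate beat times whose NN series has the requested HRV structure.

    The instantaneous interval is ``60000/mean_hr`` ms plus a sum of
    random-phase sinusoids confined to the LF (0.04-0.15 Hz) and HF
    (0.15-0.4 Hz) bands, with band variances in the ratio ``lf_hf_target``,
    plus white per-beat jitter carrying ``jitter_frac`` of the variance.
    Total modulation variance is scaled so the interval SD approaches
    ``sdnn_target``.  Deterministic given ``seed``.
    """
    if mean_hr <= 0:
        raise ValueError("mean_hr must be positive")
    if lf_hf_target <= 0:
        raise ValueError("lf_hf_target must be > 0")
    if sdnn_target < 0:
        raise ValueError("sdnn_target must be >= 0")
    mean_interval_s = 60.0 / mean_hr
    if duration < 3 * mean_interval_s:
        raise ValueError(
            f"duration {duration} s too short for 3 beats at {mean_hr} bpm"
        )
    mean_nn_ms = 60000.0 / mean_hr

    # the first beat is placed at start_offset so a full P-QRS-T template
    # fits inside the rendered record
    if sdnn_target == 0:
        n = int(np.floor((duration - start_offset) / mean_interval_s)) + 1
        beat_times = start_offset + np.arange(n) * mean_interval_s
        return NNSeries(beat_times=beat_times,
                        nn_intervals=np.full(n - 1, mean_nn_ms))

    rng = np.random.default_rng(seed)
    var_total = sdnn_target**2
    var_jitter = jitter_frac * var_total
    var_bands = var_total - var_jitter
    r = lf_hf_target
    var_lf = var_bands * r / (1.0 + r)
    var_hf = var_bands / (1.0 + r)

    def band_tones(band: Tuple[float, float], var: float):
        lo, hi = band
        margin = 0.1 * (hi - lo)
        freqs = rng.uniform(lo + margin, hi - margin, size=n_tones)
        phases = rng.uniform(0, 2 * np.pi, size=n_tones)
        amp = np.sqrt(2.0 * var / n_tones)
        return freqs, phases, amp

    f_lf, p_lf, a_lf = band_tones(_LF_BAND, var_lf)
    f_hf, p_hf, a_hf = band_tones(_HF_BAND, var_hf)
    jitter_sd = np.sqrt(var_jitter)

    def modulation(t: float) -> float:
        return float(
            a_lf * np.sum(np.sin(2 * np.pi * f_lf * t + p_lf))
            + a_hf * np.sum(np.sin(2 * np.pi * f_hf * t + p_hf))
        )

    beat_times = [start_offset]
    floor_ms = 0.25 * mean_nn_ms
    t = start_offset
    while True:
        interval_ms = mean_nn_ms + modulation(t) + jitter_sd * rng.standard_normal()
        interval_ms = max(interval_ms, floor_ms)
        t_next = t + interval_ms / 1000.0
        if t_next > duration:
            break
        beat_times.append(t_next)
        t = t_next
    if len(beat_times) < 3:
        raise ValueError("duration too short for 3 beats")
    return NNSeries(beat_times=np.asarray(beat_times))


def _render_template(beat_times: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Superpose one P-QRS-T Gaussian template at each beat time."""
    half = 0.5  # template support rendered +-0.5 s around R
    k = int(round(half * fs))
    rel = np.arange(-k, k + 1) / fs
    template = np.zeros_like(rel)
    for offset, amp, width in PQRST_TEMPLATE:
        template += amp * np.exp(-((rel - offset) ** 2) / (2 * width**2))
    out = np.zeros(n_samples)
    for bt in beat_times:
        center = int(round(bt * fs))
        lo, hi = center - k, center + k + 1
        s_lo, s_hi = max(lo, 0), min(hi, n_samples)
        if s_lo >= s_hi:
            continue
        out[s_lo:s_hi] += template[s_lo - lo : s_hi - lo]
    return out


def synthesize_ecg(
    nn: NNSeries,
    config: SimConfig,
    condition: Condition = Condition.REST,
    subject_id: str = "S000",
    creativity_score: Optional[float] = None,
) -> ECGRecord:
    """Render an ECG waveform from beat times.

    One fixed Gaussian P-QRS-T template per beat (R amplitude ~1 mV), plus a
    50 Hz powerline sinusoid, slow (<0.5 Hz) baseline wander, and white
    noise.  Deterministic given ``config.seed``.
    """
    if nn.beat_times.size == 0:
        raise ValueError("empty NN series")
    min_interval = float(np.min(np.diff(nn.beat_times)))
    if min_interval < MIN_RENDER_INTERVAL_S:
        raise ValueError(
            f"beat interval {min_interval:.3f} s shorter than template support "
            f"({MIN_RENDER_INTERVAL_S} s)"
        )
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    t = np.arange(n_samples) / fs
    x = _render_template(nn.beat_times, fs, n_samples)

    rng = np.random.default_rng(config.seed)
    if config.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += config.powerline_amp * np.sin(2 * np.pi * 50.0 * t + phase)
    if config.baseline_amp > 0:
        # three slow drift components below 0.5 Hz
        for _ in range(3):
            f = rng.uniform(0.05, 0.45)
            ph = rng.uniform(0, 2 * np.pi)
            x += (config.baseline_amp / 3.0) * np.sin(2 * np.pi * f * t + ph)
    if config.broadband_sd > 0:
        x += config.broadband_sd * rng.standard_normal(n_samples)

    return ECGRecord(
        samples=x,
        sampling_rate=fs,
        condition=condition,
        subject_id=subject_id,
        creativity_score=creativity_score,
    )


#: Default per-condition presets.  Synthetic choices, not measured values:
#: they reproduce the qualitative direction of change (heart rate and
#: sympathovagal balance rise from rest into task 1, then relax through
#: tasks 2-3; overall HRV slightly larger during tasks).
DEFAULT_PRESETS: Dict[Condition, SimConfig] = {
    Condition.REST: SimConfig(mean_hr=65.0, sdnn_target=40.0, lf_hf_target=1.5, seed=0),
    Condition.TASK1: SimConfig(mean_hr=75.0, sdnn_target=55.0, lf_hf_target=3.0, seed=0),
    Condition.TASK2: SimConfig(mean_hr=72.0, sdnn_target=50.0, lf_hf_target=2.2, seed=0),
    Condition.TASK3: SimConfig(mean_hr=70.0, sdnn_target=48.0, lf_hf_target=2.0, seed=0),
}

ScoreDistribution = Union[str, Tuple[float, float]]


def _draw_scores(
    n: int, score_distribution: ScoreDistribution, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(score_distribution, str):
        if score_distribution != "bimodal":
            raise ValueError(f"unknown score distribution {score_distribution!r}")
        # half low / half high creators, so both groups are populated
        lows = rng.normal(20.0, 8.0, size=n)
        highs = rng.normal(80.0, 8.0, size=n)
        pick_high = rng.random(n) < 0.5
        scores = np.where(pick_high, highs, lows)
    else:
        mean, sd = score_distribution
        scores = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    return np.clip(scores, 0.0, 100.0)


def simulate_cohort(
    n_subjects: int,
    condition_presets: Optional[Dict[Condition, SimConfig]] = None,
    score_distribution: ScoreDistribution = "bimodal",
    seed: int = 0,
    hr_effect: float = 6.0,
    lfhf_effect: float = 0.4,
    subject_jitter: bool = True,
) -> list[ECGRecord]:
    """Simulate one ECG record per subject x condition.

    Each subject receives a creativity score (clipped to [0, 100]) and small
    random effects on the condition presets so subjects differ.  During the
    task conditions the autonomic response scales with the subject's
    creativity: a subject ``m = (score - 50)/50`` above/below the midpoint
    gets ``hr_effect * m`` bpm extra heart rate and a ``(1 + lfhf_effect*m)``
    multiplier on LF/HF, so high- and low-creativity groups are separable
    from task-condition features.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    presets = dict(DEFAULT_PRESETS if condition_presets is None else condition_presets)
    missing = [c.value for c in CONDITIONS if c not in presets]
    if missing:
        raise ValueError(f"missing condition presets: {missing}")

    rng = np.random.default_rng(seed)
    scores = _draw_scores(n_subjects, score_distribution, rng)
    records: list[ECGRecord] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        score = float(scores[i])
        m = (score - 50.0) / 50.0
        hr_offset = rng.normal(0.0, 1.5) if subject_jitter else 0.0
        sdnn_scale = float(np.exp(rng.normal(0.0, 0.08))) if subject_jitter else 1.0
        lfhf_scale = float(np.exp(rng.normal(0.0, 0.08))) if subject_jitter else 1.0
        for cond in CONDITIONS:
            base = presets[cond]
            mean_hr = base.mean_hr + hr_offset
            lf_hf = base.lf_hf_target * lfhf_scale
            if cond is not Condition.REST:
                mean_hr += hr_effect * m
                lf_hf *= 1.0 + lfhf_effect * m
            cfg = replace(
                base,
                mean_hr=float(np.clip(mean_hr, 40.0, 110.0)),
                sdnn_target=base.sdnn_target * sdnn_scale,
                lf_hf_target=max(lf_hf, 0.1),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            nn = simulate_rr_tachogram(
                cfg.mean_hr, cfg.sdnn_target, cfg.lf_hf_target, cfg.duration,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            records.append(
                synthesize_ecg(nn, cfg, condition=cond, subject_id=sid,
                               creativity_score=score)
            )
    return records


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named pipeline stage (< 2**31)."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)
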