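"""End-to-end orchestration of the synthetic creativity-state study.

simulate -> preprocess -> beat detection -> feature extraction ->
pairwise Wilcoxon tables -> condition classification -> creativity-group
classification.  Every stage derives its own sub-seed from a single master
seed, so the whole study is reproducible from one integer.

The feature table holds one row per 5 s analysis window with the 19-feature
panel: 14 linear features (time-domain NN statistics plus the spectral band
powers and LF/HF) and 5 nonlinear features (Katz FD, Renyi entropy, and the
three wavelet entropies).  Spectral features are estimated once per
two-minute analysis segment — the HRV bands are not resolvable from a 5 s
window — and broadcast to that segment's windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .beats import detect_r_peaks, to_nn_series
from .classify import ClassifierReport, SplitSpec, repeated_evaluation
from .core import CONDITION_PAIRS, CONDITIONS, Condition, ECGRecord, NNSeries
from .ecgsim import DEFAULT_PRESETS, SimConfig, simulate_cohort, stage_seed
from .features_freq import BandSpec, spectral_features
from .features_nonlinear import nonlinear_features
from .features_time import time_domain_features
from .preprocess import FilterSpec, SegmentationSpec, preprocess_record, trim_and_window
from .stats_compare import PValueMatrix, pairwise_wilcoxon, significance_table

LINEAR_FEATURES = [
    "mean_nn", "rmssd", "sdnn", "min_nn", "max_nn", "median_nn",
    "nn50", "pnn50",
    "total_power", "ulf_power", "vlf_power", "lf_power", "hf_power",
    "lf_hf_ratio",
]
NONLINEAR_FEATURES = ["katz_fd", "renyi", "w_shannon", "w_logenergy", "w_norm"]
#: The 19-feature panel: 14 linear + 5 nonlinear.
FEATURE_COLUMNS = LINEAR_FEATURES + NONLINEAR_FEATURES

META_COLUMNS = ["subject_id", "condition", "window_start", "creativity_score", "group"]

HIGH_THRESHOLD = 70.0
LOW_THRESHOLD = 30.0


def normalize_scores(raw_totals: Sequence[float]) -> np.ndarray:
    """Map raw creativity totals onto [0, 100].

    Scores are z-transformed across subjects and the z-scores are then
    min-max mapped onto [0, 100]; the map is order-preserving, the minimum
    maps to 0 and the maximum to 100.
    """
    totals = np.asarray(raw_totals, dtype=float)
    if totals.size < 2:
        raise ValueError("need at least 2 subjects to normalize scores")
    if not np.all(np.isfinite(totals)):
        raise ValueError("raw totals must be finite")
    sd = np.std(totals)
    if sd == 0:
        raise ValueError("zero variance across subjects; scores cannot be normalized")
    z = (totals - np.mean(totals)) / sd
    return 100.0 * ((z - z.min()) / (z.max() - z.min()))


def assign_groups(scores: Sequence[float]) -> np.ndarray:
    """'high' (> 70), 'low' (< 30) or 'excluded' per normalized score."""
    scores = np.asarray(scores, dtype=float)
    out = np.where(scores > HIGH_THRESHOLD, "high",
                   np.where(scores < LOW_THRESHOLD, "low", "excluded"))
    return out.astype(object)


def extract_features(
    records: Sequence[ECGRecord],
    filter_spec: FilterSpec = FilterSpec(),
    segmentation: SegmentationSpec = SegmentationSpec(),
    bands: BandSpec = BandSpec(),
    min_window_beats: int = 4,
) -> pd.DataFrame:
    """Build the window-level 19-feature table from raw ECG records.

    Each record is filtered, trimmed and windowed; R peaks are detected on
    the full analysis segment; time-domain features are computed from the
    NN intervals ending inside each window, nonlinear features from the
    window's raw samples, and spectral features once per segment (broadcast
    to its windows).  Windows with fewer than ``min_window_beats`` beats are
    dropped, as are windows with any non-finite feature.
    """
    rows: List[dict] = []
    for rec in records:
        filtered = preprocess_record(rec, filter_spec)
        wrec = trim_and_window(filtered, segmentation)
        seg_rec = ECGRecord(
            samples=wrec.segment, sampling_rate=wrec.sampling_rate,
            condition=wrec.condition, subject_id=wrec.subject_id,
            creativity_score=wrec.creativity_score,
        )
        beat_times = detect_r_peaks(seg_rec)
        if beat_times.size < 2:
            continue
        nn = to_nn_series(beat_times, sampling_rate=wrec.sampling_rate)
        spec_feats = spectral_features(nn, bands)
        # interval i ends at beat_times[i+1]; locate it in a window
        end_times = nn.beat_times[1:] + wrec.segment_start
        window_len = wrec.windows.shape[1] / wrec.sampling_rate
        for w in range(wrec.n_windows):
            t0 = wrec.start_times[w]
            in_win = (end_times >= t0) & (end_times < t0 + window_len)
            mask = in_win & nn.accepted
            ivals = nn.nn_intervals[mask]
            if ivals.size < min_window_beats - 1:
                continue
            # rebuild a contiguous beat-time axis from the window's intervals
            sub_times = np.concatenate(([0.0], np.cumsum(ivals) / 1000.0))
            try:
                tf = time_domain_features(NNSeries(beat_times=sub_times))
            except ValueError:
                continue
            katz, renyi, w_sh, w_le, w_no = nonlinear_features(
                wrec.windows[w], dt=1.0 / wrec.sampling_rate)
            row = {
                "subject_id": wrec.subject_id,
                "condition": wrec.condition.value,
                "window_start": float(t0),
                "creativity_score": wrec.creativity_score,
                "mean_nn": tf.mean_nn, "rmssd": tf.rmssd, "sdnn": tf.sdnn,
                "min_nn": tf.min_nn, "max_nn": tf.max_nn,
                "median_nn": tf.median_nn,
                "nn50": tf.nn50, "pnn50": tf.pnn50,
                "total_power": spec_feats.total_power,
                "ulf_power": spec_feats.ulf_power,
                "vlf_power": spec_feats.vlf_power,
                "lf_power": spec_feats.lf_power,
                "hf_power": spec_feats.hf_power,
                "lf_hf_ratio": spec_feats.lf_hf_ratio,
                "katz_fd": katz, "renyi": renyi,
                "w_shannon": w_sh, "w_logenergy": w_le, "w_norm": w_no,
            }
            rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    finite = np.all(np.isfinite(table[FEATURE_COLUMNS].to_numpy(dtype=float)), axis=1)
    table = table.loc[finite].reset_index(drop=True)
    table["group"] = assign_groups(table["creativity_score"].fillna(50.0).to_numpy())
    return table


@dataclass
class StudyConfig:
    n_subjects: int = 20
    seed: int = 0
    n_runs: int = 20
    score_distribution: object = "bimodal"
    presets: Dict[Condition, SimConfig] = field(
        default_factory=lambda: dict(DEFAULT_PRESETS))
    alpha: float = 0.05
    run_anfis: bool = True
    anfis_epochs: int = 30
    anfis_rules: int = 6
    svm_C: float = 1.0


@dataclass
class StudyResult:
    feature_table: pd.DataFrame
    linear_pvalues: PValueMatrix
    nonlinear_pvalues: PValueMatrix
    condition_reports: Dict[Tuple[str, str, str], ClassifierReport]
    group_reports: Dict[Tuple[str, str], object]
    config: StudyConfig


def _subset_xy(
    table: pd.DataFrame, a: Condition, b: Condition, features: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    sub = table[table["condition"].isin([a.value, b.value])]
    return sub[features].to_numpy(dtype=float), sub["condition"].to_numpy()


def classify_pair(
    table: pd.DataFrame,
    pair: Tuple[Condition, Condition],
    features: Sequence[str],
    classifier: str = "svm",
    split: SplitSpec = SplitSpec(),
    **params,
) -> ClassifierReport:
    """Repeated-split report for one condition pair on a feature subset."""
    X, y = _subset_xy(table, pair[0], pair[1], features)
    return repeated_evaluation(
        X, y, split, classifier=classifier,
        positive_label=pair[1].value, feature_names=list(features), **params,
    )


def classify_groups(
    table: pd.DataFrame,
    condition: Condition,
    features: Sequence[str],
    classifier: str = "svm",
    split: SplitSpec = SplitSpec(),
    **params,
):
    """High-vs-low creativity classification within one task condition.

    Returns a ClassifierReport, or the string ``"insufficient groups"``
    when either group has fewer than two windows.
    """
    sub = table[(table["condition"] == condition.value)
                & (table["group"].isin(["high", "low"]))]
    counts = sub["group"].value_counts()
    if counts.get("high", 0) < 2 or counts.get("low", 0) < 2:
        return "insufficient groups"
    X = sub[features].to_numpy(dtype=float)
    y = sub["group"].to_numpy()
    return repeated_evaluation(
        X, y, split, classifier=classifier, positive_label="high",
        feature_names=list(features), **params,
    )


def run_study(config: StudyConfig = StudyConfig(), out_dir: Optional[Path] = None) -> StudyResult:
    """Execute the full synthetic study and optionally write all artifacts."""
    records = simulate_cohort(
        config.n_subjects,
        condition_presets=config.presets,
        score_distribution=config.score_distribution,
        seed=stage_seed(config.seed, "simulate"),
    )
    table = extract_features(records)
    if table.empty:
        raise RuntimeError("feature extraction produced no rows")

    lin_p = pairwise_wilcoxon(table, LINEAR_FEATURES, alpha=config.alpha)
    non_p = pairwise_wilcoxon(table, NONLINEAR_FEATURES, alpha=config.alpha)

    split = SplitSpec(n_runs=config.n_runs, seed=stage_seed(config.seed, "classify"))
    condition_reports: Dict[Tuple[str, str, str], ClassifierReport] = {}
    for pair in CONDITION_PAIRS:
        key = f"{pair[0].value}_vs_{pair[1].value}"
        condition_reports[("svm", "linear", key)] = classify_pair(
            table, pair, LINEAR_FEATURES, "svm", split, C=config.svm_C)
        condition_reports[("svm", "nonlinear", key)] = classify_pair(
            table, pair, NONLINEAR_FEATURES, "svm", split, C=config.svm_C)
        if config.run_anfis:
            condition_reports[("anfis", "linear", key)] = classify_pair(
                table, pair, LINEAR_FEATURES, "anfis", split,
                n_epochs=config.anfis_epochs, n_rules=config.anfis_rules)
            condition_reports[("anfis", "nonlinear", key)] = classify_pair(
                table, pair, NONLINEAR_FEATURES, "anfis", split,
                n_epochs=config.anfis_epochs, n_rules=config.anfis_rules)

    group_reports: Dict[Tuple[str, str], object] = {}
    for cond in (Condition.TASK1, Condition.TASK2, Condition.TASK3):
        group_reports[("linear", cond.value)] = classify_groups(
            table, cond, LINEAR_FEATURES, "svm", split, C=config.svm_C)
        group_reports[("nonlinear", cond.value)] = classify_groups(
            table, cond, NONLINEAR_FEATURES, "svm", split, C=config.svm_C)

    result = StudyResult(
        feature_table=table,
        linear_pvalues=lin_p,
        nonlinear_pvalues=non_p,
        condition_reports=condition_reports,
        group_reports=group_reports,
        config=config,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _report_frame(reports: Dict, key_names: Sequence[str]) -> pd.DataFrame:
    rows = []
    for key, rep in reports.items():
        row = dict(zip(key_names, key))
        if isinstance(rep, ClassifierReport):
            row.update(rep.to_dict())
        else:
            row["note"] = str(rep)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_artifacts(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(out_dir / "feature_table.csv", index=False)
    significance_table(result.linear_pvalues).to_csv(out_dir / "pvalues_linear.csv")
    significance_table(result.nonlinear_pvalues).to_csv(out_dir / "pvalues_nonlinear.csv")
    _report_frame(result.condition_reports, ["classifier", "features", "pair"]).to_csv(
        out_dir / "condition_classification.csv", index=False)
    _report_frame(result.group_reports, ["features", "task"]).to_csv(
        out_dir / "group_classification.csv", index=False)
    cfg = result.config
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_runs": cfg.n_runs,
        "alpha": cfg.alpha,
        "feature_columns": FEATURE_COLUMNS,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
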