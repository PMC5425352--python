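"""Plain-text persistence for records, beats and feature tables.

A record is stored as a one-column CSV of mV samples next to a JSON sidecar
holding the sampling metadata; beat annotations as a two-column CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Condition, ECGRecord, NNSeries


def record_basename(record: ECGRecord) -> str:
    return f"{record.subject_id}_{record.condition.value}"


def write_record(record: ECGRecord, out_dir: Path) -> Path:
    """Write samples CSV plus JSON metadata sidecar; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = record_basename(record)
    csv_path = out_dir / f"{base}.csv"
    pd.DataFrame({"ecg_mv": record.samples}).to_csv(csv_path, index=False)
    meta = {
        "sampling_rate": record.sampling_rate,
        "condition": record.condition.value,
        "subject_id": record.subject_id,
        "creativity_score": record.creativity_score,
    }
    (out_dir / f"{base}.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_record(csv_path: Path) -> ECGRecord:
    """Read a record written by :func:`write_record`."""
    csv_path = Path(csv_path)
    samples = pd.read_csv(csv_path)["ecg_mv"].to_numpy(dtype=float)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ECGRecord(
        samples=samples,
        sampling_rate=meta["sampling_rate"],
        condition=Condition(meta["condition"]),
        subject_id=meta["subject_id"],
        creativity_score=meta.get("creativity_score"),
    )


def read_cohort(in_dir: Path) -> list[ECGRecord]:
    """Read every record CSV (with sidecar) in a directory."""
    records = [read_record(p) for p in sorted(Path(in_dir).glob("*.csv"))
               if p.with_suffix(".json").exists()]
    if not records:
        raise FileNotFoundError(f"no record CSV/JSON pairs in {in_dir}")
    return records


def write_beats(nn: NNSeries, path: Path) -> None:
    """Beat annotation CSV: beat time (s) and accepted flag.

    The flag of beat i refers to the interval ending at that beat; the first
    beat is always marked accepted.
    """
    flags = np.concatenate(([True], nn.accepted))
    pd.DataFrame({"time_s": nn.beat_times, "accepted": flags.astype(int)}).to_csv(
        Path(path), index=False)
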