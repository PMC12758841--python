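"""File formats: waveform CSVs, cohort bundles, split/stats artifacts,
prediction JSON.

A cohort bundle on disk is a directory with one waveform CSV per record
(rows = samples, columns = the 12 canonical lead names), a ``cohort.csv``
table (id, timestamp, age, sex, 9 feature values, 9 mask bits, 13 label
bits) and a ``manifest.txt`` of ``key = value`` pairs recording the
generating configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from campnet.labels import CANONICAL_LABELS, LEAD_NAMES, N_LEADS
from campnet.preprocessing import SplitSpec, TrainStats
from campnet.synthetic import FEATURE_NAMES, Cohort, CohortConfig

logger = logging.getLogger("campnet")

__all__ = [
    "read_waveform_csv", "write_waveform_csv", "write_cohort", "read_cohort",
    "write_split", "read_split", "write_stats", "read_stats",
    "PredictionOutput",
]


class WaveformFormatError(ValueError):
    """Raised when a waveform CSV violates the 12-lead format."""


def read_waveform_csv(path) -> np.ndarray:
    """Parse a waveform CSV (rows = samples, columns = 12 named leads).

    Returns a (12, n_samples) float32 array in canonical lead order.
    Non-finite cells become zero (count logged); genuinely non-numeric
    cells raise a format error naming the offending column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise WaveformFormatError(f"{path}: empty file")
    missing = [lead for lead in LEAD_NAMES if lead not in df.columns]
    if missing:
        raise WaveformFormatError(
            f"{path}: missing lead column(s) {missing}")
    df = df[list(LEAD_NAMES)]
    for col in LEAD_NAMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise WaveformFormatError(
                f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = vals
    arr = df.to_numpy(dtype=np.float32).T
    n_bad = int(np.sum(~np.isfinite(arr)))
    if n_bad:
        logger.info("%s: replaced %d non-finite samples with zero",
                    path, n_bad)
        arr = np.where(np.isfinite(arr), arr, np.float32(0.0))
    if arr.shape[0] != N_LEADS:
        raise WaveformFormatError(f"{path}: expected {N_LEADS} leads")
    return arr


def write_waveform_csv(path, waveform: np.ndarray) -> None:
    wf = np.asarray(waveform, dtype=np.float32)
    if wf.ndim != 2 or wf.shape[0] != N_LEADS:
        raise WaveformFormatError("waveform must be (12, n_samples)")
    # 9 significant digits round-trip float32 exactly
    pd.DataFrame(wf.T, columns=list(LEAD_NAMES)).to_csv(path, index=False,
                                                        float_format="%.9g")


# --------------------------------------------------------------------------
# cohort bundle
# --------------------------------------------------------------------------

def _manifest_lines(config: CohortConfig) -> list[str]:
    lines = []
    for f in dataclasses.fields(config):
        val = getattr(config, f.name)
        if f.name == "cooccurrence":
            val = "none" if val is None else json.dumps(np.asarray(val).tolist())
        elif f.name == "prevalence":
            val = json.dumps(list(val))
        lines.append(f"{f.name} = {val}")
    return lines


def _parse_manifest(path: Path) -> CohortConfig:
    kw = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key == "cooccurrence":
            kw[key] = None if raw == "none" else np.asarray(json.loads(raw))
        elif key == "prevalence":
            kw[key] = tuple(json.loads(raw))
        elif key in ("n_records", "seed", "sampling_rate", "record_len"):
            kw[key] = int(raw)
        else:
            kw[key] = float(raw)
    return CohortConfig(**kw)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the full cohort bundle (records/, cohort.csv, manifest.txt)."""
    out_dir = Path(out_dir)
    rec_dir = out_dir / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rid, wf in zip(cohort.record_ids, cohort.waveforms):
        write_waveform_csv(rec_dir / f"{rid}.csv", wf)
    table = {"id": cohort.record_ids,
             "timestamp": cohort.timestamps,
             "age": cohort.ages,
             "sex": cohort.sexes}
    for j, name in enumerate(FEATURE_NAMES):
        table[name] = cohort.features[:, j]
    for j, name in enumerate(FEATURE_NAMES):
        table[f"{name}_valid"] = cohort.masks[:, j]
    for j, name in enumerate(CANONICAL_LABELS):
        table[f"label::{name}"] = cohort.labels[:, j]
    pd.DataFrame(table).to_csv(out_dir / "cohort.csv", index=False)
    (out_dir / "manifest.txt").write_text(
        "\n".join(_manifest_lines(cohort.config)) + "\n")
    return out_dir


def read_cohort(bundle_dir) -> Cohort:
    """Read a cohort bundle back into memory.

    Generator-only ground truth (beat parameters, ST windows) is not part
    of the on-disk format and comes back empty.
    """
    bundle_dir = Path(bundle_dir)
    config = _parse_manifest(bundle_dir / "manifest.txt")
    df = pd.read_csv(bundle_dir / "cohort.csv")
    record_ids = df["id"].astype(str).tolist()
    n = len(record_ids)
    waveforms = np.empty((n, N_LEADS, config.record_len), dtype=np.float32)
    for i, rid in enumerate(record_ids):
        wf = read_waveform_csv(bundle_dir / "records" / f"{rid}.csv")
        if wf.shape[1] != config.record_len:
            raise WaveformFormatError(
                f"{rid}: expected {config.record_len} samples, "
                f"got {wf.shape[1]}")
        waveforms[i] = wf
    features = df[list(FEATURE_NAMES)].to_numpy(np.float32)
    masks = df[[f"{n}_valid" for n in FEATURE_NAMES]].to_numpy(np.int8)
    labels = df[[f"label::{n}" for n in CANONICAL_LABELS]].to_numpy(np.int8)
    return Cohort(waveforms, features, masks,
                  df["age"].to_numpy(np.float32),
                  df["sex"].to_numpy(np.int8), labels,
                  df["timestamp"].to_numpy(np.int64),
                  record_ids, config, [], [])


# --------------------------------------------------------------------------
# split / stats artifacts
# --------------------------------------------------------------------------

def write_split(split: SplitSpec, path) -> None:
    Path(path).write_text(json.dumps(split.to_dict(), indent=1))


def read_split(path) -> SplitSpec:
    return SplitSpec.from_dict(json.loads(Path(path).read_text()))


def write_stats(stats: TrainStats, path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=1))


def read_stats(path) -> TrainStats:
    return TrainStats.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# prediction output
# --------------------------------------------------------------------------

@dataclass
class PredictionOutput:
    """One record's multilabel prediction, raw and calibrated."""

    record_id: str
    raw_probabilities: np.ndarray          # (13,) sigmoid of logits
    calibrated_probabilities: np.ndarray   # (13,) Platt-scaled (or raw copy)
    threshold: float
    mode: str
    checkpoint_id: str = ""

    @property
    def predicted_labels(self) -> list[str]:
        return [CANONICAL_LABELS[i]
                for i in np.flatnonzero(
                    self.calibrated_probabilities >= self.threshold)]

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "labels": list(CANONICAL_LABELS),
            "raw_probabilities": [float(p) for p in self.raw_probabilities],
            "calibrated_probabilities": [
                float(p) for p in self.calibrated_probabilities],
            "threshold": self.threshold,
            "predicted_labels": self.predicted_labels,
            "mode": self.mode,
            "checkpoint_id": self.checkpoint_id,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
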