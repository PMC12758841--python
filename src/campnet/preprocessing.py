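"""Deterministic input standardization and dataset splitting.

All normalization statistics are fitted on the training split only and
carried in :class:`TrainStats`, which records the identity of the split it
was fitted on so that leakage is checkable downstream. Standard deviations
are population (1/N) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from campnet.labels import N_LEADS
from campnet.synthetic import N_FEATURES

__all__ = [
    "TrainStats", "SplitSpec", "fix_length", "zscore_leads",
    "fit_feature_stats", "standardize_features", "normalize_age",
    "chronological_split", "random_split_711", "make_splits",
]


@dataclass
class TrainStats:
    """Feature and age normalization constants fitted on one training split."""

    feature_mean: np.ndarray      # (9,)
    feature_sd: np.ndarray        # (9,), all > 0 (zero-variance guard -> 1)
    age_mean: float
    age_sd: float
    split_id: str = "train"

    def __post_init__(self):
        self.feature_mean = np.asarray(self.feature_mean, dtype=np.float64)
        self.feature_sd = np.asarray(self.feature_sd, dtype=np.float64)
        if np.any(self.feature_sd < 0):
            raise ValueError("standard deviations must be non-negative")

    def to_dict(self) -> dict:
        return {
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "age_mean": float(self.age_mean),
            "age_sd": float(self.age_sd),
            "split_id": self.split_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainStats":
        return cls(np.asarray(d["feature_mean"]), np.asarray(d["feature_sd"]),
                   float(d["age_mean"]), float(d["age_sd"]),
                   d.get("split_id", "train"))


@dataclass
class SplitSpec:
    """Record indices of the four cohort partitions."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    temporal: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("train", "val", "test", "temporal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        parts = [self.train, self.val, self.test, self.temporal]
        total = np.concatenate(parts)
        if len(np.unique(total)) != len(total):
            raise ValueError("splits must be pairwise disjoint")

    def to_dict(self) -> dict:
        return {"train": self.train.tolist(), "val": self.val.tolist(),
                "test": self.test.tolist(), "temporal": self.temporal.tolist(),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(d["train"], d["val"], d["test"], d["temporal"],
                   d.get("seed"))


def fix_length(waveform: np.ndarray, target_len: int = 5000) -> np.ndarray:
    """Truncate or zero-pad a 12-lead waveform to ``target_len`` samples.

    Non-finite samples are replaced by zero *before* length fixing.
    """
    wf = np.asarray(waveform, dtype=np.float32)
    if wf.ndim != 2 or wf.shape[0] != N_LEADS:
        raise ValueError(f"expected a (12, n) waveform, got shape {wf.shape}")
    wf = np.where(np.isfinite(wf), wf, np.float32(0.0))
    n = wf.shape[1]
    if n >= target_len:
        return wf[:, :target_len]
    out = np.zeros((N_LEADS, target_len), dtype=np.float32)
    out[:, :n] = wf
    return out


def zscore_leads(waveform: np.ndarray) -> np.ndarray:
    """Per-lead z-score normalization (mean 0, population SD 1).

    A constant lead maps to all zeros. Accepts (12, n) or batched
    (b, 12, n) input.
    """
    wf = np.asarray(waveform, dtype=np.float32)
    mean = wf.mean(axis=-1, keepdims=True)
    sd = wf.std(axis=-1, keepdims=True)
    sd = np.where(sd > 0, sd, np.float32(1.0))
    return ((wf - mean) / sd).astype(np.float32)


def fit_feature_stats(features: np.ndarray, masks: np.ndarray,
                      ages: np.ndarray, split_id: str = "train") -> TrainStats:
    """Fit per-feature mean/SD over valid (mask=1) training entries only.

    A feature with no valid entries (or zero variance) gets mean 0 / SD 1
    with a warning, so standardization stays well defined.
    """
    X = np.asarray(features, dtype=np.float64)
    M = np.asarray(masks, dtype=bool)
    if X.shape[0] == 0:
        raise ValueError("training split is empty")
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        valid = X[M[:, j], j]
        if valid.size == 0:
            warnings.warn(f"feature {j} has no valid training entries; "
                          "using mean 0 / sd 1", RuntimeWarning)
            continue
        mean[j] = valid.mean()
        s = valid.std()  # population
        sd[j] = s if s > 0 else 1.0
    ages = np.asarray(ages, dtype=np.float64)
    age_sd = ages.std()
    return TrainStats(mean, sd, float(ages.mean()),
                      float(age_sd if age_sd > 0 else 1.0), split_id)


def standardize_features(features: np.ndarray, masks: np.ndarray,
                         stats: TrainStats) -> np.ndarray:
    """(x - mean) / sd on valid entries; missing entries imputed with 0."""
    X = np.asarray(features, dtype=np.float32)
    M = np.asarray(masks, dtype=np.float32)
    z = (X - stats.feature_mean.astype(np.float32)) \
        / stats.feature_sd.astype(np.float32)
    return (z * M).astype(np.float32)


def unstandardize_features(z: np.ndarray, stats: TrainStats) -> np.ndarray:
    """Inverse of :func:`standardize_features` on valid entries."""
    return (np.asarray(z, dtype=np.float64) * stats.feature_sd
            + stats.feature_mean)


def normalize_age(age, stats: TrainStats):
    """Z-score age against the training cohort's age statistics."""
    age = np.asarray(age, dtype=np.float32)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    return ((age - np.float32(stats.age_mean))
            / np.float32(stats.age_sd)).astype(np.float32)


def chronological_split(timestamps: Sequence[int],
                        record_ids: Optional[Sequence[str]] = None):
    """Reserve the most recent ceil(10%) of records as the temporal test set.

    Records are ordered by (timestamp, record id); returns
    ``(development_indices, temporal_indices)`` each in chronological order.
    """
    ts = np.asarray(timestamps)
    n = len(ts)
    if record_ids is None:
        order = np.lexsort((np.arange(n), ts))
    else:
        order = np.lexsort((np.asarray(record_ids), ts))
    n_temporal = int(np.ceil(0.10 * n))
    return order[: n - n_temporal], order[n - n_temporal:]


def random_split_711(development: np.ndarray, seed: int) -> SplitSpec:
    """Shuffle the development set into 7:1:1 train/validation/internal-test.

    Validation and test sizes are round(n/9) each; the remainder goes to
    train. The temporal slot is left empty (see :func:`make_splits`).
    """
    dev = np.asarray(development, dtype=np.int64)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dev))
    shuffled = dev[perm]
    n = len(dev)
    n_val = int(round(n / 9.0))
    n_test = int(round(n / 9.0))
    n_train = n - n_val - n_test
    return SplitSpec(shuffled[:n_train],
                     shuffled[n_train:n_train + n_val],
                     shuffled[n_train + n_val:],
                     np.empty(0, dtype=np.int64), seed=seed)


def make_splits(timestamps: Sequence[int], seed: int,
                record_ids: Optional[Sequence[str]] = None) -> SplitSpec:
    """Chronological 90/10 split followed by a seeded 7:1:1 development split."""
    dev, temporal = chronological_split(timestamps, record_ids)
    spec = random_split_711(dev, seed)
    return SplitSpec(spec.train, spec.val, spec.test, temporal, seed=seed)
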