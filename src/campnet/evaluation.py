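"""Multilabel evaluation: per-label and macro metrics, Platt calibration,
calibration curves, and demographic subgroup reports.

AUC uses the Mann–Whitney formulation (ties get half credit); average
precision is the step-function interpolation with tied scores grouped.
Macro rows are arithmetic mean and population SD across the labels for
which the metric is defined; labels with a single observed class are
excluded from rank metrics with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from campnet.labels import CANONICAL_LABELS

__all__ = [
    "SingleClassError", "MetricsReport", "CalibrationCurve", "SubgroupReport",
    "binary_auc", "average_precision", "threshold_metrics", "macro_report",
    "evaluate_multilabel", "fit_platt", "apply_platt", "calibration_curve",
    "subgroup_report", "PRESET_AGE_CUTS",
]

METRIC_COLUMNS = ("auc", "auprc", "f1", "recall", "precision",
                  "accuracy", "specificity")

#: Fixed age-quartile cut points (years) usable instead of data-driven ones.
PRESET_AGE_CUTS = (54.0, 66.0, 78.0)


class SingleClassError(ValueError):
    """Raised when a rank metric is undefined (only one class present)."""


def binary_auc(scores, labels) -> float:
    """ROC AUC as the Mann–Whitney probability.

    Equals ``(#concordant + 0.5 * #ties) / (#pos * #neg)`` over all
    positive/negative pairs.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: only one class present")
    ranks = rankdata(s)  # average ranks give ties half credit
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Step-function average precision with tied scores grouped.

    ``sum_k (R_k - R_{k-1}) * P_k`` over descending distinct-score
    thresholds.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(np.float64)
    n_pos = y.sum()
    if n_pos == 0:
        raise SingleClassError("average precision undefined: no positives")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # indices closing each tie group (last occurrence of each distinct score)
    boundary = np.r_[s[1:] != s[:-1], True]
    cum_tp = np.cumsum(y)[boundary]
    cum_n = np.arange(1, y.size + 1)[boundary]
    precision = cum_tp / cum_n
    recall = cum_tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def threshold_metrics(scores, labels, threshold: float = 0.5):
    """Confusion-matrix metrics at a probability threshold.

    Returns ``(f1, recall, precision, accuracy, specificity)``. Degenerate
    denominators fall back to 0 (precision with no predicted positives,
    recall with no positives, specificity with no negatives; F1 is 0 when
    precision + recall is 0).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if s.size == 0:
        raise ValueError("empty input")
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    accuracy = (tp + tn) / s.size
    specificity = tn / (tn + fp) if tn + fp else 0.0
    return f1, recall, precision, accuracy, specificity


@dataclass
class MetricsReport:
    """Per-label metric table with macro mean/SD rows."""

    per_label: pd.DataFrame          # index = label names, cols = metrics
    threshold: float = 0.5
    excluded: dict = field(default_factory=dict)  # metric -> [labels skipped]

    @property
    def macro_mean(self) -> pd.Series:
        return self.per_label.mean(axis=0, skipna=True)

    @property
    def macro_sd(self) -> pd.Series:
        # population SD across labels, matching mean (SD) presentation
        return self.per_label.std(axis=0, ddof=0, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        """Per-label rows plus a final macro "Mean (SD)" summary row."""
        df = self.per_label.copy()
        df.loc["Macro mean"] = self.macro_mean
        df.loc["Macro SD"] = self.macro_sd
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="label")


def macro_report(per_label: pd.DataFrame, threshold: float = 0.5,
                 excluded: Optional[dict] = None) -> MetricsReport:
    """Wrap a per-label metric table into a report with macro rows."""
    return MetricsReport(per_label, threshold, excluded or {})


def evaluate_multilabel(probs: np.ndarray, labels: np.ndarray,
                        threshold: float = 0.5,
                        label_names: Sequence[str] = CANONICAL_LABELS
                        ) -> MetricsReport:
    """Full per-label + macro report for (n, C) probabilities and labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.ndim != 2 or probs.shape != labels.shape:
        raise ValueError("probs and labels must both be (n, C)")
    rows = []
    excluded: dict[str, list[str]] = {"auc": [], "auprc": []}
    for c, name in enumerate(label_names):
        s, y = probs[:, c], labels[:, c]
        try:
            auc = binary_auc(s, y)
        except SingleClassError:
            warnings.warn(f"AUC undefined for {name!r}; excluded from macro",
                          RuntimeWarning)
            excluded["auc"].append(name)
            auc = np.nan
        try:
            ap = average_precision(s, y)
        except SingleClassError:
            warnings.warn(f"AUPRC undefined for {name!r}; excluded from macro",
                          RuntimeWarning)
            excluded["auprc"].append(name)
            ap = np.nan
        f1, rec, prec, acc, spec = threshold_metrics(s, y, threshold)
        rows.append((auc, ap, f1, rec, prec, acc, spec))
    df = pd.DataFrame(rows, index=list(label_names), columns=METRIC_COLUMNS)
    return MetricsReport(df, threshold, excluded)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def fit_platt(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-label Platt scaling: fit ``sigmoid(a * logit + b)`` by MLE.

    Returns an (C, 2) array of (a, b); labels with a single observed class
    are skipped with a warning and get (nan, nan).
    """
    from sklearn.linear_model import LogisticRegression

    z = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    y = np.atleast_2d(np.asarray(labels))
    if z.shape != y.shape:
        raise ValueError("logits and labels must have matching shapes")
    out = np.full((z.shape[1], 2), np.nan)
    for c in range(z.shape[1]):
        yc = y[:, c]
        if len(np.unique(yc)) < 2:
            warnings.warn(f"Platt fit skipped for label {c}: single class",
                          RuntimeWarning)
            continue
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        lr.fit(z[:, c, None], yc)
        out[c] = (lr.coef_[0, 0], lr.intercept_[0])
    return out


def apply_platt(logits: np.ndarray, calib: np.ndarray) -> np.ndarray:
    """Calibrated probabilities ``sigmoid(a * logit + b)`` per label.

    Labels whose calibrator is (nan, nan) fall back to the raw sigmoid.
    """
    z = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    a = np.where(np.isnan(calib[:, 0]), 1.0, calib[:, 0])
    b = np.where(np.isnan(calib[:, 1]), 0.0, calib[:, 1])
    return 1.0 / (1.0 + np.exp(-(z * a + b)))


@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray        # (n_bins + 1,)
    mean_predicted: np.ndarray   # (n_bins,), NaN for empty bins
    observed_frequency: np.ndarray  # (n_bins,), NaN for empty bins
    counts: np.ndarray           # (n_bins,), sums to n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:],
            "mean_predicted": self.mean_predicted,
            "observed_frequency": self.observed_frequency,
            "count": self.counts,
        })


def calibration_curve(probs, labels, n_bins: int = 10) -> CalibrationCurve:
    """Equal-width reliability bins on [0, 1]."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean_pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    occupied = counts > 0
    sums_p = np.bincount(idx, weights=p, minlength=n_bins)
    sums_y = np.bincount(idx, weights=y, minlength=n_bins)
    mean_pred[occupied] = sums_p[occupied] / counts[occupied]
    obs[occupied] = sums_y[occupied] / counts[occupied]
    return CalibrationCurve(edges, mean_pred, obs, counts)


# --------------------------------------------------------------------------
# subgroups
# --------------------------------------------------------------------------

@dataclass
class SubgroupReport:
    scheme: str
    groups: dict                  # key -> MetricsReport or None (empty group)
    membership: dict              # key -> np.ndarray of record indices
    boundaries: Optional[tuple] = None   # age cut points when applicable


def subgroup_report(probs, labels, ages=None, sexes=None,
                    scheme: str = "sex",
                    age_cuts: Optional[Sequence[float]] = None,
                    threshold: float = 0.5) -> SubgroupReport:
    """Per-subgroup metric reports.

    ``scheme='sex'`` splits by sex code; ``scheme='age_quartile'`` uses the
    evaluated cohort's age quartiles by default, or fixed ``age_cuts``
    (e.g. :data:`PRESET_AGE_CUTS`). Groups partition the records; empty
    groups are reported as ``None``.
    """
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    n = probs.shape[0]
    if scheme == "sex":
        if sexes is None:
            raise ValueError("sex scheme requires sexes")
        sexes = np.asarray(sexes)
        membership = {"female": np.flatnonzero(sexes == 0),
                      "male": np.flatnonzero(sexes == 1)}
        boundaries = None
    elif scheme == "age_quartile":
        if ages is None:
            raise ValueError("age scheme requires ages")
        ages = np.asarray(ages, dtype=np.float64)
        cuts = (tuple(np.quantile(ages, [0.25, 0.5, 0.75]))
                if age_cuts is None else tuple(age_cuts))
        edges = (-np.inf,) + cuts + (np.inf,)
        membership = {
            f"Q{q + 1}": np.flatnonzero((ages > edges[q]) & (ages <= edges[q + 1]))
            for q in range(4)
        }
        boundaries = cuts
    else:
        raise ValueError(f"unknown subgroup scheme {scheme!r}")
    assigned = np.concatenate(list(membership.values()))
    assert len(assigned) == n and len(np.unique(assigned)) == n
    groups = {}
    for key, idx in membership.items():
        if idx.size == 0:
            groups[key] = None
            continue
        groups[key] = evaluate_multilabel(probs[idx], labels[idx], threshold)
    return SubgroupReport(scheme, groups, membership, boundaries)
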