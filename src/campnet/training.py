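"""Class-imbalance-aware loss and the monitored training protocol.

The loss is a weighted binary cross-entropy, mean-reduced over the 13
labels and the batch, whose per-label positive weight

    w_c = (N - n_c) / (n_c + eps)

is computed from the training split only (N records, n_c positives).
Validation is monitored with a combined metric, 0.5 * macro AUC + 0.5 *
macro accuracy; the learning rate decays on plateaus (relative threshold,
cooldown), training stops early after a patience window without meaningful
improvement, and the checkpoint with the best validation metric — never
simply the last — is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from campnet.evaluation import SingleClassError, binary_auc
from campnet.model import CaMPNet
from campnet.nn.layers import Adam, clip_grad_norm
from campnet.nn.tensor import Tensor, bce_with_logits, no_grad
from campnet.preprocessing import (SplitSpec, TrainStats, fit_feature_stats,
                                   normalize_age, standardize_features,
                                   zscore_leads)

__all__ = [
    "ClassWeights", "TrainConfig", "TrainResult", "ModelInputs",
    "compute_class_weights", "weighted_bce", "combined_metric",
    "PlateauScheduler", "EarlyStopper", "train", "predict", "prepare_inputs",
]


@dataclass
class ClassWeights:
    weights: np.ndarray       # (C,)
    n_records: int
    n_positive: np.ndarray    # (C,)
    eps: float


def compute_class_weights(labels: np.ndarray, eps: float = 1e-6) -> ClassWeights:
    """Adaptive positive weights ``(N - n_c) / (n_c + eps)`` per label."""
    y = np.asarray(labels)
    if y.ndim != 2 or y.shape[0] < 1:
        raise ValueError("labels must be a non-empty (N, C) multihot matrix")
    n = y.shape[0]
    n_pos = y.sum(axis=0).astype(np.float64)
    if eps <= 0 and np.any(n_pos == 0):
        raise ZeroDivisionError(
            "a label has no positives; eps must be > 0 to guard n_c = 0")
    w = (n - n_pos) / (n_pos + eps)
    return ClassWeights(w.astype(np.float64), n, n_pos, eps)


def weighted_bce(logits, labels, weights=None) -> Tensor:
    """Batch loss: mean over labels then records of the weighted BCE."""
    w = weights.weights if isinstance(weights, ClassWeights) else weights
    if w is not None and not np.all(np.isfinite(w)):
        raise ValueError("class weights must be finite")
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    return bce_with_logits(logits, np.asarray(labels), w)


def combined_metric(probs: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> float:
    """0.5 * macro AUC + 0.5 * macro accuracy (threshold 0.5 by default).

    Labels with a single observed class on the split are skipped from the
    AUC macro with a warning; accuracy is always defined.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels)
    if p.size == 0:
        raise ValueError("empty input to combined_metric")
    if p.ndim == 1:
        p, y = p[:, None], y[:, None]
    aucs = []
    for c in range(p.shape[1]):
        try:
            aucs.append(binary_auc(p[:, c], y[:, c]))
        except SingleClassError:
            warnings.warn(f"label {c} single-class on this split; skipped "
                          "from combined-metric AUC", RuntimeWarning)
    macro_auc = float(np.mean(aucs)) if aucs else 0.5
    macro_acc = float(np.mean((p >= threshold) == y.astype(bool)))
    return 0.5 * macro_auc + 0.5 * macro_acc


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` non-improving epochs.

    Improvement means exceeding the best metric by a relative threshold:
    ``metric > best * (1 + rel_threshold)``. After a decay, ``cooldown``
    epochs pass before non-improvement is counted again.
    """

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5,
                 rel_threshold: float = 1e-3, cooldown: int = 2,
                 min_lr: float = 0.0):
        self.lr = float(lr)
        self.factor = factor
        self.patience = patience
        self.rel_threshold = rel_threshold
        self.cooldown = cooldown
        self.min_lr = min_lr
        self.best = -np.inf
        self.num_bad = 0
        self.cooldown_left = 0
        self.decay_epochs: list[int] = []
        self._epoch = 0

    def _improved(self, metric: float) -> bool:
        if self.best == -np.inf:
            return True
        return metric > self.best * (1.0 + self.rel_threshold)

    def step(self, metric: float) -> float:
        """Record one epoch's validation metric; returns the LR to use next."""
        self._epoch += 1
        if self._improved(metric):
            self.best = max(self.best, metric)
            self.num_bad = 0
        elif self.cooldown_left > 0:
            self.cooldown_left -= 1
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.decay_epochs.append(self._epoch)
                self.num_bad = 0
                self.cooldown_left = self.cooldown
        return self.lr


class EarlyStopper:
    """Stop after ``patience`` epochs without meaningful improvement."""

    def __init__(self, patience: int = 10, rel_threshold: float = 1e-3):
        self.patience = patience
        self.rel_threshold = rel_threshold
        self.best = -np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        if self.best == -np.inf or metric > self.best * (1.0 + self.rel_threshold):
            self.best = max(self.best, metric)
            self.num_bad = 0
            return False
        self.num_bad += 1
        return self.num_bad >= self.patience


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 64
    lr: float = 1e-4
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    plateau_patience: int = 5
    decay_factor: float = 0.5
    rel_threshold: float = 1e-3
    cooldown: int = 2
    early_stop_patience: int = 10
    class_weight_eps: float = 1e-6
    feature_dropout: float = 0.1
    aux_weight: float = 0.3
    attn_entropy_weight: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")
        if self.cooldown < 0:
            raise ValueError("cooldown must be non-negative")
        if min(self.lr, self.clip_norm, self.decay_factor) <= 0:
            raise ValueError("rates must be positive")


@dataclass
class ModelInputs:
    """Preprocessed model-ready arrays for a cohort.

    Waveforms are kept raw and z-scored per batch at forward time to avoid
    holding a second full-size copy of the signal matrix.
    """

    waveforms: np.ndarray     # (n, 12, L) raw mV
    features: np.ndarray      # (n, 9) standardized, missing imputed 0
    masks: np.ndarray         # (n, 9)
    ages: np.ndarray          # (n,) normalized
    sexes: np.ndarray         # (n,)
    labels: np.ndarray        # (n, 13)

    @property
    def n_records(self) -> int:
        return self.waveforms.shape[0]


def prepare_inputs(cohort, stats: TrainStats) -> ModelInputs:
    """Standardize a cohort's features and age against training statistics."""
    feats = standardize_features(cohort.features, cohort.masks, stats)
    ages = normalize_age(cohort.ages, stats)
    return ModelInputs(cohort.waveforms, feats, cohort.masks.astype(np.float32),
                       ages, cohort.sexes, cohort.labels)


def fit_stats_for_split(cohort, split: SplitSpec) -> TrainStats:
    """Training-split-only normalization statistics (no leakage)."""
    tr = split.train
    return fit_feature_stats(cohort.features[tr], cohort.masks[tr],
                             cohort.ages[tr], split_id="train")


def _forward_batch(model: CaMPNet, inputs: ModelInputs, idx: np.ndarray,
                   mode: str):
    wf = zscore_leads(inputs.waveforms[idx])
    return model.forward(wf, inputs.features[idx], inputs.masks[idx],
                         inputs.ages[idx], inputs.sexes[idx], mode=mode)


def predict(model: CaMPNet, inputs: ModelInputs,
            idx: Optional[np.ndarray] = None, mode: str = "full",
            batch_size: int = 128):
    """Batched inference. Returns ``(probs, logits, attention)`` arrays."""
    from campnet.model import predict_proba

    if idx is None:
        idx = np.arange(inputs.n_records)
    idx = np.asarray(idx)
    was_training = model.training
    model.eval()
    logits_all, attn_all = [], []
    try:
        with no_grad():
            for start in range(0, len(idx), batch_size):
                bidx = idx[start:start + batch_size]
                logits, attn = _forward_batch(model, inputs, bidx, mode)
                logits_all.append(logits.data)
                attn_all.append(attn)
    finally:
        model.train(was_training)
    logits = np.concatenate(logits_all)
    return predict_proba(logits), logits, np.concatenate(attn_all)


@dataclass
class TrainResult:
    """Best checkpoint plus the per-epoch history of a training run."""

    best_state: dict
    best_metric: float
    best_epoch: int
    history: list = field(default_factory=list)
    class_weights: Optional[ClassWeights] = None
    config: Optional[TrainConfig] = None
    mode: str = "full"

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def write_history(self, path) -> None:
        """Line-delimited JSON records (epoch, loss, lr, metric)."""
        import json
        with open(path, "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")

    def summary(self) -> str:
        lines = [
            "CaMPNet training summary",
            "------------------------",
            f"epochs run          : {len(self.history)}",
            f"best epoch          : {self.best_epoch}",
            f"best combined metric: {self.best_metric:.4f}",
            f"training mode       : {self.mode}",
        ]
        if self.history:
            lines.append(f"final train loss    : "
                         f"{self.history[-1]['loss']:.4f}")
            lines.append(f"final learning rate : {self.history[-1]['lr']:.2e}")
        return "\n".join(lines)


def train(model: CaMPNet, inputs: ModelInputs, split: SplitSpec,
          config: TrainConfig = TrainConfig(), mode: str = "full",
          verbose: bool = False) -> TrainResult:
    """Train with the monitored protocol; restores the best weights.

    ``mode='without_age_sex'`` trains the demographic-ablation variant
    (metadata tokens absent in every forward pass). Deterministic for a
    fixed seed, data and device.
    """
    if mode not in ("full", "without_age_sex"):
        raise ValueError("training mode must be 'full' or 'without_age_sex'")
    cw = compute_class_weights(inputs.labels[split.train],
                               config.class_weight_eps)
    opt = Adam(model.parameters(), lr=config.lr,
               weight_decay=config.weight_decay)
    sched = PlateauScheduler(config.lr, config.decay_factor,
                             config.plateau_patience, config.rel_threshold,
                             config.cooldown)
    stopper = EarlyStopper(config.early_stop_patience, config.rel_threshold)
    rng = np.random.default_rng(config.seed)
    model._dropout_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])
    result = TrainResult({}, -np.inf, -1, [], cw, config, mode)
    train_idx = np.asarray(split.train)
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        perm = rng.permutation(len(train_idx))
        losses = []
        lr_used = sched.lr
        opt.lr = lr_used
        for start in range(0, len(train_idx), config.batch_size):
            bidx = train_idx[perm[start:start + config.batch_size]]
            feats = inputs.features[bidx]
            masks = inputs.masks[bidx]
            if config.feature_dropout > 0.0:
                # validity-aware robustness: a fraction of records sees the
                # fully-missing feature regime during training, so masked
                # inference stays in-distribution
                drop = rng.random(len(bidx)) < config.feature_dropout
                if drop.any():
                    feats = feats.copy()
                    masks = masks.copy()
                    feats[drop] = 0.0
                    masks[drop] = 0.0
            wf = zscore_leads(inputs.waveforms[bidx])
            logits, _, aux_logits, attn = model.forward(
                wf, feats, masks, inputs.ages[bidx], inputs.sexes[bidx],
                mode=mode, with_aux=True)
            loss = weighted_bce(logits, inputs.labels[bidx], cw)
            if config.aux_weight > 0.0:
                # deep supervision of the fusion token keeps the
                # cross-attention pooling discriminative
                aux = weighted_bce(aux_logits, inputs.labels[bidx], cw)
                loss = loss + aux * config.aux_weight
            if config.attn_entropy_weight > 0.0:
                # concentration incentive: sharp attention that must stay
                # discriminative (aux head) settles on informative patches
                entropy = -(attn * attn.log()).sum(axis=-1).mean()
                loss = loss + entropy * config.attn_entropy_weight
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(model.parameters(), config.clip_norm)
            opt.step()
            losses.append(float(loss.data))
        probs, _, _ = predict(model, inputs, split.val, mode=mode,
                              batch_size=max(config.batch_size, 128))
        metric = combined_metric(probs, inputs.labels[split.val])
        result.history.append({
            "epoch": epoch, "loss": float(np.mean(losses)),
            "lr": lr_used, "metric": metric,
        })
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  "
                  f"lr {lr_used:.2e}  val metric {metric:.4f}")
        if metric > result.best_metric:
            result.best_metric = metric
            result.best_epoch = epoch
            result.best_state = model.state_dict()
        sched.step(metric)
        if stopper.step(metric):
            break
    if result.best_state:
        model.load_state_dict(result.best_state)
    model.eval()
    return result
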