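"""The CaMPNet architecture.

Fusion-before-encoding: the structured-feature token queries the ECG patch
tokens through single-head cross-attention, producing a context-enriched
fusion token. The fusion token is concatenated with a CLS token, the
original patch tokens and the demographic metadata tokens; learned
positional embeddings are added; a pre-norm transformer encoder processes
the sequence; and a linear head on the CLS state emits one logit per
diagnostic label.

Cross-attention fusion, for query token ``X_s`` and patch context ``X_p``::

    Q = X_s W_Q,  K = X_p W_K,  V = X_p W_V
    A = softmax(Q K^T / sqrt(D)),  Z = A V
    fused = LN(X_s + FFN(Z))

``A`` (one row per record, one weight per patch) is returned alongside the
logits and drives the interpretability module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from campnet import nn
from campnet.labels import CANONICAL_LABELS, N_LABELS, N_LEADS
from campnet.nn.tensor import Tensor, bce_with_logits, concat, no_grad
from campnet.preprocessing import TrainStats
from campnet.synthetic import N_FEATURES

CHECKPOINT_VERSION = 1

MODES = ("full", "feature_masked", "without_age_sex")


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 768
    patch_len: int = 50
    n_patches: int = 100
    n_layers: int = 6
    n_heads: int = 8
    n_features: int = N_FEATURES
    n_labels: int = N_LABELS
    metadata_tokens: int = 2       # age token + sex token
    dropout: float = 0.1
    ffn_mult: int = 4              # encoder FFN hidden = ffn_mult * D
    qk_norm: bool = True           # content-driven fusion attention
    attn_scale: float = 1.0        # fusion logit temperature under qk_norm

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        for name in ("embed_dim", "patch_len", "n_patches", "n_heads",
                     "n_features", "n_labels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 0 or self.metadata_tokens not in (0, 1, 2):
            raise ValueError("invalid layer or metadata-token count")

    @property
    def record_len(self) -> int:
        return self.patch_len * self.n_patches

    @property
    def seq_len(self) -> int:
        # [CLS, fusion, patches..., metadata...]
        return 2 + self.n_patches + self.metadata_tokens

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Scaled-down configuration exercising the identical code path."""
        kw = dict(embed_dim=64, n_layers=2, n_heads=2, ffn_mult=2)
        kw.update(overrides)
        return cls(**kw)


class CrossAttentionFusion(nn.Module):
    """Single-head query-conditioned fusion (scaling by sqrt(D)).

    With ``qk_norm`` (default) queries and keys are layer-normalized before
    the scaled dot product and a learnable temperature multiplies the
    logits. Unit-scale keys make the attention content-driven rather than
    amplitude-driven — without this, high-amplitude waveform patches (QRS
    complexes) monopolize the attention regardless of their diagnostic
    relevance. ``qk_norm=False`` recovers the plain formulation.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 qk_norm: bool = True, attn_scale: float = 1.0):
        super().__init__()
        self.w_q = nn.Linear(dim, dim, rng, bias=False)
        self.w_k = nn.Linear(dim, dim, rng, bias=False)
        self.w_v = nn.Linear(dim, dim, rng, bias=False)
        from campnet.nn.layers import FeedForward
        self.ffn = FeedForward(dim, dim, dim, rng)
        self.ln = nn.LayerNorm(dim)
        self.qk_norm = qk_norm
        if qk_norm:
            self.ln_q = nn.LayerNorm(dim)
            self.ln_k = nn.LayerNorm(dim)
            # fixed temperature: normalized dot products are bounded, so a
            # moderate scale yields graded (not collapsed) attention over
            # content-similar patches
            self.attn_scale = attn_scale
        self.dim = dim

    def forward(self, feature_token: Tensor, patch_tokens: Tensor):
        """(B,1,D) query + (B,Np,D) context -> (fused (B,1,D), A (B,1,Np))."""
        q = self.w_q(feature_token)
        k = self.w_k(patch_tokens)
        v = self.w_v(patch_tokens)
        if self.qk_norm:
            q = self.ln_q(q)
            k = self.ln_k(k)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        if self.qk_norm:
            scores = scores * np.float32(self.attn_scale)
        attn = scores.softmax(axis=-1)
        z = attn @ v
        fused = self.ln(feature_token + self.ffn(z))
        return fused, attn


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.w_q = nn.Linear(dim, dim, rng)
        self.w_k = nn.Linear(dim, dim, rng)
        self.w_v = nn.Linear(dim, dim, rng)
        self.w_o = nn.Linear(dim, dim, rng)
        self.n_heads = n_heads
        self.head_dim = dim // n_heads

    def _split(self, x: Tensor) -> Tensor:
        b, l, _ = x.shape
        return x.reshape(b, l, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        q = self._split(self.w_q(x))
        k = self._split(self.w_k(x))
        v = self._split(self.w_v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.w_o(out)


class EncoderBlock(nn.Module):
    """Pre-norm transformer block with GELU feed-forward."""

    def __init__(self, dim: int, n_heads: int, ffn_mult: int,
                 rng: np.random.Generator):
        super().__init__()
        from campnet.nn.layers import FeedForward
        self.ln1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.ffn = FeedForward(dim, ffn_mult * dim, dim, rng)

    def forward(self, x: Tensor, dropout: float = 0.0,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        h = self.attn(self.ln1(x))
        if dropout > 0.0 and rng is not None:
            h = h.dropout(dropout, rng)
        x = x + h
        h = self.ffn(self.ln2(x))
        if dropout > 0.0 and rng is not None:
            h = h.dropout(dropout, rng)
        return x + h


class CaMPNet(nn.Module):
    """Multimodal ECG transformer with cross-attention early fusion."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        from campnet.nn.layers import FeedForward
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.embed_dim
        self.patch_proj = nn.Linear(N_LEADS * config.patch_len, d, rng)
        self.feature_embed = FeedForward(2 * config.n_features, d, d, rng)
        self.age_embed = FeedForward(1, d, d, rng)
        self.sex_embed = FeedForward(1, d, d, rng)
        self.fusion = CrossAttentionFusion(d, rng, qk_norm=config.qk_norm,
                                           attn_scale=config.attn_scale)
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, (1, 1, d)))
        self.pos_embed = nn.Parameter(
            rng.normal(0.0, 0.02, (1, config.seq_len, d)))
        for i in range(config.n_layers):
            setattr(self, f"block{i}",
                    EncoderBlock(d, config.n_heads, config.ffn_mult, rng))
        self.final_ln = nn.LayerNorm(d)
        self.head = nn.Linear(d, config.n_labels, rng)
        # train-time deep supervision of the fusion token: keeps the
        # cross-attention pooling label-discriminative (and therefore
        # interpretable) even when the encoder path suffices on its own
        self.aux_head = nn.Linear(d, config.n_labels, rng)
        self._dropout_rng: Optional[np.random.Generator] = None

    # -- tokenization --------------------------------------------------------
    def embed_patches(self, waveform: np.ndarray) -> Tensor:
        """(B, 12, L) normalized waveform -> (B, Np, D) patch tokens.

        Non-overlapping 12-lead windows of ``patch_len`` samples are
        flattened and linearly projected — a stride-equal 1D convolution
        expressed as a matrix product.
        """
        cfg = self.config
        wf = np.asarray(waveform, dtype=np.float32)
        if wf.ndim == 2:
            wf = wf[None]
        b, leads, length = wf.shape
        if leads != N_LEADS:
            raise ValueError(f"expected 12 leads, got {leads}")
        if length != cfg.record_len:
            raise ValueError(
                f"record length {length} incompatible with "
                f"{cfg.n_patches} patches of {cfg.patch_len} samples")
        patches = (wf.reshape(b, leads, cfg.n_patches, cfg.patch_len)
                   .transpose(0, 2, 1, 3)
                   .reshape(b, cfg.n_patches, leads * cfg.patch_len))
        return self.patch_proj(Tensor(patches))

    def embed_feature_token(self, features: np.ndarray,
                            masks: np.ndarray) -> Tensor:
        """(B, 9) values + (B, 9) mask bits -> (B, 1, D) feature token."""
        f = np.atleast_2d(np.asarray(features, dtype=np.float32))
        m = np.atleast_2d(np.asarray(masks, dtype=np.float32))
        if f.shape[1] != self.config.n_features or m.shape != f.shape:
            raise ValueError("expected 9 feature values and 9 mask bits")
        x = np.concatenate([f, m], axis=1)[:, None, :]
        return self.feature_embed(Tensor(x))

    def embed_metadata(self, age_norm: np.ndarray,
                       sex: np.ndarray) -> list[Tensor]:
        """Normalized age + sex code -> list of (B, 1, D) metadata tokens."""
        a = np.atleast_1d(np.asarray(age_norm, dtype=np.float32))
        s = np.atleast_1d(np.asarray(sex))
        if not np.all(np.isin(s, (0, 1))):
            raise ValueError("sex code must be 0 or 1")
        tokens = [self.age_embed(Tensor(a[:, None, None]))]
        if self.config.metadata_tokens == 2:
            tokens.append(self.sex_embed(
                Tensor(s.astype(np.float32)[:, None, None])))
        return tokens[: self.config.metadata_tokens]

    # -- assembly and encoding ----------------------------------------------
    def assemble_sequence(self, fused: Tensor, patch_tokens: Tensor,
                          metadata: list[Tensor]) -> Tensor:
        """[CLS, fusion, patches..., metadata...] + positional embeddings."""
        b = patch_tokens.shape[0]
        cls = self.cls_token + Tensor(np.zeros((b, 1, 1), dtype=np.float32))
        seq = concat([cls, fused, patch_tokens] + metadata, axis=1)
        pos = self.pos_embed[:, : seq.shape[1], :]
        return seq + pos

    def encode(self, seq: Tensor) -> Tensor:
        rng = self._dropout_rng if self.training else None
        rate = self.config.dropout if self.training else 0.0
        x = seq
        for i in range(self.config.n_layers):
            x = getattr(self, f"block{i}")(x, rate, rng)
        if self.config.n_layers == 0:
            return x
        return self.final_ln(x)

    def classify(self, encoded: Tensor) -> Tensor:
        """Linear head on the CLS state (position 0) -> (B, 13) logits."""
        return self.head(encoded[:, 0, :])

    # -- end to end -----------------------------------------------------------
    def forward(self, waveform, features, masks, age_norm, sex,
                mode: str = "full", with_aux: bool = False):
        """Run the full model; returns ``(logits (B,13), attention (B,Np))``.

        Modes: ``full`` uses every modality; ``feature_masked`` zeroes the
        structured values *and* their mask bits at inference (weights
        untouched); ``without_age_sex`` drops the metadata tokens (the
        train-time demographic ablation).

        ``with_aux=True`` (training only) additionally returns auxiliary
        logits read directly off the fusion token.
        """
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        f = np.atleast_2d(np.asarray(features, dtype=np.float32))
        m = np.atleast_2d(np.asarray(masks, dtype=np.float32))
        if mode == "feature_masked":
            f = np.zeros_like(f)
            m = np.zeros_like(m)
        patch_tokens = self.embed_patches(waveform)
        feature_token = self.embed_feature_token(f, m)
        fused, attn = self.fusion(feature_token, patch_tokens)
        metadata = [] if mode == "without_age_sex" \
            else self.embed_metadata(age_norm, sex)
        seq = self.assemble_sequence(fused, patch_tokens, metadata)
        encoded = self.encode(seq)
        logits = self.classify(encoded)
        if with_aux:
            aux_logits = self.aux_head(fused[:, 0, :])
            return logits, attn.data[:, 0, :], aux_logits, attn
        return logits, attn.data[:, 0, :]

    def predict_proba_batch(self, waveform, features, masks, age_norm, sex,
                            mode: str = "full"):
        """Inference helper: sigmoid probabilities + attention, no tape."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits, attn = self.forward(waveform, features, masks,
                                            age_norm, sex, mode)
            return predict_proba(logits.data), attn
        finally:
            self.train(was_training)


def predict_proba(logits) -> np.ndarray:
    """Element-wise sigmoid of the 13 logits."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    from campnet.nn.tensor import _sigmoid
    return _sigmoid(z.astype(np.float32))


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, model: CaMPNet, stats: Optional[TrainStats] = None,
                    extra: Optional[dict] = None) -> None:
    """Serialize weights + config + normalization stats + label list.

    Self-describing: ``load_checkpoint`` rebuilds the model without any
    other context. Stored as a numpy ``.npz`` with a JSON metadata entry.
    """
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "labels": list(CANONICAL_LABELS),
        "train_stats": stats.to_dict() if stats is not None else None,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Returns ``(model, train_stats, meta)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: "
                             f"{meta.get('version')}")
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    model = CaMPNet(config)
    model.load_state_dict(state)
    model.eval()
    stats = (TrainStats.from_dict(meta["train_stats"])
             if meta["train_stats"] else None)
    return model, stats, meta


def weighted_bce_loss(logits: Tensor, labels: np.ndarray,
                      pos_weight: Optional[np.ndarray] = None) -> Tensor:
    """Class-imbalance-aware BCE (see :mod:`campnet.training`)."""
    return bce_with_logits(logits, labels, pos_weight)
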