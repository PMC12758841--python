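"""Attention-based interpretability.

The fusion cross-attention row (one weight per ECG patch) is mapped to
time-anchored waveform segments: patch ``i`` covers samples
``[i * patch_len, (i+1) * patch_len)``. Exported overlays list every
per-lead trace plus the segments whose attention exceeds a quantile
cutoff — the data behind shaded-band heatmap figures.

Only the single fusion cross-attention is visualized, not encoder
self-attention rollout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from campnet.labels import LEAD_NAMES
from campnet.model import CaMPNet
from campnet.nn.tensor import no_grad

__all__ = ["SegmentAttribution", "extract_attention",
           "attention_to_segments", "export_heatmap"]


@dataclass
class SegmentAttribution:
    """Per-patch attention weights anchored to sample/time windows."""

    segments: pd.DataFrame   # patch, start_sample, end_sample,
    #                          start_s, end_s, weight
    record_id: str = ""
    mode: str = "full"

    @property
    def weights(self) -> np.ndarray:
        return self.segments["weight"].to_numpy()


def extract_attention(model: CaMPNet, waveform, features, masks,
                      age_norm, sex, mode: str = "full") -> np.ndarray:
    """Fusion attention row(s) for preprocessed record(s), eval mode.

    Returns shape (Np,) for a single record, (B, Np) for a batch.
    """
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            _, attn = model.forward(waveform, features, masks,
                                    age_norm, sex, mode=mode)
    finally:
        model.train(was_training)
    return attn[0] if attn.shape[0] == 1 and np.ndim(waveform) == 2 else attn


def attention_to_segments(attention: np.ndarray, patch_len: int,
                          sampling_rate: int, record_id: str = "",
                          mode: str = "full") -> SegmentAttribution:
    """Map a (Np,) attention row to non-overlapping waveform segments."""
    w = np.asarray(attention, dtype=np.float64).ravel()
    idx = np.arange(len(w))
    start = idx * patch_len
    end = start + patch_len
    df = pd.DataFrame({
        "patch": idx,
        "start_sample": start,
        "end_sample": end,
        "start_s": start / sampling_rate,
        "end_s": end / sampling_rate,
        "weight": w,
    })
    return SegmentAttribution(df, record_id, mode)


def highlighted_patches(weights: np.ndarray, quantile: float = 0.8,
                        top_k: Optional[int] = None) -> np.ndarray:
    """Indices of the highlighted segments, sorted by descending weight.

    By default the top ``1 - quantile`` share of patches (20%) is kept:
    exactly ``ceil((1 - quantile) * Np)`` segments, ties broken by earliest
    patch index. Invariant to rescaling all weights by a constant.
    """
    w = np.asarray(weights, dtype=np.float64)
    k = top_k if top_k is not None else int(np.ceil((1.0 - quantile) * len(w)))
    k = max(min(k, len(w)), 0)
    order = np.argsort(-w, kind="stable")  # stable: earliest index wins ties
    return order[:k]


def export_heatmap(waveform: np.ndarray, attribution: SegmentAttribution,
                   quantile: float = 0.8, top_k: Optional[int] = None,
                   out_dir=None, figure_path=None) -> dict:
    """Overlay data: per-lead traces + the highlighted segment table.

    Pure data export; when ``out_dir`` is given, writes ``traces.csv`` and
    ``segments.csv`` there. ``figure_path`` optionally renders a matplotlib
    figure (requires the plotting extra).
    """
    wf = np.asarray(waveform, dtype=np.float32)
    n_patches = len(attribution.segments)
    patch_len = int(attribution.segments["end_sample"].iloc[0]
                    - attribution.segments["start_sample"].iloc[0])
    if wf.shape != (len(LEAD_NAMES), n_patches * patch_len):
        raise ValueError("attribution does not match the waveform shape")
    keep = highlighted_patches(attribution.weights, quantile, top_k)
    seg = attribution.segments.copy()
    seg["highlighted"] = seg["patch"].isin(keep)
    traces = pd.DataFrame(wf.T, columns=list(LEAD_NAMES))
    traces.insert(0, "sample", np.arange(wf.shape[1]))
    out = {"traces": traces, "segments": seg,
           "highlighted": np.sort(keep), "record_id": attribution.record_id,
           "mode": attribution.mode}
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traces.to_csv(out_dir / "traces.csv", index=False)
        seg.to_csv(out_dir / "segments.csv", index=False)
    if figure_path is not None:
        _render_figure(wf, seg, figure_path)
    return out


def _render_figure(wf: np.ndarray, segments: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(LEAD_NAMES), 1, sharex=True,
                             figsize=(10, 16))
    wmax = segments["weight"].max() or 1.0
    for ax, lead, trace in zip(axes, LEAD_NAMES, wf):
        ax.plot(trace, lw=0.5, color="black")
        ax.set_ylabel(lead, rotation=0, labelpad=15)
        for _, row in segments[segments["highlighted"]].iterrows():
            ax.axvspan(row["start_sample"], row["end_sample"],
                       alpha=0.35 * float(row["weight"]) / wmax + 0.1,
                       color="tab:red", lw=0)
    axes[-1].set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
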