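"""Canonical diagnostic label vocabulary.

Thirteen categories: one "Normal" rhythm class plus twelve cardiovascular
disease classes. The order is fixed and shared by every module — multihot
vectors, class weights, logits and metric tables all index labels this way.
"""

from __future__ import annotations

CANONICAL_LABELS: tuple[str, ...] = (
    "Atrial fibrillation",
    "Aortic stenosis or insufficiency",
    "Atrioventricular block",
    "Cardiac arrest",
    "Hypertrophic cardiomyopathy",
    "Heart failure",
    "Mitral valve prolapse or stenosis",
    "Normal",
    "Pulmonary embolism",
    "Pulmonary hypertension",
    "ST-elevation or non-ST-elevation myocardial infarction",
    "Supraventricular or ventricular tachycardia",
    "Unstable angina",
)

N_LABELS = len(CANONICAL_LABELS)

NORMAL_INDEX = CANONICAL_LABELS.index("Normal")

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CANONICAL_LABELS)}

#: Standard 12-lead montage, also the required column order of waveform CSVs.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = len(LEAD_NAMES)

LEAD_INDEX: dict[str, int] = {name: i for i, name in enumerate(LEAD_NAMES)}


def encode_labels(names) -> "np.ndarray":
    """Encode a collection of label names as a 13-bit multihot vector.

    Unknown names raise ``ValueError`` naming the offender. An empty
    collection yields the all-zero vector (the cohort generator forbids
    label-free records upstream, but encoding itself permits them).
    """
    import numpy as np

    vec = np.zeros(N_LABELS, dtype=np.int8)
    for name in names:
        if name not in LABEL_INDEX:
            raise ValueError(f"unknown diagnostic label: {name!r}")
        vec[LABEL_INDEX[name]] = 1
    return vec


def decode_labels(multihot) -> list[str]:
    """Inverse of :func:`encode_labels`: multihot vector -> label names."""
    if len(multihot) != N_LABELS:
        raise ValueError(f"expected {N_LABELS} bits, got {len(multihot)}")
    return [CANONICAL_LABELS[i] for i, bit in enumerate(multihot) if bit]
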