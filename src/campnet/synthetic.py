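"""Seeded synthetic multimodal ECG cohort generator.

Emulates the data model of a large hospital ECG archive: per record a
12-lead waveform (10 s at 500 Hz), nine machine-measured structured
features with a validity mask, age and sex, a multihot diagnostic vector
over the canonical 13 categories, and a strictly increasing acquisition
timestamp.

Waveforms are stylized, not physiologic: each beat is a sum of Gaussian
bumps (P, Q, R, S, T) on a shared template, projected onto the 12 leads by
per-lead gain factors, plus additive Gaussian noise. Disease labels plant
*signatures* — parameter- or signal-level perturbations such as an
ST-segment offset confined to known sample windows — so that tests can
verify both recoverability (a classifier can learn the labels) and
localization (attention concentrates on the perturbed windows).

Structured features are derived from generator ground truth (the beat
parameters after signatures are applied), never re-measured from the
rendered signal, so feature-level oracles are exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm as _norm

from campnet.labels import (
    CANONICAL_LABELS,
    LEAD_INDEX,
    LEAD_NAMES,
    N_LABELS,
    N_LEADS,
    NORMAL_INDEX,
)

#: Default schema of the 9 machine-measured features (interval timings,
#: electrical axes and rate — the convention of hospital acquisition systems).
FEATURE_NAMES: tuple[str, ...] = (
    "rr_interval",      # s
    "pr_interval",      # s
    "qrs_duration",     # s
    "qt_interval",      # s
    "qtc_interval",     # s, Bazett: qt / sqrt(rr)
    "p_axis",           # degrees
    "qrs_axis",         # degrees
    "t_axis",           # degrees
    "ventricular_rate", # beats/min, 60 / rr
)

N_FEATURES = len(FEATURE_NAMES)

SIGNATURE_EFFECTS = (
    "st_offset", "rr_irregular", "pr_prolong",
    "qrs_widen", "amplitude_drop", "p_suppress",
)

#: Prevalence of each canonical label in the emulated archive (fractions of
#: records carrying the label; Normal is mutually exclusive with disease).
DEFAULT_PREVALENCE: tuple[float, ...] = (
    0.322,  # Atrial fibrillation
    0.051,  # Aortic stenosis or insufficiency
    0.047,  # Atrioventricular block
    0.020,  # Cardiac arrest
    0.056,  # Hypertrophic cardiomyopathy
    0.319,  # Heart failure
    0.049,  # Mitral valve prolapse or stenosis
    0.394,  # Normal
    0.022,  # Pulmonary embolism
    0.075,  # Pulmonary hypertension
    0.117,  # ST-elevation or non-ST-elevation myocardial infarction
    0.065,  # Supraventricular or ventricular tachycardia
    0.034,  # Unstable angina
)

# Baseline per-lead gain of the beat template (dimensionless; aVR inverted).
_BASE_PROJECTION = np.array(
    [0.6, 1.0, 0.5, -0.7, 0.25, 0.75, 0.4, 0.7, 0.9, 1.0, 0.9, 0.7],
    dtype=np.float32,
)

_WAVE_ORDER = ("P", "Q", "R", "S", "T")

# Duration of the flat ST segment modelled between QRS offset and T onset.
ST_SEGMENT_LEN = 0.08  # seconds

# ST offsets decay across the T region over this interval (see
# render_waveform); the full support of an st_offset perturbation is the
# ST window plus this tail.
ST_DECAY_LEN = 0.12  # seconds


def st_offset_support(st_windows: np.ndarray, sampling_rate: int,
                      record_len: int) -> np.ndarray:
    """Sample windows [start, end) actually perturbed by an ST offset.

    Extends each ST window by the decay tail, clipped to the record.
    """
    w = np.asarray(st_windows)
    tail = int(round(ST_DECAY_LEN * sampling_rate))
    return np.stack([w[:, 0], np.minimum(w[:, 1] + tail, record_len)], axis=1)


@dataclass(frozen=True)
class BeatParams:
    """Ground-truth parameters of one record's repeating beat."""

    rr_mean: float = 0.8            # s
    rr_jitter_cv: float = 0.02      # coefficient of variation of RR
    pr_interval: float = 0.16       # s, P onset to QRS onset
    qrs_duration: float = 0.10      # s
    qt_interval: float = 0.40       # s, QRS onset to T end
    wave_amplitudes: dict = field(default_factory=lambda: {
        "P": 0.15, "Q": -0.10, "R": 1.0, "S": -0.25, "T": 0.30,  # mV
    })
    lead_projection: np.ndarray = field(
        default_factory=lambda: _BASE_PROJECTION.copy())

    def __post_init__(self):
        if not self.rr_mean > 0:
            raise ValueError("rr_mean must be positive")
        if self.rr_jitter_cv < 0:
            raise ValueError("rr_jitter_cv must be non-negative")
        if not (self.pr_interval + self.qrs_duration + self.qt_interval
                < self.rr_mean):
            raise ValueError("beat components must fit inside one RR interval")
        proj = np.asarray(self.lead_projection, dtype=np.float32)
        if proj.shape != (N_LEADS,) or not np.all(np.isfinite(proj)):
            raise ValueError("lead_projection must be 12 finite gains")
        object.__setattr__(self, "lead_projection", proj)


@dataclass(frozen=True)
class SignatureSpec:
    """A plantable, label-linked perturbation of the beat or the signal."""

    label_name: str
    effect: str
    magnitude: float
    target_leads: tuple[str, ...] = LEAD_NAMES
    time_window: str = "st"   # only signal-level effects consult this

    def __post_init__(self):
        if self.label_name not in CANONICAL_LABELS:
            raise ValueError(f"unknown label {self.label_name!r}")
        if self.effect not in SIGNATURE_EFFECTS:
            raise ValueError(f"unknown signature effect {self.effect!r}")
        if not math.isfinite(self.magnitude):
            raise ValueError("signature magnitude must be finite")
        if not self.target_leads:
            raise ValueError("target_leads must be non-empty")
        for lead in self.target_leads:
            if lead not in LEAD_INDEX:
                raise ValueError(f"unknown lead {lead!r}")


#: Stylized disease -> signature map applied by :func:`generate_cohort`.
LABEL_SIGNATURES: dict[str, tuple[SignatureSpec, ...]] = {
    "Atrial fibrillation": (
        SignatureSpec("Atrial fibrillation", "rr_irregular", 0.25),
        SignatureSpec("Atrial fibrillation", "p_suppress", 1.0),
    ),
    "Aortic stenosis or insufficiency": (
        SignatureSpec("Aortic stenosis or insufficiency", "amplitude_drop",
                      -0.30, ("I", "aVL", "V5", "V6")),
    ),
    "Atrioventricular block": (
        SignatureSpec("Atrioventricular block", "pr_prolong", 0.10),
    ),
    "Cardiac arrest": (
        SignatureSpec("Cardiac arrest", "amplitude_drop", 0.60),
    ),
    "Hypertrophic cardiomyopathy": (
        SignatureSpec("Hypertrophic cardiomyopathy", "amplitude_drop",
                      -0.40, ("V1", "V2", "V3", "V4", "V5", "V6")),
    ),
    "Heart failure": (
        SignatureSpec("Heart failure", "amplitude_drop", 0.35),
        SignatureSpec("Heart failure", "qrs_widen", 0.02),
    ),
    "Mitral valve prolapse or stenosis": (
        SignatureSpec("Mitral valve prolapse or stenosis", "p_suppress", -0.6),
    ),
    "Pulmonary embolism": (
        SignatureSpec("Pulmonary embolism", "st_offset", -0.08,
                      ("II", "III", "aVF")),
    ),
    "Pulmonary hypertension": (
        SignatureSpec("Pulmonary hypertension", "amplitude_drop",
                      -0.30, ("V1", "V2")),
        SignatureSpec("Pulmonary hypertension", "p_suppress", -0.4),
    ),
    "ST-elevation or non-ST-elevation myocardial infarction": (
        SignatureSpec("ST-elevation or non-ST-elevation myocardial infarction",
                      "st_offset", 0.20, ("V1", "V2", "V3", "V4")),
    ),
    "Supraventricular or ventricular tachycardia": (
        SignatureSpec("Supraventricular or ventricular tachycardia",
                      "qrs_widen", 0.06),
    ),
    "Unstable angina": (
        SignatureSpec("Unstable angina", "st_offset", -0.10,
                      ("V4", "V5", "V6")),
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    n_records: int = 1000
    prevalence: tuple[float, ...] = DEFAULT_PREVALENCE
    cooccurrence: Optional[np.ndarray] = None  # 12x12 copula correlation
    age_mean: float = 64.8
    age_sd: float = 17.0
    male_fraction: float = 0.524
    missingness_rate: float = 0.05
    seed: int = 0
    sampling_rate: int = 500
    record_len: int = 5000
    noise_sd: float = 0.05  # mV additive Gaussian noise on each lead
    baseline_wander: float = 0.08  # mV slow respiratory/motion drift amplitude

    def __post_init__(self):
        prev = tuple(float(p) for p in self.prevalence)
        if len(prev) != N_LABELS:
            raise ValueError(f"prevalence must have {N_LABELS} entries")
        if any(p < 0 or p > 1 for p in prev):
            raise ValueError("prevalences must lie in [0, 1]")
        if not 0 <= self.missingness_rate <= 1:
            raise ValueError("missingness_rate must lie in [0, 1]")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        object.__setattr__(self, "prevalence", prev)


@dataclass
class StructuredFeatures:
    """Nine machine-measured values plus a binary validity mask."""

    values: np.ndarray          # (9,) float32; missing entries are 0
    mask: np.ndarray            # (9,) int8; 1 = measured, 0 = missing
    schema: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.values.shape != (len(self.schema),):
            raise ValueError("values length must match schema")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask length must match values")


@dataclass
class Cohort:
    """In-memory cohort bundle."""

    waveforms: np.ndarray        # (n, 12, record_len) float32, mV
    features: np.ndarray         # (n, 9) float32
    masks: np.ndarray            # (n, 9) int8
    ages: np.ndarray             # (n,) float32, years
    sexes: np.ndarray            # (n,) int8, 1 = male, 0 = female
    labels: np.ndarray           # (n, 13) int8 multihot
    timestamps: np.ndarray       # (n,) int64, strictly increasing
    record_ids: list[str]
    config: CohortConfig
    beats: list[BeatParams]                  # post-signature ground truth
    st_windows: list[np.ndarray]             # per record, (n_beats, 2) samples

    @property
    def n_records(self) -> int:
        return len(self.record_ids)


# --------------------------------------------------------------------------
# demographics and labels
# --------------------------------------------------------------------------

def sample_demographics(n: int, config: CohortConfig,
                        rng: Optional[np.random.Generator] = None):
    """Draw ages ~ Normal(mean, sd) clipped to [18, 100] and sexes ~ Bernoulli."""
    if n < 1:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ages = rng.normal(config.age_mean, config.age_sd, n)
    ages = np.clip(ages, 18.0, 100.0).astype(np.float32)
    sexes = (rng.random(n) < config.male_fraction).astype(np.int8)
    return ages, sexes


def _calibrate_label_model(prevalence: Sequence[float]):
    """Solve for sampling probabilities whose *post*-conditioning marginals
    (Normal exclusive with disease, empty rows resampled) hit the targets.

    Returns ``(p_normal, q_disease)`` where ``q_disease`` are conditional
    disease probabilities given a non-Normal row.
    """
    t = np.asarray(prevalence, dtype=np.float64)
    t_norm = t[NORMAL_INDEX]
    t_dis = np.delete(t, NORMAL_INDEX)
    if t.sum() <= 0:
        raise ValueError("at least one label needs positive prevalence")
    if t.sum() <= 1.0 + 1e-9:
        # with >= 1 label per record the mean label count is >= 1, so
        # targets summing below 1 cannot all be met; sample uncalibrated
        if t.sum() < 1.0 - 1e-9:
            warnings.warn("prevalence targets sum below 1; empirical "
                          "frequencies will exceed targets after "
                          "empty-row resampling", RuntimeWarning)
        denom = max(1.0 - t_norm, 1e-12)
        return t_norm, np.clip(t_dis / denom, 0.0, 1.0)
    K = 1.0
    p_n, q = t_norm, t_dis.copy()
    for _ in range(200):
        p_n = min(t_norm * K, 1.0)
        denom = max(1.0 - p_n, 1e-12)
        q = np.clip(t_dis * K / denom, 0.0, 1.0)
        z = np.prod(1.0 - q)
        K_new = p_n + (1.0 - p_n) * (1.0 - z)
        if abs(K_new - K) < 1e-12:
            K = K_new
            break
        K = K_new
    if np.any(t_dis * K / max(1.0 - p_n, 1e-12) > 1.0):
        warnings.warn("prevalence targets not jointly attainable; clipped",
                      RuntimeWarning)
    return p_n, q


def sample_labels(n: int, config: CohortConfig,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw an (n, 13) multihot label matrix.

    Disease labels are independent Bernoulli draws (or coupled through a
    Gaussian copula when ``config.cooccurrence`` is set); "Normal" is
    mutually exclusive with every disease label; rows that come out empty
    are resampled. Sampling probabilities are pre-calibrated so the
    *post-conditioning* marginal frequencies converge to the configured
    prevalences.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_n, q = _calibrate_label_model(config.prevalence)
    disease_idx = [i for i in range(N_LABELS) if i != NORMAL_INDEX]
    labels = np.zeros((n, N_LABELS), dtype=np.int8)
    pending = np.arange(n)
    copula = config.cooccurrence
    if copula is not None:
        copula = np.asarray(copula, dtype=np.float64)
        if copula.shape != (len(q), len(q)):
            raise ValueError("cooccurrence must be 12x12")
        chol = np.linalg.cholesky(copula)
        thresh = _norm.ppf(q)
    for _ in range(1000):
        m = len(pending)
        if m == 0:
            break
        is_normal = rng.random(m) < p_n
        if copula is None:
            dis = rng.random((m, len(q))) < q
        else:
            zmat = rng.standard_normal((m, len(q))) @ chol.T
            dis = zmat < thresh
        dis[is_normal] = False
        block = np.zeros((m, N_LABELS), dtype=np.int8)
        block[:, disease_idx] = dis.astype(np.int8)
        block[is_normal, NORMAL_INDEX] = 1
        labels[pending] = block
        pending = pending[block.sum(axis=1) == 0]
    else:  # pragma: no cover - requires pathological prevalences
        raise RuntimeError("failed to sample non-empty label rows")
    return labels


# --------------------------------------------------------------------------
# signatures and waveform rendering
# --------------------------------------------------------------------------

def apply_signatures(beat: BeatParams,
                     signatures: Sequence[SignatureSpec]) -> BeatParams:
    """Fold all parameter-level signature effects into a new BeatParams.

    Effects compose additively (or multiplicatively for amplitude scalings);
    overlapping effects on the same quantity simply stack, with a warning.
    Signal-level effects (``st_offset``) are ignored here — they act at
    render time.
    """
    touched: dict[str, int] = {}
    cv = beat.rr_jitter_cv
    pr = beat.pr_interval
    qrs = beat.qrs_duration
    amps = dict(beat.wave_amplitudes)
    proj = beat.lead_projection.copy()
    for sig in signatures:
        if sig.effect == "st_offset":
            continue
        touched[sig.effect] = touched.get(sig.effect, 0) + 1
        if sig.effect == "rr_irregular":
            cv += sig.magnitude
        elif sig.effect == "pr_prolong":
            pr += sig.magnitude
        elif sig.effect == "qrs_widen":
            qrs += sig.magnitude
        elif sig.effect == "p_suppress":
            amps["P"] = amps["P"] * (1.0 - sig.magnitude)
        elif sig.effect == "amplitude_drop":
            idx = [LEAD_INDEX[name] for name in sig.target_leads]
            proj[idx] *= np.float32(1.0 - sig.magnitude)
    for effect, count in touched.items():
        if count > 1:
            warnings.warn(f"{count} overlapping {effect!r} signatures "
                          "compose additively", RuntimeWarning)
    # interval prolongation may no longer fit the RR interval: slow the
    # rate accordingly (a prolonged PR with preserved QT implies bradycardia)
    rr = max(beat.rr_mean, pr + qrs + beat.qt_interval + 0.06)
    return replace(beat, rr_mean=rr, rr_jitter_cv=max(cv, 0.0),
                   pr_interval=pr, qrs_duration=qrs, wave_amplitudes=amps,
                   lead_projection=proj)


def _beat_onsets(beat: BeatParams, duration: float,
                 rng: np.random.Generator) -> np.ndarray:
    """P-wave onset times of successive beats covering ``duration`` seconds."""
    onsets = []
    t = 0.05
    while t < duration:
        onsets.append(t)
        rr = beat.rr_mean * max(1.0 + beat.rr_jitter_cv * rng.standard_normal(),
                                0.3)
        t += rr
    return np.asarray(onsets)


def _wave_layout(beat: BeatParams):
    """Per-wave (center offset from beat onset, width sigma, amplitude)."""
    pr, qrs, qt = beat.pr_interval, beat.qrs_duration, beat.qt_interval
    a = beat.wave_amplitudes
    return {
        "P": (0.04, 0.025, a["P"]),
        "Q": (pr + 0.15 * qrs, 0.08 * qrs, a["Q"]),
        "R": (pr + 0.50 * qrs, 0.11 * qrs, a["R"]),
        "S": (pr + 0.85 * qrs, 0.08 * qrs, a["S"]),
        "T": (pr + max(qt - 0.12, qrs + ST_SEGMENT_LEN + 0.02), 0.06, a["T"]),
    }


def st_window_bounds(beat: BeatParams, onsets: np.ndarray,
                     sampling_rate: int, record_len: int) -> np.ndarray:
    """Sample windows [start, end) of the ST segment of each beat."""
    start_t = onsets + beat.pr_interval + beat.qrs_duration
    end_t = start_t + ST_SEGMENT_LEN
    start = np.round(start_t * sampling_rate).astype(int)
    end = np.round(end_t * sampling_rate).astype(int)
    keep = (start < record_len) & (end > start)
    return np.stack([start[keep], np.minimum(end[keep], record_len)], axis=1)


def render_waveform(beat: BeatParams, signatures: Sequence[SignatureSpec],
                    seed, *, record_len: int = 5000, sampling_rate: int = 500,
                    noise_sd: float = 0.0, baseline_wander: float = 0.0,
                    return_windows: bool = False):
    """Render a 12 x record_len waveform in millivolts.

    The beat template is a sum of Gaussian bumps projected onto the 12
    leads; ``st_offset`` signatures add their magnitude on their target
    leads inside each beat's ST window; ``baseline_wander`` adds per-lead
    slow sinusoidal drift (respiration/motion, 0.15-0.5 Hz), which also
    keeps a constant segment offset from degenerating into a global
    lead-mean shift under later per-lead normalization. ``seed`` may be an
    int or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    eff = apply_signatures(beat, signatures)
    duration = record_len / sampling_rate
    onsets = _beat_onsets(eff, duration, rng)
    t_axis = np.arange(record_len, dtype=np.float32) / sampling_rate
    template = np.zeros(record_len, dtype=np.float32)
    layout = _wave_layout(eff)
    for _, (offset, sigma, amp) in layout.items():
        if amp == 0.0:
            continue
        for t0 in onsets:
            c = t0 + offset
            lo = max(int((c - 4 * sigma) * sampling_rate), 0)
            hi = min(int((c + 4 * sigma) * sampling_rate) + 1, record_len)
            if hi <= lo:
                continue
            tt = t_axis[lo:hi] - c
            template[lo:hi] += amp * np.exp(-0.5 * (tt / sigma) ** 2)
    wf = np.outer(eff.lead_projection, template).astype(np.float32)
    if baseline_wander > 0:
        freqs = rng.uniform(0.15, 0.5, (N_LEADS, 2))
        phases = rng.uniform(0, 2 * np.pi, (N_LEADS, 2))
        amps = baseline_wander * rng.uniform(0.5, 1.0, (N_LEADS, 2))
        for lead in range(N_LEADS):
            drift = (amps[lead, 0] * np.sin(2 * np.pi * freqs[lead, 0] * t_axis
                                            + phases[lead, 0])
                     + amps[lead, 1] * np.sin(2 * np.pi * freqs[lead, 1]
                                              * t_axis + phases[lead, 1]))
            wf[lead] += drift.astype(np.float32)
    st = st_window_bounds(eff, onsets, sampling_rate, record_len)
    # ST offsets are flat across the ST window, then decay smoothly across
    # the T wave (elevation merges into repolarization rather than snapping
    # back to baseline mid-beat, which would plant a spurious notch)
    decay_len = int(round(ST_DECAY_LEN * sampling_rate))
    for sig in signatures:
        if sig.effect != "st_offset":
            continue
        idx = [LEAD_INDEX[name] for name in sig.target_leads]
        for a, b in st:
            wf[np.ix_(idx, range(a, b))] += np.float32(sig.magnitude)
            tail = min(decay_len, record_len - b)
            if tail > 0:
                ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(tail) / decay_len))
                wf[np.ix_(idx, range(b, b + tail))] += \
                    np.float32(sig.magnitude) * ramp.astype(np.float32)
    if noise_sd > 0:
        wf += rng.normal(0.0, noise_sd, wf.shape).astype(np.float32)
    if return_windows:
        return wf, st
    return wf


# --------------------------------------------------------------------------
# structured features
# --------------------------------------------------------------------------

def derive_structured_features(beat: BeatParams,
                               signatures: Sequence[SignatureSpec] = ()
                               ) -> StructuredFeatures:
    """Compute the 9-feature vector exactly from generator ground truth."""
    eff = apply_signatures(beat, signatures)
    axis = math.degrees(math.atan2(eff.lead_projection[LEAD_INDEX["aVF"]],
                                   eff.lead_projection[LEAD_INDEX["I"]]))
    values = np.array([
        eff.rr_mean,
        eff.pr_interval,
        eff.qrs_duration,
        eff.qt_interval,
        eff.qt_interval / math.sqrt(eff.rr_mean),
        axis,
        axis,
        axis,
        60.0 / eff.rr_mean,
    ], dtype=np.float32)
    return StructuredFeatures(values, np.ones(N_FEATURES, dtype=np.int8))


def inject_missingness(features: StructuredFeatures, rate: float,
                       seed) -> StructuredFeatures:
    """Independently drop each feature with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    missing = rng.random(len(features.values)) < rate
    values = features.values.copy()
    mask = features.mask.copy()
    values[missing] = 0.0
    mask[missing] = 0
    return StructuredFeatures(values, mask, features.schema)


# --------------------------------------------------------------------------
# full cohort
# --------------------------------------------------------------------------

def _sample_beat(rng: np.random.Generator) -> BeatParams:
    """Per-record baseline beat with mild physiological variation."""
    amps = {
        "P": 0.15 * float(np.exp(rng.normal(0.0, 0.1))),
        "Q": -0.10 * float(np.exp(rng.normal(0.0, 0.1))),
        "R": 1.0 * float(np.exp(rng.normal(0.0, 0.08))),
        "S": -0.25 * float(np.exp(rng.normal(0.0, 0.1))),
        "T": 0.30 * float(np.exp(rng.normal(0.0, 0.1))),
    }
    proj = _BASE_PROJECTION * np.exp(
        rng.normal(0.0, 0.05, N_LEADS)).astype(np.float32)
    proj[3] = -abs(proj[3])  # aVR stays inverted
    rr = float(np.clip(rng.normal(0.8, 0.08), 0.55, 1.15))
    pr = float(np.clip(rng.normal(0.16, 0.01), 0.12, 0.20))
    qrs = float(np.clip(rng.normal(0.10, 0.008), 0.07, 0.12))
    # rate-adapted QT keeps the beat inside one RR interval at fast rates
    qt = float(np.clip(rng.normal(0.40, 0.02), 0.33, 0.46)) * math.sqrt(rr / 0.8)
    rr = max(rr, pr + qrs + qt + 0.06)
    return BeatParams(
        rr_mean=rr,
        rr_jitter_cv=0.02,
        pr_interval=pr,
        qrs_duration=qrs,
        qt_interval=qt,
        wave_amplitudes=amps,
        lead_projection=proj,
    )


def signatures_for_labels(label_row: np.ndarray) -> list[SignatureSpec]:
    """All signatures planted for a multihot label row."""
    sigs: list[SignatureSpec] = []
    for i, bit in enumerate(label_row):
        if bit and i != NORMAL_INDEX:
            sigs.extend(LABEL_SIGNATURES.get(CANONICAL_LABELS[i], ()))
    return sigs


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete, seeded, label-consistent multimodal cohort.

    The same config (including seed) always yields a bit-identical bundle.
    Timestamps are strictly increasing, supporting the chronological split.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    ages, sexes = sample_demographics(n, config, rng)
    labels = sample_labels(n, config, rng)
    increments = rng.integers(60, 3600, size=n)
    timestamps = (1_600_000_000 + np.cumsum(increments)).astype(np.int64)

    waveforms = np.empty((n, N_LEADS, config.record_len), dtype=np.float32)
    feats = np.empty((n, N_FEATURES), dtype=np.float32)
    masks = np.empty((n, N_FEATURES), dtype=np.int8)
    beats: list[BeatParams] = []
    st_windows: list[np.ndarray] = []
    for i in range(n):
        base = _sample_beat(rng)
        sigs = signatures_for_labels(labels[i])
        with warnings.catch_warnings():
            # comorbid rows legitimately stack same-kind signatures
            warnings.filterwarnings("ignore", message=".*compose additively",
                                    category=RuntimeWarning)
            wf, st = render_waveform(
                base, sigs, rng, record_len=config.record_len,
                sampling_rate=config.sampling_rate, noise_sd=config.noise_sd,
                baseline_wander=config.baseline_wander, return_windows=True)
            waveforms[i] = wf
            st_windows.append(st)
            beats.append(apply_signatures(base, sigs))
            sf = derive_structured_features(base, sigs)
        sf = inject_missingness(sf, config.missingness_rate, rng)
        feats[i] = sf.values
        masks[i] = sf.mask
    record_ids = [f"rec{i:06d}" for i in range(n)]
    return Cohort(waveforms, feats, masks, ages, sexes, labels, timestamps,
                  record_ids, config, beats, st_windows)
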