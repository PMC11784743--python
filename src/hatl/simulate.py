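"""Synthetic multimodal datasets with controllable cross-modal structure.

A linear-Gaussian latent-factor model stands in for real recordings: each
window draws a class-conditional latent state u ~ N(mu_class, I); the non-EEG
features observe u through a fixed mixing matrix plus sensor noise, and the
EEG features observe a *coupling*-weighted mixture of the same latent and an
independent source. Coupling therefore dials how much information the non-EEG
modality carries about EEG — the quantity the adversarial generator must
exploit. Per-subject additive offsets emulate inter-subject variability.

Also provides band-limited Gaussian noise recordings as fixtures for the
feature-extraction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import FeatureSchema, MultimodalDataset, get_profile
from .features import RawRecording

__all__ = ["SimConfig", "simulate_multimodal_features", "simulate_raw_recording"]


@dataclass
class SimConfig:
    """Generative settings for :func:`simulate_multimodal_features`.

    Defaults emulate a strongly coupled multimodal recording: most EEG
    variance is explained by the latent state shared with the non-EEG
    channels (coupling 0.9), EEG sensor noise is small relative to unit
    latent variance (sd 0.1), non-EEG channels are noisier (sd 0.3, they are
    the weaker modality in emotion datasets), and subjects differ by additive
    offsets (sd 0.4) that make leave-one-subject-out transfer non-trivial.
    Class means are separated by 2.0 in latent space, giving mid-range —
    not ceiling — classification accuracy. 400 rows per subject is a
    scaled-down stand-in for sliding-window feature tables (a 60-s trial at
    3-s windows with 2-s overlap yields ~58 windows, so real sessions run to
    thousands of rows per subject).
    """

    profile: str = "mini"
    n_subjects: int = 3
    rows_per_subject: int = 400
    latent_dim: int = 4
    coupling: float = 0.9
    noise_sd_eeg: float = 0.1
    noise_sd_noneeg: float = 0.3
    subject_sd: float = 0.4
    class_sep: float = 2.0
    nonlinear: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        for name in ("noise_sd_eeg", "noise_sd_noneeg", "subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_subjects, self.rows_per_subject, self.latent_dim) < 1:
            raise ValueError("counts must be positive")


def simulate_multimodal_features(config: SimConfig) -> MultimodalDataset:
    """Draw a class-balanced multimodal feature dataset from the latent model.

    EEG row   = coupling * (A_e u) + (1 - coupling) * (B_e v) + P_e h + eps_e
    non-EEG   = A_s u + P_s h + eps_s
    with u the class-conditional shared latent, v an independent latent of the
    same dimension, and fixed mixing matrices drawn once from the seed. The
    per-subject offset is additive but coherent across modalities: one
    2-dimensional subject state h ~ N(0, subject_sd^2 I) per subject is
    projected into both feature spaces (a subject's physiological baseline
    shifts EEG and non-EEG together, which is what lets a cross-modal
    generator compensate subject drift). Rows are ordered by subject,
    shuffled within subject; class counts per subject differ by at most one.
    """
    schema = get_profile(config.profile)
    rng = np.random.default_rng(config.seed)
    k = schema.label_scheme.n_classes
    d, n_e, n_s = config.latent_dim, schema.n_eeg, schema.n_noneeg

    # Fixed structure: mixing matrices and class means, drawn once.
    A_e = rng.normal(size=(d, n_e)) / np.sqrt(d)
    B_e = rng.normal(size=(d, n_e)) / np.sqrt(d)
    A_s = rng.normal(size=(d, n_s)) / np.sqrt(d)
    d_subj = 2  # shared subject-state dimension
    P_e = rng.normal(size=(d_subj, n_e)) / np.sqrt(d_subj)
    P_s = rng.normal(size=(d_subj, n_s)) / np.sqrt(d_subj)
    mu = rng.normal(size=(k, d))
    mu *= config.class_sep / max(np.linalg.norm(mu[1] - mu[0]), 1e-9)

    X_parts, S_parts, y_parts, subj_parts = [], [], [], []
    m = config.rows_per_subject
    for s_idx in range(config.n_subjects):
        labels = np.arange(m) % k  # balanced: counts differ by <= 1
        rng.shuffle(labels)
        u = mu[labels] + rng.normal(size=(m, d))
        v = rng.normal(size=(m, d))
        h = rng.normal(scale=config.subject_sd, size=d_subj)
        X = (config.coupling * (u @ A_e)
             + (1.0 - config.coupling) * (v @ B_e)
             + h @ P_e + rng.normal(scale=config.noise_sd_eeg, size=(m, n_e)))
        S = u @ A_s + h @ P_s + rng.normal(scale=config.noise_sd_noneeg, size=(m, n_s))
        if config.nonlinear:
            X, S = np.tanh(X), np.tanh(S)
        X_parts.append(X)
        S_parts.append(S)
        y_parts.append(labels)
        subj_parts.append(np.full(m, s_idx))

    # Affine squash into plausible feature units (DE-like range for EEG).
    X = np.concatenate(X_parts) * 1.5 + 1.0
    S = np.concatenate(S_parts)
    return MultimodalDataset(
        X_eeg=X, S_noneeg=S,
        y=np.concatenate(y_parts),
        subject=np.concatenate(subj_parts),
        schema=schema,
    )


def simulate_raw_recording(band_variances: dict[tuple[float, float], float],
                           fs: float, duration_s: float, seed: int = 0,
                           n_channels: int = 1,
                           channel_names: tuple[str, ...] | None = None,
                           kind: str = "eeg") -> RawRecording:
    """Sum of band-limited Gaussian noise components with given variances.

    Each (lo, hi) band contributes an independent Gaussian process whose
    power is confined to that band (constructed in the frequency domain) and
    scaled to the requested variance.
    """
    n = int(round(fs * duration_s))
    nyq = fs / 2.0
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    signals = np.zeros((n_channels, n))
    for (lo, hi), var in band_variances.items():
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band ({lo}, {hi}) outside (0, {nyq})")
        if var == 0:
            continue
        for ch in range(n_channels):
            white = rng.normal(size=n)
            spec = np.fft.rfft(white)
            mask = (freqs >= lo) & (freqs <= hi)
            spec[~mask] = 0.0
            comp = np.fft.irfft(spec, n=n)
            sd = comp.std()
            if sd > 0:
                comp *= np.sqrt(var) / sd
            signals[ch] += comp
    if channel_names is None:
        channel_names = tuple(f"CH{i+1}" for i in range(n_channels))
    return RawRecording(signals=signals, fs=fs, channel_names=channel_names, kind=kind)
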