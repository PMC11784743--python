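"""Feature extraction from raw windowed signals.

EEG windows are reduced to one value per (channel, band): differential
entropy of the band-filtered signal for the SEED-V/DEAP-style profiles, or
Welch band power for the GraffitiVR-style profile. Peripheral physiology
windows are reduced to eight time/frequency statistics, and head-angle
recordings to fifteen first-difference statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.integrate import simpson

from .data import FeatureSchema, MultimodalDataset

__all__ = [
    "RawRecording",
    "WindowSpec",
    "sliding_windows",
    "differential_entropy",
    "welch_band_power",
    "peripheral_features",
    "head_movement_features",
    "extract_dataset",
]

PERIPHERAL_STAT_NAMES = ("mean", "std", "min", "max", "diff1", "diff2", "power", "grad")
HEAD_STAT_NAMES = ("min", "max", "mean", "median", "std")


@dataclass
class RawRecording:
    """Multichannel raw signal block (channels x samples)."""

    signals: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    kind: str = "eeg"  # eeg | peripheral | head-angles

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError("channel_names must match the signal row count")
        if self.kind == "head-angles" and self.signals.shape[0] != 3:
            raise ValueError("head-angle recordings need exactly 3 channels (yaw, pitch, roll)")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    length_s: float
    overlap_s: float = 0.0

    def __post_init__(self):
        if not 0 <= self.overlap_s < self.length_s:
            raise ValueError("need 0 <= overlap_s < length_s")


def sliding_windows(recording: RawRecording, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open sample intervals [start, start+L); trailing partial dropped."""
    L = round(spec.length_s * recording.fs)
    hop = L - round(spec.overlap_s * recording.fs)
    n = recording.n_samples
    if n < L:
        raise ValueError("recording shorter than one window")
    starts = range(0, n - L + 1, hop)
    return [(s, s + L) for s in starts]


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) must lie within (0, {nyq})")
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def differential_entropy(window: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Gaussian differential entropy of the band-filtered window, in nats.

    DE = 0.5 * ln(2*pi*e*sigma^2) with sigma^2 the sample variance of the
    band-passed signal (4th-order zero-phase Butterworth). A zero-variance
    window yields -inf.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("window must have at least 2 samples")
    filtered = _bandpass(window, band[0], band[1], fs)
    var = filtered.var()
    if var == 0:
        return -np.inf
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def welch_band_power(window: np.ndarray, bands, fs: float,
                     nperseg: int | None = None) -> np.ndarray:
    """Average band powers from Welch's PSD, integrated by Simpson's rule.

    Hann window, 50% segment overlap, segment length min(256, window length)
    unless overridden. One value per (lo, hi) band.
    """
    window = np.asarray(window, dtype=float)
    if nperseg is None:
        nperseg = min(256, window.size)
    # 4x zero-padding refines the frequency grid so that narrowband peaks
    # are integrated accurately by Simpson's rule
    freqs, psd = sps.welch(window, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, nfft=4 * nperseg)
    nyq = fs / 2.0
    out = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band ({lo}, {hi}) outside Nyquist range")
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            out[i] = 0.0
        else:
            out[i] = simpson(psd[mask], x=freqs[mask])
    return out


def peripheral_features(window: np.ndarray) -> np.ndarray:
    """Eight statistics of one peripheral-channel window.

    Order: mean, std, min, max, mean |first difference|, mean |second
    difference|, total spectral power (periodogram sum excluding DC), mean
    signed central-difference gradient.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 3:
        raise ValueError("window must have at least 3 samples")
    d1 = np.diff(window)
    d2 = np.diff(window, n=2)
    spectrum = np.abs(np.fft.rfft(window)) ** 2 / window.size
    power = spectrum[1:].sum()  # DC excluded; a constant signal has 0 power
    grad = np.gradient(window).mean()
    return np.array([
        window.mean(), window.std(), window.min(), window.max(),
        np.abs(d1).mean(), np.abs(d2).mean(), power, grad,
    ])


def head_movement_features(angles: RawRecording) -> np.ndarray:
    """Fifteen statistics of frame-to-frame head rotation changes.

    Per axis (yaw, pitch, roll): min, max, mean, median and std of the first
    differences of the angle series, concatenated axis-major.
    """
    if angles.kind != "head-angles":
        raise ValueError("expected a head-angles recording")
    if angles.n_samples < 2:
        raise ValueError("need at least 2 samples")
    out = []
    for axis in angles.signals:
        d = np.diff(axis)
        out += [d.min(), d.max(), d.mean(), np.median(d), d.std()]
    return np.array(out)


def extract_dataset(eeg: RawRecording, noneeg, schema: FeatureSchema,
                    spec: WindowSpec, label: int, subject,
                    eeg_extra: np.ndarray | None = None) -> MultimodalDataset:
    """Window one trial's recordings and assemble the feature table rows.

    EEG rows hold one value per (channel, band): differential entropy for
    profiles without composite indices, Welch band powers when the schema
    carries composite EEG indices (which must then be supplied per window via
    ``eeg_extra``, shape (n_windows, n_extra) or (n_extra,) broadcast). The
    trial label and subject ID are broadcast to every window.

    ``noneeg`` is either a RawRecording (peripheral channels reduced to eight
    statistics each, or head angles to fifteen difference statistics) or an
    already-computed feature matrix of shape (n_windows, n_noneeg) /
    (n_noneeg,) for modalities whose features arrive precomputed (e.g.
    eye-tracker software output).
    """
    missing = [c for c in schema.eeg_channels if c not in eeg.channel_names]
    if missing:
        raise ValueError(f"EEG recording missing schema channels: {missing}")
    windows = sliding_windows(eeg, spec)
    use_welch = bool(schema.eeg_extra)
    bands = [(lo, hi) for (_, lo, hi) in schema.eeg_bands]

    chan_idx = [eeg.channel_names.index(c) for c in schema.eeg_channels]
    eeg_rows = []
    for (a, b) in windows:
        row = []
        for ci in chan_idx:
            seg = eeg.signals[ci, a:b]
            if use_welch:
                row.extend(welch_band_power(seg, bands, eeg.fs))
            else:
                row.extend(differential_entropy(seg, bd, eeg.fs) for bd in bands)
        eeg_rows.append(row)
    X = np.asarray(eeg_rows)

    if use_welch:
        n_extra = len(schema.eeg_extra)
        if eeg_extra is None:
            raise ValueError("schema declares composite EEG indices; pass eeg_extra")
        eeg_extra = np.atleast_2d(np.asarray(eeg_extra, dtype=float))
        if eeg_extra.shape == (1, n_extra):
            eeg_extra = np.repeat(eeg_extra, len(windows), axis=0)
        if eeg_extra.shape != (len(windows), n_extra):
            raise ValueError("eeg_extra shape must be (n_windows, n_extra)")
        X = np.hstack([X, eeg_extra])

    if isinstance(noneeg, np.ndarray):
        S = np.atleast_2d(np.asarray(noneeg, dtype=float))
        if S.shape[0] == 1:
            S = np.repeat(S, len(windows), axis=0)
    elif noneeg.kind == "head-angles":
        # Head-angle statistics are computed per window of the angle stream.
        s_windows = sliding_windows(noneeg, spec)
        s_rows = []
        for (a, b) in s_windows[: len(windows)]:
            sub = RawRecording(noneeg.signals[:, a:b], noneeg.fs,
                               noneeg.channel_names, kind="head-angles")
            s_rows.append(head_movement_features(sub))
        S = np.asarray(s_rows)
    else:
        s_windows = sliding_windows(noneeg, spec)
        s_rows = []
        for (a, b) in s_windows[: len(windows)]:
            row = []
            for ch in noneeg.signals:
                row.extend(peripheral_features(ch[a:b]))
            s_rows.append(row)
        S = np.asarray(s_rows)

    n = min(len(X), len(S))
    X, S = X[:n], S[:n]
    if S.shape[1] != schema.n_noneeg:
        raise ValueError(
            f"extracted {S.shape[1]} non-EEG features but schema "
            f"{schema.name!r} expects {schema.n_noneeg}; check the non-EEG "
            f"channel count and kind")
    return MultimodalDataset(
        X_eeg=X, S_noneeg=S,
        y=np.full(n, label, dtype=int),
        subject=np.full(n, subject),
        schema=schema,
    )
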