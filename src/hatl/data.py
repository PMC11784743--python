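"""Typed containers for multimodal feature data.

The framework operates on tabular features: one row per analysis window, EEG
band features per channel on one side, non-EEG sensory features (eye
movements, peripheral physiology, head movements) on the other, with an
emotion label and a subject identifier per row. A :class:`FeatureSchema`
pins the column names and ordering; :class:`MultimodalDataset` holds the
matrices; min-max scaling state is tracked so that generated data can be
mapped back to feature units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import hashlib

import numpy as np

__all__ = [
    "LabelScheme",
    "FeatureSchema",
    "ScalerState",
    "MultimodalDataset",
    "minmax_scale",
    "ratings_to_quadrants",
    "validate",
    "get_profile",
    "PROFILE_NAMES",
    "SchemaError",
]

QUADRANT_CLASSES = ("HVHA", "HVLA", "LVLA", "LVHA")
CATEGORICAL5_CLASSES = ("Happy", "Sad", "Disgust", "Neutral", "Fear")


class SchemaError(ValueError):
    """Raised when data does not match the declared feature schema."""


@dataclass(frozen=True)
class LabelScheme:
    """Label convention: 5 discrete emotions, or 4 valence-arousal quadrants."""

    kind: str  # "categorical-5" | "quadrant"
    class_names: tuple[str, ...]
    rating_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind == "categorical-5":
            if tuple(self.class_names) != CATEGORICAL5_CLASSES:
                raise ValueError("categorical-5 scheme must use the canonical five emotions")
        elif self.kind == "quadrant":
            if tuple(self.class_names) != QUADRANT_CLASSES:
                raise ValueError("quadrant scheme must use HVHA/HVLA/LVLA/LVHA")
        else:
            raise ValueError(f"unknown label scheme kind: {self.kind}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class FeatureSchema:
    """Names and ordering of EEG and non-EEG feature columns.

    EEG features are channel-major: for each channel, one column per band,
    followed by any composite EEG indices (``eeg_extra``). Band ranges are in
    Hz and must not overlap.
    """

    name: str
    eeg_channels: tuple[str, ...]
    eeg_bands: tuple[tuple[str, float, float], ...]  # (band, lo_hz, hi_hz)
    noneeg_features: tuple[str, ...]
    label_scheme: LabelScheme
    eeg_extra: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.eeg_channels or not self.eeg_bands:
            raise ValueError("schema needs at least one EEG channel and band")
        if not self.noneeg_features:
            raise ValueError("schema needs at least one non-EEG feature")
        bands = sorted(self.eeg_bands, key=lambda b: b[1])
        for (name, lo, hi) in bands:
            if not lo < hi:
                raise ValueError(f"band {name}: lower edge must be below upper edge")
        for (_, _, hi), (nxt, lo, _) in zip(bands, bands[1:]):
            if lo < hi:
                raise ValueError(f"band {nxt} overlaps the previous band")

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.eeg_bands)

    def band_range(self, band: str) -> tuple[float, float]:
        for name, lo, hi in self.eeg_bands:
            if name == band:
                return (lo, hi)
        raise KeyError(f"band {band!r} not in schema {self.name!r}")

    @property
    def eeg_feature_names(self) -> tuple[str, ...]:
        names = [f"{ch}_{band}" for ch in self.eeg_channels for band in self.band_names]
        return tuple(names) + tuple(self.eeg_extra)

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_channels) * len(self.eeg_bands) + len(self.eeg_extra)

    @property
    def n_noneeg(self) -> int:
        return len(self.noneeg_features)

    def band_columns(self, band: str) -> np.ndarray:
        """Column indices (into the EEG matrix) of one band across channels."""
        if band not in self.band_names:
            raise KeyError(f"band {band!r} not in schema {self.name!r}")
        k = self.band_names.index(band)
        nb = len(self.eeg_bands)
        return np.arange(len(self.eeg_channels)) * nb + k

    def hash(self) -> str:
        payload = repr((self.name, self.eeg_channels, self.eeg_bands,
                        self.noneeg_features, self.eeg_extra,
                        self.label_scheme.kind)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScalerState:
    """Per-column minimum and maximum fitted on training data."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("scaler max must be >= min per column")

    @property
    def n_columns(self) -> int:
        return self.mins.size


def minmax_scale(data: np.ndarray, state: ScalerState | None = None,
                 clip: bool = False) -> tuple[np.ndarray, ScalerState]:
    """Map each column to [0, 1] by (v - min) / (max - min).

    Constant columns map to 0. When ``state`` is given it is reused (for test
    or generated data); with ``clip`` the result is clamped to [0, 1] so that
    out-of-range test values cannot leave the training scale.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot scale empty data")
    if data.ndim == 1:
        data = data[:, None]
    if state is None:
        state = ScalerState(data.min(axis=0), data.max(axis=0))
    elif state.n_columns != data.shape[1]:
        raise SchemaError(
            f"scaler fitted on {state.n_columns} columns, got {data.shape[1]}")
    span = state.maxs - state.mins
    safe = np.where(span > 0, span, 1.0)
    out = (data - state.mins) / safe
    out[:, span == 0] = 0.0
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out, state


def inverse_minmax(scaled: np.ndarray, state: ScalerState) -> np.ndarray:
    """Undo :func:`minmax_scale`; constant columns map back to their minimum."""
    scaled = np.asarray(scaled, dtype=float)
    return scaled * (state.maxs - state.mins) + state.mins


def ratings_to_quadrants(valence, arousal,
                         rating_range: tuple[float, float] = (1, 9)) -> np.ndarray:
    """Median-split valence/arousal ratings into the four quadrant labels.

    Each axis is split at the sample median of the vector passed in; ratings
    at or below the median are Low (ties go Low). Returns integer labels
    indexing ``QUADRANT_CLASSES``.
    """
    valence = np.asarray(valence, dtype=float)
    arousal = np.asarray(arousal, dtype=float)
    if valence.size == 0:
        raise ValueError("empty rating vectors")
    if valence.shape != arousal.shape:
        raise ValueError("valence and arousal must have equal length")
    lo, hi = rating_range
    for name, v in (("valence", valence), ("arousal", arousal)):
        if np.any(v < lo) or np.any(v > hi):
            raise ValueError(f"{name} rating outside range [{lo}, {hi}]")
    hv = valence > np.median(valence)
    ha = arousal > np.median(arousal)
    labels = np.empty(valence.shape, dtype=int)
    labels[hv & ha] = QUADRANT_CLASSES.index("HVHA")
    labels[hv & ~ha] = QUADRANT_CLASSES.index("HVLA")
    labels[~hv & ~ha] = QUADRANT_CLASSES.index("LVLA")
    labels[~hv & ha] = QUADRANT_CLASSES.index("LVHA")
    return labels


@dataclass
class MultimodalDataset:
    """EEG features, non-EEG features, labels and subject IDs, row-aligned."""

    X_eeg: np.ndarray
    S_noneeg: np.ndarray
    y: np.ndarray
    subject: np.ndarray
    schema: FeatureSchema
    scaled: bool = False
    eeg_scaler: ScalerState | None = None
    noneeg_scaler: ScalerState | None = None
    session: np.ndarray | None = None

    def __post_init__(self):
        self.X_eeg = np.asarray(self.X_eeg, dtype=float)
        self.S_noneeg = np.asarray(self.S_noneeg, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject = np.asarray(self.subject)
        if self.session is not None:
            self.session = np.asarray(self.session, dtype=int)

    @property
    def n_rows(self) -> int:
        return self.X_eeg.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject)

    def rows(self, mask: np.ndarray) -> "MultimodalDataset":
        return replace(
            self,
            X_eeg=self.X_eeg[mask],
            S_noneeg=self.S_noneeg[mask],
            y=self.y[mask],
            subject=self.subject[mask],
            session=None if self.session is None else self.session[mask],
        )

    def scale(self, eeg_state: ScalerState | None = None,
              noneeg_state: ScalerState | None = None) -> "MultimodalDataset":
        """Min-max scale both modalities (fitting states unless provided)."""
        Xs, es = minmax_scale(self.X_eeg, eeg_state, clip=eeg_state is not None)
        Ss, ns = minmax_scale(self.S_noneeg, noneeg_state, clip=noneeg_state is not None)
        return replace(self, X_eeg=Xs, S_noneeg=Ss, scaled=True,
                       eeg_scaler=es, noneeg_scaler=ns)


@dataclass
class ValidationIssue:
    code: str
    message: str


def validate(ds: MultimodalDataset) -> list[ValidationIssue]:
    """Report-only consistency check; never mutates or raises."""
    issues: list[ValidationIssue] = []
    n = ds.X_eeg.shape[0]
    counts = {"S_noneeg": ds.S_noneeg.shape[0], "y": ds.y.shape[0],
              "subject": ds.subject.shape[0]}
    for name, c in counts.items():
        if c != n:
            issues.append(ValidationIssue("row-mismatch", f"{name} has {c} rows, X_eeg has {n}"))
    if ds.X_eeg.shape[1] != ds.schema.n_eeg:
        issues.append(ValidationIssue(
            "dim-mismatch",
            f"X_eeg has {ds.X_eeg.shape[1]} columns, schema {ds.schema.name!r} expects {ds.schema.n_eeg}"))
    if ds.S_noneeg.shape[1] != ds.schema.n_noneeg:
        issues.append(ValidationIssue(
            "dim-mismatch",
            f"S_noneeg has {ds.S_noneeg.shape[1]} columns, schema expects {ds.schema.n_noneeg}"))
    for name, mat in (("X_eeg", ds.X_eeg), ("S_noneeg", ds.S_noneeg)):
        bad = ~np.isfinite(mat)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            issues.append(ValidationIssue(
                "non-finite", f"{name} has a NaN/inf at row {r}, column {c}"))
    k = ds.schema.label_scheme.n_classes
    if ds.y.size and (ds.y.min() < 0 or ds.y.max() >= k):
        issues.append(ValidationIssue("bad-label", f"labels must lie in [0, {k})"))
    if ds.scaled:
        for name, mat in (("X_eeg", ds.X_eeg), ("S_noneeg", ds.S_noneeg)):
            if mat.size and (mat.min() < -1e-9 or mat.max() > 1 + 1e-9):
                issues.append(ValidationIssue(
                    "scale", f"{name} marked scaled but has values outside [0, 1]"))
    return issues


# ---------------------------------------------------------------------------
# Built-in schema profiles
# ---------------------------------------------------------------------------

def _seedv_profile() -> FeatureSchema:
    channels = tuple(f"CH{i}" for i in range(1, 63))  # 62-channel cap
    bands = (("delta", 1.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 14.0),
             ("beta", 14.0, 31.0), ("gamma", 31.0, 50.0))
    eye = []
    for ax in ("x", "y"):
        eye += [f"pupil_{ax}_mean", f"pupil_{ax}_std"]
        eye += [f"pupil_{ax}_de_b{i}" for i in range(1, 5)]
    for ax in ("x", "y"):
        eye += [f"dispersion_{ax}_mean", f"dispersion_{ax}_std"]
    eye += ["fixation_dur_mean", "fixation_dur_std",
            "blink_dur_mean", "blink_dur_std",
            "saccade_dur_mean", "saccade_dur_std",
            "saccade_amp_mean", "saccade_amp_std",
            "blink_freq", "fixation_freq", "fixation_dur_max",
            "fixation_disp_total", "fixation_disp_max", "saccade_freq",
            "saccade_dur_avg", "saccade_amp_avg", "saccade_latency_avg"]
    return FeatureSchema(
        name="seedv", eeg_channels=channels, eeg_bands=bands,
        noneeg_features=tuple(eye),
        label_scheme=LabelScheme("categorical-5", CATEGORICAL5_CLASSES))


def _deap_profile() -> FeatureSchema:
    channels = tuple(f"EEG{i}" for i in range(1, 33))
    bands = (("theta", 4.0, 8.0), ("alpha", 8.0, 12.0),
             ("beta", 12.0, 30.0), ("gamma", 30.0, 45.0))
    periph_channels = ("hEOG", "vEOG", "zEMG", "tEMG", "GSR", "RESP", "BVP", "SKT")
    stats = ("mean", "std", "min", "max", "diff1", "diff2", "power", "grad")
    periph = tuple(f"{ch}_{st}" for ch in periph_channels for st in stats)
    return FeatureSchema(
        name="deap", eeg_channels=channels, eeg_bands=bands,
        noneeg_features=periph,
        label_scheme=LabelScheme("quadrant", QUADRANT_CLASSES, (1, 9)))


def _graffitivr_profile() -> FeatureSchema:
    channels = ("AF3", "AF4", "AF7", "AF8", "Fp1", "Fp2")
    bands = (("delta", 1.0, 3.0), ("theta", 3.0, 8.0), ("alpha", 8.0, 12.0),
             ("beta", 12.0, 38.0), ("gamma", 38.0, 45.0))
    extra = ("attention", "relaxation", "asymmetry", "left_activity", "right_activity")
    stats = ("min", "max", "mean", "median", "std")
    head = tuple(f"{ax}_{st}" for ax in ("yaw", "pitch", "roll") for st in stats)
    return FeatureSchema(
        name="graffitivr", eeg_channels=channels, eeg_bands=bands,
        eeg_extra=extra, noneeg_features=head,
        label_scheme=LabelScheme("quadrant", QUADRANT_CLASSES, (1, 7)))


def _mini_profile() -> FeatureSchema:
    """Reduced profile for fast tests and demos: 8 EEG + 4 non-EEG dims."""
    bands = (("theta", 4.0, 8.0), ("alpha", 8.0, 12.0),
             ("beta", 12.0, 30.0), ("gamma", 30.0, 45.0))
    return FeatureSchema(
        name="mini", eeg_channels=("C1", "C2"), eeg_bands=bands,
        noneeg_features=("s1", "s2", "s3", "s4"),
        label_scheme=LabelScheme("quadrant", QUADRANT_CLASSES, (1, 9)))


_PROFILES = {
    "seedv": _seedv_profile,
    "deap": _deap_profile,
    "graffitivr": _graffitivr_profile,
    "mini": _mini_profile,
}

PROFILE_NAMES = tuple(_PROFILES)


def get_profile(name: str) -> FeatureSchema:
    try:
        return _PROFILES[name]()
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; available: {PROFILE_NAMES}") from None


def schema_from_dict(d: dict) -> FeatureSchema:
    """Build a user-defined schema from a plain mapping (e.g. parsed YAML).

    Expected keys: name, eeg_channels, eeg_bands (mapping band -> [lo, hi]),
    noneeg_features, label_scheme ("categorical-5" | "quadrant"), and
    optionally eeg_extra and rating_range.
    """
    kind = d["label_scheme"]
    classes = CATEGORICAL5_CLASSES if kind == "categorical-5" else QUADRANT_CLASSES
    rating = tuple(d["rating_range"]) if "rating_range" in d else None
    bands = tuple((b, float(lo), float(hi))
                  for b, (lo, hi) in d["eeg_bands"].items())
    return FeatureSchema(
        name=d["name"],
        eeg_channels=tuple(d["eeg_channels"]),
        eeg_bands=bands,
        noneeg_features=tuple(d["noneeg_features"]),
        eeg_extra=tuple(d.get("eeg_extra", ())),
        label_scheme=LabelScheme(kind, classes, rating))
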