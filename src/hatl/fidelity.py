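"""Similarity metrics between real and generated EEG feature matrices.

Three complementary views: row-wise Euclidean distance (spatial match of
paired samples), the 1-D empirical Wasserstein distance per feature or band
(distributional match), and a histogram KL divergence per band, plus Welch's
two-sample t-test as the significance check. A :class:`FidelityReport`
aggregates them the way the per-band summary tables are usually presented:
one row per EEG band, pooling all channels' values for that band.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureSchema

__all__ = [
    "euclidean_rowwise",
    "empirical_wasserstein",
    "kl_divergence_hist",
    "band_ttest",
    "BandFidelity",
    "FidelityReport",
    "fidelity_report",
]


def euclidean_rowwise(real: np.ndarray, generated: np.ndarray,
                      labels: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and std of per-row Euclidean distances between paired samples.

    Rows are paired by (label, within-label order) when labels are given,
    otherwise by position.
    """
    real, generated = np.atleast_2d(real), np.atleast_2d(generated)
    if real.shape != generated.shape:
        raise ValueError("real and generated matrices must have equal shapes")
    if labels is not None:
        labels = np.asarray(labels)
        order = np.argsort(labels, kind="stable")
        real, generated = real[order], generated[order]
    d = np.sqrt(((real - generated) ** 2).sum(axis=1))
    return float(d.mean()), float(d.std())


def empirical_wasserstein(a: np.ndarray, b: np.ndarray) -> float:
    """1-D earth-mover distance between two empirical samples.

    Equals the integral of |F_a^{-1} - F_b^{-1}|; for equal sample sizes this
    is the mean absolute difference of the sorted samples.
    """
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.wasserstein_distance(a, b))


def kl_divergence_hist(p_sample: np.ndarray, q_sample: np.ndarray,
                       bins: int = 50, eps: float = 1e-10) -> float:
    """KL(P || Q) in nats from shared-range histograms.

    Both samples are binned over the pooled min-max range; masses get
    additive smoothing ``eps`` and are renormalised before the divergence is
    summed. A degenerate pooled range (all values identical) returns 0.
    """
    p_sample = np.asarray(p_sample, float).ravel()
    q_sample = np.asarray(q_sample, float).ravel()
    if p_sample.size == 0 or q_sample.size == 0:
        raise ValueError("samples must be non-empty")
    lo = min(p_sample.min(), q_sample.min())
    hi = max(p_sample.max(), q_sample.max())
    if lo == hi:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(p_sample, bins=edges)
    q, _ = np.histogram(q_sample, bins=edges)
    p = p.astype(float) + eps
    q = q.astype(float) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def band_ttest(real_values: np.ndarray, generated_values: np.ndarray) -> tuple[float, float]:
    """Welch's two-sided two-sample t-test; returns (t statistic, p-value)."""
    real_values = np.asarray(real_values, float).ravel()
    generated_values = np.asarray(generated_values, float).ravel()
    if real_values.size < 2 or generated_values.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.allclose(real_values, real_values[0]) and np.allclose(
            generated_values, generated_values[0]) and np.isclose(
            real_values[0], generated_values[0]):
        return 0.0, 1.0  # identical constant samples: no difference
    t, p = stats.ttest_ind(real_values, generated_values, equal_var=False)
    if np.isnan(t):  # zero variance in both samples with equal means
        return 0.0, 1.0
    return float(t), float(p)


@dataclass
class BandFidelity:
    band: str
    kl: float
    wasserstein: float
    t_stat: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class FidelityReport:
    euclidean_mean: float
    euclidean_std: float
    wasserstein_mean: float
    wasserstein_std: float
    bands: list[BandFidelity]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bands:
            d = asdict(b)
            d["significant"] = b.significant
            rows.append(d)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "euclidean_mean": self.euclidean_mean,
            "euclidean_std": self.euclidean_std,
            "wasserstein_mean": self.wasserstein_mean,
            "wasserstein_std": self.wasserstein_std,
            "bands": [asdict(b) for b in self.bands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FidelityReport":
        return cls(
            euclidean_mean=d["euclidean_mean"],
            euclidean_std=d["euclidean_std"],
            wasserstein_mean=d["wasserstein_mean"],
            wasserstein_std=d["wasserstein_std"],
            bands=[BandFidelity(**b) for b in d["bands"]],
        )


def fidelity_report(real: np.ndarray, generated: np.ndarray,
                    labels: np.ndarray, schema: FeatureSchema) -> FidelityReport:
    """Full fidelity summary between paired real and generated EEG matrices.

    Row-wise Euclidean distances are aggregated over (label-paired) rows;
    the Wasserstein distance is computed per feature column then aggregated;
    per band, all channels' values are pooled into one sample per source and
    compared by KL divergence, Wasserstein distance and Welch's t-test.
    """
    real, generated = np.atleast_2d(real), np.atleast_2d(generated)
    if real.shape[1] != schema.n_eeg:
        raise ValueError("matrix width does not match the schema")
    eu_mean, eu_std = euclidean_rowwise(real, generated, labels)
    per_feature = np.array([
        empirical_wasserstein(real[:, j], generated[:, j])
        for j in range(real.shape[1])
    ])
    bands = []
    for band in schema.band_names:
        cols = schema.band_columns(band)
        r, g = real[:, cols].ravel(), generated[:, cols].ravel()
        t, p = band_ttest(r, g)
        bands.append(BandFidelity(
            band=band,
            kl=kl_divergence_hist(r, g),
            wasserstein=empirical_wasserstein(r, g),
            t_stat=t, p_value=p,
        ))
    return FidelityReport(
        euclidean_mean=eu_mean, euclidean_std=eu_std,
        wasserstein_mean=float(per_feature.mean()),
        wasserstein_std=float(per_feature.std()),
        bands=bands,
    )
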