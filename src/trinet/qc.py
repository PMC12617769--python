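"""Predefined two-criterion sample exclusion.

A sample is excluded only when it fails *both* of two independent checks:

1. multivariate profile outlier — Mahalanobis distance from the PCA
   centroid of the log1p-transformed matrix exceeds the empirical 99.5th
   percentile (strictly), and
2. aberrant sequencing depth — raw library size falls outside 1.5x the
   interquartile range from the first or third quartile (strictly).

Requiring the intersection keeps single-criterion borderline samples; the
IQR depth check effectively vetoes PCA-only flags on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import OmicsMatrix


@dataclass
class QCReport:
    table: pd.DataFrame  # per-sample: library_size, mahalanobis, flags, excluded
    pca_threshold: float
    iqr_fences: tuple
    n_components: int
    params: dict

    @property
    def excluded_samples(self) -> list:
        return list(self.table.index[self.table["excluded"]])

    def to_dict(self) -> dict:
        return {
            "samples": self.table.reset_index().rename(columns={"index": "sample_id"}).to_dict(orient="records"),
            "pca_threshold": float(self.pca_threshold),
            "iqr_fences": [float(x) for x in self.iqr_fences],
            "n_components": int(self.n_components),
            "params": self.params,
        }


def transform_for_qc(counts: OmicsMatrix) -> OmicsMatrix:
    """log(1+x) transform with zero-variance features dropped."""
    if counts.n_samples < 3:
        raise ValueError("QC requires at least 3 samples")
    logged = np.log1p(counts.data.astype(float))
    keep = logged.var(axis=1, ddof=0) > 0.0
    return OmicsMatrix(logged.loc[keep], counts.layer)


def pca_mahalanobis(x: OmicsMatrix, n_components: int) -> pd.Series:
    """Mahalanobis distance of each sample from the PCA centroid.

    Samples are centred, scores obtained by SVD, and the distance computed
    with the diagonal score covariance — exact in PC space because scores
    are uncorrelated:  D_s = sqrt(sum_k (score_sk / sd_k)^2).
    """
    data = x.data.to_numpy(dtype=float).T  # samples x features
    n = data.shape[0]
    if n_components > n - 1:
        raise ValueError("n_components must be at most n_samples - 1")
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    nonzero = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if nonzero == 0:
        raise ValueError("degenerate input: all samples identical")
    k = min(n_components, nonzero)
    scores = u[:, :k] * s[:k]
    sd = scores.std(axis=0, ddof=1)
    d = np.sqrt(((scores / sd) ** 2).sum(axis=1))
    return pd.Series(d, index=x.samples, name="mahalanobis")


def _percentile_flags(d: pd.Series, pct: float) -> tuple:
    """Strictly-greater-than-empirical-percentile flags (linear interp)."""
    thr = float(np.percentile(d.to_numpy(), pct))
    return d > thr, thr


def _iqr_flags(libsize: pd.Series, mult: float) -> tuple:
    q1, q3 = np.percentile(libsize.to_numpy(), [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - mult * iqr, q3 + mult * iqr
    return (libsize < lo) | (libsize > hi), (float(lo), float(hi))


def flag_outliers(
    counts: OmicsMatrix,
    n_components: int = 5,
    pca_pct: float = 99.5,
    iqr_mult: float = 1.5,
) -> QCReport:
    """Run both criteria and combine them by intersection."""
    if counts.n_samples < 4:
        raise ValueError("outlier flagging requires at least 4 samples")
    k = min(n_components, counts.n_samples - 1)
    libsize = counts.library_sizes()
    transformed = transform_for_qc(counts)
    d = pca_mahalanobis(transformed, k)
    flagged_pca, thr = _percentile_flags(d, pca_pct)
    flagged_iqr, fences = _iqr_flags(libsize, iqr_mult)
    table = pd.DataFrame(
        {
            "library_size": libsize,
            "mahalanobis": d,
            "flagged_pca": flagged_pca,
            "flagged_iqr": flagged_iqr,
        }
    )
    table["excluded"] = table["flagged_pca"] & table["flagged_iqr"]
    return QCReport(
        table=table,
        pca_threshold=thr,
        iqr_fences=fences,
        n_components=k,
        params={"pca_pct": pca_pct, "iqr_mult": iqr_mult, "n_components_requested": n_components},
    )
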