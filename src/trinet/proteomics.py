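"""Protein-matrix preprocessing: completeness filter and QRILC imputation.

Label-free proteomics matrices are left-censored: low-abundance proteins
drop out.  Features are kept when at least one sample group is
sufficiently complete (>= 80% quantified by default), and remaining
missing values are imputed by QRILC — per sample, the underlying normal
is estimated by quantile regression of the observed (upper-tail) order
statistics against standard-normal quantiles, and each missing value is
drawn from that normal truncated above at the sample's observed minimum.

Downstream correlation analysis deliberately uses the *non-imputed*
matrix with pairwise-complete observations; the imputed matrix feeds only
Z-score summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix, group_key

log = logging.getLogger(__name__)

MIN_OBSERVED_FOR_FIT = 5


@dataclass
class ProteinFilterReport:
    fraction_positive: pd.DataFrame  # feature x group
    kept: pd.Series
    min_frac: float

    def to_dict(self) -> dict:
        return {
            "min_frac": self.min_frac,
            "n_kept": int(self.kept.sum()),
            "n_removed": int((~self.kept).sum()),
            "removed": list(self.kept.index[~self.kept]),
        }


def filter_proteins(protein: OmicsMatrix, design: pd.DataFrame, min_frac: float = 0.8):
    """Keep features quantified in >= `min_frac` of samples of some group."""
    groups = group_key(design)
    groups.index = design["sample_id"]
    groups = groups.loc[list(protein.samples)]
    observed = protein.data.notna()
    frac = observed.T.groupby(groups.to_numpy()).mean().T
    if (design.groupby(["condition", "time_point"]).size() == 0).any():
        raise ValueError("group with zero samples")
    kept = frac.max(axis=1) >= min_frac
    report = ProteinFilterReport(fraction_positive=frac, kept=kept, min_frac=min_frac)
    return OmicsMatrix(protein.data.loc[kept].copy(), protein.layer), report


def _censored_normal_fit(values: np.ndarray, n_total: int) -> tuple:
    """(mean, sd) by regressing observed order statistics on normal quantiles.

    The observed values are treated as the top `len(values)` of `n_total`
    draws; plotting positions follow Blom's rule.
    """
    obs = np.sort(values)
    m = obs.size
    ranks = np.arange(n_total - m + 1, n_total + 1)
    pp = (ranks - 0.375) / (n_total + 0.25)
    q = stats.norm.ppf(pp)
    sd, mean = np.polyfit(q, obs, 1)
    return float(mean), float(max(sd, 1e-8))


def impute_qrilc(protein: OmicsMatrix, seed=None, rng: np.random.Generator = None) -> OmicsMatrix:
    """Impute left-censored missing values from per-sample truncated normals.

    Observed cells are untouched; every imputed value lies at or below its
    sample's observed minimum.  Samples with fewer than five observed
    values fall back to a global fit (logged).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    data = protein.data.copy()
    values = data.to_numpy()
    n_total = values.shape[0]

    pooled = values[~np.isnan(values)]
    global_fit = None
    if pooled.size >= MIN_OBSERVED_FOR_FIT:
        # pooled fit assumes a common underlying scale across samples
        global_fit = _censored_normal_fit(pooled, values.size)

    for j, sample in enumerate(data.columns):
        col = values[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        obs = col[~missing]
        if obs.size >= MIN_OBSERVED_FOR_FIT:
            mean, sd = _censored_normal_fit(obs, n_total)
        elif global_fit is not None:
            log.warning("sample %s has %d observed values; using global censoring fit", sample, obs.size)
            mean, sd = global_fit
        else:
            raise ValueError(f"sample {sample} has too few observed values to impute")
        upper = obs.min() if obs.size else mean
        b = (upper - mean) / sd
        draws = stats.truncnorm.rvs(-np.inf, b, loc=mean, scale=sd, size=missing.sum(), random_state=rng)
        col[missing] = draws
        values[:, j] = col
    return OmicsMatrix(pd.DataFrame(values, index=data.index, columns=data.columns), protein.layer)
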