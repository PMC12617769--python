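"""Core containers shared across the pipeline.

The pipeline passes feature-by-sample matrices between stages.  Rather than
inventing a heavyweight container, :class:`OmicsMatrix` is a thin wrapper
around a :class:`pandas.DataFrame` (features as rows, samples as columns)
carrying a layer tag that records what the numbers mean.  Sample metadata
travels as a plain DataFrame with a fixed column contract (see
:func:`validate_sample_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised matrix layers.  Count layers must hold nonnegative integers;
#: the protein layer holds real log-abundances and may contain NaN.
LAYERS = ("mrna_counts", "mirna_counts", "protein_log_abundance")

#: Ordered post-injury time points of the study design, plus "none" for
#: uninjured controls.  Durations are in hours (used as a numeric trait).
TIME_POINTS = ("3h", "12h", "24h", "3d", "7d")
TIME_HOURS = {"none": 0.0, "3h": 3.0, "12h": 12.0, "24h": 24.0, "3d": 72.0, "7d": 168.0}

CONDITIONS = ("control", "sham", "sci")


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with a layer tag.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
    layer
        One of :data:`LAYERS`.
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.layer.endswith("_counts"):
            values = self.data.to_numpy()
            if np.isnan(values).any():
                raise ValueError(f"missing values not allowed in layer {self.layer!r}")
            if (values < 0).any():
                raise ValueError("counts must be nonnegative")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(sample_ids)].copy(), self.layer)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(feature_ids)].copy(), self.layer)

    def library_sizes(self) -> pd.Series:
        """Raw per-sample column sums (before any transformation)."""
        return self.data.sum(axis=0)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.data.copy(), self.layer)


SAMPLE_TABLE_COLUMNS = ("sample_id", "condition", "time_point")


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-table column contract and return the table.

    Required columns: ``sample_id``, ``condition`` (control|sham|sci) and
    ``time_point`` (3h|12h|24h|3d|7d|none).  Optional columns such as
    ``library_size`` and outlier flags are passed through untouched.
    """
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    bad_tp = set(table["time_point"]) - (set(TIME_POINTS) | {"none"})
    if bad_tp:
        raise ValueError(f"unknown time points: {sorted(bad_tp)}")
    return table


def group_key(table: pd.DataFrame) -> pd.Series:
    """(condition, time_point) group label per sample, as 'condition:time'."""
    return table["condition"].astype(str) + ":" + table["time_point"].astype(str)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id -> tuple of feature ids."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, key):
        return self.sets[key]

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with `universe`, dropping empty sets."""
        uni = set(universe)
        out = {}
        for name, members in self.sets.items():
            kept = tuple(m for m in members if m in uni)
            if kept:
                out[name] = kept
        return GeneSetCollection(out, dict(self.descriptions))
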