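"""Signed weighted co-expression networks.

The canonical workflow: Pearson correlation between gene profiles, signed
soft-threshold adjacency a_ij = ((1 + cor)/2)^beta, topological overlap
smoothing, average-linkage hierarchical clustering of 1 - TOM, static
dendrogram cut with a minimum module size, module eigengenes (first
principal component of standardized module expression), eigengene-based
merging, membership (kME) reassignment, and module-trait correlation.

The dynamic hybrid tree cut of the reference implementation is replaced
by a static cut at a fraction of the maximum merge height combined with
the minimum-size rule; the workflow's standard module parameters
(beta = 15, min size 100, merge dissimilarity 0.16) are kept as defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import OmicsMatrix


@dataclass
class CoexpressionParams:
    beta: float = 15.0
    signed: bool = True
    min_module_size: int = 100
    merge_cut: float = 0.16
    cut_height_frac: float = 0.99
    linkage: str = "average"

    def validate(self) -> "CoexpressionParams":
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 < self.merge_cut < 1):
            raise ValueError("merge_cut must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        return self


@dataclass
class NetworkModules:
    labels: pd.Series                 # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame          # module x sample, unit norm
    kme: pd.DataFrame                 # gene x module
    merge_history: list = field(default_factory=list)
    module_trait: pd.DataFrame = None

    @property
    def module_ids(self) -> list:
        return [m for m in sorted(self.labels.unique()) if m != 0]


def _correlation(expr: np.ndarray) -> np.ndarray:
    if (expr.std(axis=1) == 0).any():
        raise ValueError("zero-variance feature in expression matrix")
    return np.corrcoef(expr)


def signed_adjacency(expr: OmicsMatrix, params: CoexpressionParams) -> pd.DataFrame:
    """Soft-threshold adjacency; signed: ((1+cor)/2)^beta, unsigned: |cor|^beta."""
    params.validate()
    if expr.n_samples < 3:
        raise ValueError("adjacency requires at least 3 samples")
    cor = _correlation(expr.data.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    if params.signed:
        a = ((1.0 + cor) / 2.0) ** params.beta
    else:
        a = np.abs(cor) ** params.beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.features, columns=expr.features)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour smoothing of the adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; diagonal 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1) - 1.0
    shared = a @ a - a  # (A^2)_ij - a_ij == sum_{u != i,j} a_iu a_uj + a_ij
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = shared / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(tom_dissim: pd.DataFrame, params: CoexpressionParams) -> pd.Series:
    """Cluster 1-TOM and cut statically; small clusters become unassigned.

    Labels are positive integers ordered by module size (1 = largest);
    genes in clusters smaller than `min_module_size` get label 0.
    """
    params.validate()
    genes = tom_dissim.index
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes unassigned")
        return pd.Series(0, index=genes, dtype=int)
    d = tom_dissim.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method=params.linkage)
    cut = params.cut_height_frac * z[:, 2].max()
    raw = hierarchy.fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= params.min_module_size]
    order = sorted(keep.index, key=lambda c: (-keep[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel.get(c, 0) for c in raw], index=genes, dtype=int)
    return labels


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def eigengenes(expr: OmicsMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module over samples (unit norm).

    The sign is chosen so that the mean correlation with the module's own
    members is positive.
    """
    modules = [m for m in sorted(labels.unique()) if m != 0]
    if not modules:
        raise ValueError("no assigned module")
    out = {}
    for m in modules:
        members = labels.index[labels == m]
        x = _standardize_rows(expr.data.loc[members].to_numpy(dtype=float))
        if x.shape[0] == 1:
            e = x[0] / np.linalg.norm(x[0])
        else:
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            e = vt[0]
        if (x @ e).mean() < 0:
            e = -e
        out[m] = e
    return pd.DataFrame(out, index=expr.samples).T


def _kme(expr: OmicsMatrix, eig: pd.DataFrame) -> pd.DataFrame:
    x = _standardize_rows(expr.data.to_numpy(dtype=float))
    e = eig.to_numpy(dtype=float)
    e_std = _standardize_rows(e)
    n = x.shape[1]
    k = (x @ e_std.T) / (n - 1)
    return pd.DataFrame(k, index=expr.features, columns=eig.index)


def merge_modules(
    expr: OmicsMatrix,
    labels: pd.Series,
    eig: pd.DataFrame,
    merge_cut: float = 0.16,
) -> NetworkModules:
    """Merge eigengene-similar modules and reassign genes by membership.

    Pairs with eigengene dissimilarity 1 - cor strictly below `merge_cut`
    are merged iteratively (closest pair first, eigengene recomputed),
    then each assigned gene moves to its argmax-kME module.
    """
    labels = labels.copy()
    history = []
    while True:
        ids = [m for m in sorted(labels.unique()) if m != 0]
        if len(ids) < 2:
            break
        e = eigengenes(expr, labels).loc[ids]
        cor = np.corrcoef(e.to_numpy())
        dis = 1.0 - cor
        np.fill_diagonal(dis, np.inf)
        i, j = np.unravel_index(np.argmin(dis), dis.shape)
        if dis[i, j] >= merge_cut:
            break
        a, b = sorted((ids[i], ids[j]))
        labels[labels == b] = a
        history.append((a, b, float(dis[i, j])))

    ids = [m for m in sorted(labels.unique()) if m != 0]
    if ids:
        eig = eigengenes(expr, labels)
        kme = _kme(expr, eig)
        assigned = labels != 0
        best = kme.loc[labels.index[assigned]].idxmax(axis=1)
        labels.loc[assigned] = best.astype(int)
        # relabel by size, recompute final eigengenes/kME
        sizes = labels[labels != 0].value_counts()
        relabel = {m: i + 1 for i, m in enumerate(sorted(sizes.index, key=lambda c: (-sizes[c], c)))}
        labels = labels.map(lambda m: relabel.get(m, 0)).astype(int)
        eig = eigengenes(expr, labels)
        kme = _kme(expr, eig)
    else:
        eig = pd.DataFrame(columns=expr.samples)
        kme = pd.DataFrame(index=expr.features)
    return NetworkModules(labels=labels, eigengenes=eig, kme=kme, merge_history=history)


def flag_module_trait(r: float, p: float, r_cut: float = 0.6, p_cut: float = 0.05) -> str:
    """Directional flag for one module-trait correlation (strict |r| > r_cut)."""
    if np.isnan(r) or np.isnan(p):
        return "na"
    if p < p_cut and r > r_cut:
        return "positive"
    if p < p_cut and r < -r_cut:
        return "negative"
    return "none"


def module_trait(modules: NetworkModules, traits: pd.DataFrame, r_cut: float = 0.6, p_cut: float = 0.05) -> pd.DataFrame:
    """Pearson r and two-sided p between eigengenes and numeric traits."""
    rows = []
    for m in modules.module_ids:
        e = modules.eigengenes.loc[m]
        for trait in traits.columns:
            t = traits[trait].loc[e.index].astype(float)
            if t.std(ddof=0) == 0 or e.std(ddof=0) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(e.to_numpy(), t.to_numpy())
            rows.append({"module": m, "trait": trait, "r": r, "p": p, "flag": flag_module_trait(r, p, r_cut, p_cut)})
    out = pd.DataFrame(rows)
    modules.module_trait = out
    return out


def encode_traits(design: pd.DataFrame) -> pd.DataFrame:
    """Numeric traits from the sample table: injury indicator and time (h)."""
    from .datatypes import TIME_HOURS

    idx = design["sample_id"]
    return pd.DataFrame(
        {
            "injury": (design["condition"] == "sci").astype(float).to_numpy(),
            "time_h": design["time_point"].map(TIME_HOURS).to_numpy(),
        },
        index=idx,
    )


def run_wgcna(expr: OmicsMatrix, params: CoexpressionParams = None, traits: pd.DataFrame = None) -> NetworkModules:
    """Adjacency -> TOM -> modules -> merge -> (optional) trait correlation."""
    params = (params or CoexpressionParams()).validate()
    adj = signed_adjacency(expr, params)
    tom = tom_similarity(adj)
    labels = detect_modules(1.0 - tom, params)
    if (labels != 0).sum() == 0:
        return NetworkModules(labels=labels, eigengenes=pd.DataFrame(columns=expr.samples),
                              kme=pd.DataFrame(index=expr.features))
    eig = eigengenes(expr, labels)
    modules = merge_modules(expr, labels, eig, params.merge_cut)
    if traits is not None:
        module_trait(modules, traits)
    return modules
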