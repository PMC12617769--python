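"""Over-representation analysis, pre-ranked GSEA and marker summaries.

ORA tests the overlap of a query list with each annotation set by a
one-sided Fisher's exact test on the 2x2 table and reports the sample odds
ratio.  GSEA runs in weighted pre-ranked mode: genes are scored as
sign(log2FC) * -log10(padj), the enrichment score is the maximal deviation
of a running sum with |score|^weight hit increments, and significance
comes from random same-size gene-set permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, OmicsMatrix, group_key

log = logging.getLogger(__name__)

PADJ_FLOOR = 1e-300


@dataclass
class ORAResult:
    set_id: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    odds_ratio: float
    pvalue: float


def ora(query, annot, universe, alternative: str = "greater") -> ORAResult:
    """Fisher's exact test of the query/annotation overlap.

    Table: a = |query & set|, b = |query \\ set|, c = |set \\ query|,
    d = rest of the universe.  OR = ad/bc with the conventions OR = inf
    when bc = 0 and ad > 0, OR = 0 when a = 0.
    """
    query, annot, universe = set(query), set(annot), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not annot <= universe:
        raise ValueError("annotation set is not a subset of the universe")
    a = len(query & annot)
    b = len(query - annot)
    c = len(annot - query)
    d = len(universe) - a - b - c
    if a == 0:
        odds = 0.0
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return ORAResult(
        set_id="", overlap=a, query_size=len(query), set_size=len(annot),
        universe_size=len(universe), odds_ratio=float(odds), pvalue=float(p),
    )


def ora_table(query, sets: GeneSetCollection, universe, alternative: str = "greater") -> pd.DataFrame:
    """ORA over a collection, BH-adjusted across the tested sets."""
    rows = []
    for name, members in sets:
        r = ora(query, members, universe, alternative)
        rows.append(
            {"set_id": name, "overlap": r.overlap, "set_size": r.set_size,
             "odds_ratio": r.odds_ratio, "pvalue": r.pvalue}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def rank_genes(de: pd.DataFrame) -> pd.Series:
    """Signed -log10(padj) scores, ordered for GSEA.

    Features with NA padj are excluded; padj is floored at 1e-300; ties
    are broken by feature id so the order is deterministic.
    """
    tested = de.dropna(subset=["padj"])
    score = np.sign(tested["log2FC"]) * -np.log10(np.maximum(tested["padj"], PADJ_FLOOR))
    score = score.astype(float)
    order = sorted(score.index, key=lambda g: (-score[g], g))
    return score.loc[order]


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Enrichment score given sorted 0-based hit positions.

    `weights` are |score|^w at those positions.  The running-sum curve is
    piecewise linear, so its extremes occur at hit break points; the score
    is the extreme of largest magnitude (positive wins exact ties).
    """
    k = positions.size
    if k == 0 or k == n:
        return 0.0
    nr = weights.sum()
    if nr <= 0:
        # all hit scores are exactly zero: hits contribute nothing
        nr = 1.0
        weights = np.zeros_like(weights)
    miss = 1.0 / (n - k)
    cum_hit = np.cumsum(weights) / nr
    j = np.arange(1, k + 1)
    after = cum_hit - (positions + 1 - j) * miss                 # just after hit j
    before = cum_hit - weights / nr - (positions + 1 - j) * miss  # just before hit j
    hi = max(after.max(), before.max(), 0.0)
    lo = min(after.min(), before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def _prepare_ranked(ranked: pd.Series) -> tuple:
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    scores = ranked.loc[order].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(order)}
    return order, scores, index


def gsea_enrichment_score(ranked: pd.Series, members, weight: float = 1.0) -> float:
    """ES of one gene set against a ranked list (public single-set entry)."""
    _, scores, index = _prepare_ranked(ranked)
    pos = np.array(sorted(index[g] for g in members if g in index), dtype=int)
    w = np.abs(scores[pos]) ** weight
    return _es_from_positions(pos, w, scores.size)


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    nperm: int = 1000,
    weight: float = 1.0,
    min_size: int = 10,
    max_size: int = 800,
    seed=None,
    rng: np.random.Generator = None,
) -> pd.DataFrame:
    """Weighted pre-ranked GSEA with gene-permutation nulls.

    Sets are restricted to ranked features and skipped (with a log entry)
    when their restricted size falls outside [min_size, max_size].  The
    null for each set size is built from `nperm` random same-size sets;
    NES divides the ES by the mean |null ES| of matching sign and the
    empirical p-value is sign-matched.
    """
    if nperm < 100:
        log.warning("nperm=%d is very low; permutation p-values will be coarse", nperm)
    if rng is None:
        rng = np.random.default_rng(seed)
    order, scores, index = _prepare_ranked(ranked)
    n = scores.size
    absw = np.abs(scores) ** weight

    kept = {}
    for name, members in sets:
        pos = np.array(sorted(index[g] for g in members if g in index), dtype=int)
        if not (min_size <= pos.size <= max_size):
            log.info("skipping set %s: restricted size %d outside [%d, %d]", name, pos.size, min_size, max_size)
            continue
        kept[name] = pos

    # one shared null per distinct set size
    sizes = sorted({p.size for p in kept.values()})
    nulls = {}
    for sz in sizes:
        es_null = np.empty(nperm)
        for b in range(nperm):
            pos = np.sort(rng.choice(n, sz, replace=False))
            es_null[b] = _es_from_positions(pos, absw[pos], n)
        nulls[sz] = es_null

    rows = []
    for name, pos in kept.items():
        es = _es_from_positions(pos, absw[pos], n)
        null = nulls[pos.size]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            nes, p = np.nan, 1.0
        else:
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
            p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
        rows.append({"set_id": name, "size": pos.size, "ES": es, "NES": nes, "pvalue": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def marker_enrichment(deg_up, deg_down, markers: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA of each cell-type marker set against up- and down-DEG lists."""
    if not len(markers):
        raise ValueError("empty marker collection")
    uni = set(universe)
    for name, members in markers:
        if not set(members) & uni:
            raise ValueError(f"marker set {name!r} is disjoint from the universe")
    rows = []
    for direction, degs in (("up", deg_up), ("down", deg_down)):
        for name, members in markers:
            r = ora(set(degs) & uni, set(members) & uni, uni)
            rows.append(
                {"cell_type": name, "direction": direction, "overlap": r.overlap,
                 "odds_ratio": r.odds_ratio, "pvalue": r.pvalue}
            )
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def protein_marker_zscores(protein: OmicsMatrix, markers: GeneSetCollection, design: pd.DataFrame) -> pd.DataFrame:
    """Averaged per-group Z-scored expression of cell-type markers.

    Each feature is Z-scored across samples (mean 0, sd 1, ddof=1), then
    averaged over a cell type's detected markers within each sample group.
    Cell types with zero detected markers are reported with n_markers = 0
    and missing values.
    """
    data = protein.data
    if data.isna().any().any():
        raise ValueError("protein matrix must be complete (imputed) for Z-score summaries")
    z = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
    design = design.set_index("sample_id")
    groups = group_key(design.loc[list(data.columns)].reset_index().rename(columns={"index": "sample_id"}))
    groups.index = data.columns
    rows = []
    for name, members in markers:
        detected = [m for m in members if m in z.index]
        if not detected:
            rows.append({"cell_type": name, "n_markers": 0, **{g: np.nan for g in groups.unique()}})
            continue
        per_sample = z.loc[detected].mean(axis=0)
        by_group = per_sample.groupby(groups).mean()
        rows.append({"cell_type": name, "n_markers": len(detected), **by_group.to_dict()})
    return pd.DataFrame(rows).set_index("cell_type")
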