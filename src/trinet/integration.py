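"""miRNA-mRNA-protein interactome by correlation cascade.

The cascade: (1) select differentially expressed miRNAs at the stricter
integration thresholds (padj < 0.05, |log2FC| > 1), pooling the union
over time-point contrasts; (2) look up their predicted targets; (3)
correlate miRNA and target transcript expression (log10 of normalized
counts) and keep strongly anti-correlated pairs (r < -0.85, BH-adjusted
p < 0.05 over all tested pairs); (4) confirm repression at the protein
level (non-imputed abundances) by requiring a negative miRNA-protein
correlation; (5) assemble and export the tripartite graph.

The protein cohort is by default independent of the RNA cohort, so the
protein confirmation correlates per-group means rather than per-sample
values; the protein step applies a sign rule only (no multiple-testing
adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import OmicsMatrix, group_key

log = logging.getLogger(__name__)

PAIR_COLUMNS = ("mirna", "mrna", "r_mm", "p_mm", "padj_mm", "n_samples")
TRIPLET_COLUMNS = (
    "mirna", "mrna", "protein", "r_mm", "padj_mm", "r_mp",
    "direction_mirna", "direction_target", "bridge",
)


@dataclass
class Interactome:
    triplets: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.triplets.itertuples(index=False):
            prot = f"prot:{row.protein}"
            g.add_node(row.mirna, node_type="mirna", direction=row.direction_mirna)
            g.add_node(row.mrna, node_type="mrna", direction=row.direction_target,
                       bridge=bool(row.bridge))
            g.add_node(prot, node_type="protein", direction=row.direction_target)
            g.add_edge(row.mirna, row.mrna, edge_type="mirna-mrna",
                       r=float(row.r_mm), padj=float(row.padj_mm))
            g.add_edge(row.mrna, prot, edge_type="mrna-protein", r=float(row.r_mp))
        return g


def log10_normalized(counts: OmicsMatrix, size_factors: pd.Series, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(normalized count + pseudocount) expression for correlation."""
    norm = counts.data.astype(float) / size_factors.loc[list(counts.samples)]
    return np.log10(norm + pseudocount)


def select_de_mirnas(de_tables, padj_cut: float = 0.05, lfc_cut: float = 1.0) -> tuple:
    """Union of significant miRNAs over contrasts, split by direction.

    `de_tables` is one DE result frame or an iterable of them.  A miRNA
    that passes in both directions at different time points is assigned
    the direction of its largest-|log2FC| significant entry.
    """
    if isinstance(de_tables, pd.DataFrame):
        de_tables = [de_tables]
    best: dict = {}
    for de in de_tables:
        if de.empty:
            continue
        sig = de[(de["padj"] < padj_cut) & (de["log2FC"].abs() > lfc_cut)]
        for mi, lfc in sig["log2FC"].items():
            if mi not in best or abs(lfc) > abs(best[mi]):
                best[mi] = float(lfc)
    up = sorted(m for m, l in best.items() if l > 0)
    down = sorted(m for m, l in best.items() if l < 0)
    return up, down


def correlate_pairs(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    targets: dict,
    mirnas=None,
) -> pd.DataFrame:
    """Pearson correlation of each (miRNA, predicted target) pair.

    Expression inputs are log-scale matrices with matching sample
    columns.  p-values come from the t-distribution with n - 2 degrees of
    freedom; BH adjustment spans all tested pairs.
    """
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    mi_x = mirna_expr[shared]
    mr_x = mrna_expr[shared]
    if mirnas is None:
        mirnas = [m for m in targets if m in mi_x.index]
    rows = []
    n = len(shared)
    mr_arr = mr_x.to_numpy(dtype=float)
    mr_std = mr_arr.std(axis=1)
    mr_centered = mr_arr - mr_arr.mean(axis=1, keepdims=True)
    mr_index = {g: i for i, g in enumerate(mr_x.index)}
    for mi in mirnas:
        if mi not in mi_x.index:
            log.info("miRNA %s absent from expression matrix; skipped", mi)
            continue
        v = mi_x.loc[mi].to_numpy(dtype=float)
        v_c = v - v.mean()
        v_sd = v.std()
        for target in targets.get(mi, ()):
            idx = mr_index.get(target)
            if idx is None:
                log.info("target %s of %s absent from mRNA matrix; skipped", target, mi)
                continue
            if v_sd == 0 or mr_std[idx] == 0:
                continue
            r = float((v_c @ mr_centered[idx]) / (n * v_sd * mr_std[idx]))
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append({"mirna": mi, "mrna": target, "r_mm": r, "p_mm": p, "n_samples": n})
    out = pd.DataFrame(rows, columns=[c for c in PAIR_COLUMNS if c != "padj_mm"])
    if not out.empty:
        out["padj_mm"] = multipletests(out["p_mm"], method="fdr_bh")[1]
    else:
        out["padj_mm"] = pd.Series(dtype=float)
    return out[list(PAIR_COLUMNS)]


def filter_pairs(pairs: pd.DataFrame, r_cut: float = -0.85, padj_cut: float = 0.05) -> pd.DataFrame:
    """Keep strongly negative, significant pairs (strict inequalities)."""
    if pairs.empty:
        return pairs.copy()
    return pairs[(pairs["r_mm"] < r_cut) & (pairs["padj_mm"] < padj_cut)].reset_index(drop=True)


def _group_means(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    g = group_key(design)
    g.index = design["sample_id"]
    cols = [s for s in expr.columns if s in g.index]
    return expr[cols].T.groupby(g.loc[cols].to_numpy()).mean().T


def overlay_protein(
    pairs: pd.DataFrame,
    protein: OmicsMatrix,
    mirna_expr: pd.DataFrame,
    mirna_design: pd.DataFrame = None,
    protein_design: pd.DataFrame = None,
    matching: str = "group-mean",
    mirna_directions: dict = None,
    mrna_de_tables=None,
    r_mp_cut: float = 0.0,
    deg_padj: float = 0.05,
    deg_lfc: float = 0.58,
) -> Interactome:
    """Promote pairs with protein-level confirmation to triplets.

    For each surviving pair whose target has a detected protein, the
    miRNA-protein Pearson correlation is computed per sample (matched
    cohorts) or between per-group means (independent cohorts, the
    default); triplets require r_mp strictly below `r_mp_cut` (0).

    Direction flags come from the DE tables.  Targets that never pass the
    DEG cutoffs are retained but flagged ``bridge=True`` (they connect
    significant miRNAs and proteins without being significant themselves).
    """
    if matching not in ("group-mean", "sample-matched"):
        raise ValueError(f"unknown matching mode {matching!r}")
    mirna_directions = mirna_directions or {}

    # direction / bridge lookup for targets
    target_dir: dict = {}
    if mrna_de_tables is not None:
        if isinstance(mrna_de_tables, pd.DataFrame):
            mrna_de_tables = [mrna_de_tables]
        best_sig: dict = {}
        best_any: dict = {}
        for de in mrna_de_tables:
            for gene, row in de.dropna(subset=["pvalue"]).iterrows():
                lfc = float(row["log2FC"])
                padj = float(row["padj"]) if pd.notna(row["padj"]) else 1.0
                if padj < deg_padj and abs(lfc) > deg_lfc:
                    if gene not in best_sig or abs(lfc) > abs(best_sig[gene]):
                        best_sig[gene] = lfc
                cur = best_any.get(gene)
                if cur is None or padj < cur[0]:
                    best_any[gene] = (padj, lfc)
        for gene, lfc in best_sig.items():
            target_dir[gene] = ("up" if lfc > 0 else "down", False)
        for gene, (_, lfc) in best_any.items():
            if gene not in target_dir:
                target_dir[gene] = ("up" if lfc > 0 else "down", True)

    if matching == "group-mean":
        if mirna_design is None or protein_design is None:
            raise ValueError("group-mean matching requires both design tables")
        mi_g = _group_means(mirna_expr, mirna_design)
        pr_g = _group_means(protein.data, protein_design)
        shared_groups = [g for g in mi_g.columns if g in set(pr_g.columns)]
        mi_use, pr_use = mi_g[shared_groups], pr_g[shared_groups]
    else:
        shared = [s for s in mirna_expr.columns if s in set(protein.samples)]
        mi_use, pr_use = mirna_expr[shared], protein.data[shared]

    rows = []
    for row in pairs.itertuples(index=False):
        if row.mrna not in pr_use.index:
            log.info("no detected protein for %s; pair (%s, %s) not promoted", row.mrna, row.mirna, row.mrna)
            continue
        x = mi_use.loc[row.mirna].to_numpy(dtype=float)
        y = pr_use.loc[row.mrna].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            log.info("fewer than 3 usable points for protein %s; pair dropped", row.mrna)
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            continue
        r_mp = float(np.corrcoef(x[ok], y[ok])[0, 1])
        if not (r_mp < r_mp_cut):
            continue
        direction, bridge = target_dir.get(row.mrna, ("down" if row.r_mm < 0 and mirna_directions.get(row.mirna) == "up" else "up", True))
        rows.append(
            {
                "mirna": row.mirna,
                "mrna": row.mrna,
                "protein": row.mrna,
                "r_mm": row.r_mm,
                "padj_mm": row.padj_mm,
                "r_mp": r_mp,
                "direction_mirna": mirna_directions.get(row.mirna, "na"),
                "direction_target": direction,
                "bridge": bool(bridge),
            }
        )
    triplets = pd.DataFrame(rows, columns=list(TRIPLET_COLUMNS))
    return Interactome(triplets=triplets, thresholds={"r_mp": r_mp_cut})


def export_interactome(net: Interactome, outdir) -> dict:
    """Write triplets TSV, typed edge list TSV and GraphML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "triplets": outdir / "triplets.tsv",
        "edges": outdir / "edges.tsv",
        "graphml": outdir / "interactome.graphml",
    }
    net.triplets.to_csv(paths["triplets"], sep="\t", index=False)
    edges = []
    for row in net.triplets.itertuples(index=False):
        edges.append({"source": row.mirna, "target": row.mrna, "edge_type": "mirna-mrna",
                      "r": row.r_mm, "padj": row.padj_mm, "via_mirna": ""})
        edges.append({"source": row.mrna, "target": f"prot:{row.protein}", "edge_type": "mrna-protein",
                      "r": row.r_mp, "padj": "", "via_mirna": row.mirna})
    pd.DataFrame(edges, columns=["source", "target", "edge_type", "r", "padj", "via_mirna"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    nx.write_graphml(net.graph, paths["graphml"])
    return {k: str(v) for k, v in paths.items()}


def read_interactome(outdir) -> Interactome:
    """Reload an exported interactome from its triplets TSV."""
    path = Path(outdir) / "triplets.tsv"
    triplets = pd.read_csv(path, sep="\t")
    if triplets.empty:
        triplets = pd.DataFrame(columns=list(TRIPLET_COLUMNS))
    triplets["bridge"] = triplets["bridge"].astype(bool)
    return Interactome(triplets=triplets)
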