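"""End-to-end orchestration of the multi-omics analysis.

``run_all`` executes the stages in order — synthetic-data generation (or
loading of user inputs), sample QC, differential expression of both RNA
layers, enrichment, co-expression modules, protein preprocessing and the
integration cascade — writing every artifact under one output directory
and returning a run report with record counts at each transition.  All
randomness derives from the single configured seed, so identical
configurations yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, enrichment, integration, proteomics, qc, simulate
from .datatypes import TIME_POINTS, GeneSetCollection, OmicsMatrix
from . import io as tio

ALL_STAGES = ("qc", "de", "enrich", "wgcna", "proteins", "integrate")


@dataclass
class QCConfig:
    n_components: int = 5
    pca_pct: float = 99.5
    iqr_mult: float = 1.5


@dataclass
class DEConfig:
    expr_filter: float = 5.0
    padj: float = 0.05
    lfc_deg: float = 0.58


@dataclass
class EnrichConfig:
    nperm: int = 1000
    weight: float = 1.0
    min_size: int = 10
    max_size: int = 800


@dataclass
class WGCNAConfig:
    beta: float = 15.0
    signed: bool = True
    min_module_size: int = 100
    merge_cut: float = 0.16
    cut_height_frac: float = 0.99
    linkage: str = "average"
    top_n_genes: int = 2000


@dataclass
class ProteinConfig:
    min_frac: float = 0.8


@dataclass
class IntegrateConfig:
    padj: float = 0.05
    lfc_mirna: float = 1.0
    r_mm: float = -0.85
    r_mp: float = 0.0
    matching: str = "group-mean"


@dataclass
class RunConfig:
    outdir: str = "trinet_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    de: DEConfig = field(default_factory=DEConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    wgcna: WGCNAConfig = field(default_factory=WGCNAConfig)
    proteins: ProteinConfig = field(default_factory=ProteinConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["sim"]["groups"] = [list(g) for g in self.sim.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sections = {
            "sim": simulate.config_from_dict,
            "qc": lambda x: _section(QCConfig, x),
            "de": lambda x: _section(DEConfig, x),
            "enrich": lambda x: _section(EnrichConfig, x),
            "wgcna": lambda x: _section(WGCNAConfig, x),
            "proteins": lambda x: _section(ProteinConfig, x),
            "integrate": lambda x: _section(IntegrateConfig, x),
        }
        for key, builder in sections.items():
            if key in d and isinstance(d[key], dict):
                d[key] = builder(d[key])
        if "stages" in d:
            bad = set(d["stages"]) - set(ALL_STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _section(cls, d: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(cfg: RunConfig, data: simulate.SimDataset = None) -> dict:
    """Execute the enabled stages on simulated (or provided) data.

    Returns the run report (also written to ``run_report.json``).
    """
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "seed": cfg.seed, "counts": {}}
    counts = report["counts"]

    # ---- data ----------------------------------------------------------
    sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
    if data is None:
        data = simulate.simulate_dataset(sim_cfg)
    tio.write_matrix(data.mrna, outdir / "mrna_counts.tsv")
    tio.write_matrix(data.mirna, outdir / "mirna_counts.tsv")
    tio.write_matrix(data.protein, outdir / "protein.tsv")
    tio.write_sample_table(data.design, outdir / "samples.csv")
    tio.write_sample_table(data.protein_design, outdir / "protein_samples.csv")
    tio.write_target_map(data.truth.target_map, outdir / "targets.tsv")
    data.truth.to_json(outdir / "truth.json")
    counts["samples"] = len(data.design)
    counts["mrna_features"] = data.mrna.n_features
    counts["mirna_features"] = data.mirna.n_features
    counts["protein_features"] = data.protein.n_features

    design = data.design
    mrna, mirna = data.mrna, data.mirna

    try:
        # ---- QC --------------------------------------------------------
        if "qc" in cfg.stages:
            rep = qc.flag_outliers(mrna, cfg.qc.n_components, cfg.qc.pca_pct, cfg.qc.iqr_mult)
            with open(outdir / "qc_report.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=1)
            excluded = rep.excluded_samples
            (outdir / "excluded_samples.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
            keep = [s for s in mrna.samples if s not in set(excluded)]
            mrna = mrna.subset_samples(keep)
            mirna = mirna.subset_samples([s for s in mirna.samples if s not in set(excluded)])
            design = design[~design["sample_id"].isin(excluded)].reset_index(drop=True)
            counts["samples_excluded"] = len(excluded)
            counts["samples_retained"] = len(design)
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e

    de_mrna: dict = {}
    de_mirna: dict = {}
    norm_mrna = diffexpr.size_factors(mrna)
    norm_mirna = diffexpr.size_factors(mirna)
    try:
        if "de" in cfg.stages:
            filt_mrna = diffexpr.filter_low_expression(norm_mrna, cfg.de.expr_filter)
            filt_mirna = diffexpr.filter_low_expression(norm_mirna, cfg.de.expr_filter)
            counts["mrna_features_tested"] = filt_mrna.n_features
            counts["mirna_features_tested"] = filt_mirna.n_features
            deg_counts = {}
            for tp in TIME_POINTS:
                de_mrna[tp] = diffexpr.nb_wald_test(filt_mrna, design, ("sci", "sham", tp))
                de_mrna[tp].to_csv(outdir / f"de_mrna_{tp}.tsv", sep="\t", index_label="feature_id")
                de_mirna[tp] = diffexpr.nb_wald_test(filt_mirna, design, ("sci", "sham", tp))
                de_mirna[tp].to_csv(outdir / f"de_mirna_{tp}.tsv", sep="\t", index_label="feature_id")
                up, down = diffexpr.call_degs(de_mrna[tp], cfg.de.padj, cfg.de.lfc_deg)
                deg_counts[tp] = {"up": len(up), "down": len(down)}
            counts["degs"] = deg_counts
    except Exception as e:  # noqa: BLE001
        raise StageError("de", e) from e

    try:
        if "enrich" in cfg.stages and de_mrna:
            sets = GeneSetCollection({k: tuple(v) for k, v in data.truth.marker_sets.items()})
            universe = list(de_mrna[TIME_POINTS[-1]].index)
            rows = []
            rng = np.random.default_rng(cfg.seed + 17)
            for tp in TIME_POINTS:
                up, down = diffexpr.call_degs(de_mrna[tp], cfg.de.padj, cfg.de.lfc_deg)
                me = enrichment.marker_enrichment(up, down, sets.restrict(universe), universe)
                me.insert(0, "time_point", tp)
                rows.append(me)
            pd.concat(rows).to_csv(outdir / "marker_ora.tsv", sep="\t", index=False)
            ranked = enrichment.rank_genes(de_mrna[TIME_POINTS[-1]])
            gsea = enrichment.gsea_preranked(
                ranked, sets.restrict(universe), nperm=cfg.enrich.nperm, weight=cfg.enrich.weight,
                min_size=min(cfg.enrich.min_size, 5), max_size=cfg.enrich.max_size, rng=rng,
            )
            gsea.to_csv(outdir / "gsea_markers.tsv", sep="\t", index=False)
            counts["marker_sets_tested"] = len(sets)
    except Exception as e:  # noqa: BLE001
        raise StageError("enrich", e) from e

    try:
        if "wgcna" in cfg.stages:
            expr = np.log2(norm_mrna.normalized + 1.0)
            keep = expr.var(axis=1).sort_values(ascending=False).index[: cfg.wgcna.top_n_genes]
            expr = OmicsMatrix(expr.loc[sorted(keep)], "mrna_counts")
            params = coexpression.CoexpressionParams(
                beta=cfg.wgcna.beta, signed=cfg.wgcna.signed,
                min_module_size=cfg.wgcna.min_module_size, merge_cut=cfg.wgcna.merge_cut,
                cut_height_frac=cfg.wgcna.cut_height_frac, linkage=cfg.wgcna.linkage,
            )
            traits = coexpression.encode_traits(design)
            modules = coexpression.run_wgcna(expr, params, traits)
            modules.labels.to_csv(outdir / "module_labels.tsv", sep="\t", header=["module"], index_label="feature_id")
            modules.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
            if modules.module_trait is not None:
                modules.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
            counts["modules"] = len(modules.module_ids)
    except Exception as e:  # noqa: BLE001
        raise StageError("wgcna", e) from e

    protein_filtered = data.protein
    try:
        if "proteins" in cfg.stages:
            protein_filtered, prep = proteomics.filter_proteins(data.protein, data.protein_design, cfg.proteins.min_frac)
            with open(outdir / "protein_filter.json", "w") as fh:
                json.dump(prep.to_dict(), fh, indent=1)
            imputed = proteomics.impute_qrilc(protein_filtered, seed=cfg.seed + 23)
            tio.write_matrix(protein_filtered, outdir / "protein_filtered.tsv")
            tio.write_matrix(imputed, outdir / "protein_imputed.tsv")
            counts["proteins_kept"] = protein_filtered.n_features
    except Exception as e:  # noqa: BLE001
        raise StageError("proteins", e) from e

    try:
        if "integrate" in cfg.stages and de_mirna:
            up, down = integration.select_de_mirnas(list(de_mirna.values()), cfg.integrate.padj, cfg.integrate.lfc_mirna)
            directions = {m: "up" for m in up} | {m: "down" for m in down}
            counts["de_mirnas"] = len(directions)
            rna_design = design[design["condition"].isin(["sham", "sci"])]
            rna_samples = [s for s in rna_design["sample_id"] if s in set(mirna.samples)]
            mi_expr = integration.log10_normalized(mirna.subset_samples(rna_samples),
                                                   norm_mirna.size_factors)
            mr_expr_counts = mrna.subset_samples([s for s in rna_samples if s in set(mrna.samples)])
            mr_expr = integration.log10_normalized(mr_expr_counts, norm_mrna.size_factors)
            pairs = integration.correlate_pairs(mi_expr, mr_expr, data.truth.target_map, sorted(directions))
            counts["pairs_tested"] = len(pairs)
            surviving = integration.filter_pairs(pairs, cfg.integrate.r_mm, cfg.integrate.padj)
            counts["pairs_surviving"] = len(surviving)
            net = integration.overlay_protein(
                surviving, protein_filtered, mi_expr,
                mirna_design=design, protein_design=data.protein_design,
                matching=cfg.integrate.matching, mirna_directions=directions,
                mrna_de_tables=list(de_mrna.values()) if de_mrna else None,
                r_mp_cut=cfg.integrate.r_mp,
                deg_padj=cfg.de.padj, deg_lfc=cfg.de.lfc_deg,
            )
            counts["triplets"] = len(net.triplets)
            pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
            integration.export_interactome(net, outdir / "interactome")
    except Exception as e:  # noqa: BLE001
        raise StageError("integrate", e) from e

    report["wall_time_s"] = round(time.time() - t0, 2)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
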