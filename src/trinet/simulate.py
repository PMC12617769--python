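"""Tri-omic synthetic data with planted ground truth.

Generates matched mRNA and miRNA count matrices, a (by default independent)
protein log-abundance cohort, a miRNA->mRNA target map and a complete truth
ledger for a spinal-cord-injury-style design: one uninjured control group
plus sham and injured (SCI) groups at five acute-phase time points, n
animals per group.

The count model is the negative binomial the downstream Wald test assumes,
with variance mu + alpha*mu^2 and a DESeq2-style dispersion trend
alpha(mu) = a0 + a1/mu.  Injury effects are multiplicative on the mean and
follow one of three temporal archetypes (early, sustained, late).
Repression triplets are planted as a strongly induced (or suppressed)
miRNA paired with an oppositely regulated target mRNA whose protein tracks
the transcript; triplet effects use the full ``lfc_scale`` magnitude because
the integration cascade is designed to recover the strongest interactions,
while background differential expression draws smaller effects from a
normal distribution.  Cell-composition shifts are emulated by scaling
marker-gene means with per-group cell-type proportions.

Everything is driven by one seed; each stage consumes an independent child
stream so that toggling one stage does not reshuffle the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import TIME_POINTS, OmicsMatrix, validate_sample_table

ARCHETYPES = ("early", "sustained", "late")
#: Time points at which each archetype's multiplicative effect is active.
ARCHETYPE_TIMEPOINTS = {
    "early": ("3h", "12h"),
    "sustained": TIME_POINTS,
    "late": ("3d", "7d"),
}

#: Emulated cell types and their proportions per group.  The injured cord
#: loses neurons and oligodendrocytes while microglia/immune cells invade;
#: control and sham groups keep the baseline composition.
CELL_TYPES = ("neuron", "oligodendrocyte", "astrocyte", "microglia", "other")
_BASELINE_PROPORTIONS = {
    "neuron": 0.35,
    "oligodendrocyte": 0.15,
    "astrocyte": 0.20,
    "microglia": 0.05,
    "other": 0.25,
}
# Relative change of each type across SCI time points (fold vs baseline).
_SCI_TRAJECTORY = {
    "neuron": (0.95, 0.90, 0.80, 0.65, 0.55),
    "oligodendrocyte": (0.95, 0.90, 0.85, 0.75, 0.70),
    "astrocyte": (1.00, 1.05, 1.10, 1.25, 1.35),
    "microglia": (1.20, 1.60, 2.20, 3.20, 4.00),
    "other": (1.0, 1.0, 1.0, 1.0, 1.0),
}


def default_groups() -> tuple:
    groups = [("control", "none")]
    groups += [("sham", tp) for tp in TIME_POINTS]
    groups += [("sci", tp) for tp in TIME_POINTS]
    return tuple(groups)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_per_group: int = 4
    n_mrna: int = 3000
    n_mirna: int = 315
    n_protein: int = 600
    groups: tuple = field(default_factory=default_groups)
    de_fraction: float = 0.1
    lfc_scale: float = 2.5
    background_lfc_sd: float = 0.8
    fixed_lfc: float | None = None
    dispersion_trend: tuple = (0.05, 2.0)
    n_modules: int = 3
    module_size: int = 150
    module_cor: float = 0.8
    n_true_triplets: int = 30
    decoy_targets_per_mirna: int = 300
    protein_attenuation: float = 0.8
    protein_noise_sd: float = 0.3
    protein_matched: bool = False
    censor_quantile: float = 0.15
    n_outliers: int = 0
    markers_per_type: int = 40
    size_factor_range: tuple = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("n_per_group", "n_mrna", "n_mirna", "n_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("de_fraction", "module_cor", "censor_quantile"):
            v = getattr(self, name)
            if not (0 <= v < 1) and name != "de_fraction":
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (0 < self.protein_attenuation <= 1):
            raise ValueError("protein_attenuation must lie in (0, 1]")
        if not (0 <= self.censor_quantile < 1):
            raise ValueError("censor_quantile must lie in [0, 1)")
        if self.n_modules * self.module_size > self.n_mrna:
            raise ValueError("module demands exceed available genes")
        return self

    def n_samples(self) -> int:
        return self.n_per_group * len(self.groups)


@dataclass
class SimTruth:
    """Ledger of everything the generator planted.

    ``de_mrna`` / ``de_mirna`` are feature-by-time-point frames of true
    log2 fold changes (0 where the feature is null at that time point).
    """

    de_mrna: pd.DataFrame = None
    de_mirna: pd.DataFrame = None
    archetype_mrna: pd.Series = None
    archetype_mirna: pd.Series = None
    module_label: pd.Series = None
    true_triplets: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)
    cell_type_proportions: pd.DataFrame = None
    marker_sets: dict = field(default_factory=dict)
    target_map: dict = field(default_factory=dict)
    protein_genes: list = field(default_factory=list)
    # Per-gene group means and dispersions, kept so an independent protein
    # cohort can be drawn from the same underlying expression program.
    mu_mrna: pd.DataFrame = None
    alpha_mrna: pd.Series = None

    def de_flags(self, layer: str = "mrna") -> pd.DataFrame:
        lfc = self.de_mrna if layer == "mrna" else self.de_mirna
        return lfc != 0.0

    def to_json(self, path) -> None:
        payload = {
            "de_mrna": self.de_mrna.to_dict(),
            "de_mirna": self.de_mirna.to_dict(),
            "archetype_mrna": self.archetype_mrna.dropna().to_dict(),
            "archetype_mirna": self.archetype_mirna.dropna().to_dict(),
            "module_label": self.module_label.to_dict(),
            "true_triplets": [list(t) for t in self.true_triplets],
            "outlier_samples": list(self.outlier_samples),
            "cell_type_proportions": self.cell_type_proportions.to_dict(),
            "marker_sets": {k: list(v) for k, v in self.marker_sets.items()},
            "target_map": {k: sorted(v) for k, v in self.target_map.items()},
            "protein_genes": list(self.protein_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    """Independent child stream for one generation stage."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[stage])


def generate_design(cfg: SimConfig) -> pd.DataFrame:
    """Sample table for the configured group layout (deterministic ids)."""
    cfg.validate()
    rows = []
    for cond, tp in cfg.groups:
        for i in range(cfg.n_per_group):
            rows.append({"sample_id": f"{cond}_{tp}_{i + 1}", "condition": cond, "time_point": tp})
    return validate_sample_table(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2; alpha broadcast over rows."""
    size = 1.0 / np.maximum(alpha, 1e-12)
    size = np.broadcast_to(size[:, None], mu.shape)
    p = size / (size + np.maximum(mu, 1e-12))
    return rng.negative_binomial(size, p).astype(np.int64)


def _effect_matrix(lfc: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    """Per-gene, per-sample log2 effect from a gene x time-point LFC frame.

    Effects apply only to SCI samples at their time point (sham and
    control stay at baseline), so contrasts SCI - sham carry the effect.
    """
    eff = np.zeros((lfc.shape[0], len(design)))
    tp_arr = design["time_point"].to_numpy()
    sci = (design["condition"] == "sci").to_numpy()
    for j, tp in enumerate(TIME_POINTS):
        cols = sci & (tp_arr == tp)
        if cols.any():
            eff[:, cols] = lfc[tp].to_numpy()[:, None]
    return eff


def _assign_archetype_lfc(features, chosen, magnitudes, archetypes) -> tuple:
    """Build a feature x time-point LFC frame and archetype series."""
    lfc = pd.DataFrame(0.0, index=features, columns=list(TIME_POINTS))
    arch = pd.Series(pd.NA, index=features, dtype="object")
    for f, mag, a in zip(chosen, magnitudes, archetypes):
        arch.loc[f] = a
        for tp in ARCHETYPE_TIMEPOINTS[a]:
            lfc.loc[f, tp] = mag
    return lfc, arch


def simulate_counts(design: pd.DataFrame, cfg: SimConfig):
    """Simulate mRNA and miRNA count matrices plus the truth ledger."""
    cfg.validate()
    if len(design) != cfg.n_samples():
        raise ValueError("design inconsistent with cfg group layout")
    rng = _stage_rng(cfg, 1)
    a0, a1 = cfg.dispersion_trend

    genes = pd.Index([f"gene{i:05d}" for i in range(cfg.n_mrna)])
    mirnas = pd.Index([f"mir{i:04d}" for i in range(cfg.n_mirna)])

    # --- partition gene roles (disjoint) -------------------------------
    n_marker = cfg.markers_per_type * (len(CELL_TYPES) - 1)  # 'other' has no markers
    n_module = cfg.n_modules * cfg.module_size
    needed = n_module + cfg.n_true_triplets + n_marker
    if needed > cfg.n_mrna:
        raise ValueError("gene roles exceed available genes; increase n_mrna")
    perm = rng.permutation(cfg.n_mrna)
    module_idx = perm[:n_module]
    triplet_idx = perm[n_module : n_module + cfg.n_true_triplets]
    marker_idx = perm[n_module + cfg.n_true_triplets : needed]
    free_idx = perm[needed:]

    module_label = pd.Series(0, index=genes, dtype=int)
    for m in range(cfg.n_modules):
        module_label.iloc[module_idx[m * cfg.module_size : (m + 1) * cfg.module_size]] = m + 1

    marker_sets = {}
    marker_types = [ct for ct in CELL_TYPES if ct != "other"]
    for t, ct in enumerate(marker_types):
        ids = genes[marker_idx[t * cfg.markers_per_type : (t + 1) * cfg.markers_per_type]]
        marker_sets[ct] = tuple(sorted(ids))

    # --- base means and dispersions ------------------------------------
    base = np.exp(rng.normal(np.log(50.0), 1.5, cfg.n_mrna))
    # Planted features sit on well-expressed genes so that effects are
    # identifiable at n = 4/group (the regime the cascade targets).
    hot = np.concatenate([triplet_idx, marker_idx])
    base[hot] = np.exp(rng.uniform(np.log(200.0), np.log(2000.0), hot.size))
    base[module_idx] = np.exp(rng.uniform(np.log(200.0), np.log(2000.0), module_idx.size))
    alpha = a0 + a1 / base

    # --- planted differential expression -------------------------------
    tri_signs = rng.choice([-1.0, 1.0], cfg.n_true_triplets)
    tri_arch = rng.choice(ARCHETYPES, cfg.n_true_triplets)
    n_bg = int(round(cfg.de_fraction * free_idx.size))
    bg_idx = rng.choice(free_idx, n_bg, replace=False) if n_bg else np.array([], dtype=int)
    if cfg.fixed_lfc is not None:
        bg_mag = rng.choice([-1.0, 1.0], n_bg) * cfg.fixed_lfc
    else:
        bg_mag = rng.normal(0.0, cfg.background_lfc_sd, n_bg)
    bg_arch = rng.choice(ARCHETYPES, n_bg)

    de_genes = list(genes[triplet_idx]) + list(genes[bg_idx])
    de_mags = list(-tri_signs * cfg.lfc_scale) + list(bg_mag)
    de_archs = list(tri_arch) + list(bg_arch)
    lfc_mrna, arch_mrna = _assign_archetype_lfc(genes, de_genes, de_mags, de_archs)

    # --- cell-composition effects on marker genes ----------------------
    prop = pd.DataFrame(index=list(CELL_TYPES), columns=[f"{c}:{t}" for c, t in cfg.groups], dtype=float)
    for cond, tp in cfg.groups:
        col = f"{cond}:{tp}"
        raw = {}
        for ct in CELL_TYPES:
            f = 1.0
            if cond == "sci" and tp in TIME_POINTS:
                f = _SCI_TRAJECTORY[ct][TIME_POINTS.index(tp)]
            raw[ct] = _BASELINE_PROPORTIONS[ct] * f
        total = sum(raw.values())
        for ct in CELL_TYPES:
            prop.loc[ct, col] = raw[ct] / total

    marker_logfold = np.zeros((cfg.n_mrna, len(design)))
    gkey = (design["condition"] + ":" + design["time_point"]).to_numpy()
    for ct in marker_types:
        rows = genes.get_indexer(list(marker_sets[ct]))
        rel = (prop.loc[ct] / prop.loc[ct, "control:none"]).to_dict()
        marker_logfold[np.ix_(rows, np.arange(len(design)))] = np.log2(
            np.array([rel[k] for k in gkey])
        )[None, :]

    # --- module latent factors ------------------------------------------
    # Within-module correlation on the log scale is sigma_f^2/(sigma_f^2+v)
    # where v ~ alpha + 1/mu is the per-gene log-count noise variance.
    module_logfold = np.zeros((cfg.n_mrna, len(design)))
    if cfg.n_modules:
        v_med = np.median((alpha + 1.0 / base)[module_idx])
        sigma_f = np.sqrt(cfg.module_cor / (1.0 - cfg.module_cor) * v_med)
        for m in range(cfg.n_modules):
            f = rng.normal(0.0, 1.0, len(design))
            rows = module_idx[m * cfg.module_size : (m + 1) * cfg.module_size]
            module_logfold[rows, :] = (sigma_f * f - sigma_f**2 / 2.0) / np.log(2.0)

    # --- assemble means and draw ----------------------------------------
    sf_lo, sf_hi = cfg.size_factor_range
    sf_mrna = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), len(design)))
    eff = _effect_matrix(lfc_mrna, design)
    mu = base[:, None] * 2.0 ** (eff + marker_logfold + module_logfold)
    counts_mrna = _nb_draw(rng, mu * sf_mrna[None, :], alpha)

    # Group means (without size factors / module noise) for the protein stage.
    mu_group = pd.DataFrame(index=genes, columns=[f"{c}:{t}" for c, t in cfg.groups], dtype=float)
    for cond, tp in cfg.groups:
        col = f"{cond}:{tp}"
        e = lfc_mrna[tp].to_numpy() if (cond == "sci" and tp in TIME_POINTS) else np.zeros(cfg.n_mrna)
        ct_fold = np.zeros(cfg.n_mrna)
        for ct in marker_types:
            rows = genes.get_indexer(list(marker_sets[ct]))
            ct_fold[rows] = np.log2(prop.loc[ct, col] / prop.loc[ct, "control:none"])
        mu_group[col] = base * 2.0 ** (e + ct_fold)

    # --- miRNA layer -----------------------------------------------------
    base_mi = np.exp(rng.normal(np.log(50.0), 1.5, cfg.n_mirna))
    mi_perm = rng.permutation(cfg.n_mirna)
    tri_mi_idx = mi_perm[: cfg.n_true_triplets]
    base_mi[tri_mi_idx] = np.exp(rng.uniform(np.log(200.0), np.log(2000.0), tri_mi_idx.size))
    alpha_mi = a0 + a1 / base_mi
    free_mi = mi_perm[cfg.n_true_triplets :]
    n_bg_mi = int(round(cfg.de_fraction * free_mi.size))
    bg_mi = rng.choice(free_mi, n_bg_mi, replace=False) if n_bg_mi else np.array([], dtype=int)
    if cfg.fixed_lfc is not None:
        bg_mi_mag = rng.choice([-1.0, 1.0], n_bg_mi) * cfg.fixed_lfc
    else:
        bg_mi_mag = rng.normal(0.0, cfg.background_lfc_sd, n_bg_mi)
    de_mi = list(mirnas[tri_mi_idx]) + list(mirnas[bg_mi])
    de_mi_mags = list(tri_signs * cfg.lfc_scale) + list(bg_mi_mag)
    de_mi_archs = list(tri_arch) + list(rng.choice(ARCHETYPES, n_bg_mi))
    lfc_mirna, arch_mirna = _assign_archetype_lfc(mirnas, de_mi, de_mi_mags, de_mi_archs)

    sf_mi = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), len(design)))
    mu_mi = base_mi[:, None] * 2.0 ** _effect_matrix(lfc_mirna, design)
    counts_mirna = _nb_draw(rng, mu_mi * sf_mi[None, :], alpha_mi)

    # --- truth ledger ----------------------------------------------------
    triplets = [
        (mirnas[tri_mi_idx[k]], genes[triplet_idx[k]], genes[triplet_idx[k]])
        for k in range(cfg.n_true_triplets)
    ]
    # Protein panel: triplet targets and markers always covered, padded with
    # random other genes up to n_protein.
    covered = list(genes[triplet_idx]) + [g for ct in marker_types for g in marker_sets[ct]]
    remaining = [g for g in genes if g not in set(covered)]
    extra = cfg.n_protein - len(covered)
    if extra > 0:
        pad = rng.choice(len(remaining), min(extra, len(remaining)), replace=False)
        covered += [remaining[i] for i in sorted(pad)]
    protein_genes = sorted(covered[: max(cfg.n_protein, len(covered))])

    truth = SimTruth(
        de_mrna=lfc_mrna,
        de_mirna=lfc_mirna,
        archetype_mrna=arch_mrna,
        archetype_mirna=arch_mirna,
        module_label=module_label,
        true_triplets=triplets,
        cell_type_proportions=prop,
        marker_sets=marker_sets,
        protein_genes=protein_genes,
        mu_mrna=mu_group,
        alpha_mrna=pd.Series(alpha, index=genes),
    )
    mrna = OmicsMatrix(pd.DataFrame(counts_mrna, index=genes, columns=design["sample_id"].to_numpy()), "mrna_counts")
    mirna = OmicsMatrix(pd.DataFrame(counts_mirna, index=mirnas, columns=design["sample_id"].to_numpy()), "mirna_counts")
    return mrna, mirna, truth


def simulate_proteins(mrna: OmicsMatrix, truth: SimTruth, cfg: SimConfig, design: pd.DataFrame = None):
    """Protein log-abundances coupled to the mRNA program, left-censored.

    Returns ``(protein_matrix, protein_design)``.  With
    ``cfg.protein_matched`` the cohort reuses the RNA samples; otherwise an
    independent set of animals is drawn from the same per-group expression
    program (mass spectrometry on a separate cohort), with fresh sample ids.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 2)
    pg = [g for g in truth.protein_genes if g in mrna.features]
    if not pg:
        raise ValueError("protein features must map to a subset of mRNA features")

    if cfg.protein_matched:
        signal = np.log2(mrna.data.loc[pg].to_numpy() + 1.0)
        sample_ids = list(mrna.samples)
        pdesign = design.copy() if design is not None else None
    else:
        groups = list(truth.mu_mrna.columns)
        rows = []
        cols = []
        for g in groups:
            cond, tp = g.split(":")
            for i in range(cfg.n_per_group):
                cols.append(f"P_{cond}_{tp}_{i + 1}")
                rows.append({"sample_id": cols[-1], "condition": cond, "time_point": tp})
        pdesign = pd.DataFrame(rows)
        mu = np.repeat(truth.mu_mrna.loc[pg].to_numpy(), cfg.n_per_group, axis=1)
        counts = _nb_draw(rng, mu, truth.alpha_mrna.loc[pg].to_numpy())
        signal = np.log2(counts + 1.0)
        sample_ids = cols

    # The abundance keeps each protein's baseline (log2 of transcript level)
    # so that left-censoring acts on absolute abundance, as in label-free MS,
    # instead of coupling to the biological effect.  Per-row offsets are
    # invisible to every downstream correlation or Z-score computation.
    values = cfg.protein_attenuation * signal
    if cfg.protein_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.protein_noise_sd, values.shape)

    if cfg.censor_quantile > 0:
        for j in range(values.shape[1]):
            cut = np.quantile(values[:, j], cfg.censor_quantile)
            values[values[:, j] < cut, j] = np.nan

    protein = OmicsMatrix(pd.DataFrame(values, index=pg, columns=sample_ids), "protein_log_abundance")
    return protein, pdesign


def make_target_map(truth: SimTruth, cfg: SimConfig) -> dict:
    """miRNA -> predicted-target map: true targets plus random decoys.

    Stands in for a sequence-based target-prediction database: every miRNA
    receives ``decoy_targets_per_mirna`` random non-target genes, and
    planted triplet miRNAs additionally carry their true targets.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 4)
    genes = list(truth.de_mrna.index)
    true_by_mirna: dict = {}
    all_targets: set = set()
    for mi, mr, _ in truth.true_triplets:
        true_by_mirna.setdefault(mi, set()).add(mr)
        all_targets.add(mr)
    if cfg.decoy_targets_per_mirna > len(genes):
        raise ValueError("decoy_targets_per_mirna exceeds available genes")
    # Decoys are non-target genes: the pool excludes every gene that is a
    # planted target of any miRNA, so a decoy is never a real target.
    pool = [g for g in genes if g not in all_targets]
    target_map = {}
    for mi in truth.de_mirna.index:
        true = true_by_mirna.get(mi, set())
        n_decoy = min(cfg.decoy_targets_per_mirna, len(pool))
        decoys = rng.choice(len(pool), n_decoy, replace=False) if n_decoy else []
        target_map[mi] = sorted(true | {pool[i] for i in decoys})
    truth.target_map = target_map
    return target_map


def inject_outliers(matrix: OmicsMatrix, design: pd.DataFrame, cfg: SimConfig):
    """Degrade ``n_outliers`` samples: library x0.1 plus a profile shuffle.

    Emulates failed libraries with aberrant expression profiles: the
    selected columns are down-scaled to 10% depth and 30% of their gene
    values are permuted among themselves.  Flags are recorded in the
    returned sample table (column ``outlier_injected``).
    """
    cfg.validate()
    if cfg.n_outliers >= len(design):
        raise ValueError("n_outliers must be smaller than the number of samples")
    rng = _stage_rng(cfg, 3)
    data = matrix.data.copy()
    design = design.copy()
    design["outlier_injected"] = False
    chosen = []
    if cfg.n_outliers > 0:
        idx = rng.choice(len(design), cfg.n_outliers, replace=False)
        for i in idx:
            sid = design["sample_id"].iloc[i]
            chosen.append(sid)
            col = data[sid].to_numpy().astype(float) * 0.1
            col = np.rint(col).astype(np.int64)
            n_shuf = int(round(0.3 * len(col)))
            pos = rng.choice(len(col), n_shuf, replace=False)
            col[pos] = col[rng.permutation(pos)]
            data[sid] = col
        design.loc[design["sample_id"].isin(chosen), "outlier_injected"] = True
    return OmicsMatrix(data, matrix.layer), design, chosen


@dataclass
class SimDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    design: pd.DataFrame
    mrna: OmicsMatrix
    mirna: OmicsMatrix
    protein: OmicsMatrix
    protein_design: pd.DataFrame
    truth: SimTruth
    cfg: SimConfig


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator: design, counts, proteins, targets, outliers."""
    cfg.validate()
    design = generate_design(cfg)
    mrna, mirna, truth = simulate_counts(design, cfg)
    protein, pdesign = simulate_proteins(mrna, truth, cfg, design)
    make_target_map(truth, cfg)
    mrna, design, outliers = inject_outliers(mrna, design, cfg)
    truth.outlier_samples = outliers
    design["library_size"] = mrna.library_sizes().loc[design["sample_id"]].to_numpy()
    if cfg.protein_matched:
        pdesign = design.copy()
    return SimDataset(design, mrna, mirna, protein, pdesign, truth, cfg)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    d = dict(d)
    if "groups" in d:
        d["groups"] = tuple(tuple(g) for g in d["groups"])
    return SimConfig(**d)
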