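# Methods

This note records the models, parameter choices and numerical decisions
behind `trinet`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Study design and synthetic data

The generator emulates a rat spinal-cord-injury time course: one uninjured
control group plus sham-operated and injured (SCI) groups at 3 h, 12 h,
24 h, 3 d and 7 d post-injury, n = 4 animals per group (44 samples).
Counts are negative binomial with variance μ + αμ² and a DESeq2-style
dispersion trend α(μ) = a₀ + a₁/μ (defaults a₀ = 0.05, a₁ = 2 — typical
bulk RNA-seq values: α ≈ 0.05 for well-expressed genes, rising for low
counts).  Per-sample size factors are log-uniform in [0.5, 2], emulating a
4-fold technical depth spread.  Base means are log-normal
(median 50, log-sd 1.5); planted features (triplets, markers, module
genes) are drawn from well-expressed genes (200–2,000) because the
integration cascade targets identifiable effects at n = 4/group.

**Injury effects.**  Differential expression is multiplicative on the mean
and applies only to SCI groups, following one of three temporal
archetypes — *early* (3 h, 12 h), *sustained* (all time points), *late*
(3 d, 7 d) — mirroring the three temporal clusters of dysregulated miRNAs
the analysis is designed around.  Background DE (10% of genes and miRNAs
by default) draws effects from N(0, 0.8²) log₂ units; an optional
`fixed_lfc` plants a constant magnitude for power studies.

**Repression triplets.**  Each of the 30 planted triplets couples a miRNA
(|log₂FC| = `lfc_scale`, default 2.5, random sign and archetype) to a
target mRNA with the opposite effect and to that mRNA's protein.  Triplet
effects use the full `lfc_scale` rather than the background distribution:
the cascade's r < −0.85 filter selects, by construction, only the
strongest interactions, so the planted truth represents exactly that
regime.  The magnitude was fixed analytically before any end-to-end runs:
for an early/late-archetype pair only 8 of 40 correlated samples carry the
effect, and a point-biserial argument gives an expected pair correlation
of ≈ 0.9 at Δ = 2.5 with the default noise (α ≈ 0.055 at μ ≥ 200), i.e.
just inside the −0.85 band; weaker planting would make early/late triplets
undetectable by design rather than by failure of the method.

**Target map.**  Stands in for a sequence-based target-prediction
database: every miRNA receives 300 random decoy targets drawn from genes
that are *no* miRNA's planted target, and triplet miRNAs additionally
carry their true targets.  Decoys can still be differentially expressed
background genes, so spuriously anti-correlated pairs do occur and the
cascade's precision is a meaningful quantity.

**Cell composition.**  Four cell types with marker sets (40 genes each)
emulate composition shifts: neurons and oligodendrocytes decline after
injury, astrocytes rise moderately and microglia expand up to 4-fold by
7 d; marker-gene means scale with the per-group proportions (which sum to
one per group).  This yields marker enrichment in directional DEG lists
and monotone marker-protein Z-score trajectories.

**Modules.**  Module genes share a per-module latent factor; the loading
is calibrated from the delta-method log-count noise v ≈ α + 1/μ so the
expected within-module correlation equals `module_cor`
(σ_f² = cor/(1−cor)·v, default 0.8).  Module factors are independent of
condition, so module recovery is tested separately from DE recovery.

**Proteins.**  The protein layer covers 600 genes (triplet targets and
markers always included).  Abundance = attenuation · log₂(counts + 1) +
N(0, 0.3), attenuation 0.8, for an *independent* cohort of animals by
default (drawn from the same per-group expression program with fresh NB
noise), matching a design where mass spectrometry used a separate sample
set; a flag switches to a sample-matched cohort.  Each protein keeps its
baseline (log transcript level): left-censoring — values below the
per-sample 15% quantile set missing — therefore acts on absolute
abundance, as in label-free MS where dropout is driven by being near the
detection limit, not by row-relative change.  (An earlier row-centred
variant coupled censoring to the planted repression itself and made
repressed proteins vanish exactly where the signal was.)

**Outlier injection** scales a sample's library to 10% and permutes 30% of
its gene values, emulating a failed library with an aberrant profile.

All stages draw from independent child streams of one seed, so disabling
one stage does not reshuffle the others; a fixed seed gives byte-identical
output.

What the generator does **not** model: batch effects, GC/length biases,
spike-ins, isoform structure, miRNA-specific count distributions (the
miRNA layer reuses the mRNA NB machinery with 315 features), correlated
biological replicates, or peptide-level proteomics artifacts.  Passing the
synthetic benchmarks therefore shows the chain is implemented correctly
and calibrated under its own assumptions — not that those assumptions hold
for any particular real dataset.

## Sample QC

Counts are log(1+x)-transformed, zero-variance genes dropped, samples
centred, and PC scores obtained by SVD.  Mahalanobis distance uses the
diagonal score covariance (exact in PC space); K = min(5, n−1) components
by default, exposed because the appropriate number is data-dependent.
Flags: distance strictly above the empirical 99.5th percentile (linear
interpolation between order statistics), and raw library size strictly
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].  Exclusion is the *intersection*:
the percentile criterion alone always flags the most extreme sample, so
the depth criterion acts as a veto.  Note that with n = 44 the
interpolated 99.5th percentile lies between the two largest distances, so
at most one sample can be PCA-flagged per pass; the IQR fences are only
meaningful when intended sequencing depths are comparable — with a 4-fold
technical depth spread the lower fence is negative and a 10× depth drop
goes unflagged by depth alone.

## Differential expression

A deliberately compact NB Wald engine (used for both mRNA and miRNA
layers): median-of-ratios size factors (reference = per-feature geometric
mean over samples, features with any zero excluded); expression filter
keeping features with mean normalized count ≥ 5; per-gene dispersion by
pooled within-arm method of moments, a 1/μ trend fitted by non-negative
least squares to the *unclipped* moment estimates (clipping at zero first
biases the trend upward for low-dispersion data), and strong shrinkage
toward the trend (weight 0.75) — appropriate at n = 4/group where
gene-wise estimates are extremely noisy.  Arm means are fitted by Newton
iteration on the NB score with size-factor offsets; the Wald statistic is
log₂FC over its delta-method standard error, two-sided normal p,
Benjamini–Hochberg adjustment over tested features.  Features with zero
counts in both arms are excluded from the BH family; |log₂FC| is capped
at 10.  Omitted relative to full DESeq2: Cook's-distance outlier
handling, independent filtering, LFC shrinkage and the local dispersion
fit.  Calibration is property-checked by simulation (null type-I error
≈ 0.05, power ≈ 1 at |log₂FC| = 2 for well-expressed genes) rather than by
matching another implementation's output.

Two idealizations worth noting: size factors are identified only up to a
common scale, so rescaling one sample by c multiplies its factor *ratio*
to other samples by exactly c (the factor itself by c^((m−1)/m)); and
fold-change invariance under such rescaling is exact only in the Poisson
limit, since NB likelihood weight depends on depth.

## Enrichment

ORA uses the 2×2 table odds ratio (ad/bc, with 0 and ∞ conventions) and a
one-sided (enrichment) Fisher's exact test; depletion is available behind
a flag.  The universe for DEG ORA is the set of expression-filtered
features, not the whole annotation, to avoid detection-bias inflation.

GSEA runs in weighted pre-ranked mode: scores sign(log₂FC)·−log₁₀(padj)
(padj floored at 1e−300; NA excluded), ties broken by feature id.  The
enrichment score is the extreme of the running sum with |score|^w hit
increments (w = 1) and uniform miss decrements; since the curve is
piecewise linear, only the break points just before/after each hit need
evaluation, making per-set cost O(k log k).  The null is gene-set
permutation (the only choice for pre-ranked input), one shared null per
set size; NES divides ES by the mean |null ES| of matching sign, and the
empirical p is sign-matched, with the +1 correction.  Set sizes outside
[10, 800] after restriction to ranked features are skipped with a log
entry.

Marker summaries Z-score each protein across samples (mean 0, sd 1,
ddof = 1) before averaging over a cell type's detected markers per group;
types with no detected markers are reported with n = 0, not dropped.

## Co-expression modules

Signed adjacency ((1+cor)/2)^β with β = 15 (fixed, no scale-free fit
scan), unsigned-TOM formula applied to the signed adjacency (the common
signed-hybrid convention, flag-switchable), average-linkage clustering of
1−TOM.  The dynamic hybrid tree cut of the reference workflow is replaced
by a static cut at 0.99 × the maximum merge height combined with the
minimum-size rule (100 genes); this keeps the workflow's parameters while
staying proportionate, and the cut fraction is exposed.  Eigengenes are
the first right-singular vectors of standardized module expression
(unit norm, oriented so mean member correlation is positive); modules
with eigengene dissimilarity strictly below 0.16 merge iteratively
(closest pair first), then every assigned gene moves to its argmax-kME
module.  Module–trait correlation uses Pearson r with a t-distribution
p (df = n−2) against numeric traits (injury indicator, time in hours),
flagged at |r| > 0.6 and p < 0.05, both strict.

## Proteomics preprocessing

"Quantified" means non-missing; a protein is kept when at least one
sample group reaches ≥ 80% completeness (the any-group reading — the
all-groups reading would discard nearly everything under censoring).
QRILC imputation fits, per sample, a normal to the observed order
statistics regressed on standard-normal quantiles at Blom plotting
positions, treating the observed values as the upper tail of the full
feature count; missing values are drawn from that normal truncated above
at the sample's observed minimum.  Samples with < 5 observed values fall
back to a pooled global fit (logged).  Observed cells are never modified,
and imputation is seed-reproducible.  Downstream correlation uses the
non-imputed matrix with pairwise-complete observations; the imputed
matrix feeds only Z-score summaries.

## Integration cascade

DE-miRNA selection pools the union over all time-point contrasts (the
acute phase is integrated as a whole; per-time-point mode available), at
the stricter thresholds padj < 0.05 and |log₂FC| > 1.  Expression for
correlation is log₁₀(normalized count + 1) — pseudocount 1, bounded and
conventional.  Pearson r and t-distribution p are computed for every
(selected miRNA, predicted target) pair over all QC-passed sham + SCI
samples shared by the two RNA layers; BH adjustment spans all tested
pairs in the run (global family, since the selection pools time points).
Pairs survive at r < −0.85 and padj < 0.05, both strict.

Protein confirmation defaults to group-mean correlation (per-group means
of miRNA expression vs. protein abundance over shared groups with ≥ 1
observation, ≥ 3 groups required) because the default protein cohort is
independent of the RNA cohort; sample-matched mode correlates per sample.
The protein rule is sign-only (r < 0, strict) with no multiplicity
adjustment — the protein layer confirms rather than discovers.  Targets
that never pass the DEG cutoffs are retained in the interactome but
flagged `bridge=true`, since they connect significant miRNAs and
proteins without being significant themselves.  All thresholds are
monotone: tightening any of them can only shrink the triplet set.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use 2,500-gene null/planted
datasets (5 seeds) for calibration, 750-gene expression matrices for
module recovery, and the full default design (3,000 genes, 315 miRNAs,
30 triplets, 300 decoys/miRNA, 10 seeds) for cascade recovery — sizes
chosen so the complete benchmark runs in well under a minute per
component on a single core while keeping ≥ 2,000 features in every
family-wise calibration measurement.

## Known limitations

- The Wald engine's calibration is demonstrated under the generator's NB
  assumptions; heavy-tailed real data (outlier replicates) would need the
  omitted Cook's-distance machinery.
- The static dendrogram cut can fragment nested or weakly separated
  modules that the dynamic hybrid algorithm would capture; module counts
  on real data are therefore not comparable to the reference workflow.
- Group-mean protein correlation over ≤ 11 groups has low resolution; the
  sign-only rule is intentionally permissive and inherits that weakness.
- The percentile-based QC flag always marks the most extreme sample, so
  exclusion decisions rest entirely on the depth veto; datasets with
  genuinely variable sequencing depth need the fences interpreted with
  care.
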