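# trinet

Multi-omics integration of the acute response to spinal cord injury (SCI):
from mRNA / small-RNA count matrices and protein log-abundances to a
miRNA–mRNA–protein interactome.

Bulk RNA-seq, small RNA-seq and label-free proteomics of the injured cord
each capture one layer of a regulatory cascade: an induced miRNA represses
its target transcript, and the repression propagates to the protein.
`trinet` implements the full analysis chain used to reconstruct that
cascade, together with a synthetic tri-omic data generator with planted
ground truth so every stage is testable without any external download:

- **Sample QC** — log(1+x) transform, PCA, Mahalanobis distance from the
  centroid; a sample is excluded only when it exceeds the empirical 99.5th
  distance percentile *and* its library size falls outside 1.5×IQR fences.
- **Differential expression** — median-of-ratios size factors, a
  mean-normalized-count ≥ 5 expression filter, and a per-time-point
  negative-binomial Wald test (variance μ + αμ², moment dispersions shrunk
  toward an α(μ) = a₀ + a₁/μ trend). DEGs: padj < 0.05 and |log₂FC| > 0.58.
- **Enrichment** — over-representation (odds ratio + one-sided Fisher),
  weighted pre-ranked GSEA (score = sign(log₂FC)·−log₁₀ padj, 1,000
  gene-set permutations, set sizes 10–800) and cell-type marker summaries.
- **Co-expression modules** — signed adjacency ((1+cor)/2)^β with β = 15,
  topological overlap, average-linkage clustering of 1−TOM, minimum module
  size 100, eigengene merging at dissimilarity 0.16, kME reassignment, and
  module–trait correlation (flagged at |r| > 0.6, p < 0.05).
- **Proteomics preprocessing** — keep proteins quantified in ≥ 80% of at
  least one group; impute left-censored missing values by QRILC
  (per-sample truncated normal fitted to the observed upper tail).
- **Integration** — the correlation cascade: DE miRNAs (padj < 0.05,
  |log₂FC| > 1) → predicted targets → Pearson r < −0.85 with BH-adjusted
  p < 0.05 on log₁₀ normalized expression → negative miRNA–protein
  correlation (non-imputed abundances) → tripartite interactome exported
  as edge-list TSV and GraphML.

## Worked example

Run the whole chain on a synthetic dataset (default design: 1 control +
5 sham + 5 SCI time-point groups, n = 4; 3,000 genes, 315 miRNAs, 600
proteins, 30 planted repression triplets, 300 decoy targets per miRNA):

```sh
trinet all --out demo_run --seed 5
```

which finishes in a few seconds and prints the per-stage record counts,
ending with:

```
 "modules": 3,
 "proteins_kept": 512,
 "de_mirnas": 44,
 "pairs_tested": 13230,
 "pairs_surviving": 32,
 "triplets": 26
```

Reading the cascade bottom-up: 44 miRNAs pass the integration DE cutoffs;
their 13,230 predicted miRNA–target pairs shrink to 32 strongly
anti-correlated pairs (r < −0.85, padj < 0.05), of which 26 are confirmed
by a negative protein correlation — against 30 planted triplets, so the
run recovers most of the planted regulation with few false calls.  The
three planted co-expression modules are found exactly.  All outputs
(DE tables, QC report, module labels/eigengenes, filtered and imputed
protein matrices, `interactome/triplets.tsv`, GraphML) are written under
`demo_run/`, along with `run_report.json` echoing the full configuration;
rerunning with the same seed reproduces every file byte for byte.

Each stage is also available as a library function
(`trinet.diffexpr.nb_wald_test`, `trinet.coexpression.run_wgcna`,
`trinet.integration.correlate_pairs`, ...) and as an individual
subcommand (`trinet simulate|qc|de|enrich|wgcna|proteins|integrate`).

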