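# peaknet

Correlation-network analysis of ATAC-seq peak matrices: hub-peak selection,
principal-component axis stratification, survival association and gene-set
enrichment — with a synthetic-cohort generator so every stage is testable
without access to protected tumor data.

## The problem

Chromatin accessibility assays summarize a tumor's regulatory state as tens
of thousands of fixed-width peaks (501 bp) with a normalized height per
sample. Working directly with ~10⁵ correlated features against small
clinical cohorts is hopeless, so this package implements a network-based
reduction: peaks that co-vary with many other peaks ("hub peaks") are more
likely to sit in coordinated regulatory programs, and a handful of principal
components of the hub set captures the biology worth correlating with
clinical variables — here, smoking exposure (pack-years) and survival in a
lung-adenocarcinoma-like cohort.

## The method

1. **QC.** A peak is low-quality if some value repeats in more than 5% of
   the samples of any single cancer type (repeated values betray uncovered
   regions that were zero before normalization). Per peak, entries outside
   the Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are masked out of every
   correlation.
2. **Network.** Peaks *i, j* are connected **directly** when
   `|r(i,j)| ≥ 0.4` (Pearson, pairwise-complete over unmasked entries;
   the cutoff is calibrated against a background noise level of ~0.2), and
   **indirectly** when they share a direct neighbor without being directly
   connected. A peak's connection count is its number of distinct peers
   over both edge kinds; the **hub set** is the top decile
   (`floor(0.10·M)` peaks — 6,431 from a 64,316-peak network).
3. **Axis analysis.** PCA of the cohort over the hub peaks (variables
   centered and scaled, five components). A sample's *distance* from the
   PC-k axis is `|score_k|`; the cohort-mean distance is the *border*
   splitting samples into **inside** (stable component-related peaks) and
   **outside** groups. Light (<20 pack-years) and heavy (≥20) smokers are
   compared on the distances with a two-tailed Welch t-test after iterative
   Grubbs outlier exclusion.
4. **Survival.** Kaplan-Meier curves and the log-rank test compare OS and
   PFS between the inside and outside groups; Cox proportional-hazards
   models (univariable, and multivariable with stage, age, gender, T/N/M)
   quantify the hazard ratio of being outside the border.
5. **Enrichment.** Peaks with `|peak-PC correlation| > 0.8` on the
   component of interest map to genes, which are tested against a
   hallmark-style GMT collection with the hypergeometric overlap test and
   Benjamini-Hochberg FDR control (`q < 0.05`).

The synthetic generator plants exactly this structure — correlated hub
blocks driven by latent factors, a smoking-linked factor with inflated
variance in heavy smokers, exponential survival with hazard rising along
that factor, zero-inflation and heavy-tailed outliers — so recovery of
every planted quantity is a testable claim. See `docs/methods.md`.

## Worked example

```sh
peaknet synth --seed 3 --outdir demo/data
peaknet run-all --config demo/config.yaml --outdir demo/run
```

with `demo/config.yaml`:

```yaml
matrix_path: demo/data/matrix.tsv
clinical_path: demo/data/clinical.tsv
peak_gene_map_path: demo/data/peak_gene_map.tsv
gmt_path: demo/data/gene_sets.gmt
seed: 3
```

On the default synthetic cohort (2,000 peaks × 100 samples, 20 planted hub
blocks, 5% zero-inflation, 2% outliers) the run prints a summary containing:

```
qc:               kept 894/2000 peaks; masked 2885 outlier entries
network:          894 nodes; 89 hubs selected
pca explained:    [0.1114, 0.0611, 0.0361, 0.0320, 0.0301]
axis partition:   border 1.7955; 60 inside / 40 outside
group comparison: t = -2.697, p = 0.00827 (1 Grubbs exclusion)
survival:         OS log-rank p = 0.00138, univariable HR (outside) = 2.24
                  PFS log-rank p = 0.0632
enrichment:       HALLMARK_SYNTH_POSITIVE q = 2.4e-08 (only significant set)
```

Reading this: the repeated-value filter removes roughly half the peaks (the
zero-inflated entries are designed to trip it), the hub selection is
dominated by planted block peaks, the heavy-smoker group sits significantly
farther from the PC2 axis (negative t: light mean < heavy mean), samples
outside the PC2 border die faster (HR ≈ 2), and the gene set fed by the hub
blocks is the lone enrichment hit.

Each subcommand (`synth`, `qc`, `network`, `pca`, `survival`, `enrich`) is
also usable standalone; the library API in `peaknet.*` exposes the same
operations for scripting.

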