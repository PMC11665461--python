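# Methods

This note records the statistical model behind `peaknet`, the defaults and
why they are what they are, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Pipeline model

The analysis treats a peaks × samples matrix of non-negative normalized
accessibility values as the primary object. Three derived structures carry
the inference:

* a **co-accessibility network** whose nodes are QC-passing peaks. Direct
  edges require `|r| ≥ r_threshold` (default 0.4, against an assumed
  background correlation noise level of about 0.2). Indirect edges connect
  two non-adjacent peaks sharing at least one direct neighbor; the closure
  is applied for exactly one level of intermediation (`indirect_depth=1`).
  Deeper closure is available behind the `indirect_depth` flag but is off
  by default: full transitive closure would connect entire components and
  erase the degree contrast that hub selection depends on. Direct and
  indirect edges count equally toward a node's connection count.
* **hub peaks**: exactly `floor(hub_fraction · M)` nodes with the highest
  connection count (default decile). Ties at the cutoff break by
  lexicographic peak id so a selection is reproducible across runs and
  platforms.
* **axis partitions**: per principal component k, distance
  `d_s = |score_{s,k}|`, border `mean_s(d_s)`, inside = strictly below the
  border. Strictness matters only on ties, which have measure zero in
  continuous data; the choice is recorded here because it is otherwise
  arbitrary.

### Correlation details

Pearson correlations are computed over pairwise-complete, unmasked
observations. Entries flagged by the per-peak Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are excluded from every correlation — both
peak-peak (network) and peak-component (enrichment gate) — but are never
removed from the matrix and do not affect the PCA decomposition itself.
Quartiles use linear interpolation of order statistics (the type-7
estimator), the default of the mainstream statistical environments, since
hand-computed fixtures depend on the choice. A correlation is treated as
missing (no edge) when fewer than `min_pairs = 8` complete observations
remain or either side has zero variance on the complete subset. The
pairwise products stream over row blocks, so no full M × M dense table is
required to build edges for large peak sets.

### PCA

Samples are observations, hub peaks variables; variables are centered and
scaled to unit (population) variance by default. Scores come from the SVD
of the standardized matrix; explained fractions are squared singular
values over their total. Component signs are arbitrary in theory, so each
component is oriented to correlate positively with its most-correlated
variable. Constant variables are dropped with a warning before scaling.
Components beyond the matrix rank are never reported; with an n-sample
cohort at most n − 1 components exist.

### Group comparison

Smoking groups split at 20 pack-years (≥ 20 = heavy); missing pack-years
means unknown and the sample is excluded from the comparison (never coded
as zero — zero pack-years is a meaningful never-smoker value). Within each
group, iterative two-sided Grubbs exclusion at α = 0.05 removes the most
extreme distance while the Grubbs statistic exceeds its t-based critical
value; there is no cap on removals, but in practice one or zero values
fall. Grubbs tests one value at a time, so two opposite extremes can mask
each other — this is a property of the test, not a defect, and is covered
by a regression test. The group test is Welch's unequal-variance t by
default (`equal_var=True` recovers the pooled Student form).

### Survival

Kaplan-Meier product-limit curves per partition group; two-group log-rank
test. Cox models use the partial likelihood with the Efron tie
approximation (the lifelines default). Ordered clinical categories (stage,
T/N/M) collapse to numeric ranks by default; a dummy coding exists behind
`categorical="dummy"` but is numerically untenable at the cohort sizes
this analysis targets (with ~20 samples a full dummy expansion of stage
plus T/N/M exceeds the event count). Fits are refused outright when events
fall below the coefficient count and warned about below ten events per
coefficient. Unordered labels (gender) are dummy-coded against the first
level.

### Enrichment

The component gate keeps peaks with `|peak-PC correlation|` strictly
greater than 0.8 — absolute value because component orientation is
arbitrary. Their genes (via the peak-gene map) form an unranked query, so
enrichment is the hypergeometric upper-tail overlap test per gene set with
Benjamini-Hochberg adjustment across all tested sets; the ranked
running-sum enrichment statistic is undefined for an unranked list and is
deliberately not offered. The default gene universe is every gene
reachable from the peak-gene map, overridable by the caller; query genes
outside the universe are dropped with a warning.

## Synthetic generator

A latent-factor linear-Gaussian model generates every input the pipeline
reads. With within-block correlation c, a hub-block peak is
`√c · f + √(1−c) · ε` for its block's factor f and i.i.d. noise ε, so the
planted pairwise correlation inside a block (and between blocks sharing a
factor) is exactly c in expectation. Background peaks are independent
noise. Defaults (2,000 peaks, 100 samples, 20 blocks × 10 peaks, c = 0.7,
5% zero-inflation, 2% outliers ×10) define the standard test conditions
used throughout the suite.

Design choices worth knowing:

* **Block-to-factor allocation is geometrically front-loaded** (weights
  2^(F−1), …, 2, 1 over factors). Equal allocation makes the planted
  correlation-matrix eigenvalues nearly equal, and then the sample
  eigenvectors of a 22-sample cohort no longer identify which component is
  which factor. The steep profile keeps factor 2 recoverable as PC2 even
  at the small cohort sizes the axis analysis targets.
* **Non-negativity by shifting each peak to minimum 0**, not truncation or
  softplus, because a shift preserves the planted correlations exactly.
  A side effect is one exact zero per peak row, which slightly sharpens
  the repeated-value filter.
* **Zero-inflation is i.i.d. per entry** and applied after the shift; at
  the default 5% with 100 samples this drops roughly half the peaks at
  the >5% repeated-value rule — deliberately harsh, because that filter's
  behavior under heavy corruption is part of what the suite exercises.
  Scenario configs that need a gentler matrix (the multi-group pipeline
  demo) use 1%.
* **Smoking axis**: heavy smokers' factor-2 scores have their standard
  deviation multiplied by `variance_inflation` (default 2.0), so the
  heavy group spreads farther from the PC2 axis; pack-years are drawn
  uniform below/above the 20-year cutoff per group.
* **Survival**: exponential event times with hazard
  `λ₀·exp(hazard_coef · s)`; the signal s is `|factor-2 score|` by default,
  or the 0/1 outside-border indicator (`hazard_on="outside_indicator"`),
  which makes the planted outside-vs-inside hazard ratio exactly
  `exp(hazard_coef)` — the form parameter-recovery simulations need.
  λ₀ = ln 2 / 730 days (two-year baseline median); PFS uses a 1.5× baseline
  hazard. Censoring replaces a `censor_rate` fraction of times with a
  uniform draw on (0, T).

What the generator does **not** emulate: read-level sampling, the
reference normalization pipeline, genomic correlation structure along
chromosomes (peak coordinates are synthetic bookkeeping), cancer-type
batch effects beyond group labels, and correlated missingness. Passing
tests therefore demonstrate that the implementation recovers the
statistical structure it assumes — not that the assumptions hold in any
particular real dataset.

## Simulation sizes and known limitations

* Hub recovery is checked over 10 standard cohorts; the Cox recovery uses
  50 cohorts of n = 400 (true HR 2.0) plus 100 null cohorts; the axis
  power sweep uses 200 cohorts of 22 samples. These sizes keep the whole
  suite and the acceptance script in the minutes range while leaving
  Monte-Carlo error well below the asserted margins.
* **The 11-vs-11 Welch test on axis distances is underpowered by
  construction.** With a twofold spread difference, |PC2| distances are
  approximately half-normal with scale ratio 2, giving an expected Welch
  t ≈ 1.96 at n = 11 per group — about 45–50% rejection at α = 0.05 in
  the ideal case, and ~22% through the full generator → PCA → Grubbs →
  Welch path once component-estimation noise is included. The package
  reports the honest rejection rate; a cohort of this size mainly detects
  direction (the heavy group shows the larger mean distance in ~88% of
  replicates), not significance.
* The strict 0.8 peak-component gate composes badly with heavy entry
  corruption: at 5% zero-inflation only ~20 factor-2 peaks survive QC,
  corr(PC2, factor 2) fluctuates around 0.8, and many replicates select
  zero peaks. Enrichment recovery is therefore demonstrated at the
  gentler demo conditions; under the harsh defaults the planted set tops
  the ranking in only ~30–40% of replicates, which the acceptance script
  reports as-is.
* Grubbs critical values use the standard t-quantile closed form; no
  simulation-based small-sample correction is applied.
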