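# Methods

## The generative model behind the synthetic experiments

The generator produces the latent log2 ratio of probe *p* on sample *s*
(donor *d*, platform *q*) as

    M[p,s] = mu_p + alpha_q * beta[p,d] + delta[p,q] + eps[p,s]

with

- `mu_p ~ N(0, probe_baseline_sd)` — probe baseline vs the common
  reference RNA (default sd 1.0 log2 units, a typical spread for
  reference-design arrays);
- `beta[p,d] ~ N(0, donor_effect_sd)` — the between-individual signal the
  platforms are judged on (default tau = 0.25 log2);
- `alpha_q in [0,1]` — per-platform attenuation of donor signal,
  modelling chemistry that erases individual differences;
- `delta[p,q] ~ N(0, platform_offset_sd)` — probe-specific platform
  offsets (default 0.3 log2), the source of the platform separation PCA
  shows. The spec'd configuration surface had no scale for these
  offsets, so it is exposed as `platform_offset_sd`;
- `eps[p,s] ~ N(0, sigma[p,q])` — replicate noise with
  `sigma[p,q] = noise_sd_q * (1 + kappa_q * z(GC_p))`, floored at
  `0.1 * noise_sd_q` so sds stay positive. `z` is standardized GC
  percent; `kappa_q > 0` ties noise to GC content the way
  degradation-prone chemistry would. GC is the single linked property by
  default; the link is a per-platform knob.

Channel intensities are `R = 2^(A + M/2 + b(A))`, `G = 2^(A - M/2)` with
`A ~ N(intensity_mean, intensity_sd)` (defaults 10 and 1.5 log2) and a
smooth intensity-dependent dye bias
`b(A) = dye_bias_amplitude * sin((A - intensity_mean)/intensity_sd)`
(default amplitude 0.3). The bias depends on A only, which is exactly
the structure within-array loess can remove — so the normalization stage
is tested against a cleanly recoverable target. A `duplicate_fraction`
(default 5%) of probes appears twice per array with independent noise.

The default design is 8 donors and three platforms with 3/2/3 technical
replicates (64 arrays, 2000 probes). Default platform profiles —
RNAgard (sd 0.25, alpha 1.0), PAXgene (sd 0.25, alpha 0.9), PBMC/Trizol
(sd 0.35, alpha 0.6) — encode the qualitative behavior the statistic is
meant to resolve: whole-blood stabilizers retain more donor signal than
the extra-processing PBMC route. All randomness flows from a single
integer seed through separate deterministic streams for annotation and
experiment generation.

What the generator does **not** emulate: cell-type composition
differences between whole blood and PBMCs, scanner/image artifacts,
spot-level quality flags, probe sequence effects beyond the GC-noise
link, and correlated (non-independent) noise between duplicates. Passing
tests therefore demonstrate that the statistics recover known structure
of this additive log-scale model, not that the pipeline is robust to
every failure mode of real arrays.

## Normalization chain

Order is fixed: per-array M/A computation → loess of M on A per array →
quantile normalization of M across arrays → duplicate averaging →
optional variance filter.

- **Loess**: locally linear, tricube weights, span 0.3, 4 robustifying
  iterations (statsmodels `lowess`), with an interpolation step of
  0.01 × range(A) for speed. The robust passes estimate outlier weights
  from the residual scale; when the initial non-robust fit already
  explains >99% of var(M) (noiseless or calibration-type input) that
  scale is pure lack-of-fit, the weights degenerate (median |residual|
  ≈ 0 zeroes out edge points), and the robust passes are skipped.
  Constant A falls back to mean-centering with a warning; fewer than 10
  probes is an error.
- **Quantile normalization** acts on M values, not per channel; the
  reference is the row-mean of column-sorted values, and ties within a
  column share the mean of the reference quantiles they span (the dense
  convention). With ties a column's value multiset can therefore differ
  from a tie-free column's — the "identical distributions" property is
  exact only for tie-free columns.
- **Duplicate averaging** happens after normalization; arithmetic mean
  per probe and sample, for A values as well as M.
- **Variance filter** ranks by variance (ddof 1) descending, boundary
  ties resolve to the lexicographically smaller probe id, keeps
  `ceil(keep_fraction * n)`. Off by default — the comparison analysis is
  reported unfiltered, and a 50% cutoff is exposed as an option.

## Concordance statistic

S/N is the **ratio of the two pair means** (mean within-donor r divided
by mean across-donor r), not the mean of per-pair ratios; the published
summary-table layout prints the two means and a ratio row consistent
with dividing them. Across-donor pairs are restricted to the same
platform. Pearson correlation is the default; Spearman is available via
`method=`. Division of means rounded to three decimals reproduces two of
the three published ratios exactly; the third (0.972/0.913 = 1.0646 vs
printed 1.064) is consistent only with unrounded inputs, so agreement is
asserted at ±0.001.

PCA centers each probe across samples and does not scale to unit
variance (M values already share a scale after quantile normalization);
scores come from the SVD of the centered samples × probes matrix.

## Per-probe metrics

- `Var` — mean over donors of the replicate sample variance (ddof 1).
- `FD` — mean over donors of the mean absolute pairwise replicate
  difference, in log2 units (fold-difference-type quantities live on the
  M scale).
- `pval` — one-way ANOVA donor-effect p-value over replicate groups,
  computed by vectorized sums of squares (scipy only supplies the F
  tail). The published table never defines its p-value; a one-sample
  t-test of M against 0 is available via `pval_method="ttest"`.
  Degenerate rows: zero within- and between-group variance → p = 1;
  zero within-, positive between- → p = 0.
- Cross-platform test — replicates averaged to one M per (donor,
  platform), then a paired two-sided t over donors ("across the same
  individuals"); all-zero differences → p = 1, zero-variance non-zero
  differences → p = 0. Unpaired Welch is behind `method="welch"`.
  At least 3 common donors required.
- Property correlations — Pearson r with the t-transform p-value
  (`t = r·sqrt((n−2)/(1−r²))`, n−2 df), significance flagged at
  p < 0.01, no multiple-testing correction (matching the raw-correlation
  reporting convention); probes without annotation are dropped listwise,
  constant inputs flagged undefined. Properties are the five physical
  columns plus meanM and meanA.

## Selection and enrichment

Probe→gene collapse uses the **maximum** Var per gene (the most variable
probe represents the gene; `collapse="mean"` available) — the source
analysis does not state its collapse, and max is the conservative choice
for flagging unstable genes. Top-variance selection takes
`ceil(fraction * n_genes)` (default 5%) with lexicographic tie-breaks.
For the platform-higher selection a gene qualifies when any of its
probes passes the paired test at alpha, signed by that probe's mean
difference. The enrichment universe is the genes measured on the array
after preprocessing, not the genome. The over-representation p-value is
the exact hypergeometric upper tail; FDR is Benjamini–Hochberg across
the tested sets.

## Numerical and design choices

- Matrices are written with `%.10g` formatting, making repeated runs
  with one seed byte-identical (the JSON report additionally logs
  wall-clock stage timings and is excluded from byte comparisons).
- The report schema ships as `schemas/report_schema.json`, generated
  from the pydantic report model; validation runs through pydantic.
- Validation problem sizes: the multi-seed checks use 20–50 seeds at
  1000–2000 probes and the default or reduced replicate designs —
  enough for the pass criteria (95% sign recovery, ±0.02 null
  calibration) while keeping the suite quick on one CPU.

## Known limitations

- Published per-probe tables (property correlations, GO terms) derive
  from undeposited raw arrays and are not numerically reproducible here;
  the package reproduces the *machinery* and validates it on synthetic
  ground truth instead.
- The quantile-normalization target (M values vs per-channel) is an
  interpretation; per-channel normalization is not implemented.
- The hypergeometric enrichment is a documented stand-in for DAVID's
  EASE score.
- Loess edge bias at extreme A values is inherent to local regression;
  the exact-fit guarantees in the tests apply to interior points.
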