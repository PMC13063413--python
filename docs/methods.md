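# Methods

This note documents the statistical model behind `kbench`, the conventions
and numerical choices the implementation fixes, and what the synthetic
validation does and does not demonstrate.

## The benchmarking model and the REM statistic

The analysis variable throughout is log10 k, with k a first-order
biodegradation rate constant in d⁻¹. Base 10 is used everywhere so that a
standard deviation translates directly into a multiplicative fold factor:
`fold_factor(x) = 10^x` (a stddev of 0.4 ≈ a factor 2.5 spread in k).

Benchmarking assumes k_i,j / k_BM,j is constant over site-experiments j. A
*site-experiment* is one incubation with water and sediment from one
location at one sampling time; seasonal repeats at a location are distinct
site-experiments, so the stddev over them pools spatial and temporal
(seasonal) variability into a single spatiotemporal measure.

For chemical i with N valid sites:

* stddev_i — sample standard deviation (N−1 denominator) of log10 k_i,j;
* stddev′_i — the same for the benchmarked series
  log10 k′_i,j = log10 k_i,j − log10 k_BM,j;
* REM_i = stddev_i − stddev′_i.

Because each stddev is taken about its own mean, the unknown reference-site
ratio k_i,ref/k_BM,ref cancels; it is never estimated separately. REM is
invariant to adding a constant to any chemical's row (i.e. to rescaling k by
a chemical-specific factor).

**Gap rule.** Where the benchmark lacks a valid value at a site, the
chemical's raw mean-centered residual log10 k_i,j − mean_i(log10 k) is
substituted for the missing benchmarked residual. Conventions the
implementation fixes (the underlying definition leaves them open):

* benchmarked residuals are centered on the mean difference over
  benchmark-valid sites only;
* substituted raw residuals are centered on the chemical's mean over all its
  valid sites;
* the pooled sum of squares is divided by N−1 with N the chemical's total
  valid sites, with no re-centering after pooling.

With no gaps this reduces exactly to the plain stddev of the differences.
The brute-force oracle used in the tests transcribes the same conventions
independently, so the dual-route check validates the implementation, not the
convention itself; sensitivity to the re-centering choice is confined to
chemicals with many gap-filled sites.

**Benchmark selection.** Every pool member is scored by the median REM it
achieves over the remaining members; the largest median wins, with ties
broken by lexicographically smallest chemical id for determinism. Candidates
that cannot be scored against a given benchmark (fewer than `min_n` valid
sites, or no shared site) are skipped from that median. Benchmark chemicals
are excluded from their own per-chemical entries and from all summary
medians. `min_n` defaults to 3 valid sites: the N−1 denominator needs at
least 2, and 2-point stddevs are noisy enough to distort medians.

UBM selects one benchmark over all chemicals; GBM repeats the selection
independently inside each group and pools the non-benchmark chemicals for
the summary. A GBM with a single all-inclusive group is exactly UBM. TOC
normalization is implemented as benchmarking against a pseudo-chemical whose
log-rate row is log10 TOC_j, which makes the identity with the benchmarking
transform explicit and reuses the same code path.

## Preprocessing conventions

Order of operations: dissolved-fraction correction → pH correction → log10
pivot → per-chemical IQR outlier removal → coverage filter.

* **Dissolved-fraction correction**: k / f_dissolved references the rate
  constant to the freely dissolved concentration (sorbed chemical is assumed
  unavailable for biodegradation).
* **pH-7 speciation correction**: k × f_neutral(7) / f_neutral(pH_exp),
  with neutral fractions from the Henderson–Hasselbalch closed form per
  ionizable site (acid: 1/(1+10^(pH−pKa)); base: 1/(1+10^(pKa−pH))).
  Multiprotic chemicals use the independent-site product approximation; the
  correction is known to overcorrect somewhat in reality, so exactness
  beyond the monoprotic closed form is not claimed.
* **Outlier removal**: Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR per chemical
  across all its site-experiments, on log10 k (a `raw` mode exists for
  sensitivity analysis). Quartiles use linear interpolation of order
  statistics ("type 7", numpy's default) — fences depend on this choice, so
  it is fixed and documented. With fewer than 4 values the test is skipped;
  with zero IQR, values off the median are flagged.
* **Coverage filter**: a chemical is kept when it has values in at least
  ceil(fraction × n_sites) site-experiments; the default fraction 0.5 reads
  "at least half" conservatively (19 of 38 is kept).

All thresholds live in `PreprocessConfig` and in the YAML config consumed by
the CLI.

## Chemical grouping

Ward's minimum-variance agglomeration under Euclidean distance, in the
Ward.D2 convention (linkage heights on the distance scale; two singletons at
distance d merge at height d). The clustering itself is delegated to
scipy's linkage; the tests verify it against an exhaustive implementation
that recomputes within-cluster variances at every step.

* **Data-dependent ("optimized") features**: chemical i's vector of Pearson
  coefficients of its log10 k profile against every other chemical, computed
  pairwise-complete. Pairs with fewer than 5 shared sites (configurable) or
  a zero-variance profile get no coefficient and are imputed with 0 in the
  feature vector — no evidence of co-variation. The self-correlation column
  (constant 1) is kept so all vectors have equal length; a shared constant
  column does not affect between-chemical distances.
* **Data-independent features**: MACCS bits, biotransformation-rule triggers
  (binary, treated as 0/1 reals — Euclidean distance is then the square root
  of Hamming distance) or rule probabilities in [0, 1]. Canonical widths
  (166/208/65) are expected but only warned about, since subsets are
  legitimate.
* **Minimum group size**: benchmarking inside a singleton group is
  impossible, so the optimized grouping repairs a k-cluster cut by merging
  every undersized cluster into its nearest cluster under the Ward distance
  (smallest cluster first, deterministic tie-breaks), reducing the effective
  group count rather than re-cutting at a lower k — this preserves the
  requested granularity as closely as possible. Descriptor-based groupings
  use the plain cut. The number of groups is always user-supplied; no
  automatic model selection is attempted.

## Synthetic data and what the validation shows

The generator draws log10 k_ij = mu_i + lambda_i·delta_{g(i),j} + eps_ij with
delta ~ N(0, σ²_group) per (group, site), eps ~ N(0, σ²_noise) i.i.d., and
MCAR missingness (optional value-dependent censoring via `censor_below`
emulates rate constants too small to be significant, the dominant real cause
of gaps). Default conditions: 8 groups × 8 chemicals, 38 site-experiments,
σ_group = 0.3, σ_noise = 0.1 (log10 units), unit loadings, 20% missing.
Per-chemical means are uniform on (−3.0, 1.5) log10 d⁻¹, spanning roughly
0.001–30 d⁻¹ as observed for surface-water micropollutants; means do not
affect any variability statistic (shift invariance), only realism of the
tables. The default outlier shift of 3 log10 units represents a gross error
(three orders of magnitude), well clear of the fences implied by the default
sigmas.

Within a group the benchmark cancels the shared delta, leaving a difference
of two independent noise terms, so as N → ∞

    REM → sqrt(σ²_group + σ²_noise) − sqrt(2)·σ_noise

(0.1748 at the default sigmas). With no group structure the same formula
gives (1 − √2)·σ_noise < 0: benchmarking independent noise *adds* variance,
which is the null-safety check that the pipeline cannot manufacture variance
reduction. At finite N and with benchmark selection there are two small
opposing biases — selection of the best-scoring benchmark inflates REM,
finite-sample noise in stddev′ deflates it — so Monte-Carlo medians sit
within a few hundredths of the closed form; the recovery tests allow ±0.03.

What passing these tests shows: the pipeline recovers planted group
structure and measures its variance reduction correctly under Gaussian
log-scale effects with exchangeable site-experiments and (by default) MCAR
gaps. What they do not show: real rate-constant data need not have
homogeneous within-group loadings, Gaussian site effects, or ignorable
missingness (real gaps are censoring at small k), and the spatial/seasonal
mix of real site-experiments is not exchangeable. Results on synthetic data
therefore validate the machinery, not the environmental hypothesis.

## Numerical and degenerate-input choices

* Stddevs are computed with the N−1 denominator throughout; `min_n = 3`
  valid values are required, otherwise an `InsufficientDataError` is raised
  (drivers skip and count such chemicals rather than fail).
* Exact limits hold exactly in floating point where the inputs allow it: a
  benchmark parallel to the chemical gives stddev′ = 0 and REM = stddev; a
  constant benchmark gives REM = 0.
* All row/column orders in files are sorted, all tie-breaks are
  lexicographic or smallest-index, and the generator uses per-component
  seed sub-streams, so every output is byte-reproducible.
* Missing values are NaN in memory and empty fields on disk, never sentinel
  numbers.

## Known limitations

* The pH correction's independent-site product is approximate for
  multiprotic/zwitterionic chemicals.
* Replicate stddevs (measurement uncertainty) are carried through the data
  model but not propagated into REM confidence intervals.
* Benchmarking efficacy is quantified retrospectively; forward prediction of
  absolute k at new sites from a measured benchmark is out of scope.
* Descriptor matrices are inputs; the package does not compute fingerprints
  or biotransformation-rule predictions from structures.
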