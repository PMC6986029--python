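# Methods

This note records the statistical model, the algorithmic choices and
defaults, what the synthetic data generator does and does not emulate,
and the known limitations. Empirical statements below are limited to
what the shipped test suite and acceptance script actually compute.

## Count model

Counts are modeled as negative binomial (NB): a gene's count in a sample
has mean *u* and variance *u + φu²*, where *φ* ≥ 0 is the dispersion.
*φ* → 0 recovers the Poisson; the implementation switches to exact
Poisson formulas below *φ* = 1e-10 to avoid loss of precision. The NB
arises as a Gamma-mixed Poisson, which is the representation used by the
exact test below.

## Input handling and filtering

`read_counts` accepts delimited text with genes as rows and a sample-id
header; counts must be non-negative and integral (values within 1e-9 of
an integer are accepted and rounded, so normalized matrices that have
been written to text round-trip cleanly). `filter_genes` removes genes
whose fraction of zero counts exceeds `max_zero_fraction` (default 0.5,
strict inequality) and always removes all-zero genes. Filtering is
re-applied inside every benchmark repeat because the zero pattern
depends on which samples were drawn.

## Normalizations

All quantiles (Q2, Q3) use linear interpolation (type-7, the numpy
default). This is fixed in one place (`normalization.QUANTILE_METHOD`)
because Q3 differs across quantile conventions.

- **UQ**: sample *j* is scaled by Q3 of its *nonzero* counts, then the
  whole matrix is multiplied by the mean of the per-sample Q3s. Samples
  need at least four nonzero genes for a meaningful Q3. Zero removal is
  per-sample by default (`zero_removal="per_sample"`); a matrix-wide
  alternative (drop genes that are zero in every sample) is available
  for sensitivity analysis.
- **UQ-pgQ2**: UQ first, then each gene is divided by its across-sample
  median and multiplied by 100. Genes whose median is zero are left on
  the UQ scale and flagged rather than divided by zero. The intermediate
  UQ matrix is retained on the result, which lets the moderated-t path
  use it directly (see below).
- **RLE**: size factor = median over genes of the sample's counts
  divided by the per-gene geometric mean, computed over genes positive
  in all samples. Factors are *not* rescaled to unit geometric mean;
  consequently re-estimating factors on an RLE-normalized matrix yields
  a constant vector equal to the geometric mean of the first-round
  factors (not exactly 1).
- **TMM**: M (log2 ratio of proportions) and A (average log2 abundance)
  values against a reference sample (the sample whose Q3-of-proportions
  is closest to the mean), doubly trimmed by ranks (30% of M, 5% of A
  per side), combined by a delta-method precision-weighted mean, and
  rescaled to unit geometric mean. At least 20 genes positive in both
  samples are required per pair.

Size-factor methods (RLE, TMM) divide counts by factor × library-size
scale; quantile methods (UQ, UQ-pgQ2) produce directly comparable
matrices. By default all four feed the count-based tests as
nearest-integer-rounded normalized matrices with equal offsets; for RLE
and TMM an alternative route (raw counts with log effective-library-size
offsets) is available via `use_offsets`.

## Dispersion estimation

Cox–Reid adjusted profile likelihood (APL). With equal offsets the NB
group-mean MLE equals the sample mean for every *φ*, so the profile is
closed-form per gene; the CR adjustment is ½·log det(XᵀWX) with
*w = μ/(1 + φμ)*. The **common** dispersion maximizes the summed APL by
golden-section search on log *φ* ∈ [1e-6, 10]. **Tagwise** dispersions
maximize APL_g + `prior_weight` × (mean APL across genes), evaluated on
a 61-point log-spaced grid with parabolic refinement; `prior_weight`
defaults to 10 (roughly: the shared curve counts as ten genes of prior
evidence), and `prior_weight=inf` collapses every gene to the common
value. Estimates are floored at 1e-6. At least two replicates per group
are required.

## Tests

All tests operate on the (filtered, normalized, rounded) matrix with two
groups A/B taken in lexicographic label order (first label = reference;
log2fc is B relative to A).

- **Exact test**: conditional on the total *Y_S = Y_A + Y_B*. Because
  the NB is a Gamma–Poisson mixture with the same success probability in
  both groups under the null, *Y_A | Y_S* is beta-binomial(*Y_S*,
  *n_A/φ*, *n_B/φ*) (binomial in the Poisson limit). The p-value sums
  conditional probabilities no larger than the observed one (relative
  tolerance 1e-12), evaluated in log space. For *Y_S* ≤ `exact_limit`
  (default 2000) the enumeration is exact; above it the beta-binomial is
  replaced by its limiting Beta distribution with a ±0.5 continuity
  correction, whose error is negligible at the read depths where it
  activates. Group sums use per-group mean counts times group size, so
  unequal group sizes are handled.
- **Wald test**: *Z* = β̂₁/SE(β̂₁) from the log-link NB GLM. With equal
  offsets the fit is closed-form (β̂₁ = log of the group-mean ratio,
  variance by the delta method / observed information); the general IRLS
  fit (`fit_nb_glm`) handles unequal offsets. Fold changes for genes
  with an all-zero group are clamped to ±log(1e8) and flagged.
- **QL F-test**: per-gene quasi-dispersion *s²* = deviance/(m − 2),
  squeezed toward a common value by the log-moment empirical-Bayes
  procedure (digamma/trigamma moment matching with Newton inversion of
  the trigamma function), giving prior df *d₀* and posterior *s²*. The
  statistic *F = Z²/s²_post* is referred to F(1, d₀ + df); when the
  *s²* spread is consistent with pure chi-squared noise, *d₀* = ∞ and
  the reference becomes χ²(1).
- **Moderated t**: two-sample t on log2(x + 0.5) with the same
  empirical-Bayes variance squeezing; `d0_override=0` gives the plain
  pooled-variance t. For UQ-pgQ2 input the per-gene Q2 division is a
  gene-wise additive constant on the log scale and cancels from the
  t-statistic, so the implementation evaluates the retained intermediate
  UQ matrix directly — UQ and UQ-pgQ2 moderated-t p-values are therefore
  bit-identical, not merely close.

**Multiple testing**: Benjamini–Hochberg step-up, implemented directly
(vectorized cumulative minimum over the sorted p-values) so that NaN
p-values pass through as NaN without perturbing the ranks of the rest.

**DEG calling**: FDR ≤ 0.05 and |log2 fold change| ≥ 1 by default, both
boundaries inclusive; NaNs are never called.

## Simulator

A *reference profile* is a matrix of per-sample gene proportions
(R_gj/N_j) estimated from a source cohort. Each simulated sample draws a
depth from Normal(`mean_depth`, `sd_depth`²) (rounded, floored at
`min_depth` = 1e6 by default; a warning fires if mean ≤ 3·sd because
the floor then truncates noticeably) and a count vector from
Multinomial(depth, proportions of a source sample drawn without
replacement within the repeat). Columns therefore sum exactly to their
drawn depths. RNG streams are keyed by (seed, repeat, sample) so any
sample of any repeat is reproducible in isolation.

What this emulates: realistic heavy-tailed abundance spectra,
sample-to-sample biological variability (inherited from the source
cohort's distinct proportion vectors), uneven sequencing depth, and a
null with no differential expression by construction. What it does not
emulate: gene-length or GC effects, technical batch effects, novel
biological variability beyond what the source cohort exhibits (counts
are multinomial conditional on the chosen source sample), or any true
signal — alternatives must be spiked in by the user. `synth_reference`
provides a stand-in source cohort (log-normal(meanlog 4, sdlog 2)
baselines, NB dispersion 0.1 across samples) when no real cohort is
available. `thin_counts` reduces effective depth by binomial
downsampling, preserving expected proportions.

## Benchmarks

- **Intra-group FPR**: for each sample size *n* and repeat, 2*n* distinct
  samples of one condition are drawn and split into two disjoint
  pseudo-groups; the full pipeline runs and the fraction of tested genes
  called DE is recorded. Reported as mean ± SE over repeats (default 50
  repeats, configurable). Repeat streams are keyed by (seed, size,
  repeat), so enlarging the size grid never changes existing cells.
- **Bootstrap DE**: per repeat, *n* case and *n* control samples are
  drawn without replacement and the DEG count recorded, summarized as
  mean ± SE.

## Numerical choices

- All pmf/test computations in log space; log-gamma via
  `scipy.special.gammaln`.
- Exact-test tie tolerance 1e-12 (relative), matching the convention of
  counting outcomes "as or less likely" under floating-point evaluation.
- Poisson switch at *φ* < 1e-10; dispersion bounds [1e-6, 10];
  fold-change clamp ±log(1e8).
- Quantiles: type-7 everywhere.
- Seeds: `numpy.random.default_rng` with explicit integer-sequence keys;
  no global RNG state.

## Limitations

- The exact test's large-total branch is an approximation; its error is
  far below the resolution of the benchmark bounds it feeds but it is
  not suitable for certifying individual p-values beyond ~3 significant
  digits when *Y_S* > `exact_limit`.
- The Wald test is asymptotic and conservative-to-liberal behavior at
  very small *n* should be read from the benchmarks, not assumed.
- Tagwise dispersion uses a grid-plus-refinement maximizer, accurate to
  well below the statistical uncertainty of the estimates but not to
  machine precision.
- The simulator's null preserves the source cohort's biology; if the
  source cohort is itself small or atypical, the estimated FPRs inherit
  that.
- Sensitivity/specificity against external validated gene lists depend
  on denominator conventions; both raw-list and effective (tested-genes)
  denominators are reported because published tables are not always
  internally consistent on this point.
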