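# Methods

## The model

Counts `y_ij` for taxon `i` in sample `j` are modelled as negative binomial
with mean `mu_ij` and taxon-specific dispersion `phi_i`
(`Var = mu + phi mu^2`), with

    log mu_ij = zeta_i + (M beta_i)_j + (W alpha_i)_j

* `zeta_i` — taxon intercept (baseline abundance);
* `M` (N x m) — known binary membership of samples in biological sources;
  `beta_i` (m) — how the sources differ biologically for taxon i;
* `W` (N x k) — **unknown** sample-level unwanted-factor scores
  (sequencing depth, storage condition, library kit, ...);
  `alpha_i` (k) — how strongly taxon i responds to each factor.

Two pieces of side information identify the decomposition: technical
replicates (rows of `M`) share biology, so within-group count differences
are technical; negative-control taxa (spike-ins or empirically selected
taxa) carry no biology of interest, so their between-sample variation
identifies `W`.

## Estimation

Alternating ridge-penalized IRLS (`ruvnb.fit_ruv3nb`):

1. **Initialization.** `W1` is the standardized per-sample log geometric
   mean of counts (+1) — a depth surrogate; remaining columns come from a
   truncated SVD of within-replicate-centered CLR residuals of the control
   taxa (residuals standardized per taxon so rare-taxon noise does not
   dominate the leading directions, and the `W1` component projected out).
2. **Taxon step.** Per taxon, NB IRLS of `y_i` on `[M | W]` with ridge
   `lambda_a` (default 0.01) on the `alpha` block only; `zeta_i` is the
   mean of the per-group coefficients. Dispersions maximize the profile
   likelihood on `[1e-8, 1e8]` (vectorized golden-section search).
3. **Sample step.** Per sample, holding `alpha`, `beta`, `phi` fixed, NB
   IRLS of the control-taxa counts on `alpha_C` with offset
   `zeta_C + (M beta)_C` and ridge `lambda_b` (default 5) on every `W`
   coordinate.
4. **Identifiability.** `W` columns are centered (the shift absorbed into
   `zeta`), orthogonalized by the SVD rotation `W = U S V'`,
   `W <- U S`, `alpha <- V' alpha` — which leaves the fit and both
   (isotropic) ridge penalties exactly unchanged and orders the factors by
   explained variance — and sign-fixed by positive correlation with the
   initialization.
5. **Convergence** when `max|dW| / (1 + max|W|) < 1e-4` (default) or after
   `max_iter = 50` outer iterations; non-convergence is flagged, not
   raised.

Both block updates (warm-started across iterations) ascend the
control-taxa penalized log-likelihood, which is recorded as the trace and
is non-decreasing by construction; the all-taxa likelihood is not the
ascent objective because the sample step sees control taxa only.

**Factor screening.** Before fitting, Horn's parallel analysis decides how
many of the requested `k` factors carry real signal: singular values of
the within-replicate-centered, per-taxon-standardized log control
residuals are compared, rank by rank, against the 99th percentile of 50
column-permuted copies (seeded); the strict percentile keeps the
per-dataset false-retention rate around 1%. Factors that fail are returned as exact
zero columns. Without this, the ridge MAP at the default penalties absorbs
noticeable noise rank on data that contain no unwanted variation at all;
with it, the adjustment is exactly the identity there. Disable with
`factor_screen=False`.

## Percentile-invariant adjusted counts

Each observation keeps its percentile: `p_ij` is the midpoint (mode
`mid`, deterministic, default) or a seeded uniform draw (mode
`randomized`) of the interval `(F(y_ij - 1), F(y_ij)]` under the fitted
NB, and the adjusted count is the smallest integer whose CDF under the
reference model — `W` term replaced by the column means, i.e. zero —
reaches `p_ij`. Quantiles numerically at 1 are capped at `1 - 1e-12`.
Counts of taxa with zero loadings are reproduced exactly; `log_pac` uses
offset 1.

## Differential abundance and pi0

Per taxon, the likelihood-ratio test of a two-group contrast against
chi-square(1), full model `~ group + covariates` with offset log(TMM
effective library size); estimated `W` columns enter as covariates.
Dispersion is estimated under the full design by Cox-Reid adjusted
profile likelihood and held fixed for both fits: plain profile ML is
biased low by the number of fitted coefficients, which inflates the LRT
when several W covariates are present at small n. Trend moderation is
deliberately *not* applied in this generic test — with taxon dispersions
spanning an order of magnitude, shrinking individual estimates toward a
binned trend miscalibrates them (the conservative half clumps near
p = 1, which saturates the pi0 estimate). Null calibration at the default
scenario's scale: type-I fraction ~0.06 at the 0.05 level, KS distance to
uniform ~0.04.

`storey_pi0` follows the qvalue recipe: `pi0(lambda) = #{p > lambda} /
(m (1 - lambda))` on the grid 0.05..0.95 (step 0.05), a cubic smoothing
spline with 3 effective degrees of freedom (penalty found by bisection on
the smoother-matrix trace), evaluated at the largest lambda, clamped to
[0, 1]. Below 20 p-values it falls back to the single lambda = 0.5
estimate. The estimate is noisy when few taxa are tested: its tail
statistic has standard deviation roughly `sqrt(0.05/m)/0.05`, so runs
with m in the low hundreds can saturate at 1.0.

## Empirical negative controls

* **Biological-contrast procedure** — taxa with the highest p-values in an
  unadjusted between-source test (`n_keep`, default 1000, capped at the
  matrix size), optionally refined by dropping, per source, the 15% of
  taxa most affected by the spiked/unspiked comparison and intersecting
  the survivors. `n_keep` must stay below the plausible number of
  biology-free taxa; a keep count above it guarantees contamination.
* **Permutation procedure** — per factor of interest, 10 random splits of
  the samples into two groups balancing that factor's level counts (odd
  leftovers alternate); taxa in the top `ceil(0.75 T)` by p-value in every
  split are kept, and the per-factor sets intersected. Dispersion is
  estimated once under the replicate-group design (Cox-Reid, shrunk
  toward the abundance trend) and held fixed across
  splits; per-split estimation would let genuine group structure inflate
  the dispersion and survive as stably conservative p-values. Exclusion of
  biological taxa works through the imbalance that the *other* factors'
  splits leave, so at least two factors of interest are advisable.

## Evaluation metrics

* RLE: deviations of log values from each taxon's cross-sample median;
  per-sample medians and IQRs (25th/75th percentiles, linear
  interpolation); `V_med`, `V_iqr` = mean within-group variances of those
  summaries over groups of size >= 2; `Omega_RLE = -ln(V_med + V_iqr)`
  (natural log; a zero sum is reported as the sentinel 1e9 with a flag).
* `NCC_RLE = 1 - sqrt(1 - Wilks' Lambda)` between the N x 2 RLE summary
  and the dummy-coded technical factors (collinear columns dropped);
  equal to `1 - |r|` when a single canonical pair exists. Larger = less
  residual technical signal.
* PCA on samples (taxa centered, not scaled), silhouette (Euclidean) on
  the first four PC scores, by biology (higher = better) and by each
  technical factor (lower = better); singleton labels and exact ties
  score 0.
* Factor interpretation: canonical correlation of each `W` column with
  each categorical factor, signed Pearson r with numeric covariates
  (log library size, log geometric mean).
* Spike-in check: per-taxon mean-CPM ratio spiked vs unspiked samples
  (0/0 reported as NaN, positive/0 as +inf).

## Attribution

Per taxon, NB GLMs on cumulative factor sets (intercept; +W1; +W1+W2; ...)
without a library-size offset — the leading factor carries depth, so depth
is attributed rather than conditioned away (configurable by passing a
reduced `W`). `R^2` of each model against the intercept-only null uses the
Veall-Zimmermann correction `R2_VZ = [G2/(G2+n)] x [(2 l0 - n)/(2 l0)]`,
clamped to [0, 1]; dispersion is re-estimated per nested model, so raw
increments can be slightly negative and are floored at 0 (raw values kept
in `delta_r2_raw`). Rankings per factor take the top-n taxa by increment
(ties by id), merge classes with fewer than 2 members into "others", and
`affected_abundance_proportion` is the mean over samples of the count
share in the top set.

## Synthetic data

`simulate_experiment` draws the study conditions the pipeline assumes:
few biological sources x many technical replicates (default 2 x 20);
log-normal abundance intercepts (sd 2.0) with the location calibrated by
bisection so the expected zero fraction hits `sparsity_target` (default
0.6); biological group effects N(0, 1.2) for non-control taxa (the scale
chosen so uncorrected CLR-PCA shows biology at silhouette >= 0.3, with an
optional `bio_floor` bounding every non-control taxon's between-group
spread for labeled strong-biology scenarios) and exactly 0 for the
designated control taxa; unwanted factors = standardized log depth
(log-normal, sd 0.5) plus one standardized dummy per batch factor
(default storage at scale 1.0 and library kit at 0.7), with
class-structured loadings (5 taxon classes; each batch factor loads on
its dominant class with probability 0.9, others 0.3); dispersions uniform
on (0.05, 0.5); spike-in taxa with elevated abundance, reduced 50-fold in
unspiked samples. `spike_fraction` defaults to 1 (all samples spiked,
matching analyses that use spiked samples only): with a partial fraction
the spike indicator acts as an extra latent technical factor that is not
part of `W_true`, which is intended for control-identification scenarios
but must be kept in mind when scoring factor recovery.

What the generator does not emulate: taxonomic correlation structure
(taxa are conditionally independent given the factors), classifier
mis-assignment noise, compositional closure at the sequencer (depth is a
latent factor, not a hard sum constraint), and realistic phylogeny-linked
effect sizes. Passing tests therefore demonstrate correctness of the
machinery under the stated model, not performance on any particular real
dataset.

## Problem sizes

The shipped analyses and tests run the default scenario at 400 taxa x 40
samples (10 seeded replicates for the recovery/metric panels), a
storage-confounded specificity scenario (depth + one strong storage
factor, modest biology, 400 taxa), and a labeled strong-biology scenario
at 800 taxa with a heavy-tailed abundance spectrum (log-normal sd 4,
median library ~10^5) so that the CPM filter is informative. These sizes
keep every property measurable while staying desk-sized.

## Known limitations

* `pi0` saturation at small taxon counts (above).
* The factor screen tests unwanted structure in *control* residuals; a
  factor that affects only non-control taxa is invisible to the model by
  construction (controls identify `W`).
* Ridge penalties are interpreted as `lambda_a` on loadings and
  `lambda_b` on scores; with both active the MAP shrinks weakly-loaded
  factors, which is why screening, not shrinkage, provides null safety.
* The NB LRT stand-in is calibrated here, not output-identical to any
  external differential-abundance tool.
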