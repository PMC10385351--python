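# Methods

`augbreed` analyzes early-generation fruit-breeding trials laid out as a
Federer augmented block design and selects genotypes with a weighted
rank-summation index. This note describes the statistical model, the
estimators, the synthetic-trial generator used for validation, and the
numerical and design choices that were genuinely open.

## The augmented block model

The observation model is additive and fixed-effect:

    Y_ij = mu + tau_i + B_j + e_ij,        e_ij ~ N(0, sigma_e^2)

where treatments `tau_i` split into `c` replicated **checks** (one plot in
every one of `b` blocks) and `v` unreplicated **test genotypes** (one plot
each). Because only the checks are replicated, everything about blocks and
error is estimated from the checks:

* **error variance** `sigma_e^2`: residual mean square of the two-way
  checks x blocks ANOVA, with `(b-1)(c-1)` degrees of freedom;
* **block effects** `B_hat_j`: mean of the checks in block `j` minus the
  grand mean of all check plots (these sum to zero);
* **adjusted test values**: `Y_gj - B_hat_j`.

This check-mean estimator equals the least-squares solution of the full
model: each unreplicated test plot is fitted exactly, so the residual sum
of squares — and therefore the block-effect estimates — is driven entirely
by the checks. The test suite verifies the equivalence against a direct
pseudoinverse fit to 1e-8 on small designs.

Identifiability caveat: only block *contrasts* are estimable. Adding
per-block constants that sum to zero leaves every adjusted value
unchanged; an arbitrary per-block shift moves all adjusted values by the
mean shift (no genotype contrast moves). For the same reason the
synthetic generator centers its block effects to sum to zero.

The ANOVA reports blocks (ignoring treatments), treatments adjusted for
blocks (from the model fit), and the classical components — checks,
adjusted genotypes, and the 1-df checks-vs-genotypes contrast — each
F-tested against the check-derived error mean square. These components
are the standard presentation and are not forced to add to the adjusted
treatment sum of squares. Under zero genotypic variance the
adjusted-genotype F ratio is *not* exactly centered at 1 in small
designs: the adjustment injects block-estimation noise, giving the exact
null expectation `(1 + (v - sum_j n_j^2 / v) / (c (v-1))) * d2/(d2-2)`
with `d2 = (b-1)(c-1)`; this approaches 1 at study scale (13 checks,
48 error df). The simulation tests assert the exact expectation.

Missing data: a missing *check* plot aborts that trait's analysis (the
error estimate requires the complete check layout; nothing is imputed).
A missing *test* plot only removes that genotype from that trait
(pairwise deletion, logged).

## Genetic parameters

Per trait, from the adjusted test values:

* `sigma_p^2` — sample variance (n-1) of the adjusted test values; the
  test genotypes are a sample from the population of crosses;
* `sigma_g^2 = max(sigma_p^2 - sigma_e^2, 0)` — truncated at zero with a
  logged warning; a small upward bias of order `sigma_e^2 / c` remains
  because adjusted values carry the block-estimation noise;
* `h^2 = sigma_g^2 / sigma_p^2` — broad-sense heritability, stored as a
  proportion and rendered as a percentage in reports;
* `CVg = 100 sqrt(sigma_g^2) / Xo`, `CVe = 100 sqrt(sigma_e^2) / Xo`,
  and their ratio `sqrt(sigma_g^2 / sigma_e^2)`;
* expected gain `GG = (Xs - Xo) h^2` and `GS% = 100 GG / Xo`, with `Xs`
  the mean adjusted value of the selected set.

**Reference mean Xo.** Conventions differ on whether `Xo` is the mean of
the candidate (test) genotypes or of the checks. The default here is the
mean of all adjusted test values — the choice under which the published
panel's gain rows reproduce arithmetically — with `xo_reference="checks"`
as a switch. The same mean is used in the CV denominators.

**Federer weighted mean.** Reported alongside the grand mean and never
used downstream: the replication-weighted mean of entry means (check
means weighted `b`, adjusted test values weighted 1), which reduces to
the arithmetic mean when all entries are equally replicated.

## Rank-summation selection

Each trait is ranked in its configured direction of improvement (rank 1 =
best; ties averaged by default, `min`/`first` available; missing values
rank last). The index is `I_i = sum_j p_j r_ij`, smaller is better; the
conventional economic weights are the genotypic coefficients of variation
(`weights="cvg"`), with unweighted and explicit-weight modes available.
Truncation keeps `round(n * intensity)` genotypes with half-up rounding
(870 at 5% -> 44; 1500 at 3% -> 45); index ties at the cutoff are broken
deterministically by genotype identifier and logged. Because the index is
rank-based, the selected set is invariant to strictly monotone transforms
of any trait and to common positive rescaling of the weights.

Directions: production and quality traits default to larger-is-better.
For colour traits (lightness, hue) the breeding intent depends on the
market; they must be set explicitly in a trait config. The synthetic
preset sets both to +1, matching the direction in which the published
selected-set means moved.

In the pipeline, traits whose adjusted-genotype F test is not significant
at `alpha` (default 0.01) are excluded from the index and the
multivariate stages, with a `keep_nonsignificant` override.

## Multivariate characterization

All multivariate analyses run on the Z-score matrix of the selected
genotypes' adjusted values, `Z = (x - xbar)/s` columnwise with the sample
SD — standardization absorbs the traits' different scales, and PCA on Z
is PCA of the trait correlation matrix. Genotypes and traits are each
clustered by UPGMA on Euclidean distances (the trait tree on the
transposed matrix) for the dual-dendrogram heatmap; UPGMA's merge heights
are mean inter-cluster distances and are ultrametric. PCA is computed by
SVD with a deterministic sign convention (each component's
largest-magnitude eigenvector entry made positive); per-trait
contributions are 100 x squared eigenvector entries, summing to 100 per
component. The trait network carries every pairwise Pearson correlation;
the display threshold (default |r| >= 0.3, unstated in the source
conventions and treated as cosmetic) only flags edges for visual
de-emphasis — all r values are serialized.

## Synthetic trials and what they validate

`simulate_trial` draws from exactly the additive model above: genotype
effects multivariate normal across traits (configured genetic correlation
matrix and per-trait `sigma_g^2`), residuals independent normals
(independent across traits by default), block effects drawn once per
trial and centered. Checks are genotypes too and receive effects from the
same distribution. One master seed drives everything; replicate
sub-streams are spawned deterministically.

`table1_preset()` is the study-scale configuration: 5 blocks, 13 checks
(8 commercial cultivars + 5 first-generation parents), 870 test genotypes
split over five cross populations, and nine traits whose means and
variance components equal the published panel (`augbreed.reference`).
Free parameters the published study does not determine were fixed once:
block-effect SD at half the residual SD (moderate field heterogeneity),
and a genetic correlation matrix with a positive production block
(TFM/CFM/CFN r = 0.7) plus a negative hue-yield association (r = -0.4),
mimicking the qualitative published correlation pattern. The generator
emulates the statistical structure of such a trial, not its biology: no
spatial trends, no G x E, no non-normality, no missing plots. Passing
recovery tests therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to real-field violations.

`recovery_experiment` replicates the full pipeline (adjust -> estimate ->
CVg-weighted selection) and reports bias/RMSE for `h^2`, `sigma_g^2` and
`GS%`, plus realized response — the mean *true* genotypic value of the
selected set. At study scale (200 replicates) mean estimated `h^2` is
within 0.02 of truth for every trait.

**Correlated response.** The univariate gain `GG = h^2 (Xs - Xo)` ignores
selection pressure transmitted through genetic correlations. Under the
generative model the regression of genotypic values on adjusted
phenotypes is linear, so for any selection rule the expected per-trait
response is the multivariate `G P^{-1} dp` (G the genetic covariance, P
the adjusted-phenotype covariance including the `sigma_e^2 / c`
block-estimation term, dp the realized phenotypic differential). The two
coincide for traits genetically independent of the rest of the index; for
the preset's correlated production traits the realized response exceeds
univariate GG by up to ~35%. The validation suite checks realized
response against the multivariate prediction (4 Monte-Carlo SEs) and
against univariate GG for the independent traits only; the pipeline still
reports univariate GG because that is the conventional panel quantity.

## Numerical and formatting choices

* "Marketable" fruit means diameter strictly greater than the 35 mm
  threshold (configurable); a plot with no marketable fruit gets
  CFM = CFN = 0 and ACFM missing.
* Hue uses the two-argument arctangent mapped to [0, 360): the
  single-argument `arctan(b/a)` form is ambiguous outside the first
  quadrant, and ripe-strawberry coordinates (a > 0, b > 0) make the two
  agree where it matters. Hue/chroma are computed per fruit from that
  fruit's mean (a, b), then averaged over the plot.
* Firmness aggregation averages all supplied penetrometer readings,
  leaving the sampling scheme (how many fruits, how many points) to the
  data producer.
* CSV dialect: comma-separated, UTF-8, "." decimal; role labels accept a
  configurable alias map (e.g. "control" -> "check").
* The published panel in `augbreed.reference` carries only the
  internally consistent rows (variances, h2, CVg, CVg/CVe, Xo, Xs, GG,
  GS%); its identity helpers evaluate derived rows over the +-0.005
  rounding box of the printed inputs, since all the printed values have
  two decimals.
* `alpha` for the F-test filter, the selection intensity, tie policy,
  weight mode and the heatmap cluster count are all run configuration,
  not constants.

## Known limitations

* Fixed-effect adjustment only: no REML/BLUP shrinkage of test-genotype
  values, no spatial or alpha-lattice extensions.
* Broad-sense heritability from a single unreplicated trial; no
  narrow-sense decomposition, no multi-environment analysis.
* `sigma_g^2` inherits an `O(sigma_e^2 / c)` upward bias from the
  block-estimation noise in adjusted values (negligible with 13 checks).
* The correlation network reports no significance tests; with ~44
  selected genotypes, |r| below ~0.3 is within sampling noise.
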