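# Methods

## The assessment model

The paninvasion severity framework treats a biological invasion the way
pandemic severity assessment treats an emerging pathogen: instead of a
single forecast, it asks whether three per-region *potentials* are aligned
across the world's regions, because global market disruption requires all
three to coincide in the same places.

For a region set (states and countries are always analyzed separately —
their trade data, production registers and region identifiers are not
commensurable):

- **Transport potential** `T_r = log10(mean annual tonnage imported by r
  from the invaded region set)`, a propagule-pressure proxy: regions that
  import more total tonnage from the invaded range also receive more of
  the cargo, pallets and containers that move egg masses long distances.
  The mean is taken over a *fixed* year window (2012–2017 by default);
  years absent from the data count as zero tonnage, so the denominator is
  always the window length. The data source is silent on this divisor;
  fixed-window averaging was chosen because it keeps the mean a linear
  functional of the flow table (the conservation property tested in the
  suite) and does not reward sparse reporting.
- **Establishment potential** `E_r ∈ [0, 1]`, a zonal summary of an
  ensemble habitat-suitability surface (below).
- **Impact potential** `I_r = log10(mean annual grape or wine production
  tonnage)`, the size of the vulnerable industry. Wine reported in U.S.
  gallons is converted at 3.776e-3 t/gallon before averaging.
- **Market size** `M_r = log10(mean annual wine-export value, USD)` over
  the same window.

Zero tonnage, production or exports leave log10 undefined; such values
propagate as missing and the region is listwise-dropped from the affected
regression/correlation, with the dropped set reported in every result
object. An optional `log10(x+1)` mode exists for users who prefer
pseudo-counts, but it is off by default because it silently mixes "no
industry" with "tiny industry" on an arbitrary scale.

**Alignment** (per impact measure): OLS of `I` on `(1, T, E)` on raw
scales, then Spearman's ρ (average ranks for ties, two-sided
t-approximation p) between `I` and the fitted values `Î`. Spearman is
used because the claim is about monotone coincidence of rankings, not
linearity of the response.

**Severity**: `Î` is min–max rescaled to [1, 10] (per-region risk), risk
is correlated with `M`, and the correlation is mapped affinely from
[-1, 1] to [1, 10]; the headline integer rounds half away from zero
(0.66 → 8.47 → 8). The source describes this correlation once as Pearson
and reports it as ρ; the package defaults to Spearman — under which the
severity is invariant to *any* strictly monotone rescaling of the
predicted risk, so the min–max choice is immaterial — and exposes
`correlation_kind="pearson"` for the other reading. Because Spearman is
rank-invariant, computing the market correlation on `Î` directly or on
the 1–10 risk rescale gives identical severity; the tests assert this.

p-values throughout are descriptive; no multiple-testing correction is
applied to the four alignment correlations.

## Establishment stage

The suitability model is a ridge-penalized logistic regression of
presences against background points on standardized linear + quadratic
covariate features — a deliberate, documented surrogate for MaxEnt-family
presence–background fitters, which are equivalent to penalized
binomial/Poisson regressions up to feature classes and penalty form. The
pipeline consumes any `SuitabilityGrid`, so rasters produced by external
SDM software can be substituted without touching downstream stages.

Workflow and defaults:

- **Thinning**: exact duplicate coordinates removed, then at most one
  record per grid cell (cell assignment `floor((lon − west)/cellsize)`,
  `floor((north − lat)/cellsize)`; boundary points go to the higher-index
  cell). Deterministic survivor (lowest (lon, lat) key) unless a seed
  requests random choice. Idempotent by construction.
- **Covariate screening**: greedy elimination until all pairwise
  |Pearson r| ≤ 0.7 (default), dropping from the worst pair the member
  with the higher mean absolute correlation to the rest; constant
  covariates are dropped with a warning.
- **Background**: 10,000 uniform draws from valid pixels (or all pixels
  if fewer), seeded.
- **Regularization**: penalty weight 1.0 on standardized features —
  mild shrinkage appropriate for the ≤ 12-feature designs used here.
- **Host chaining**: a univariate presence–background model of the pest
  on the predicted suitability of its preferred host (tree of heaven for
  SLF), capturing biotic dependence; a constant host surface is flagged
  degenerate rather than silently fit.
- **Ensemble**: per-pixel arithmetic mean; a pixel is nodata if *any*
  member is nodata (conservative; the alternative — mean of available
  members — would mix ensembles of different sizes across space).
- **Zonal statistic**: max by default (an invasion needs only one
  suitable foothold in a region); mean and median are exposed because
  published results are robust to that choice.
- **Evaluation**: seeded k-fold (k = 5) over presences; AUC computed by
  the rank (Mann-Whitney) method of held-out presences vs background;
  omission rate = fraction of held-out presences scoring below the
  minimum training-presence score, the most widely used presence-only
  threshold rule (the source does not state its rule; this is the
  package's choice).

Grids follow the ESRI ASCII convention (row 0 north, origin at the
top-left corner, square cells in decimal degrees); geometry equality is
exact, no reprojection or resampling is attempted, and region zoning uses
a pre-rasterized label grid (integer codes + CSV legend on disk) rather
than polygon intersection, avoiding a geometry-engine dependency.

## Synthetic scenario generator

Every quantity the assessment correlates is log10-transformed, so the
generator is a latent-factor Gaussian model on log scales: region quality
`z ~ N(0, 1)` (shifted +1 for invaded regions so the transport-validation
check has signal), transport and establishment drivers each couple to `z`
with weight `a` (the *alignment* parameter, complement noise keeping unit
variance), log-production couples with weight `a` to the standardized sum
of the two drivers, and log-exports couple to standardized log-production
with weight `market_coupling`. Establishment is reported through the
normal CDF, which changes nothing rank-based. Annual tables add
multiplicative lognormal year noise (`noise_sd`, default 0.3 on the
natural-log scale) around each region's latent level, and trade tonnage
is split across invaded origins by a Dirichlet draw.

Defaults mirror the worked example's country-level study shape: 223
regions, 9 invaded, window 2012–2017, alignment 0.7 and market coupling
0.66 — values in the range of the published alignment (0.41–0.67) and
market (0.66) correlations.

The map from `a` to the Spearman ρ recovered by the full tabular pipeline
is not identity (rank vs product-moment correlation, year noise, and the
small-sample bias of correlating `I` with its own fitted values — ≈
√(2/n) at `a = 0`). It was therefore calibrated once at n_regions = 300
with 2,000 replicates per knot and frozen as
`ALIGNMENT_RHO_TARGETS` (linear interpolation between knots); the
recovery test checks the pipeline against this frozen table.

What the generator does *not* emulate: real trade-network topology
(flows are independent across destination pairs), zero-inflated industry
tables unless `zero_rate` is set, spatially structured establishment
(the per-region establishment table is exchangeable with the latent
driver), currency deflation, and any spread dynamics. Passing the
recovery tests therefore shows the *estimator chain* is unbiased under
the generative model, not that the published field estimates are correct.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; rank deficiency (collinear transport and
  establishment) raises rather than silently pseudo-inverting.
- Spearman ρ from `scipy.stats.spearmanr`; constant vectors raise
  (undefined ranks) instead of returning NaN.
- Perfect separation in the exploratory invaded-vs-uninvaded logistic
  check yields a signed infinite coefficient with an undefined Wald p;
  the Wilcoxon rank-sum test carries the inference in that case.
- Min–max rescaling computes the unit scale first, so endpoints are
  exactly 1 and 10 in floating point; constant vectors raise.
- ESRI ASCII grids are written at full repr precision, so write→read
  round-trips are bit-exact.
- Test problem sizes (≤ 200×200 grids, ≤ 500 regions, 200-replicate
  recovery runs) were chosen as the smallest sizes at which the sampling
  intervals in the assertions are meaningful.

## Known limitations

- The suitability surrogate is qualitatively, not numerically, equivalent
  to MaxEnt: coefficients, feature classes and regularization paths
  differ, so pixel values will not match a MaxEnt raster even on
  identical inputs. Zonal summaries and downstream correlations are the
  supported interface.
- The severity scale inherits every caveat of its inputs: it relativizes
  potentials within the region set and cannot place a pest on an absolute
  scale without potentials for comparison species.
- Transport potential counts tonnage from the invaded set only;
  bridgehead populations elsewhere make true transport potential higher
  than estimated.
- The alignment regression is deliberately simple (two predictors, OLS);
  it is a descriptive alignment summary, not a causal or predictive
  spread model.
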