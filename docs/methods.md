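# Methods

## Scope and data model

`ectosize` analyses geographic variation in body size and body condition of an
ectotherm sampled at a modest number of sites (~10–20) along a climatic
gradient. Two tables drive everything:

- **sites** — `site_id`, WGS84 `lat`/`lon` (decimal degrees), `elevation_m`,
  and five covariates: `bio1` (annual mean temperature, °C), `bio4`
  (temperature seasonality, WorldClim units = 100 × SD of monthly
  temperature), `bio12` (annual precipitation, mm), `ndvi` (unitless, 0–1),
  and `t_winter` (mean temperature of the coldest quarter, °C; used only for
  the seasonality/winter-temperature diagnostic correlation, never as a
  candidate-model predictor).
- **individuals** — `site_id`, `svl_mm`, `mass_g` (optional; some literature
  sites report length only), `stage` (`adult`/`juvenile`), `sex`, `brooding`.

Raster/GIS extraction of covariates is out of scope: covariates are inputs.

## Scaled mass index

The condition index is `SMI = M · (L0/L)^b_SMA`. `b_SMA` comes from a
standardised major axis fit of ln-mass on ln-SVL: an OLS slope divided by the
absolute Pearson correlation, which symmetrises measurement error between the
two log axes. Natural logs are used; the base cancels in `b_SMA`, and the
stored intercept is the natural-log intercept of the SMA line through the
data centroid.

Filtering rules, chosen to mirror standard field practice:

- brooding males are excluded from the SMA fit and from all SMI summaries
  (their mass includes the brood) but **not** from SVL summaries — carrying
  tadpoles does not change body length;
- juveniles enter the SMA fit by default (`include_juveniles=True`) because
  the exponent is better identified when the full length range is sampled,
  but never enter adult site summaries;
- records without mass are skipped; a site with no usable mass rows gets a
  missing (NaN) mean SMI, never zero.

The fit pools individuals across sites rather than weighting sites equally;
with strongly unbalanced per-site samples this is the convention under which
the reported record counts add up.

## AICc multimodel inference

Candidate models are Gaussian linear regressions of a per-site response on
subsets of {BIO1, BIO4, BIO12, NDVI}, in raw covariate units (only signs and
ranks are interpreted, so standardisation would change nothing that is used).
The default candidate set is 11 additive subsets; the full 15-subset pool is
available (`all_predictor_subsets`) and the set is user-configurable. Each
single covariate carries its biogeographic hypothesis tags with predicted
sign (e.g. BIO4: starvation-resistance “+”, growing-season-length “−”).

Conventions, stated because AIC implementations differ:

- the likelihood is evaluated at the **ML variance** RSS/n, giving
  `ℓ = −(n/2)(ln 2πσ̂² + 1)`;
- `K = p + 2` (intercept, p slopes, residual variance), which makes a
  one-predictor model K = 3;
- `AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1)`; the function raises when
  `n − K − 1 ≤ 0`, while `ols_fit` still returns the (determined) coefficient
  fit with a NaN criterion in that regime;
- a zero-residual fit is flagged `perfect_fit` (infinite likelihood) instead
  of yielding a fake finite criterion;
- evidence ratios are computed from Δ values as `exp((Δ_b−Δ_a)/2)`, not from
  rounded weights (rounding to 3 dp visibly distorts ratios near 60);
- adjusted R² is stored unclamped (it can be negative); the text renderer
  prints negative values as 0.000 and can hide rows with w < 0.01, matching
  how such tables are usually published — the full table is always retained;
- ties in AICc are broken by smaller K, then label, for a deterministic
  ordering.

A structural fact worth knowing when reading ranked tables at small n: for
nested candidates the ML fit of a superset is never worse, so the AICc gap
between a model and its superset is bounded by the penalty difference alone —
at n = 14 that is 4.044 for one extra predictor (K 3→4) and 9.100 for two
(K 3→5). Consequently the Akaike weight of a single-predictor model competing
against two 2-predictor supersets and one 3-predictor superset can never
exceed `1/(1 + 2e^{−2.022} + e^{−4.550}) ≈ 0.784`, no matter how strong the
effect. Published tables that show larger nested gaps were necessarily
computed under some other likelihood or K convention.

`compare_functional_forms` screens linear vs quadratic shape by refitting
with an added x² column and flagging a relative residual-variance reduction
above 1% (configurable).

## Hierarchical partitioning

`all_subsets_r2` enumerates R² over all 2^k predictor subsets (k ≤ 12 hard
limit) via least squares; `independent_contributions` converts the map into
each predictor's independent contribution using Shapley weights
`|S|!(k−|S|−1)!/k!` on the increments `R²(S∪{x})−R²(S)` — algebraically
identical to the classic level-averaged-increment formulation. Properties
relied on and tested: efficiency (independent contributions sum to the
full-model R²), independent + joint = univariate R², percentages sum to 100.
Negative increments under suppression are kept, not clamped. Rank-deficient
designs (duplicated predictors) are solved with `lstsq` (minimum-norm
pseudo-inverse), which leaves R² well defined; the result is flagged
`rank_deficient` and a duplicated predictor's contribution splits about
evenly between the copies. The goodness-of-fit measure is R²; the
`independent_contributions` interface accepts any complete subset→statistic
map, so deviance-based measures can plug in. No randomisation (Z-score) test
is provided.

## Spatial autocorrelation

Great-circle distances use a sphere of radius 6371.0088 km (site-scale
geodesic precision is irrelevant at distance-class widths of tens of km).
Distance classes default to equal-width bins spanning (0, max]; equal-count
binning is a flag, and the binning mode is recorded in the result. Class
weights are binary 0/1 membership (classic correlogram practice);
row-standardisation is deliberately not applied.

Moran's I uses the standard cross-product form with null expectation
−1/(n−1). Significance is Monte-Carlo: values are permuted across sites and
`p = (b+1)/(m+1)` with b the number of permutations at least as extreme as
the observation (ties count as extreme, with a 1e−12 tolerance). The
two-sided default measures extremeness as |I − E[I]|; `greater`/`less` are
available. The add-one estimator makes p = 0 impossible — with the
conventional m = 199 the floor is exactly 0.005. Empty distance classes are
reported with NaN statistics rather than dropped, so a correlogram always has
exactly `n_classes` rows.

## Q10 metabolic model

`rate = MR20 · mass^b · Q10^((T−20)/10)` with defaults Q10 = 2.21,
MR20 = 0.081 mL O₂ h⁻¹, b = 0.884 — amphibian standard-metabolic-rate
literature values. MR20 is read as the rate of a 1 g animal at 20 °C, the
only reading under which a 1 g worked example is well-posed; temperatures are
Celsius only. Equal-mass rate ratios reduce to `Q10^(ΔT/10)`; for the
coldest-quarter means 7.6 °C vs 2.9 °C this gives 2.21^0.47 ≈ 1.452. A
published rounding of this quantity prints 1.43 (≈1.5% lower, consistent
with intermediate rounding); the formula value is authoritative here.

## Synthetic scenario

The generator emulates the study conditions the pipeline expects, not any
real gazetteer or climate surface:

- **Sites.** 14 sites on a synthetic latitudinal transect (lat −43.4…−35.2,
  lon −73.8…−71.5). Covariates are one multivariate-normal draw per site with
  means/SDs (BIO1 9.5 ± 1.5 °C, BIO4 380 ± 60, BIO12 2200 ± 600 mm,
  NDVI 0.78 ± 0.06 clipped to [0,1], t_winter 5.5 ± 1.8 °C) and a positive-
  definite correlation target including BIO4↔t_winter = −0.65 (more seasonal
  sites have colder winters) and BIO1↔t_winter = 0.80. Elevation is uniform
  on 9–1120 m. Non-positive-definite correlation requests are rejected with
  the most likely offending pair named.
- **Individuals.** Per-site n is log-uniform on [10, 271] (field sampling is
  strongly right-skewed; expected total ≈ 1000). Adult SVL is
  `13.06 + 0.028·BIO4 + N(0, 0.4²)` at the site level plus N(0, 1.5²) within
  site, putting the grand mean near 23.7 mm and the 14 site means typically
  within ~21–27 mm. Juveniles (fraction 0.2) are drawn at 0.62 of the adult
  site mean ± 2.0 mm. Mass is `a·SVL^3.278 · exp(N(0, 0.1²))` with
  `a = 23.7^−3.278`, so a mean-length adult weighs ~1 g. Sex is Bernoulli(½)
  and 30% of adult males brood. Non-positive draws are redrawn, not
  truncated, keeping the lognormal mass model clean. Within-site SVL spread
  and the juvenile parameters are this package's defaults — they are scenario
  configuration, not field estimates.
- **What it does not emulate.** Condition (mass noise) is generated
  independently of site covariates, so the body-condition response contains
  no real BIO4 effect; there is no residual spatial structure beyond what the
  covariates induce, no climate time series, no measurement rounding, and no
  mark-recapture structure. Passing tests therefore demonstrate parameter
  recovery and calibration of the machinery under the assumed generative
  model, not field validity of any ecological conclusion.

Determinism: `generate_sites` consumes `seed` and `generate_individuals` a
child of it; the pipeline derives every stage's seed from the single run seed
via `SeedSequence`, so identical configs give byte-identical artifacts.

## Problem sizes used by the test-suite and acceptance script

Distributional recovery is checked at 10 000 sites; parameter recovery and
calibration at the scenario's native scale (14 sites, ~1000 individuals),
with 100 replicates for model-selection calibration and 500 null replicates
(199 permutations each) for permutation-test type-I error. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances.

## Known limitations

- No model averaging, AIC/BIC variants, or GLS/mixed spatial regression.
- No alternative condition indices (residual index, Fulton's K) and no
  sex-specific allometry.
- HP is exact-enumeration only (k ≤ 12); no sampled Shapley approximation.
- The Moran permutation test treats sites as exchangeable under the null;
  unequal per-site sampling error is not modelled.
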