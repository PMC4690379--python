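# ectosize

Statistical toolkit for intraspecific body-size macroecology in ectotherms,
built around the analysis design used in range-wide amphibian surveys: a small
frog is measured (snout-vent length, SVL, mm; body mass, g) at a set of sites
along a climatic gradient, and site-level body size and body condition are
modelled against bioclimatic covariates.

The package implements, as composable scikit-learn-style estimators:

- **`SMAAllometry`** — body condition via the scaled mass index (SMI).
  The allometric exponent `b_SMA` is the standardised major axis slope of
  ln(mass) on ln(SVL) (`b_SMA = slope_OLS / |r|`), and each animal's mass is
  standardised to a common length `L0`:
  `SMI = M · (L0 / L)^b_SMA`.
  Brooding males (mass inflated by vocal-sac tadpoles) are excluded from all
  SMI computations; juveniles can enter the allometric fit to widen the
  sampled length range.
- **`AICcModelSelector`** — multimodel inference over hypothesis-mapped
  Gaussian linear models with the small-sample Akaike criterion
  `AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1)` (K counts intercept, slopes and
  residual variance; ℓ uses the ML variance RSS/n), Akaike weights
  `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`, evidence ratios
  `w_a/w_b = exp((Δ_b−Δ_a)/2)` and per-variable summed weights.
  The default candidate set is the 11 additive combinations of BIO1 (annual
  mean temperature), BIO4 (temperature seasonality), BIO12 (annual
  precipitation) and NDVI used in the study design it follows.
- **`HierarchicalPartitioning`** — each predictor's independent contribution
  to R², i.e. its Shapley value over all 2^k subset models (equivalently the
  level-averaged R² increments of classic hierarchical partitioning), plus
  joint contributions and percentages.
- **`MoranCorrelogram`** — Moran's *I* per great-circle distance class with
  Monte-Carlo permutation p-values `p = (b+1)/(m+1)` (floor 1/(m+1); with the
  conventional 199 permutations the smallest attainable p is exactly 0.005).
- **`metabolic`** — a Q10 standard-metabolic-rate model
  `rate = MR20 · mass^b · Q10^((T−20)/10)` with amphibian literature defaults
  (Q10 = 2.21, MR20 = 0.081 mL O₂ h⁻¹ for 1 g at 20 °C, b = 0.884).
- **`simulate`** — a synthetic-data generator (`darwinii_like_scenario`)
  emulating a 14-site survey of a small temperate-forest frog: correlated
  bioclimatic covariates, a positive BIO4 effect on adult SVL, power-law
  mass allometry with exponent 3.278, juveniles and brooding males.

## Worked example

```python
import ectosize as es
from ectosize.pipeline import COLUMN_TO_PREDICTOR

spec = es.darwinii_like_scenario(seed=0)      # 14 sites, ~1000 frogs
sites, individuals = es.simulate_tables(spec)

fit = es.fit_sma(individuals, include_juveniles=True)
print(f"b_SMA = {fit.b_sma:.3f} (n = {fit.n})")

params = es.SMIParams(b_sma=fit.b_sma, l0=spec.smi_l0)
summaries = es.site_summaries(individuals, params, sites=sites)
X = sites.set_index("site_id")[["bio1", "bio4", "bio12", "ndvi"]] \
         .rename(columns=COLUMN_TO_PREDICTOR)
y = summaries.set_index("site_id")["mean_svl_mm"]

sel = es.AICcModelSelector().fit(X.loc[y.index], y)
print(sel.table_.render(hide_below=0.01))
```

prints (seed 0):

```
b_SMA = 3.303 (n = 803)
model               adj R2   K      AICc   Delta       w
BIO4                 0.854   3    30.931   0.000   0.742
BIO1+BIO4            0.850   4    34.157   3.226   0.148
BIO4+BIO12           0.841   4    34.961   4.029   0.099
BIO1+BIO4+BIO12      0.835   5    39.211   8.280   0.012
(7 model(s) with w < 0.01 not shown)
```

The allometric exponent recovered from ~800 simulated animals is within 0.03
of the generating value 3.278, and the seasonality-only model (BIO4) leads the
AICc ranking: larger frogs in more seasonal climates, the pattern the
starvation-resistance and hibernation hypotheses both predict.  (At n = 14
sites, AICc caps the gap to any superset of BIO4 at 4.04, so single-model
weights above ~0.78 are unreachable within this candidate set.)  The same
pipeline is scriptable end to end:

```sh
ectosize run-all --scenario darwinii --seed 1 --out run1
ectosize report --run-dir run1
ectosize metabolism --mass 1.0 --temp-a 7.6 --temp-b 2.9
```

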