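# Methods

## The scientific model

The package operationalises a two-part hypothesis about insect population
responses to climatic variability. Write N_jit for the annual abundance
index of species *j* at site *i* in year *t*, r = log(N_jit/N_jit−1) for
annual log growth, W_it′ for the standardized climatic anomaly of the
species' driver variable over its sensitive phenological window t′, and
B_ji ∈ [−1, 1] for the population's position on the species' bioclimatic
niche axis (−1 cool/wet leading margin, +1 hot/dry trailing margin).

* **Locally adapted species** have their performance optimum at each
  site's own average conditions, so growth responds to the *local* anomaly
  with an n-shaped (negative-quadratic) curve peaking at W = 0, at every
  niche position.
* **Globally adapted species** share a single optimum near the centre of
  their climatic range, so local anomalies act through the population's
  niche position: roughly linear responses of opposite sign at the two
  margins (positive anomalies help the leading margin and hurt the
  trailing one) and a weak, curved response at the centre.

The *degree of local adaptation* separates the two regimes empirically.
Per species, log growth is modelled as

    r = β0 + βd·log N_it−1 + β1·W + β2·W² + ε,

once with anomalies measured from each site's own long-run window mean
(local scale) and once from the species-wide mean over all occupied
site-years (global scale), over every candidate driver variable
(temperature, precipitation, aridity) and phenological window. The
AIC-best candidate per scale is retained and

    dla = R²_local − R²_global ∈ [−1, 1],

positive values classifying the species as locally adapted. R² is the
Nakagawa *marginal* R² (fixed-effect variance over total variance), so the
two scales are compared on the same footing regardless of random-effect
structure; conditional R² is available via `r2_kind="conditional"`.
Site enters the candidate models as a random intercept except for species
occupying fewer than 10 sites, where the model reduces to ordinary least
squares. Species with fewer than 20 growth observations are skipped with a
logged reason; non-converged candidates are excluded from the AIC
comparison, never patched.

The two pooled headline models are Gaussian linear mixed models fitted
separately per adaptation category:

* growth: r ~ log N_t−1 + W + W² + B + W:B, crossed random intercepts for
  species and site;
* trend: arcsinh(N_jit) ~ Z + B + Z:B, where Z_jt = 1, 2, … counts years
  since the species' first observed year, with a species random intercept,
  a random Z slope within species, and a site random intercept. The
  response transform log(N + √(N² + 1)) = arcsinh N behaves like log(2N)
  for N ≳ 5 (within 0.5%) but keeps zero defined.

Stepwise AIC reduction compares interaction vs additive and quadratic vs
linear structures (four candidates for the growth model, two for the
trend model), fitting by maximum likelihood whenever AICs are compared;
REML is available for final variance components. Wald z tests on the
fixed effects provide significance; their calibration is verified
empirically on pure-noise panels (see below) rather than assumed.
Prediction grids evaluate fixed effects over 21 niche levels (−1 to 1 in
0.1 steps) with density dependence held at the sample mean of log N_t−1.

## Climate summaries

* Temperature window summaries are means of daily means (°C);
  precipitation summaries are totals (mm). Day-of-year windows are
  half-open [start, end); Feb 29 is dropped and later leap days shifted
  back one, so bounds mean the same calendar dates every year.
* Windows: flight = [10th, 90th percentile] of the flight curve;
  pre-flight = Feb 1 → flight start; post-flight = flight end → Oct 31,
  defined for year t−1 only (adults of year t are dead by then);
  overwinter fixed Nov (t−1) – Jan (t), assigned to the later year. Each
  window except post-flight also exists lagged one year, giving the
  7-window × 3-variable candidate set.
* The standardized aridity index is SAI = 0.5·(z_T − z_P) with z-scores
  computed per site over years within the window — positive in hot–dry
  years. The difference form is adopted because it directly encodes the
  "hotter and/or drier" reading of aridity; the alternative product form
  −z_P·0.5·z_T is exposed as `sai_form="literal"` for comparison. Because
  the index is site-standardized, its local and global anomalies coincide
  by construction; cross-scale contrasts therefore ride on temperature and
  precipitation.
* Raw anomalies subtract the site's long-run window mean computed over the
  study years only. Standardization is per variable across the full table
  (not within species), with precipitation multiplied by −1 first; the
  sample (n−1) standard deviation is used throughout.

## Phenology and indexing

Flight curves are Poisson spline regressions (B-spline basis, default 6
degrees of freedom) of weekly counts pooled per species × zone, normalized
to sum 1 over the 26-week March–September season; degenerate fits fall
back to the empirical normalized mean profile. Discrete percentiles use
the smallest week whose cumulative proportion reaches the quantile. The
annual index sums observed weekly counts and adds, for missing weeks, the
curve-expected share scaled from observed weeks — on complete data the
index is exactly the weekly sum. Indices missing more than 50% of the
season's weeks are excluded (the 50% rule counts the whole monitoring
season, not only the flight period — configurable via
`n_weeks_expected`). Series must contribute at least 10 interannual
growth observations; growth is undefined at zero indices and such pairs
are dropped (the trend model's arcsinh transform handles zeros instead).
This is a deliberately simplified one-stage form of the two-stage regional
GAM used operationally by monitoring schemes: the curve is pooled at zone
level and sites enter only through a scaling multiplier.

## The synthetic generator

The generator emulates the features the analysis relies on, not the full
ecology of any real scheme:

* three schemes ("south" 37–43° N, "central" 50.5–58.5° N, "north"
  60–65° N, emulating a Spain/UK/Finland design) over a default 1999–2017
  study window; site mean temperature declines with latitude
  (−0.57 °C/degree), precipitation rises slightly;
* daily climate = site mean + seasonal cosine (amplitude 9 °C, peak
  mid-July) + independent monthly anomalies (s.d. 1.2 °C) + daily noise
  (s.d. 2 °C); precipitation uses monthly log-normal rate anomalies and a
  daily gamma observation layer (shape 0.7), hence is non-negative;
  setting all noise scales to zero yields a fully deterministic climate;
* species performance is Gaussian in the driver value, scaled to 1 at its
  peak. Locally adapted species centre it on each site's long-run window
  mean with breadth 1.2 × the driver's interannual s.d. — responses on
  the anomaly scale. Globally adapted species share one optimum at the
  occupied mean with breadth 0.35 × the occupied site-mean range —
  populations persist on both niche flanks and respond to anomalies with
  opposite signs;
* dynamics are Gompertz: log N_t = log N_t−1 + max_growth·perf +
  dd·log N_t−1 + process noise (max_growth 1.0, dd −0.4, noise s.d.
  0.15), started at the deterministic equilibrium of mean conditions with
  a 5-year burn-in;
* observation: expected weekly counts spread latent abundance over a
  normalized Gaussian flight curve (one mode per brood), scaled by
  detection (default 1 in the generator, 5 in the recovery experiments so
  counting noise stays below process noise), drawn Poisson, with weeks
  missing independently (default probability 0.1).

Not emulated: spatial autocorrelation of climate, dispersal, interspecific
interactions, volunteer-driven (non-random) missingness, or transect-level
detection heterogeneity. Passing recovery tests therefore demonstrate that
the estimators recover the signal *they model* under realistic noise — not
that the model is correct for any particular real dataset.

## Recovery experiments and problem sizes

The experiments module fixes the problem sizes used by the acceptance
suite, chosen to exercise the full pipeline at desk scale:

* **dla sign recovery**: 50 + 50 species on a 24-site network, 8 occupied
  sites each (the OLS route of the <10-site rule), complete weekly counts
  (indices are then exactly weekly sums; the imputation path is tested
  separately), full 21-candidate scan at both scales;
* **driver selection**: 50 locally adapted replicate species, true driver
  = flight-window temperature at year t; the candidate windows are
  anchored on the known flight period (in the data pipeline they come
  from fitted flight curves);
* **growth-shape recovery**: 20 replicate panels per mode, 8 species × 12
  sites, crossed-random-intercept fits;
* **type-I calibration**: 200 pure-noise panels (6 species × 8 sites × 12
  years) checking the Wald tests at α = 0.05;
* **mixed-vs-OLS oracle**: a balanced species × site × year panel with a
  year-level anomaly, site-level niche and zero random-effect variance,
  where generalized and ordinary least squares must agree;
* **trend recovery**: 20 panels with decline −0.08/yr at the trailing
  margin and stability at the leading margin;
* **index robustness**: complete counts for one species across 6 sites
  and 8 years, 20% of weeks masked at random.

## Numerical choices and limitations

* Mixed models use statsmodels' MixedLM; crossed random effects are
  expressed as variance components within a single all-ones group. AIC is
  −2·logL + 2·(k_fixed + k_variance + 1) from ML fits.
* Marginal R² uses the population variance of the fixed-effect predictor;
  for OLS this reproduces the classical R² exactly.
* AIC ties in the candidate scan break by a canonical order (temperature <
  precipitation < aridity; overwinter < pre-flight < flight < post-flight;
  year t before t−1); reduction ties prefer fewer parameters.
* The min/max of the niche rescaling are taken over occupied site-year
  values by default (`extent="site_year"`), so interior sites need not
  attain ±1; `extent="site_mean"` attains the endpoints. The latitudinal
  range position uses each site's own latitude scaled to the species
  extent — the only reading that yields a per-site value — with the
  abundance-weighted centroid available as a separate diagnostic.
* Within-scale AIC selection runs first and dla compares the two scale
  winners; a joint cross-scale selection is a plausible alternative and
  the per-scale AICs are retained for sensitivity.
* Variance components estimated at a boundary make mixed and OLS fixed
  effects differ at O(1/n); the oracle experiment controls this by design
  (balance and group-level covariates), not by loosening its tolerance.
* The sensitivity suite refits under stricter dla bounds ([0.025, 1]
  local, [−1, −0.025] global) and with configurable outlier species
  removed, skipping (with a reason) restrictions that leave fewer than two
  species.
* Phylogenetic mixed models, ingestion of real scheme/climate archives and
  map rendering are out of scope.
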