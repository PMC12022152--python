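# nichegrowth

Quantitative tools for a question in climate-change population ecology: when
a climatic anomaly hits a butterfly population, does the population's
response depend on where it sits inside its species' bioclimatic niche — and
does that depend on whether the species is *locally* or *globally* adapted
to climate?

The package provides, as a tested and reusable pipeline:

* a seed-reproducible **synthetic monitoring-scheme generator** (three
  transect networks along a latitudinal gradient, daily climate, Gaussian
  thermal-performance curves, Gompertz density-dependent dynamics, Poisson
  weekly Pollard-walk counts with missing weeks);
* **climate summaries**: species-specific phenological windows (pre-flight,
  flight, post-flight, overwinter; year *t* or *t−1*), the standardized
  aridity index SAI = ½(z_T − z_P), raw site anomalies
  W_it′ = W̄_it′ − W̄_i, and per-variable standardization with
  precipitation inverted;
* **phenology and abundance indexing**: Poisson-spline flight curves,
  percentile-based windows, imputation of missing survey weeks, the annual
  index N_jit, the >50%-missing exclusion and ≥10-growth-observation
  filters, and growth rates r = log(N_jit / N_jit−1);
* the **degree of local adaptation** (dla): for each species, growth is
  regressed on log N_t−1 + W + W² for every candidate variable
  (temperature, precipitation, aridity) × window × scale (local vs global
  anomalies); the AIC-best candidate per scale gives
  dla = R²_local − R²_global ∈ [−1, 1], positive for locally adapted
  species (site random intercept, dropped below 10 occupied sites);
* the **bioclimatic niche axis** B_ji = 2·(W − min W)/(max W − min W) − 1
  (leading margin −1, trailing margin +1), the latitudinal relative range
  position RRP ∈ [0, 1], and their Pearson alignment;
* the **headline mixed models**, fitted per adaptation category with
  crossed species/site random intercepts:

      log(N_jit / N_jit−1) = log N_it−1 + W_it′ × B_ji + W²_it′ + ε
      log(N_jit + √(N²_jit + 1)) = Z_jt × B_ji + ε

  with stepwise AIC reduction (interaction vs additive, quadratic vs
  linear), Nakagawa marginal/conditional R², prediction grids over 21 niche
  levels, and a sensitivity suite with stricter dla bounds and outlier
  removal.

Because the original monitoring data are licence-restricted, every stage is
verified against the synthetic generator by parameter recovery: the sign of
dla recovers the generating adaptation mode, AIC recovers the true driver
window, the growth model recovers the n-shaped local response and the
sign-reversing global interaction, and the trend model recovers
margin-dependent declines.

## Worked example

```python
from nichegrowth.experiments import dla_sign_recovery, _mode_panel
from nichegrowth.response import GrowthNicheModel

# 10 locally + 10 globally adapted synthetic species through the full
# candidate scan
df = dla_sign_recovery(n_local=10, n_global=10, seed=4)
print(df.groupby("adaptation_mode")["dla"].agg(["mean", "min", "max"]).round(3))
#                   mean    min    max
# adaptation_mode
# global          -0.230 -0.299 -0.137
# local            0.217  0.153  0.338
print(df["sign_correct"].mean())      # 1.0

# the anomaly x niche growth model on a globally adapted panel
panel = _mode_panel("global", seed=4)
print(GrowthNicheModel(panel, category="global").fit().summary())
```

```
GrowthNicheModel [global]
================================================================
n obs: 1728   species: 8   sites: 12
AIC (ML): 1008.41   R2_m: 0.473   R2_c: 0.824
----------------------------------------------------------------
term                coef      s.e.       z         p
const             2.3652    0.1481   15.97         0
log_n_lag        -0.7802    0.0238  -32.79         0
w                 0.0144    0.0076    1.91   0.05656
b                -0.2681    0.1666   -1.61    0.1076
w2               -0.0045    0.0050   -0.90    0.3689
w:b              -0.0976    0.0099   -9.86         0
----------------------------------------------------------------
random species      variance: 0.0002
random site         variance: 0.1984
residual variance: 0.0997
```

Every species' dla sign matches its generating mode, and the globally
adapted panel shows the expected signature: a strongly negative anomaly ×
niche interaction (`w:b` = −0.098) with no overall quadratic term, i.e.
positive anomalies raise growth at the leading margin (B = −1) and depress
it at the trailing margin (B = +1), while the negative `log_n_lag`
coefficient reflects Gompertz density regulation.

A command-line interface mirrors the pipeline stages
(`nichegrowth simulate / climate / index / dla / niche / fit`); run any
subcommand with `--help`.

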