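"""Parameter-recovery and calibration experiments on the synthetic scenario.

Each function runs one simulation study end-to-end through the package and
returns the measured quantity: sign recovery of the degree of local
adaptation, AIC selection of the true climatic driver, recovery of the
n-shaped growth response and of the anomaly x niche interaction, type-I
error calibration on pure-noise panels, mixed-vs-OLS agreement at zero
random variance, trend-slope recovery, and robustness of the abundance
index to masked survey weeks.

All randomness flows from a single integer seed per experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import climate as _climate
from .adaptation import DegreeOfAdaptationModel, select_best_candidate
from ._lmm import FitConvergenceError, fit_linear_model
from .phenology import FlightCurve, fit_flight_curve, growth_rates, impute_and_index
from .niche import niche_positions
from .response import AbundanceTrendModel, GrowthNicheModel
from .simulate import (
    N_WEEKS,
    SimulationConfig,
    flight_window,
    generate_daily_climate,
    generate_sites,
    generate_species,
    simulate_population_dynamics,
    simulate_weekly_counts,
)

#: the generator's default driver window (flight period, mid-June--early August)
TRUE_DRIVER_WINDOW = ("flight", 0)
TRUE_DRIVER_DOYS = (166, 222)
TRUE_DRIVER_VARIABLE = "temperature"


def _seed(seed: int, salt: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), salt])


def _complete_week_indices(counts: pd.DataFrame) -> pd.DataFrame:
    """Annual abundance indices from complete weekly counts (plain sums,
    which equals the imputation-based index when no weeks are missing)."""
    g = (
        counts.groupby(["species_id", "site_id", "year"])["count"]
        .sum()
        .rename("index")
        .reset_index()
    )
    return g


def _recovery_scenario(
    n_local: int,
    n_global: int,
    seed: int,
    n_sites_per_scheme: int = 8,
    n_sites_per_species: int = 8,
    detection_scale: float = 5.0,
):
    """Shared scaffolding: network, climate, species, growth observations and
    the candidate window-summary table."""
    cfg = SimulationConfig(
        n_sites_per_scheme=n_sites_per_scheme,
        n_species_local=n_local,
        n_species_global=n_global,
        n_sites_per_species=n_sites_per_species,
        missing_week_prob=0.0,
        detection_scale=detection_scale,
        rng_seed=int(seed) % (2**31),
    )
    sites = generate_sites(cfg)
    clim = generate_daily_climate(sites, cfg)
    rng = np.random.default_rng(_seed(seed, 11))
    species, occupancy = generate_species(cfg, sites, clim, rng=rng)
    wv = _climate.window_values(clim, _climate.candidate_windows(*TRUE_DRIVER_DOYS))
    growth_frames = []
    for sp in species:
        occ = occupancy[sp.species_id]
        latent = simulate_population_dynamics(sp, occ, clim, cfg, rng=rng)
        counts = simulate_weekly_counts(latent, sp, cfg, rng=rng)
        idx = _complete_week_indices(counts)
        growth_frames.append(growth_rates(idx))
    growth = pd.concat(growth_frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "species_id": [sp.species_id for sp in species],
            "adaptation_mode": [sp.adaptation_mode for sp in species],
        }
    )
    occupancy_ids = {k: [s.site_id for s in v] for k, v in occupancy.items()}
    return cfg, growth, wv, truth, occupancy_ids


def dla_sign_recovery(n_local: int = 50, n_global: int = 50, seed: int = 0) -> pd.DataFrame:
    """Does the sign of the estimated degree of local adaptation recover the
    generating adaptation mode?  Returns one row per species with the
    estimated dla, its classification and the truth."""
    _, growth, wv, truth, occ = _recovery_scenario(n_local, n_global, seed)
    model = DegreeOfAdaptationModel(growth, wv, occupancy=occ)
    res = model.fit().to_frame()
    out = res.merge(truth, on="species_id", validate="1:1")
    out["sign_correct"] = (
        ((out["dla"] > 0) & (out["adaptation_mode"] == "local"))
        | ((out["dla"] < 0) & (out["adaptation_mode"] == "global"))
    )
    return out


def driver_selection(n_replicates: int = 50, seed: int = 0) -> pd.DataFrame:
    """How often does AIC pick the true driver variable and window?

    Each replicate is one locally adapted species simulated with the
    flight-window temperature as its driver; the local-scale candidate scan
    (3 variables x 7 windows) is run and the AIC winner recorded.
    """
    _, growth, wv, truth, occ = _recovery_scenario(n_replicates, 0, seed)
    model = DegreeOfAdaptationModel(growth, wv, occupancy=occ)
    rows = []
    for sp in truth["species_id"]:
        local_c, _ = model._species_candidates(sp)
        try:
            best = select_best_candidate(local_c)
        except FitConvergenceError:
            rows.append({"species_id": sp, "variable": None, "window_kind": None,
                         "year_offset": None, "correct": False})
            continue
        rows.append(
            {
                "species_id": sp,
                "variable": best.variable,
                "window_kind": best.window_kind,
                "year_offset": best.year_offset,
                "correct": (
                    best.variable == TRUE_DRIVER_VARIABLE
                    and (best.window_kind, best.year_offset) == TRUE_DRIVER_WINDOW
                ),
            }
        )
    return pd.DataFrame(rows)


def _mode_panel(mode: str, seed: int, n_species: int = 8, n_sites_per_scheme: int = 4):
    """One pooled growth panel of a single adaptation mode, with standardized
    local anomalies of the true driver window and niche positions."""
    cfg = SimulationConfig(
        n_sites_per_scheme=n_sites_per_scheme,
        n_species_local=n_species if mode == "local" else 0,
        n_species_global=n_species if mode == "global" else 0,
        n_sites_per_species=3 * n_sites_per_scheme,
        missing_week_prob=0.0,
        detection_scale=5.0,
        rng_seed=int(seed) % (2**31),
    )
    sites = generate_sites(cfg)
    clim = generate_daily_climate(sites, cfg)
    rng = np.random.default_rng(_seed(seed, 13))
    species, occupancy = generate_species(cfg, sites, clim, rng=rng)
    window = flight_window(*TRUE_DRIVER_DOYS)
    wv = _climate.window_values(clim, [window], variables=(TRUE_DRIVER_VARIABLE,))
    anoms = _climate.compute_anomalies(wv)
    anoms = _climate.standardize_anomalies(anoms)
    frames = []
    for sp in species:
        occ = occupancy[sp.species_id]
        occ_ids = [s.site_id for s in occ]
        latent = simulate_population_dynamics(sp, occ, clim, cfg, rng=rng)
        counts = simulate_weekly_counts(latent, sp, cfg, rng=rng)
        growth = growth_rates(_complete_week_indices(counts))
        b = niche_positions(
            wv[wv["site_id"].isin(occ_ids)][["site_id", "year", "value"]],
            variable=TRUE_DRIVER_VARIABLE,
            extent="site_mean",
        )
        df = growth.merge(
            anoms.rename(columns={"standardized": "w"})[["site_id", "year", "w"]],
            on=["site_id", "year"],
        ).merge(
            b.rename(columns={"niche_position": "b"})[["site_id", "b"]], on="site_id"
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def growth_shape_recovery(mode: str, n_replicates: int = 20, seed: int = 0) -> pd.DataFrame:
    """Recovery of the headline growth-model shapes.

    For each replicate panel the full anomaly x niche model is fitted and
    the W^2 coefficient, the W x B coefficient, and the implied anomaly
    slopes at the leading (B = -1) and trailing (B = +1) margins recorded.
    """
    rows = []
    for k in range(n_replicates):
        panel = _mode_panel(mode, seed=int(np.random.default_rng(_seed(seed, 17 + k)).integers(2**31)))
        res = GrowthNicheModel(panel, category=mode).fit()
        w, w2, wb = res.params["w"], res.params["w2"], res.params["w:b"]
        rows.append(
            {
                "replicate": k,
                "w": float(w),
                "w2": float(w2),
                "w_x_b": float(wb),
                "slope_leading": float(w - wb),    # d r / d W at B = -1
                "slope_trailing": float(w + wb),   # d r / d W at B = +1
            }
        )
    return pd.DataFrame(rows)


def type_one_error(n_replicates: int = 200, seed: int = 0,
                   n_species: int = 6, n_sites: int = 8, n_years: int = 12) -> pd.DataFrame:
    """Type-I calibration of the growth-niche model on pure-noise panels.

    Growth is independent N(0,1) noise with no climate or niche effect;
    the W x B and W^2 rejection rates at alpha = 0.05 should sit near 5%.
    """
    rows = []
    for k in range(n_replicates):
        rng = np.random.default_rng(_seed(seed, 1000 + k))
        sites = [f"s{i}" for i in range(n_sites)]
        species = [f"sp{j}" for j in range(n_species)]
        w_site_year = rng.normal(size=(n_sites, n_years))
        b = {(sp, s): rng.uniform(-1, 1) for sp in species for s in sites}
        recs = []
        for sp in species:
            for i, s in enumerate(sites):
                for t in range(n_years):
                    recs.append(
                        (sp, s, t, rng.normal(), rng.normal(), w_site_year[i, t], b[(sp, s)])
                    )
        panel = pd.DataFrame(
            recs, columns=["species_id", "site_id", "year", "r", "log_n_lag", "w", "b"]
        )
        res = GrowthNicheModel(panel).fit()
        rows.append(
            {
                "replicate": k,
                "p_w2": float(res.pvalues["w2"]),
                "p_wb": float(res.pvalues["w:b"]),
            }
        )
    return pd.DataFrame(rows)


def mixed_vs_ols_oracle(
    seed: int = 0,
    n_species: int = 8,
    n_sites: int = 12,
    n_years: int = 18,
    noise_sd: float = 0.1,
) -> dict:
    """With zero simulated random-effect variance the mixed fixed effects
    must coincide with the OLS oracle.

    The panel is a balanced species x site x year crossing structured like
    the monitoring data: the climatic anomaly is a year-level covariate,
    the niche position a site-level one, and lagged log abundance varies
    per observation.  No species or site effect is simulated.
    """
    rng = np.random.default_rng(_seed(seed, 23))
    w_year = rng.normal(size=n_years)
    b_site = rng.uniform(-1, 1, size=n_sites)
    recs = []
    for j in range(n_species):
        for i in range(n_sites):
            lag_series = rng.normal(size=n_years)
            for t in range(n_years):
                lag, w, b = lag_series[t], w_year[t], b_site[i]
                r = (
                    0.2 - 0.3 * lag + 0.4 * w - 0.25 * w**2 - 0.15 * w * b
                    + rng.normal(0, noise_sd)
                )
                recs.append((f"sp{j}", f"s{i}", t, r, lag, w, b))
    panel = pd.DataFrame(
        recs, columns=["species_id", "site_id", "year", "r", "log_n_lag", "w", "b"]
    )
    mixed = GrowthNicheModel(panel).fit()
    X = pd.DataFrame(
        {
            "const": 1.0,
            "log_n_lag": panel["log_n_lag"],
            "w": panel["w"],
            "b": panel["b"],
            "w2": panel["w"] ** 2,
            "w:b": panel["w"] * panel["b"],
        }
    )
    ols = fit_linear_model(panel["r"].to_numpy(), X)
    diff = (mixed.params - ols.params[mixed.params.index]).abs()
    return {"max_abs_diff": float(diff.max()), "mixed": mixed.params, "ols": ols.params}


def trend_recovery(n_replicates: int = 20, seed: int = 0,
                   n_species: int = 6, n_sites: int = 10, n_years: int = 15) -> pd.DataFrame:
    """Recovery of the margin-dependent abundance trend.

    Panels decline at the trailing margin (slope -0.08/yr at B = +1) and are
    stable at the leading margin; the fitted Z x B coefficient should be
    negative."""
    rows = []
    for k in range(n_replicates):
        rng = np.random.default_rng(_seed(seed, 2000 + k))
        recs = []
        for j in range(n_species):
            b_sites = np.linspace(-1, 1, n_sites) + rng.normal(0, 0.05, n_sites)
            b_sites = np.clip(b_sites, -1, 1)
            for i in range(n_sites):
                slope = -0.08 * (1.0 + b_sites[i]) / 2.0
                log_n0 = rng.normal(2.5, 0.3)
                for t in range(n_years):
                    log_n = log_n0 + slope * t + rng.normal(0, 0.2)
                    n_latent = np.exp(log_n)
                    n_obs = rng.poisson(5.0 * n_latent) / 5.0
                    recs.append((f"sp{j}", f"s{i}", 2000 + t, n_obs, b_sites[i]))
        panel = pd.DataFrame(recs, columns=["species_id", "site_id", "year", "n_index", "b"])
        res = AbundanceTrendModel(panel).fit()
        rows.append({"replicate": k, "z_x_b": float(res.params["z:b"])})
    return pd.DataFrame(rows)


def index_masking_robustness(
    seed: int = 0,
    mask_fraction: float = 0.2,
    n_sites: int = 6,
    n_years: int = 8,
) -> pd.DataFrame:
    """Robustness of the abundance index to missing survey weeks.

    Complete synthetic weekly counts are indexed, then ``mask_fraction`` of
    each series' weeks is masked and the imputation-based index recomputed;
    returns the per-series relative index change."""
    cfg = SimulationConfig(
        n_sites_per_scheme=n_sites // 3 + 1,
        n_species_local=1,
        n_species_global=0,
        n_sites_per_species=n_sites,
        years=(2000, 2000 + n_years - 1),
        missing_week_prob=0.0,
        detection_scale=5.0,
        rng_seed=int(seed) % (2**31),
    )
    sites = generate_sites(cfg)
    clim = generate_daily_climate(sites, cfg)
    rng = np.random.default_rng(_seed(seed, 31))
    species, occupancy = generate_species(cfg, sites, clim, rng=rng)
    sp = species[0]
    latent = simulate_population_dynamics(sp, occupancy[sp.species_id], clim, cfg, rng=rng)
    counts = simulate_weekly_counts(latent, sp, cfg, rng=rng)
    curve = fit_flight_curve(counts, sp.species_id)
    complete = _complete_week_indices(counts).set_index(["site_id", "year"])["index"]

    masked = counts.copy()
    mask = rng.random(len(masked)) < mask_fraction
    masked.loc[mask, "count"] = np.nan
    rows = []
    for (site, year), _ in complete.items():
        ai = impute_and_index(masked, curve, sp.species_id, site, int(year))
        full = complete.loc[(site, year)]
        if full > 0 and not np.isnan(ai.index):
            rows.append(
                {
                    "site_id": site,
                    "year": year,
                    "complete_index": float(full),
                    "masked_index": ai.index,
                    "rel_change": abs(ai.index - full) / full,
                }
            )
    return pd.DataFrame(rows)
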