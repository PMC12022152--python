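"""Seed-reproducible synthetic butterfly monitoring data.

Emulates a three-scheme transect network (a warm southern scheme, a temperate
one and a boreal one) spanning a latitudinal climate gradient, with:

* daily site climate = site mean + sinusoidal seasonal cycle + independent
  monthly anomalies + daily noise (precipitation via a gamma observation
  layer, so it is non-negative);
* species whose thermal/hydric performance curve is Gaussian in a driver
  variable (temperature, precipitation or aridity) summarised over one
  phenological window, centred either on each site's own long-run mean
  (locally adapted) or on a single species-wide optimum (globally adapted);
* Gompertz density-dependent log-linear population dynamics with additive
  process noise;
* an observation layer of weekly Pollard-walk counts: Poisson draws around
  latent abundance spread over a normalized Gaussian flight curve
  (one mode per brood), with weeks missing independently at random.

Every generator takes a :class:`SimulationConfig` whose ``rng_seed`` fully
determines the output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import climate as _climate
from .climate import WindowDefinition, flight_window

N_WEEKS = 26          # monitoring season, March-September
WEEK1_DOY = _climate.MAR1

SCHEME_LATITUDES = {"south": (37.0, 43.0), "central": (50.5, 58.5), "north": (60.0, 65.0)}
SCHEME_LONGITUDES = {"south": (-6.0, 2.0), "central": (-5.0, 1.0), "north": (22.0, 30.0)}
SCHEME_START_YEARS = {"south": 1994, "central": 1976, "north": 1999}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    latitude: float
    longitude: float
    scheme: str
    mean_temp: float      # long-run annual mean, deg C
    mean_precip: float    # long-run annual total, mm
    first_year: int
    last_year: int

    def __post_init__(self):
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    adaptation_mode: str            # "local" or "global"
    driver_variable: str            # temperature | precipitation | aridity
    driver_window: WindowDefinition
    optimum: float | None           # climate value (global mode); None = site mean (local)
    breadth: float                  # performance-curve s.d., driver units
    max_growth: float               # log growth per year at the optimum
    density_dependence: float       # Gompertz coefficient, in (-1, 0]
    voltinism: int = 1
    flight_peak_week: float = 13.0
    flight_sd_weeks: float = 2.5

    def __post_init__(self):
        if self.adaptation_mode not in ("local", "global"):
            raise ValueError("adaptation_mode must be 'local' or 'global'")
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")
        if not (-1.0 < self.density_dependence <= 0.0):
            raise ValueError("density_dependence must lie in (-1, 0]")
        if not (1 <= self.flight_peak_week <= N_WEEKS):
            raise ValueError("flight peak must fall inside the monitoring season")
        if self.voltinism not in (1, 2):
            raise ValueError("voltinism must be 1 or 2")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic three-scheme scenario.

    Defaults emulate the desk-scale version of the real design: a 1999-2017
    study window, sites spanning roughly 37-65 degrees N, and species in two
    adaptation modes.  Setting every ``*_sd`` and ``precip_gamma_shape`` to 0
    produces a fully deterministic climate.
    """

    n_sites_per_scheme: int = 10
    n_species_local: int = 5
    n_species_global: int = 5
    years: tuple[int, int] = (1999, 2017)
    n_sites_per_species: int = 8
    missing_week_prob: float = 0.1
    detection_scale: float = 1.0
    rng_seed: int = 0

    # climate process
    seasonal_amplitude: float = 9.0      # deg C, peak mid-July
    temp_lat_slope: float = -0.57        # deg C per degree latitude
    temp_lat_intercept: float = 38.5
    site_temp_sd: float = 0.6            # site-level scatter around the gradient
    monthly_anom_sd: float = 1.2         # deg C, independent per site x month
    daily_noise_sd: float = 2.0          # deg C
    precip_base_total: float = 620.0     # mm / year at 37 N
    precip_lat_slope: float = 6.0        # mm per degree latitude
    site_precip_sd: float = 40.0
    precip_month_sd: float = 0.35        # lognormal s.d. of monthly rate
    precip_gamma_shape: float = 0.7      # daily gamma shape; 0 = deterministic

    # population process
    max_growth: float = 1.0
    density_dependence: float = -0.4
    breadth_scale: float = 1.2           # local mode: performance s.d. in units of driver interannual s.d.
    global_breadth_scale: float = 0.35   # global mode: fraction of the occupied site-mean range
    process_noise_sd: float = 0.15
    burn_in_years: int = 5

    def __post_init__(self):
        if not (0.0 <= self.missing_week_prob <= 1.0):
            raise ConfigurationError("missing_week_prob must be in [0, 1]")
        if min(self.n_sites_per_scheme, self.n_species_local + self.n_species_global) <= 0:
            raise ConfigurationError("site and species counts must be positive")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("years must be an increasing (first, last) pair")


def generate_sites(config: SimulationConfig) -> list[SiteSpec]:
    """Generate the three-scheme site network along a latitudinal gradient.

    Mean annual temperature decreases with latitude in expectation; annual
    precipitation increases slightly.
    """
    if config.n_sites_per_scheme <= 0:
        raise ConfigurationError("n_sites_per_scheme must be positive")
    rng = np.random.default_rng(config.rng_seed)
    sites = []
    y0, y1 = config.years
    for scheme in ("south", "central", "north"):
        lat_lo, lat_hi = SCHEME_LATITUDES[scheme]
        lon_lo, lon_hi = SCHEME_LONGITUDES[scheme]
        for k in range(config.n_sites_per_scheme):
            lat = rng.uniform(lat_lo, lat_hi)
            lon = rng.uniform(lon_lo, lon_hi)
            mtemp = (
                config.temp_lat_intercept
                + config.temp_lat_slope * lat
                + rng.normal(0.0, config.site_temp_sd)
            )
            mprec = max(
                50.0,
                config.precip_base_total
                + config.precip_lat_slope * (lat - 37.0)
                + rng.normal(0.0, config.site_precip_sd),
            )
            sites.append(
                SiteSpec(
                    site_id=f"{scheme}_{k:03d}",
                    latitude=float(lat),
                    longitude=float(lon),
                    scheme=scheme,
                    mean_temp=float(mtemp),
                    mean_precip=float(mprec),
                    first_year=max(SCHEME_START_YEARS[scheme], y0),
                    last_year=y1,
                )
            )
    return sites


def sites_frame(sites: list[SiteSpec]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in sites])


def generate_daily_climate(sites: list[SiteSpec], config: SimulationConfig) -> pd.DataFrame:
    """Daily temperature/precipitation per site.

    Two years before the study window are generated so that year t-1 windows
    (including the overwinter window reaching into November of t-2) are
    covered for the first study year.
    """
    if not sites:
        raise ConfigurationError("site list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    y0, y1 = config.years
    dates = pd.date_range(f"{y0 - 2}-01-01", f"{y1}-12-31", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    doy = np.where(
        dates.is_leap_year & (dates.dayofyear > 59),
        dates.dayofyear - 1,
        dates.dayofyear,
    )
    years = dates.year.to_numpy()
    months = dates.month.to_numpy()
    n_days = len(dates)
    year_index = years - (y0 - 2)
    month_key = year_index * 12 + (months - 1)
    n_months = (y1 - y0 + 3) * 12
    seasonal = np.cos(2 * np.pi * (doy - 196) / 365.0)

    frames = []
    for site in sites:
        t_anom = (
            rng.normal(0.0, config.monthly_anom_sd, size=n_months)
            if config.monthly_anom_sd > 0
            else np.zeros(n_months)
        )
        p_anom = (
            rng.normal(0.0, config.precip_month_sd, size=n_months)
            if config.precip_month_sd > 0
            else np.zeros(n_months)
        )
        temp = (
            site.mean_temp
            + config.seasonal_amplitude * seasonal
            + t_anom[month_key]
            + (
                rng.normal(0.0, config.daily_noise_sd, size=n_days)
                if config.daily_noise_sd > 0
                else 0.0
            )
        )
        # monthly log-rate anomalies keep the expected annual total at mean_precip
        rate = (site.mean_precip / 365.0) * np.exp(
            p_anom[month_key] - 0.5 * config.precip_month_sd**2
        )
        if config.precip_gamma_shape > 0:
            k = config.precip_gamma_shape
            prec = rate * rng.gamma(k, 1.0 / k, size=n_days)
        else:
            prec = rate
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site.site_id,
                    "date": dates,
                    "tmean_c": temp,
                    "prec_mm": np.maximum(prec, 0.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def performance(value: np.ndarray, optimum: float, breadth: float) -> np.ndarray:
    """Gaussian performance curve scaled to 1 at its peak."""
    return np.exp(-0.5 * ((np.asarray(value, dtype=float) - optimum) / breadth) ** 2)


def driver_series(
    species: SpeciesSpec,
    sites: list[SiteSpec],
    climate: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Window summaries of the species' driver variable at its occupied sites.

    Returns columns ``site_id, year, value`` for the species' driver window.
    """
    site_ids = [s.site_id for s in sites]
    sub = climate[climate["site_id"].isin(site_ids)]
    vals = _climate.window_values(
        sub, [species.driver_window], variables=(species.driver_variable,)
    )
    return vals[["site_id", "year", "value"]]


def simulate_population_dynamics(
    species: SpeciesSpec,
    sites: list[SiteSpec],
    climate: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    driver: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Latent annual abundance under Gompertz dynamics with a Gaussian
    performance response to the species' driver window.

    log N_t = log N_{t-1} + max_growth * performance(driver value)
              + density_dependence * log N_{t-1} + process noise

    Locally adapted species have the performance curve centred on each
    site's long-run window mean; globally adapted species share a single
    optimum.  Returns ``species_id, site_id, year, latent_n``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    if driver is None:
        driver = driver_series(species, sites, climate, config)
    y0, y1 = config.years
    needed = range(y0, y1 + 1)
    rows = []
    for site in sites:
        v = driver[driver["site_id"] == site.site_id].set_index("year")["value"]
        missing = [y for y in needed if y not in v.index]
        if missing:
            raise _climate.ClimateCoverageError(
                f"no climate window value for site {site.site_id!r}, "
                f"year {missing[0]}, window {species.driver_window.label}"
            )
        opt = float(v.mean()) if species.adaptation_mode == "local" else float(species.optimum)
        perf = performance(v.loc[list(needed)].to_numpy(), opt, species.breadth)
        dd = species.density_dependence
        # start at the deterministic equilibrium of mean conditions
        perf0 = performance(np.array([v.mean()]), opt, species.breadth)[0]
        log_n = species.max_growth * perf0 / -dd if dd < 0 else np.log(20.0)
        burn_perf = np.full(config.burn_in_years, perf0)
        trajectory = []
        for j, p in enumerate(np.concatenate([burn_perf, perf])):
            noise = rng.normal(0.0, config.process_noise_sd) if config.process_noise_sd > 0 else 0.0
            log_n = log_n + species.max_growth * p + dd * log_n + noise
            if j >= config.burn_in_years:
                trajectory.append(log_n)
        for year, ln in zip(needed, trajectory):
            rows.append((species.species_id, site.site_id, year, float(np.exp(ln))))
    return pd.DataFrame(rows, columns=["species_id", "site_id", "year", "latent_n"])


def flight_curve_weights(species: SpeciesSpec) -> np.ndarray:
    """Normalized expected weekly proportions over the 26-week season
    (one Gaussian mode per brood)."""
    weeks = np.arange(1, N_WEEKS + 1, dtype=float)
    w = np.exp(-0.5 * ((weeks - species.flight_peak_week) / species.flight_sd_weeks) ** 2)
    if species.voltinism == 2:
        w = w + np.exp(
            -0.5 * ((weeks - (species.flight_peak_week + 8.0)) / species.flight_sd_weeks) ** 2
        )
    return w / w.sum()


def simulate_weekly_counts(
    latent: pd.DataFrame,
    species: SpeciesSpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Poisson weekly counts around the latent abundance spread over the
    flight curve, with weeks independently missing.

    Returns ``species_id, site_id, year, week, count`` where missing weeks
    carry NaN counts.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    props = flight_curve_weights(species)
    sub = latent[latent["species_id"] == species.species_id]
    n = len(sub)
    lam = sub["latent_n"].to_numpy()[:, None] * config.detection_scale * props[None, :]
    counts = rng.poisson(lam).astype(float)
    if config.missing_week_prob > 0:
        mask = rng.random(size=counts.shape) < config.missing_week_prob
        counts[mask] = np.nan
    out = pd.DataFrame(
        {
            "species_id": np.repeat(sub["species_id"].to_numpy(), N_WEEKS),
            "site_id": np.repeat(sub["site_id"].to_numpy(), N_WEEKS),
            "year": np.repeat(sub["year"].to_numpy(), N_WEEKS),
            "week": np.tile(np.arange(1, N_WEEKS + 1), n),
            "count": counts.ravel(),
        }
    )
    return out


def generate_species(
    config: SimulationConfig,
    sites: list[SiteSpec],
    climate: pd.DataFrame,
    rng: np.random.Generator | None = None,
    driver_variable: str = "temperature",
    driver_window: WindowDefinition | None = None,
) -> tuple[list[SpeciesSpec], dict[str, list[SiteSpec]]]:
    """Draw species specs (local then global mode) and their occupied sites.

    Performance breadths differ by mode, mirroring the two adaptation
    stories: locally adapted species respond on the scale of interannual
    anomalies (breadth = ``breadth_scale`` x the driver's interannual s.d.
    at occupied sites), while globally adapted species share one optimum at
    the occupancy-wide mean with a breadth of ``global_breadth_scale`` x the
    occupied site-mean range, so populations on both niche flanks persist
    but respond to anomalies with opposite sign.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 4]))
    if driver_window is None:
        driver_window = flight_window(166, 222)  # mid-June to early August
    vals = _climate.window_values(climate, [driver_window], variables=(driver_variable,))
    species_list: list[SpeciesSpec] = []
    occupancy: dict[str, list[SiteSpec]] = {}
    modes = ["local"] * config.n_species_local + ["global"] * config.n_species_global
    for k, mode in enumerate(modes):
        occ = list(rng.choice(len(sites), size=min(config.n_sites_per_species, len(sites)), replace=False))
        occ_sites = [sites[i] for i in occ]
        occ_ids = [s.site_id for s in occ_sites]
        sub = vals[vals["site_id"].isin(occ_ids)]
        if mode == "local":
            interannual_sd = float(sub.groupby("site_id")["value"].std(ddof=1).mean())
            breadth = config.breadth_scale * interannual_sd
            optimum = None
        else:
            site_means = sub.groupby("site_id")["value"].mean()
            breadth = config.global_breadth_scale * float(site_means.max() - site_means.min())
            optimum = float(sub["value"].mean())
        sp = SpeciesSpec(
            species_id=f"sp_{mode}_{k:03d}",
            adaptation_mode=mode,
            driver_variable=driver_variable,
            driver_window=driver_window,
            optimum=optimum,
            breadth=breadth,
            max_growth=config.max_growth,
            density_dependence=config.density_dependence,
            voltinism=1,
            flight_peak_week=float(rng.uniform(11, 16)),
            flight_sd_weeks=float(rng.uniform(2.0, 3.0)),
        )
        species_list.append(sp)
        occupancy[sp.species_id] = occ_sites
    return species_list, occupancy


@dataclass
class SimulationResult:
    sites: pd.DataFrame
    climate: pd.DataFrame
    counts: pd.DataFrame
    latent: pd.DataFrame
    truth: pd.DataFrame
    species: list[SpeciesSpec]
    occupancy: dict[str, list[SiteSpec]]


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: sites, climate, species, dynamics, counts."""
    sites = generate_sites(config)
    clim = generate_daily_climate(sites, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 5]))
    species, occupancy = generate_species(config, sites, clim, rng=rng)
    latents, counts, truth_rows = [], [], []
    for sp in species:
        occ = occupancy[sp.species_id]
        latent = simulate_population_dynamics(sp, occ, clim, config, rng=rng)
        latents.append(latent)
        counts.append(simulate_weekly_counts(latent, sp, config, rng=rng))
        truth_rows.append(
            {
                "species_id": sp.species_id,
                "adaptation_mode": sp.adaptation_mode,
                "driver_variable": sp.driver_variable,
                "driver_window_kind": sp.driver_window.kind,
                "driver_year_offset": sp.driver_window.year_offset,
                "optimum": sp.optimum,
                "breadth": sp.breadth,
                "max_growth": sp.max_growth,
                "density_dependence": sp.density_dependence,
                "n_sites": len(occ),
            }
        )
    return SimulationResult(
        sites=sites_frame(sites),
        climate=clim,
        counts=pd.concat(counts, ignore_index=True),
        latent=pd.concat(latents, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        species=species,
        occupancy=occupancy,
    )
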