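"""Headline mixed models: growth vs anomaly x niche, and abundance trends.

Two statsmodels-style model classes, each fitted separately for the locally
and globally adapted species categories:

* :class:`GrowthNicheModel` -- annual log population growth regressed on
  lagged log abundance (density dependence), the standardized local climatic
  anomaly W, its square, the site's bioclimatic niche position B and the
  W x B interaction, with crossed random intercepts for species and site.
  Locally adapted species are expected to show an n-shaped (negative W^2)
  response independent of B; globally adapted species a sign-reversing
  linear response across the niche (negative W x B: positive anomalies help
  the leading margin, hurt the trailing margin).

* :class:`AbundanceTrendModel` -- the zero-safe transformed abundance index
  log(N + sqrt(N^2 + 1)) (= arcsinh N) regressed on the cumulative number of
  observation years Z per species in interaction with B, with a random Z
  slope within species plus species and site intercepts.

Both support stepwise AIC reduction (interaction vs additive, quadratic vs
linear), fixed-effect prediction grids over 21 niche levels, and a
sensitivity suite re-fitting under stricter adaptation-category definitions
and with candidate outlier species removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lmm import FitConvergenceError, LinearMixedFit, fit_linear_model

NICHE_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 1)  # 21 levels


def zero_safe_log(n):
    """log(N + sqrt(N^2 + 1)): behaves like log(2N) for large N but is
    defined (and 0) at N = 0.  This is the inverse hyperbolic sine."""
    return np.arcsinh(np.asarray(n, dtype=float))


def zero_safe_log_inverse(y):
    return np.sinh(np.asarray(y, dtype=float))


def _vc_designs(data: pd.DataFrame, terms: dict[str, tuple[str, str | None]]):
    """Variance-component dummy designs: {name: (factor_col, slope_col|None)}."""
    vc = {}
    for name, (factor, slope) in terms.items():
        d = pd.get_dummies(data[factor].astype("category"), dtype=float)
        d.columns = [f"{name}[{c}]" for c in d.columns]
        if slope is not None:
            d = d.mul(data[slope].to_numpy(), axis=0)
        vc[name] = d
    return vc


@dataclass
class MixedModelResults:
    """Shared result container: estimates, uncertainty, diagnostics."""

    fit: LinearMixedFit
    model: object
    terms: tuple[str, ...]
    category: str | None = None
    n_species: int = 0
    n_sites: int = 0

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def r2_marginal(self) -> float:
        return self.fit.r2_marginal

    @property
    def r2_conditional(self) -> float:
        return self.fit.r2_conditional

    def summary(self) -> str:
        head = [
            f"{type(self.model).__name__}"
            + (f" [{self.category}]" if self.category else ""),
            "=" * 64,
            f"n obs: {self.fit.n_obs}   species: {self.n_species}   sites: {self.n_sites}",
            f"AIC (ML): {self.fit.aic:.2f}   R2_m: {self.r2_marginal:.3f}   "
            f"R2_c: {self.r2_conditional:.3f}",
            "-" * 64,
            f"{'term':<14}{'coef':>10}{'s.e.':>10}{'z':>8}{'p':>10}",
        ]
        for t in self.fit.params.index:
            b, se, p = self.fit.params[t], self.fit.bse[t], self.fit.pvalues[t]
            z = b / se if se > 0 else np.nan
            head.append(f"{t:<14}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.4g}")
        head.append("-" * 64)
        for name, v in self.fit.random_variances.items():
            head.append(f"random {name:<12} variance: {v:.4f}")
        head.append(f"residual variance: {self.fit.var_resid:.4f}")
        return "\n".join(head)


class GrowthNicheModel:
    """Population growth vs local climatic anomaly x bioclimatic niche.

    Parameters
    ----------
    data
        One row per growth observation with columns ``r`` (log growth),
        ``log_n_lag``, ``w`` (standardized local anomaly), ``b`` (niche
        position), ``species_id``, ``site_id``.
    category
        Optional label ("local"/"global") carried into results.
    """

    def __init__(self, data: pd.DataFrame, category: str | None = None):
        required = {"r", "log_n_lag", "w", "b", "species_id", "site_id"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.data = data.dropna(subset=sorted(required & {"r", "log_n_lag", "w", "b"})).copy()
        self.category = category

    @classmethod
    def from_frames(
        cls,
        growth: pd.DataFrame,
        anomalies: pd.DataFrame,
        niche: pd.DataFrame,
        category: str | None = None,
    ) -> "GrowthNicheModel":
        """Assemble the modelling frame from pipeline outputs.

        ``growth``: species_id, site_id, year, r, log_n_lag;
        ``anomalies``: site_id, year, standardized (one variable/window,
        optionally per species); ``niche``: species_id?, site_id,
        niche_position.
        """
        on = ["site_id", "year"] + (["species_id"] if "species_id" in anomalies else [])
        df = growth.merge(
            anomalies.rename(columns={"standardized": "w"})[on + ["w"]], on=on, how="inner"
        )
        non = ["site_id"] + (["species_id"] if "species_id" in niche else [])
        df = df.merge(
            niche.rename(columns={"niche_position": "b"})[non + ["b"]], on=non, how="inner"
        )
        return cls(df, category=category)

    def _design(self, interaction: bool, quadratic: bool) -> pd.DataFrame:
        d = self.data
        X = pd.DataFrame({"const": 1.0, "log_n_lag": d["log_n_lag"], "w": d["w"], "b": d["b"]})
        if quadratic:
            X["w2"] = d["w"] ** 2
        if interaction:
            X["w:b"] = d["w"] * d["b"]
        return X

    def fit(
        self, interaction: bool = True, quadratic: bool = True, reml: bool = False
    ) -> MixedModelResults:
        d = self.data
        X = self._design(interaction, quadratic)
        terms = {"site": ("site_id", None)}
        if d["species_id"].nunique() > 1:
            terms = {"species": ("species_id", None), **terms}
        vc = _vc_designs(d, terms)
        try:
            fit = fit_linear_model(d["r"].to_numpy(), X, vc=vc, reml=reml)
        except FitConvergenceError as err:
            raise FitConvergenceError(
                f"growth-niche model did not converge ({err}); consider a "
                "simplified random structure (drop the species or site term)"
            ) from err
        return MixedModelResults(
            fit=fit,
            model=self,
            terms=tuple(X.columns),
            category=self.category,
            n_species=d["species_id"].nunique(),
            n_sites=d["site_id"].nunique(),
        )

    def model_reduction(self, reml: bool = False) -> "ReductionResult":
        """Stepwise AIC comparison of interaction x quadratic structures."""
        ledger = []
        fits = {}
        for interaction in (True, False):
            for quadratic in (True, False):
                label = (
                    ("interaction" if interaction else "additive")
                    + "+"
                    + ("quadratic" if quadratic else "linear")
                )
                res = self.fit(interaction=interaction, quadratic=quadratic, reml=reml)
                fits[label] = res
                ledger.append(
                    {
                        "model": label,
                        "interaction": interaction,
                        "quadratic": quadratic,
                        "k_fixed": len(res.fit.params),
                        "aic": res.aic,
                    }
                )
        ledger_df = pd.DataFrame(ledger)
        best_label = ledger_df.sort_values(["aic", "k_fixed"]).iloc[0]["model"]
        return ReductionResult(ledger=ledger_df, best_label=best_label, best=fits[best_label])

    def predict_grid(
        self,
        results: MixedModelResults,
        x_grid: np.ndarray | None = None,
        niche_levels: np.ndarray = NICHE_GRID,
    ) -> pd.DataFrame:
        """Fixed-effect predictions over anomaly x 21 niche levels, density
        dependence held at the sample mean of log N_{t-1}."""
        return _predict_grid(
            results, self.data, x_col="w", x_grid=x_grid, niche_levels=niche_levels,
            extras={"log_n_lag": float(self.data["log_n_lag"].mean())},
        )


class AbundanceTrendModel:
    """Abundance trends along the niche: arcsinh(N) ~ Z x B.

    ``data`` needs ``n_index`` (annual abundance index, >= 0), ``b`` (niche
    position), ``species_id``, ``site_id``, ``year``.  The cumulative year
    count Z is computed per species from its first observed year (1, 2, ...).
    """

    def __init__(self, data: pd.DataFrame, category: str | None = None):
        required = {"n_index", "b", "species_id", "site_id", "year"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        d = data.dropna(subset=["n_index", "b"]).copy()
        if (d["n_index"] < 0).any():
            raise ValueError("abundance indices must be non-negative")
        first = d.groupby("species_id")["year"].transform("min")
        d["z"] = d["year"] - first + 1
        d["y"] = zero_safe_log(d["n_index"])
        self.data = d
        self.category = category

    def _design(self, interaction: bool) -> pd.DataFrame:
        d = self.data
        X = pd.DataFrame({"const": 1.0, "z": d["z"].astype(float), "b": d["b"]})
        if interaction:
            X["z:b"] = d["z"] * d["b"]
        return X

    def fit(self, interaction: bool = True, reml: bool = False) -> MixedModelResults:
        d = self.data
        X = self._design(interaction)
        terms: dict[str, tuple[str, str | None]] = {}
        if d["species_id"].nunique() > 1:
            terms["species"] = ("species_id", None)
            terms["species_z"] = ("species_id", "z")
        terms["site"] = ("site_id", None)
        vc = _vc_designs(d, terms)
        try:
            fit = fit_linear_model(d["y"].to_numpy(), X, vc=vc, reml=reml)
        except FitConvergenceError as err:
            raise FitConvergenceError(
                f"trend model did not converge ({err}); consider dropping the "
                "random Z slope"
            ) from err
        return MixedModelResults(
            fit=fit,
            model=self,
            terms=tuple(X.columns),
            category=self.category,
            n_species=d["species_id"].nunique(),
            n_sites=d["site_id"].nunique(),
        )

    def model_reduction(self, reml: bool = False) -> "ReductionResult":
        ledger, fits = [], {}
        for interaction in (True, False):
            label = "interaction" if interaction else "additive"
            res = self.fit(interaction=interaction, reml=reml)
            fits[label] = res
            ledger.append(
                {"model": label, "interaction": interaction,
                 "k_fixed": len(res.fit.params), "aic": res.aic}
            )
        ledger_df = pd.DataFrame(ledger)
        best_label = ledger_df.sort_values(["aic", "k_fixed"]).iloc[0]["model"]
        return ReductionResult(ledger=ledger_df, best_label=best_label, best=fits[best_label])

    def predict_grid(
        self,
        results: MixedModelResults,
        x_grid: np.ndarray | None = None,
        niche_levels: np.ndarray = NICHE_GRID,
    ) -> pd.DataFrame:
        return _predict_grid(
            results, self.data, x_col="z", x_grid=x_grid, niche_levels=niche_levels, extras={}
        )


@dataclass
class ReductionResult:
    ledger: pd.DataFrame
    best_label: str
    best: MixedModelResults


def _predict_grid(results, data, x_col, x_grid, niche_levels, extras) -> pd.DataFrame:
    params = results.fit.params
    xs = data[x_col].to_numpy(dtype=float)
    if x_grid is None:
        x_grid = np.linspace(xs.min(), xs.max(), 41)
    else:
        x_grid = np.asarray(x_grid, dtype=float)
        if x_grid.min() < xs.min() - 1e-12 or x_grid.max() > xs.max() + 1e-12:
            warnings.warn("prediction grid extends beyond the fitted range "
                          f"of {x_col}: extrapolation", stacklevel=2)
    rows = []
    for b in niche_levels:
        for x in x_grid:
            pred = params.get("const", 0.0)
            for name, val in extras.items():
                pred += params.get(name, 0.0) * val
            key_x = "w" if x_col == "w" else "z"
            pred += params.get(key_x, 0.0) * x
            pred += params.get("w2", 0.0) * x**2
            pred += params.get("b", 0.0) * b
            pred += params.get(f"{key_x}:b", 0.0) * x * b
            rows.append({"niche_level": round(float(b), 1), x_col: float(x), "predicted": float(pred)})
    return pd.DataFrame(rows)


@dataclass
class SensitivitySpec:
    """Stricter adaptation-category definitions and outlier drops."""

    local_bounds: tuple[float, float] = (0.025, 1.0)
    global_bounds: tuple[float, float] = (-1.0, -0.025)
    local_outliers: tuple[str, ...] = ("Parnassius apollo",)
    global_outliers: tuple[str, ...] = ("Laeosopis roboris", "Cupido osiris")
    min_species: int = 2


def sensitivity_suite(
    growth_data: pd.DataFrame,
    trend_data: pd.DataFrame | None,
    dla: pd.Series,
    category: str,
    spec: SensitivitySpec = SensitivitySpec(),
) -> pd.DataFrame:
    """Refit the headline models under each restriction of the species set.

    Restrictions per category: the full category (dla > 0 for local,
    dla < 0 for global) and the conservative one (dla inside the stricter
    bounds, named outliers removed).  Under-sized restrictions are reported
    as skipped, never fatal.  Returns one row per restriction x model with
    the key coefficient signs.
    """
    if category == "local":
        bounds, outliers = spec.local_bounds, spec.local_outliers
        full = dla[dla > 0]
    elif category == "global":
        bounds, outliers = spec.global_bounds, spec.global_outliers
        full = dla[dla < 0]
    else:
        raise ValueError("category must be 'local' or 'global'")
    strict = full[(full >= bounds[0]) & (full <= bounds[1])]
    strict = strict[~strict.index.isin(outliers)]
    restrictions = {"full": set(full.index), "conservative": set(strict.index)}

    rows = []
    for name, species in restrictions.items():
        for model_name, table in (("growth", growth_data), ("trend", trend_data)):
            if table is None:
                continue
            sub = table[table["species_id"].isin(species)]
            n_sp = sub["species_id"].nunique()
            row = {"restriction": name, "model": model_name, "n_species": n_sp}
            if n_sp < spec.min_species:
                row["status"] = f"skipped: {n_sp} species < {spec.min_species}"
                rows.append(row)
                continue
            try:
                if model_name == "growth":
                    res = GrowthNicheModel(sub, category=category).fit()
                    row.update(
                        status="fit",
                        aic=res.aic,
                        w2_sign=float(np.sign(res.params.get("w2", np.nan))),
                        wb_sign=float(np.sign(res.params.get("w:b", np.nan))),
                    )
                else:
                    res = AbundanceTrendModel(sub, category=category).fit()
                    row.update(
                        status="fit",
                        aic=res.aic,
                        zb_sign=float(np.sign(res.params.get("z:b", np.nan))),
                    )
            except FitConvergenceError as err:
                row["status"] = f"failed: {err}"
            rows.append(row)
    return pd.DataFrame(rows)


def plot_predictions(grid: pd.DataFrame, x_col: str = "w", ax=None, cmap: str = "coolwarm"):
    """Prediction lines over the niche gradient, one line per niche level
    (leading margin cool colours, trailing margin warm)."""
    import matplotlib.pyplot as plt
    from matplotlib import cm

    if ax is None:
        _, ax = plt.subplots()
    levels = sorted(grid["niche_level"].unique())
    colors = cm.get_cmap(cmap)(np.linspace(0, 1, len(levels)))
    for lev, col in zip(levels, colors):
        sub = grid[grid["niche_level"] == lev].sort_values(x_col)
        ax.plot(sub[x_col], sub["predicted"], color=col, lw=1.2)
    ax.set_xlabel("standardized climatic anomaly" if x_col == "w" else "cumulative years")
    ax.set_ylabel("predicted response")
    return ax
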