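"""Thin wrapper over statsmodels OLS / MixedLM with Nakagawa R-squared.

All growth and trend models in this package are Gaussian linear models with
at most crossed random intercepts (species, site) and one random slope
(cumulative years within species).  This module gives them a single fitting
surface that returns fixed effects, Wald tests, an ML-comparable AIC, and the
variance partition needed for marginal / conditional R-squared:

    R2_marginal    = var_fixed / (var_fixed + var_random + var_residual)
    R2_conditional = (var_fixed + var_random) / (var_fixed + var_random + var_residual)

where ``var_fixed`` is the population variance of the fixed-effect linear
predictor, ``var_random`` the summed random-effect variances and
``var_residual`` the residual variance.  For an ordinary regression this
reduces exactly to the classical R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
import statsmodels.api as sm


class FitConvergenceError(RuntimeError):
    """Raised when a mixed fit fails to produce usable estimates."""


@dataclass
class LinearMixedFit:
    """Unified result of an OLS or mixed fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    n_obs: int
    var_fixed: float
    var_random: float
    var_resid: float
    converged: bool
    method: str                      # "ols" | "mixed"
    random_variances: dict[str, float]
    exog_names: tuple[str, ...]

    @property
    def r2_marginal(self) -> float:
        return r2_nakagawa(self.var_fixed, self.var_random, self.var_resid)[0]

    @property
    def r2_conditional(self) -> float:
        return r2_nakagawa(self.var_fixed, self.var_random, self.var_resid)[1]


def r2_nakagawa(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Marginal and conditional R-squared from a variance partition."""
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("zero total variance: R-squared undefined")
    return var_fixed / total, (var_fixed + var_random) / total


def _dummies(codes: pd.Series) -> tuple[np.ndarray, list[str]]:
    d = pd.get_dummies(codes.astype("category"), dtype=float)
    return d.to_numpy(), [str(c) for c in d.columns]


def fit_linear_model(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: pd.Series | None = None,
    vc: dict[str, pd.DataFrame] | None = None,
    reml: bool = False,
) -> LinearMixedFit:
    """Fit a Gaussian linear (mixed) model.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (including the constant).
    groups
        Optional grouping factor for a single random intercept.
    vc
        Optional variance-component designs, ``{name: design DataFrame}``;
        used for crossed random effects (one overall group).  Ignores
        ``groups`` when given.
    reml
        REML for final variance components; ML (default) whenever AICs are
        compared across fixed-effect structures.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    exog_names = tuple(X.columns)
    Xv = X.to_numpy(dtype=float)

    if groups is None and vc is None:
        res = sm.OLS(y, Xv).fit()
        params = pd.Series(res.params, index=exog_names)
        fitted = Xv @ res.params
        return LinearMixedFit(
            params=params,
            bse=pd.Series(res.bse, index=exog_names),
            pvalues=pd.Series(res.pvalues, index=exog_names),
            llf=float(res.llf),
            aic=float(res.aic),
            n_obs=n,
            var_fixed=float(np.var(fitted)),
            var_random=0.0,
            var_resid=float(res.ssr / n),
            converged=True,
            method="ols",
            random_variances={},
            exog_names=exog_names,
        )

    if vc is not None:
        names = list(vc)
        colnames = [[list(vc[nm].columns)] for nm in names]
        mats = [[vc[nm].to_numpy(dtype=float)] for nm in names]
        spec = VCSpec(names, colnames, mats)
        model = MixedLM(y, Xv, groups=np.zeros(n, dtype=int), exog_vc=spec)
    else:
        model = MixedLM(y, Xv, groups=np.asarray(groups))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
            bse_fe = np.asarray(res.bse_fe, dtype=float)
        except (np.linalg.LinAlgError, ValueError) as err:
            raise FitConvergenceError(str(err)) from err
    fe = np.asarray(res.fe_params, dtype=float)
    if not np.all(np.isfinite(fe)):
        raise FitConvergenceError("non-finite fixed effects")

    if vc is not None:
        rand_vars = {nm: float(v) for nm, v in zip(names, np.atleast_1d(res.vcomp))}
        k_var = len(names) + 1
    else:
        rand_vars = {"group": float(np.asarray(res.cov_re)[0, 0])}
        k_var = 1 + 1
    var_random = float(sum(rand_vars.values()))
    fitted = Xv @ fe
    llf = float(res.llf)
    aic = -2.0 * llf + 2.0 * (len(fe) + k_var)
    idx = list(exog_names)
    return LinearMixedFit(
        params=pd.Series(fe, index=idx),
        bse=pd.Series(bse_fe, index=idx),
        pvalues=pd.Series(
            2.0 * (1.0 - _norm_cdf(np.abs(fe / bse_fe))), index=idx
        ),
        llf=llf,
        aic=float(aic),
        n_obs=n,
        var_fixed=float(np.var(fitted)),
        var_random=var_random,
        var_resid=float(res.scale),
        converged=bool(res.converged),
        method="mixed",
        random_variances=rand_vars,
        exog_names=exog_names,
    )


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.cdf(z)
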