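import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichegrowth import response as rp
from nichegrowth._lmm import fit_linear_model


class TestZeroSafeTransform:
    def test_zero_maps_to_zero(self):
        assert rp.zero_safe_log(0.0) == 0.0

    def test_close_to_log_2n_for_moderate_n(self):
        for n in (5.0, 10.0, 100.0):
            assert abs(rp.zero_safe_log(n) - np.log(2 * n)) / np.log(2 * n) < 0.005

    @given(st.floats(0.0, 1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, n):
        assert rp.zero_safe_log_inverse(rp.zero_safe_log(n)) == pytest.approx(n, abs=1e-9, rel=1e-9)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 50, 500)
        assert np.all(np.diff(rp.zero_safe_log(grid)) > 0)


def growth_panel(rng, n_species=4, n_sites=8, n_years=12, coefs=None, noise=0.25):
    """Species x site x year panel from the anomaly x niche growth equation."""
    c = {"const": 0.1, "log_n_lag": -0.3, "w": 0.2, "w2": -0.2, "b": 0.0, "w:b": -0.1}
    if coefs:
        c.update(coefs)
    rows = []
    for j in range(n_species):
        b_sites = np.linspace(-1, 1, n_sites)
        for i in range(n_sites):
            w_series = rng.normal(size=n_years)
            log_n = 1.5
            for t in range(n_years):
                w, b = w_series[t], b_sites[i]
                r = (c["const"] + c["log_n_lag"] * log_n + c["w"] * w + c["w2"] * w**2
                     + c["b"] * b + c["w:b"] * w * b + rng.normal(0, noise))
                rows.append((f"sp{j}", f"s{i}", 2000 + t, r, log_n, w, b))
                log_n = np.clip(log_n + r, -2, 6)
    return pd.DataFrame(
        rows, columns=["species_id", "site_id", "year", "r", "log_n_lag", "w", "b"]
    )


class TestGrowthNicheModel:
    def test_recovers_generating_coefficients(self, rng):
        panel = growth_panel(rng, n_species=6, n_sites=10, n_years=15, noise=0.15)
        res = rp.GrowthNicheModel(panel, category="test").fit()
        assert res.params["w2"] == pytest.approx(-0.2, abs=0.05)
        assert res.params["w:b"] == pytest.approx(-0.1, abs=0.05)
        assert res.n_species == 6 and res.n_sites == 10

    def test_summary_mentions_key_terms(self, rng):
        res = rp.GrowthNicheModel(growth_panel(rng), category="local").fit()
        text = res.summary()
        for token in ("w:b", "w2", "R2_m", "random", "residual variance"):
            assert token in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            rp.GrowthNicheModel(pd.DataFrame({"r": [1.0]}))

    def test_anomaly_centring_equivariance(self, rng):
        # shifting all anomalies by a constant changes the intercept and
        # linear term but never the quadratic coefficient (exact for OLS)
        panel = growth_panel(rng, n_species=1, n_sites=6, n_years=20)
        for shift in (0.7, -1.3):
            X0 = pd.DataFrame({"const": 1.0, "log_n_lag": panel["log_n_lag"],
                               "w": panel["w"], "w2": panel["w"] ** 2})
            X1 = pd.DataFrame({"const": 1.0, "log_n_lag": panel["log_n_lag"],
                               "w": panel["w"] + shift, "w2": (panel["w"] + shift) ** 2})
            f0 = fit_linear_model(panel["r"].to_numpy(), X0)
            f1 = fit_linear_model(panel["r"].to_numpy(), X1)
            assert f1.params["w2"] == pytest.approx(f0.params["w2"], abs=1e-9)


class TestModelReduction:
    def test_ledger_has_four_candidates(self, rng):
        red = rp.GrowthNicheModel(growth_panel(rng)).model_reduction()
        assert len(red.ledger) == 4
        assert red.ledger["aic"].notna().all()

    def test_no_interaction_data_selects_additive(self, rng):
        picks = []
        for k in range(8):
            local_rng = np.random.default_rng(100 + k)
            panel = growth_panel(local_rng, n_species=5, n_sites=8, n_years=14,
                                 coefs={"w:b": 0.0}, noise=0.2)
            red = rp.GrowthNicheModel(panel).model_reduction()
            picks.append("additive" in red.best_label)
        assert np.mean(picks) >= 0.8

    def test_pure_linear_data_selects_linear(self, rng):
        panel = growth_panel(rng, n_species=5, n_sites=8, n_years=14,
                             coefs={"w2": 0.0, "w:b": -0.2}, noise=0.2)
        red = rp.GrowthNicheModel(panel).model_reduction()
        assert "linear" in red.best_label


def _manual_results(params: dict, data: pd.DataFrame):
    from nichegrowth._lmm import LinearMixedFit

    fit = LinearMixedFit(
        params=pd.Series(params), bse=pd.Series(params) * 0, pvalues=pd.Series(params) * 0,
        llf=0.0, aic=0.0, n_obs=len(data), var_fixed=1.0, var_random=0.0, var_resid=1.0,
        converged=True, method="ols", random_variances={}, exog_names=tuple(params),
    )
    return rp.MixedModelResults(fit=fit, model=None, terms=tuple(params))


class TestPredictionGrid:
    def test_exactly_21_niche_levels(self, rng):
        model = rp.GrowthNicheModel(growth_panel(rng))
        res = model.fit()
        grid = model.predict_grid(res)
        assert grid["niche_level"].nunique() == 21
        assert grid["niche_level"].min() == -1.0 and grid["niche_level"].max() == 1.0

    def test_pure_quadratic_symmetry(self, rng):
        panel = growth_panel(rng, n_species=1, n_sites=4, n_years=10)
        model = rp.GrowthNicheModel(panel)
        res = _manual_results(
            {"const": 0.0, "log_n_lag": 0.0, "w": 0.0, "w2": -1.0, "b": 0.0, "w:b": 0.0},
            panel,
        )
        grid = model.predict_grid(res, x_grid=np.linspace(-2, 2, 41))
        sub = grid[grid["niche_level"] == 0.0].sort_values("w")
        preds = sub["predicted"].to_numpy()
        assert np.allclose(preds, preds[::-1], atol=1e-9)

    def test_zero_interaction_b_zero_matches_b_free(self, rng):
        panel = growth_panel(rng, n_species=1, n_sites=4, n_years=10)
        model = rp.GrowthNicheModel(panel)
        with_b = _manual_results(
            {"const": 0.2, "log_n_lag": 0.0, "w": 0.3, "w2": -0.5, "b": 0.4, "w:b": 0.0},
            panel,
        )
        no_b = _manual_results(
            {"const": 0.2, "log_n_lag": 0.0, "w": 0.3, "w2": -0.5}, panel
        )
        xg = np.linspace(-1, 1, 11)
        g1 = model.predict_grid(with_b, x_grid=xg)
        g0 = model.predict_grid(no_b, x_grid=xg)
        a = g1[g1["niche_level"] == 0.0].sort_values("w")["predicted"].to_numpy()
        b = g0[g0["niche_level"] == 0.0].sort_values("w")["predicted"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    def test_extrapolation_warns(self, rng):
        panel = growth_panel(rng)
        model = rp.GrowthNicheModel(panel)
        res = model.fit()
        with pytest.warns(UserWarning, match="extrapolation"):
            model.predict_grid(res, x_grid=np.array([panel["w"].max() + 10]))


def trend_panel(rng, slope_by_b=-0.08, n_species=4, n_sites=8, n_years=12):
    rows = []
    for j in range(n_species):
        b_sites = np.linspace(-1, 1, n_sites)
        for i in range(n_sites):
            log_n0 = rng.normal(2.5, 0.3)
            slope = slope_by_b * (1.0 + b_sites[i]) / 2.0
            for t in range(n_years):
                n = np.exp(log_n0 + slope * t + rng.normal(0, 0.2))
                rows.append((f"sp{j}", f"s{i}", 2000 + t, n, b_sites[i]))
    return pd.DataFrame(rows, columns=["species_id", "site_id", "year", "n_index", "b"])


class TestAbundanceTrendModel:
    def test_cumulative_years_start_at_one(self, rng):
        panel = trend_panel(rng)
        model = rp.AbundanceTrendModel(panel)
        assert model.data["z"].min() == 1
        assert model.data.groupby("species_id")["z"].max().eq(12).all()

    def test_margin_dependent_decline_recovered(self, rng):
        res = rp.AbundanceTrendModel(trend_panel(rng), category="global").fit()
        assert res.params["z:b"] < 0

    def test_negative_index_rejected(self):
        panel = pd.DataFrame(
            {"species_id": ["a"], "site_id": ["s"], "year": [2000], "n_index": [-1.0], "b": [0.0]}
        )
        with pytest.raises(ValueError, match="non-negative"):
            rp.AbundanceTrendModel(panel)

    def test_reduction_ledger_two_candidates(self, rng):
        red = rp.AbundanceTrendModel(trend_panel(rng)).model_reduction()
        assert len(red.ledger) == 2


class TestSensitivitySuite:
    def _dla(self):
        return pd.Series(
            {"sp0": 0.30, "sp1": 0.05, "sp2": 0.01, "sp3": 0.10},
            name="dla",
        )

    def test_dropping_absent_species_is_noop(self, rng):
        panel = growth_panel(rng)
        dla = pd.Series({f"sp{j}": 0.1 for j in range(4)})
        spec = rp.SensitivitySpec(local_outliers=("Species absentis",),
                                  local_bounds=(0.0, 1.0))
        out = rp.sensitivity_suite(panel, None, dla, "local", spec)
        fits = out[out["model"] == "growth"]
        assert fits["aic"].nunique() == 1  # full and conservative fits identical

    def test_undersized_restriction_skipped(self, rng):
        panel = growth_panel(rng)
        dla = pd.Series({"sp0": 0.30, "sp1": 0.01, "sp2": 0.01, "sp3": 0.01})
        out = rp.sensitivity_suite(panel, None, dla, "local")
        row = out[(out["restriction"] == "conservative") & (out["model"] == "growth")].iloc[0]
        assert row["status"].startswith("skipped")
        assert "1 species" in row["status"]

    def test_conservative_fit_preserves_signs(self, rng):
        panel = growth_panel(rng, n_species=6, n_sites=10, n_years=14, noise=0.15)
        dla = pd.Series({f"sp{j}": 0.2 for j in range(6)})
        out = rp.sensitivity_suite(panel, None, dla, "local")
        fits = out[out["status"] == "fit"]
        assert (fits["w2_sign"] == -1.0).all()
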