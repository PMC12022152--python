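import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

from nichegrowth import adaptation as ad
from nichegrowth._lmm import fit_linear_model, r2_nakagawa


def window_value_table(site_values: dict, years, variable="temperature",
                       window=("flight", 0), rng=None, sd=1.0):
    """Window summaries with site-specific means and optional interannual noise."""
    rows = []
    for site, base in site_values.items():
        for year in years:
            v = base + (rng.normal(0, sd) if rng is not None else 0.0)
            rows.append((site, year, variable, window[0], window[1], v))
    return pd.DataFrame(
        rows, columns=["site_id", "year", "variable", "window_kind", "year_offset", "value"]
    )


class TestGlobalAnomalies:
    def test_brute_force_species_mean(self, rng):
        vals = window_value_table({"a": 8.0, "b": 10.0, "c": 14.0}, range(2000, 2010), rng=rng)
        out = ad.global_anomalies(vals, ["a", "b", "c"])
        flat_mean = vals["value"].mean()  # brute-force flat average oracle
        assert np.allclose(out["anomaly"], out["value"] - flat_mean, atol=1e-9)

    def test_one_site_species_global_equals_local(self, rng):
        vals = window_value_table({"a": 8.0}, range(2000, 2015), rng=rng)
        glo = ad.global_anomalies(vals, ["a"])
        loc = ad.local_anomalies(vals, ["a"])
        assert np.allclose(
            glo.sort_values("year")["anomaly"], loc.sort_values("year")["anomaly"], atol=1e-9
        )

    def test_site_at_species_mean_matches_local(self, rng):
        vals = window_value_table({"a": 8.0, "b": 12.0}, range(2000, 2010))
        # deterministic values: site means are 8 and 12, species mean 10
        glo = ad.global_anomalies(vals, ["a", "b"])
        loc = ad.local_anomalies(vals, ["a", "b"])
        # add a site exactly at the species mean
        vals3 = pd.concat(
            [vals, window_value_table({"m": 10.0}, range(2000, 2010))], ignore_index=True
        )
        glo3 = ad.global_anomalies(vals3, ["a", "b", "m"])
        loc3 = ad.local_anomalies(vals3, ["a", "b", "m"])
        m_glo = glo3[glo3["site_id"] == "m"]["anomaly"].to_numpy()
        m_loc = loc3[loc3["site_id"] == "m"]["anomaly"].to_numpy()
        assert np.allclose(m_glo, m_loc, atol=1e-9)


def simulated_growth(anoms, coefs=(0.3, -0.4, 0.25, -0.15), noise=0.0, rng=None,
                     species_id="sp"):
    """Growth observations generated exactly from the candidate-model equation."""
    a0, a_dd, a_w, a_w2 = coefs
    rows = []
    state = {}
    for _, row in anoms.sort_values(["site_id", "year"]).iterrows():
        key = row["site_id"]
        log_n = state.get(key, 1.5)
        w = row["anomaly"]
        r = a0 + a_dd * log_n + a_w * w + a_w2 * w**2
        if noise > 0 and rng is not None:
            r += rng.normal(0, noise)
        rows.append((species_id, key, row["year"], r, log_n))
        state[key] = log_n + r
    return pd.DataFrame(rows, columns=["species_id", "site_id", "year", "r", "log_n_lag"])


class TestFitGrowthModel:
    def test_noise_free_coefficient_recovery(self, rng):
        vals = window_value_table(
            {f"s{k}": 8.0 + k for k in range(6)}, range(2000, 2015), rng=rng
        )
        anoms = ad.local_anomalies(vals, vals["site_id"].unique())
        std = ad._standardize(anoms)
        growth = simulated_growth(std.rename(columns={"w": "anomaly_std"})
                                  .assign(anomaly=lambda d: d["anomaly_std"]))
        cand = ad.fit_growth_model(growth, std)
        assert cand.converged and cand.fit.method == "ols"
        assert cand.fit.params["const"] == pytest.approx(0.3, abs=1e-6)
        assert cand.fit.params["log_n_lag"] == pytest.approx(-0.4, abs=1e-6)
        assert cand.fit.params["w"] == pytest.approx(0.25, abs=1e-6)
        assert cand.fit.params["w2"] == pytest.approx(-0.15, abs=1e-6)

    def test_mixed_matches_ols_at_zero_site_variance(self, rng):
        # 12 sites -> random-intercept route; no site effect simulated
        vals = window_value_table(
            {f"s{k:02d}": 8.0 + 0.3 * k for k in range(12)}, range(2000, 2030), rng=rng
        )
        anoms = ad.local_anomalies(vals, vals["site_id"].unique())
        std = ad._standardize(anoms)
        growth = simulated_growth(std.assign(anomaly=std["w"]), noise=0.01, rng=rng)
        mixed = ad.fit_growth_model(growth, std)
        assert mixed.fit.method == "mixed"
        ols = ad.fit_growth_model(growth, std, min_sites_for_re=99)
        diff = (mixed.fit.params - ols.fit.params).abs().max()
        assert diff < 1e-4

    def test_under_ten_sites_no_random_intercept(self, rng):
        vals = window_value_table(
            {f"s{k}": 8.0 + k for k in range(9)}, range(2000, 2010), rng=rng
        )
        std = ad._standardize(ad.local_anomalies(vals, vals["site_id"].unique()))
        growth = simulated_growth(std.assign(anomaly=std["w"]), noise=0.1, rng=rng)
        cand = ad.fit_growth_model(growth, std)
        assert cand.fit.method == "ols"
        assert cand.n_sites == 9


class TestNakagawaR2:
    def test_reduces_to_classical_r2_without_random_effects(self, rng):
        x = rng.normal(size=50)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 50)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_linear_model(y, X)
        import statsmodels.api as sm

        classical = sm.OLS(y, X.to_numpy()).fit().rsquared
        assert fit.r2_marginal == pytest.approx(classical, abs=1e-10)
        assert fit.r2_conditional == pytest.approx(classical, abs=1e-10)

    def test_intercept_only_marginal_zero(self, rng):
        y = rng.normal(size=30)
        fit = fit_linear_model(y, pd.DataFrame({"const": np.ones(30)}))
        assert fit.r2_marginal == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_variance_ratio(self):
        # ten-point fixture, components computed by hand
        var_f, var_r, var_e = 2.0, 1.0, 1.0
        r2m, r2c = r2_nakagawa(var_f, var_r, var_e)
        assert r2m == pytest.approx(0.5)
        assert r2c == pytest.approx(0.75)
        with pytest.raises(ValueError):
            r2_nakagawa(0.0, 0.0, 0.0)


def _candidate(species, scale, variable, kind, offset, aic, r2m=0.2, n_obs=100):
    from nichegrowth._lmm import LinearMixedFit

    var_f = r2m
    fit = LinearMixedFit(
        params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
        pvalues=pd.Series(dtype=float), llf=0.0, aic=aic, n_obs=n_obs,
        var_fixed=var_f, var_random=0.0, var_resid=1.0 - var_f,
        converged=True, method="ols", random_variances={}, exog_names=(),
    )
    return ad.CandidateModel(species, scale, variable, kind, offset, fit, True, n_obs, 8)


class TestSelectionAndDla:
    def test_minimum_aic_wins(self):
        c = [
            _candidate("sp", "local", "temperature", "flight", 0, 100.0),
            _candidate("sp", "local", "precipitation", "overwinter", 0, 95.0),
            _candidate("sp", "local", "aridity", "pre_flight", 1, 102.0),
        ]
        assert ad.select_best_candidate(c).aic == 95.0

    def test_exact_tie_broken_canonically(self):
        c = [
            _candidate("sp", "local", "aridity", "flight", 0, 95.0),
            _candidate("sp", "local", "temperature", "post_flight", 1, 95.0),
            _candidate("sp", "local", "temperature", "overwinter", 0, 95.0),
        ]
        best = ad.select_best_candidate(c)
        assert (best.variable, best.window_kind) == ("temperature", "overwinter")

    def test_no_converged_candidates_raises(self):
        c = [ad.CandidateModel("sp", "local", "temperature", "flight", 0, None, False, 0, 0)]
        with pytest.raises(Exception, match="no converged"):
            ad.select_best_candidate(c)

    def test_dla_definition_and_classification(self):
        res = ad.compute_dla(
            _candidate("sp", "local", "temperature", "flight", 0, 90.0, r2m=0.30),
            _candidate("sp", "global", "temperature", "flight", 0, 95.0, r2m=0.10),
        )
        assert res.dla == pytest.approx(0.20)
        assert res.classification == "local"
        assert -1.0 <= res.dla <= 1.0

    def test_dla_antisymmetry(self):
        loc = _candidate("sp", "local", "temperature", "flight", 0, 90.0, r2m=0.30)
        glo = _candidate("sp", "global", "temperature", "flight", 0, 95.0, r2m=0.10)
        assert ad.compute_dla(loc, glo).dla == pytest.approx(-ad.compute_dla(glo, loc).dla)

    def test_identical_fits_ambiguous(self):
        a = _candidate("sp", "local", "temperature", "flight", 0, 90.0, r2m=0.25)
        b = _candidate("sp", "global", "temperature", "flight", 0, 90.0, r2m=0.25)
        assert ad.compute_dla(a, b).classification == "ambiguous"

    def test_row_mismatch_raises(self):
        a = _candidate("sp", "local", "temperature", "flight", 0, 90.0, n_obs=100)
        b = _candidate("sp", "global", "temperature", "flight", 0, 90.0, n_obs=90)
        with pytest.raises(ValueError, match="different observations"):
            ad.compute_dla(a, b)

    def test_one_site_species_dla_zero(self, rng):
        vals = window_value_table({"a": 8.0}, range(2000, 2030), rng=rng)
        std_l = ad._standardize(ad.local_anomalies(vals, ["a"]))
        growth = simulated_growth(std_l.assign(anomaly=std_l["w"]), noise=0.1, rng=rng)
        model = ad.DegreeOfAdaptationModel(growth, vals, occupancy={"sp": ["a"]})
        res = model.fit()
        assert res.results[0].dla == pytest.approx(0.0, abs=1e-12)


class TestAgainstLme4:
    def test_site_random_intercept_matches_lme4(self, rng, tmp_path):
        """Independent cross-check of the mixed machinery against R's lme4."""
        n_sites, n_years = 12, 25
        rows = []
        for i in range(n_sites):
            site_eff = rng.normal(0, 0.3)
            for t in range(n_years):
                w = rng.normal()
                lag = rng.normal()
                r = 0.2 - 0.3 * lag + 0.25 * w - 0.1 * w**2 + site_eff + rng.normal(0, 0.4)
                rows.append((f"s{i:02d}", t, r, lag, w))
        df = pd.DataFrame(rows, columns=["site_id", "year", "r", "log_n_lag", "w"])
        df["w2"] = df["w"] ** 2
        csv = tmp_path / "panel.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(r ~ log_n_lag + w + w2 + (1 | site_id), data = d, REML = FALSE)
                cat(fixef(m), sep = "\\n")
                """
            )
        )
        try:
            out = subprocess.run(
                ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
            )
        except FileNotFoundError:
            pytest.skip("Rscript unavailable")
        assert out.returncode == 0, out.stderr
        lme4_fe = np.array([float(v) for v in out.stdout.split()])

        X = pd.DataFrame({"const": 1.0, "log_n_lag": df["log_n_lag"],
                          "w": df["w"], "w2": df["w2"]})
        fit = fit_linear_model(df["r"].to_numpy(), X, groups=df["site_id"])
        assert np.allclose(fit.params.to_numpy(), lme4_fe, atol=1e-4)
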