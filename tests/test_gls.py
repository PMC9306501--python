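"""Heterogeneous-CS GLS: oracles, calibration, marginality reduction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ipdflux import design, stats
from ipdflux.gls import ModelSpec, build_design, is_marginality_closed


@pytest.fixture(scope="module")
def surface_rows():
    """Non-drought plots of the default design, one row per plot x season."""
    d = design.sampled_design(seed=0)
    surface = d[~d.drought].reset_index(drop=True)
    rows = surface.loc[surface.index.repeat(3)].reset_index(drop=True)
    rows["season"] = ["May", "Jul", "Oct"] * len(surface)
    return rows


def simulate_response(rows, rng, beta_temp=0.0, beta_season=(0.0, 0.0),
                      tau=1.0, sds=(1.0, 1.0, 1.0)):
    n_plots = rows.plot_id.nunique()
    u = rng.normal(0, tau, n_plots)
    plot_codes = pd.Categorical(rows.plot_id).codes
    season_idx = rows.season.map({"May": 0, "Jul": 1, "Oct": 2}).to_numpy()
    season_fx = np.array([0.0, *beta_season])[season_idx]
    y = (
        beta_temp * rows.temp_level.to_numpy() / 1.5
        + season_fx
        + u[plot_codes]
        + np.array(sds)[season_idx] * rng.standard_normal(len(rows))
    )
    return rows.assign(y=y)


class TestAgainstOLS:
    def test_identity_covariance_reduces_to_ols(self, surface_rows):
        rng = np.random.default_rng(1)
        df = simulate_response(surface_rows, rng, beta_temp=0.8,
                               beta_season=(0.5, -0.4))
        spec = ModelSpec(response="y", terms=("season", "co2", "temp"))
        fit = stats.fit_rs_gls(df, spec, fix_rho=0.0, homoscedastic=True)
        X, names, *_ = build_design(df, spec)
        ols = sm.OLS(df.y.to_numpy(), X).fit()
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ols.params, rtol=1e-8
        )

    def test_ml_loglik_never_decreases_with_added_term(self, surface_rows):
        rng = np.random.default_rng(2)
        df = simulate_response(surface_rows, rng, beta_temp=0.3)
        small = ModelSpec(response="y", terms=("season", "temp"))
        large = ModelSpec(response="y", terms=("season", "temp", "co2"))
        ll_small = stats.fit_rs_gls(df, small, reml=False).loglik
        ll_large = stats.fit_rs_gls(df, large, reml=False).loglik
        assert ll_large >= ll_small - 1e-6


class TestCovarianceStructure:
    def test_recovers_rho_and_heterogeneous_sds(self):
        base = design.sampled_design(seed=0)
        reps = [base.assign(plot_id=base.plot_id + f"_r{k}") for k in range(12)]
        big = pd.concat(reps, ignore_index=True)
        big = big[~big.drought].reset_index(drop=True)
        rows = big.loc[big.index.repeat(3)].reset_index(drop=True)
        rows["season"] = ["May", "Jul", "Oct"] * len(big)
        rng = np.random.default_rng(3)
        df = simulate_response(rows, rng, tau=1.0, sds=(1.0, 2.0, 3.0))
        # marginal per-season sd includes the shared plot effect:
        # sqrt(tau^2 + sd_s^2); rho_s,s' = tau^2/(sd_m sd_m')... CS on the
        # total scale holds only approximately, so check the May/Oct spread
        fit = stats.fit_rs_gls(
            df, ModelSpec(response="y", terms=("season", "temp"))
        )
        assert fit.season_sd["Oct"] > fit.season_sd["Jul"] > fit.season_sd["May"]
        assert fit.season_sd["May"] == pytest.approx(np.sqrt(2.0), rel=0.15)
        assert 0.0 < fit.rho < 1.0

    def test_aliased_design_raises(self, surface_rows):
        rng = np.random.default_rng(4)
        df = simulate_response(surface_rows, rng)
        df["co2_level"] = df["temp_level"] * 100.0  # co2 column == temp column
        with pytest.raises(ValueError, match="singular|aliased"):
            stats.fit_rs_gls(
                df, ModelSpec(response="y", terms=("season", "co2", "temp"))
            )


class TestConfidenceCoverage:
    def test_temp_slope_coverage(self, surface_rows):
        """95% CI coverage of a between-plot slope under CS noise."""
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        beta = 0.7
        hits = 0
        n_rep = 400
        spec = ModelSpec(response="y", terms=("season", "co2", "temp"))
        for _ in range(n_rep):
            df = simulate_response(surface_rows, rng, beta_temp=beta,
                                   sds=(1.5, 1.0, 0.8))
            fit = stats.fit_rs_gls(df, spec)
            est = fit.coefficients["temp"]
            se = np.sqrt(fit.cov_coefficients.loc["temp", "temp"])
            den_df = fit.anova[fit.anova.term == "temp"].den_df.iloc[0]
            tcrit = sps.t.ppf(0.975, den_df)
            if abs(est - beta) <= tcrit * se:
                hits += 1
        assert 0.93 <= hits / n_rep <= 0.97


class TestMarginalityReduction:
    def test_spec_requires_closed_term_set(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(response="y", terms=("season", "season:temp"))
        assert is_marginality_closed(("season", "temp", "season:temp"))

    def test_margin_never_dropped_under_retained_interaction(self, surface_rows):
        rng = np.random.default_rng(6)
        # strong season x temp interaction, weak temp main effect
        df = surface_rows.copy()
        season_idx = df.season.map({"May": 0, "Jul": 1, "Oct": 2}).to_numpy()
        inter = (season_idx == 2) * df.temp_level.to_numpy()
        df["y"] = inter * 2.0 + rng.standard_normal(len(df))
        fit = stats.reduce_by_marginality(
            df, ModelSpec(response="y", terms=("season", "temp", "season:temp"))
        )
        assert "season:temp" in fit.terms
        assert {"season", "temp"} <= set(fit.terms)
        dropped = {t["term"] for t in fit.reduction_trail}
        assert not dropped & set(fit.terms)

    def test_season_only_signal_reduces_to_season(self, surface_rows):
        """Backward elimination keeps the real effect and sheds null terms.

        With three null candidate terms tested at alpha = 0.05 the chance of
        ending at exactly {season} is about 0.95**3 = 0.857; the observed
        rate must sit in the binomial band around that, and season itself
        must never be dropped.
        """
        rng = np.random.default_rng(7)
        n_exact = 0
        n_rep = 200
        spec = ModelSpec(
            response="y", terms=("season", "co2", "temp", "season:temp")
        )
        for _ in range(n_rep):
            df = simulate_response(surface_rows, rng, beta_season=(2.0, -1.5))
            fit = stats.reduce_by_marginality(df, spec)
            assert "season" in fit.terms
            if set(fit.terms) == {"season"}:
                n_exact += 1
        assert 0.78 <= n_exact / n_rep <= 0.93
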