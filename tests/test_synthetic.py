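"""Synthetic dataset generator: calibration, reproducibility, round trips."""

import numpy as np
import pandas as pd
import pytest

from ipdflux import design, ipd, synthetic
from ipdflux.synthetic import CovariateSpec, EffectConfig


def noise_free_config() -> EffectConfig:
    return EffectConfig(
        faa_pool_cv={"May": 0.0, "Jul": 0.0, "Oct": 0.0},
        inorganic_pool_cv=0.0,
        rate_sd_plot=0.0,
        rate_sd_within=0.0,
        consumption_extra_sd=0.0,
        conc_noise_cv=0.0,
        atom_noise_cv=0.0,
    )


class TestGenerateTruth:
    def test_seed_reproducibility_bytewise(self, sampled_design_df):
        a = synthetic.generate_truth(sampled_design_df, seed=5).frame
        b = synthetic.generate_truth(sampled_design_df, seed=5).frame
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = synthetic.generate_truth(sampled_design_df, seed=6).frame
        assert a.to_csv(index=False) != c.to_csv(index=False)

    def test_zero_noise_hits_configured_means(self, sampled_design_df):
        cfg = noise_free_config()
        truth = synthetic.generate_truth(sampled_design_df, cfg, seed=0).frame
        ambient = truth[
            (truth.temp_level == 0) & (truth.co2_level == 0) & ~truth.drought
        ]
        for season, base in cfg.depolymerization_base.items():
            sub = ambient[ambient.season == season]
            np.testing.assert_allclose(sub.depolymerization, base)
            np.testing.assert_allclose(sub.faa_pool, cfg.faa_pool_means[season])
        warmed = truth[
            (truth.temp_level == 3.0) & (truth.co2_level == 150.0)
        ]
        for season, mult in cfg.warming_mult_3C.items():
            sub = warmed[warmed.season == season]
            np.testing.assert_allclose(
                sub.depolymerization, cfg.depolymerization_base[season] * mult
            )

    def test_drought_multiplier_applied_in_july_only(self, sampled_design_df):
        cfg = noise_free_config()
        truth = synthetic.generate_truth(sampled_design_df, cfg, seed=0).frame
        dr = truth[truth.drought & (truth.temp_level == 0)]
        jul = dr[dr.season == "Jul"]
        may = dr[dr.season == "May"]
        np.testing.assert_allclose(
            jul.depolymerization,
            cfg.depolymerization_base["Jul"] * cfg.drought_mult["ambient"],
        )
        np.testing.assert_allclose(
            may.depolymerization, cfg.depolymerization_base["May"]
        )

    def test_depolymerization_dominates_inorganic_rates(self, sampled_design_df):
        """Organic-N influx exceeds mineralization/nitrification 10-30-fold."""
        truth = synthetic.generate_truth(sampled_design_df, seed=2).frame
        surface = truth[~truth.drought]
        by_season = surface.groupby("season")
        fold_min = (
            by_season.depolymerization.mean() / by_season.gross_mineralization.mean()
        )
        fold_nit = (
            by_season.depolymerization.mean() / by_season.gross_nitrification.mean()
        )
        assert fold_min.between(10, 30).all()
        assert fold_nit.between(10, 30).all()

    def test_large_sample_may_faa_mean(self):
        """Law-of-large-numbers check of the spring pool calibration."""
        base = design.sampled_design(seed=0)
        reps = [
            base.assign(plot_id=base.plot_id + f"_r{k}") for k in range(295)
        ]
        big = pd.concat(reps, ignore_index=True)  # ~10^4 plots
        truth = synthetic.generate_truth(big, seed=9).frame
        may = truth[truth.season == "May"]
        ambient_pool = may[~may.drought].faa_pool.mean()
        assert ambient_pool == pytest.approx(7.9, rel=0.01)


class TestSimulateMeasurements:
    def test_zero_noise_round_trip(self, sampled_design_df):
        cfg = EffectConfig(conc_noise_cv=0.0, atom_noise_cv=0.0)
        truth = synthetic.generate_truth(sampled_design_df, cfg, seed=4)
        bundle = synthetic.simulate_measurements(truth)
        rates = ipd.estimate_rates_table(
            bundle["ipd_raw"], background_atom_pct=cfg.background_atom_pct
        )
        merged = rates[rates.pool_id == "FAA"].merge(
            truth.frame, on=["plot_id", "season"]
        )
        np.testing.assert_allclose(
            merged.gross_influx, merged.depolymerization, rtol=1e-9
        )
        np.testing.assert_allclose(
            merged.gross_efflux, merged.aa_consumption, rtol=1e-9
        )

    def test_same_seed_identical_csv_bytes(self, sampled_design_df):
        t = synthetic.generate_truth(sampled_design_df, seed=8)
        a = synthetic.simulate_measurements(t)["ipd_raw"].to_csv(index=False)
        b = synthetic.simulate_measurements(t)["ipd_raw"].to_csv(index=False)
        assert a == b

    def test_long_format_schema(self, default_bundle):
        raw = default_bundle["ipd_raw"]
        assert list(raw.columns) == ipd.MEASUREMENT_COLUMNS
        # two timepoints per plot x season x pool
        sizes = raw.groupby(["plot_id", "season", "pool_id"]).size()
        assert (sizes == 2).all()


class TestCovariateStructure:
    def test_within_plot_correlation_targets(self):
        """Generated covariates hit the configured repeated-measures
        correlations with log depolymerization (large design)."""
        from ipdflux import stats

        base = design.sampled_design(seed=0)
        reps = [base.assign(plot_id=base.plot_id + f"_r{k}") for k in range(8)]
        big = pd.concat(reps, ignore_index=True)
        frame = synthetic.generate_truth(big, seed=3).frame
        frame["log_dep"] = np.log(frame.depolymerization)
        surface = frame[~frame.drought].assign(
            log_cov=lambda d: np.log(d.anpp)
        )
        r_anpp = stats.rmcorr(
            surface, "plot_id", "log_cov", "log_dep", n_boot=0
        ).r
        assert r_anpp == pytest.approx(0.576, abs=0.08)
        full = frame.assign(log_cov=np.log(frame.swc))
        r_swc = stats.rmcorr(full, "plot_id", "log_cov", "log_dep", n_boot=0).r
        assert r_swc == pytest.approx(-0.710, abs=0.08)


class TestBundleIO:
    def test_write_read_identity(self, default_bundle, tmp_path):
        synthetic.write_dataset(default_bundle, tmp_path)
        back = synthetic.read_dataset(tmp_path)
        for name in ("ipd_raw", "native_pools", "covariates", "truth"):
            pd.testing.assert_frame_equal(
                back[name].reset_index(drop=True),
                pd.read_csv(tmp_path / f"{name}.csv"),
            )
        assert isinstance(back["config"], EffectConfig)
        assert back["config"].to_dict() == default_bundle["config"].to_dict()

    def test_missing_column_schema_error(self, tmp_path):
        pd.DataFrame({"plot_id": ["P01"]}).to_csv(
            tmp_path / "ipd_raw.csv", index=False
        )
        with pytest.raises(ValueError, match="missing required columns"):
            synthetic.read_dataset(tmp_path)

    def test_extra_columns_preserved(self, default_bundle, tmp_path):
        bundle = dict(default_bundle)
        raw = bundle["ipd_raw"].copy()
        raw["operator"] = "lab-a"
        bundle["ipd_raw"] = raw
        synthetic.write_dataset(bundle, tmp_path)
        back = synthetic.read_dataset(tmp_path)
        assert "operator" in back["ipd_raw"].columns


def test_covariate_spec_round_trip():
    cfg = EffectConfig(
        covariates={"anpp": CovariateSpec(mean=450.0, rho=0.5)}
    )
    again = EffectConfig.from_dict(cfg.to_dict())
    assert again.covariates["anpp"] == cfg.covariates["anpp"]
    assert again.faa_times_min == cfg.faa_times_min
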