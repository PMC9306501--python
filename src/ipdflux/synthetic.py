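"""Synthetic study datasets: true fluxes, covariates, and noisy measurements.

The generator emulates a three-season (May/Jul/Oct) sampling campaign on the
response-surface grassland design: plot-level true gross rates for the three
N pools, seasonal pool sizes, treatment effect structure (season-dependent
warming effect on organic-N rates, a small CO2 effect on amino-acid
consumption, drought doubling of organic-N rates at peak drought with full
recovery), latent covariates with configured within-plot correlations to
log depolymerization, and finally raw two-timepoint IPD measurement tables
produced by the exact forward model plus measurement noise.

Default effect sizes are calibrated to the study system: seasonal free
amino acid pool means 7.9/4.1/3.7 µg N g⁻¹ dm, +3 °C warming multipliers on
depolymerization 0.74/1.00/1.55 by season, drought multipliers 2.27
(ambient) and 2.34 (future scenario), a 10–30-fold excess of
depolymerization over mineralization and nitrification, and May amino-acid
residence times inside 1.04–2.52 h.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ipd
from .design import SEASONS

POOLS = ("FAA", "NH4", "NO3")

TRUTH_RATE_COLUMNS = {
    "FAA": ("faa_pool", "depolymerization", "aa_consumption"),
    "NH4": ("nh4_pool", "gross_mineralization", "nh4_consumption"),
    "NO3": ("no3_pool", "gross_nitrification", "no3_consumption"),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class CovariateSpec:
    """Latent covariate: lognormal around ``mean`` with a target within-plot
    correlation ``rho`` to log depolymerization (on log scales)."""

    mean: float
    rho: float
    between_sd: float = 0.20  # lognormal sd of the plot intercept
    within_sd: float = 0.25   # lognormal sd of the plot x season deviation


def default_covariates() -> dict[str, CovariateSpec]:
    # rho targets follow the repeated-measures correlation structure of the
    # study system (plant descriptors positive, SWC/total N/PLFA negative).
    return {
        "anpp": CovariateSpec(mean=450.0, rho=0.576),
        "root_biomass": CovariateSpec(mean=800.0, rho=0.463),
        "root_turnover": CovariateSpec(mean=1.5, rho=0.454),
        "total_soil_N": CovariateSpec(mean=4.5, rho=-0.395),
        "swc": CovariateSpec(mean=0.28, rho=-0.710),
        "don": CovariateSpec(mean=20.0, rho=0.443),
        "microbial_C": CovariateSpec(mean=900.0, rho=0.30),
        "microbial_N": CovariateSpec(mean=120.0, rho=0.479),
        "microbial_turnover": CovariateSpec(mean=80.0, rho=-0.443),
        "plfa_gram_pos": CovariateSpec(mean=30.0, rho=-0.372),
        "plfa_gram_neg": CovariateSpec(mean=35.0, rho=-0.454),
        "enzyme_LAP": CovariateSpec(mean=50.0, rho=0.25),
        "enzyme_TAP": CovariateSpec(mean=20.0, rho=0.25),
        "delta15N_root": CovariateSpec(mean=2.0, rho=-0.30),
    }


@dataclass
class EffectConfig:
    """Study-condition parameters of the generator (units in field names)."""

    # seasonal pool means, µg N g⁻¹ dm
    faa_pool_means: dict[str, float] = field(
        default_factory=lambda: {"May": 7.9, "Jul": 4.1, "Oct": 3.7}
    )
    faa_pool_cv: dict[str, float] = field(
        default_factory=lambda: {
            "May": 1.3 / 7.9, "Jul": 0.4 / 4.1, "Oct": 0.5 / 3.7
        }
    )
    nh4_pool_means: dict[str, float] = field(
        default_factory=lambda: {"May": 2.5, "Jul": 2.0, "Oct": 1.8}
    )
    no3_pool_means: dict[str, float] = field(
        default_factory=lambda: {"May": 4.0, "Jul": 5.0, "Oct": 6.0}
    )
    inorganic_pool_cv: float = 0.20

    # ambient-condition gross influx bases, µg N g⁻¹ dm d⁻¹
    depolymerization_base: dict[str, float] = field(
        default_factory=lambda: {"May": 110.0, "Jul": 55.0, "Oct": 45.0}
    )
    mineralization_base: float = 4.0  # season-invariant
    nitrification_base: dict[str, float] = field(
        default_factory=lambda: {"May": 3.7, "Jul": 4.2, "Oct": 4.5}
    )

    # treatment effect multipliers
    warming_mult_3C: dict[str, float] = field(
        default_factory=lambda: {"May": 0.74, "Jul": 1.00, "Oct": 1.55}
    )
    consumption_ratio: float = 0.95  # GE/GI for the FAA pool
    consumption_co2_mult_300: float = 1.025
    mineralization_temp_mult_3C: float = 0.85  # at ambient CO2; -> 1 at +300
    nh4_consumption_ratio: float = 0.97
    no3_consumption_ratio: float = 0.90
    drought_mult: dict[str, float] = field(
        default_factory=lambda: {"ambient": 2.27, "future": 2.34}
    )
    nitrification_drought_mult: float = 2.0
    faa_pool_drought_mult: float = 1.15
    faa_pool_recovery_mult: float = 0.85

    # biological variability (lognormal sds on the log scale)
    rate_sd_plot: float = 0.12
    rate_sd_within: float = 0.15
    consumption_extra_sd: float = 0.08

    # measurement noise
    conc_noise_cv: float = 0.05
    atom_noise_cv: float = 0.02

    # tracer protocol
    tracer_target_fraction: float = 0.20
    tracer_enrichment: float = 97.0
    background_atom_pct: float = ipd.ATMOSPHERIC_N2_ATOM_PCT
    faa_times_min: tuple[float, float] = (15.0, 60.0)
    inorganic_times_min: tuple[float, float] = (240.0, 1440.0)

    covariates: dict[str, CovariateSpec] = field(
        default_factory=default_covariates
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["faa_times_min"] = list(self.faa_times_min)
        d["inorganic_times_min"] = list(self.inorganic_times_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = {
                k: CovariateSpec(**v) if isinstance(v, dict) else v
                for k, v in d["covariates"].items()
            }
        for key in ("faa_times_min", "inorganic_times_min"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """True plot × season fluxes, pools, and covariates plus provenance."""

    frame: pd.DataFrame
    config: EffectConfig
    seed: int


def _lognormal_factor(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise (exactly 1 when sd=0)."""
    if sd == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(sd * rng.standard_normal(size) - 0.5 * sd * sd)


def _cv_to_sd(cv: float) -> float:
    """Lognormal log-sd giving a coefficient of variation of ``cv``."""
    return float(np.sqrt(np.log1p(cv * cv)))


def _drought_scenario(temp: float, co2: float) -> str:
    return "future" if (temp, co2) == (3.0, 300.0) else "ambient"


def generate_truth(
    design: pd.DataFrame, config: EffectConfig | None = None, seed: int = 0
) -> SyntheticTruth:
    """Draw true rates, pools, and covariates for every sampled plot × season.

    Rates are lognormal around season × treatment means: the +3 °C warming
    multiplier is applied with exponent temp/3 (geometric interpolation over
    the three levels), the CO2 multiplier analogously with exponent co2/300,
    and drought multiplies organic-N rates (and nitrification) at the July
    peak-drought sampling only.  Covariates are drawn conditionally on the
    standardized within-plot deviation of log depolymerization so that
    repeated-measures correlations match the configured targets.
    """
    cfg = config or EffectConfig()
    if "sampled" in design.columns:
        plots = design[design["sampled"].astype(bool)]
    else:
        plots = design
    plots = plots.reset_index(drop=True)
    n_plots = len(plots)
    seasons = list(SEASONS)
    n = n_plots * len(seasons)

    rng_rates = substream(seed, "truth/rates")
    rng_pools = substream(seed, "truth/pools")
    rng_cov = substream(seed, "truth/covariates")

    # plot-level intercepts per pool family
    u = {
        pool: (
            cfg.rate_sd_plot * rng_rates.standard_normal(n_plots)
            - 0.5 * cfg.rate_sd_plot**2
            if cfg.rate_sd_plot > 0
            else np.zeros(n_plots)
        )
        for pool in POOLS
    }

    rows = []
    for i, plot in plots.iterrows():
        t, c = float(plot.temp_level), float(plot.co2_level)
        scenario = _drought_scenario(t, c)
        for s in seasons:
            warm = cfg.warming_mult_3C[s] ** (t / 3.0)
            drought_on = bool(plot.drought) and s == "Jul"

            depoly_mean = cfg.depolymerization_base[s] * warm
            if drought_on:
                depoly_mean *= cfg.drought_mult[scenario]
            e = _lognormal_factor(rng_rates, cfg.rate_sd_within, None)
            depoly = depoly_mean * np.exp(u["FAA"][i]) * e
            cons = (
                depoly
                * cfg.consumption_ratio
                * cfg.consumption_co2_mult_300 ** (c / 300.0)
                * _lognormal_factor(rng_rates, cfg.consumption_extra_sd, None)
            )

            min_mult = cfg.mineralization_temp_mult_3C ** (
                (t / 3.0) * (1.0 - c / 300.0)
            )
            mineral = (
                cfg.mineralization_base
                * min_mult
                * np.exp(u["NH4"][i])
                * _lognormal_factor(rng_rates, cfg.rate_sd_within, None)
            )
            nh4_cons = mineral * cfg.nh4_consumption_ratio

            nitrif_mean = cfg.nitrification_base[s]
            if drought_on:
                nitrif_mean *= cfg.nitrification_drought_mult
            nitrif = (
                nitrif_mean
                * np.exp(u["NO3"][i])
                * _lognormal_factor(rng_rates, cfg.rate_sd_within, None)
            )
            no3_cons = nitrif * cfg.no3_consumption_ratio

            faa_mean = cfg.faa_pool_means[s]
            if bool(plot.drought):
                if s == "Jul":
                    faa_mean *= cfg.faa_pool_drought_mult
                elif s == "Oct":
                    faa_mean *= cfg.faa_pool_recovery_mult
            faa_pool = faa_mean * _lognormal_factor(
                rng_pools, _cv_to_sd(cfg.faa_pool_cv[s]), None
            )
            nh4_pool = cfg.nh4_pool_means[s] * _lognormal_factor(
                rng_pools, _cv_to_sd(cfg.inorganic_pool_cv), None
            )
            no3_pool = cfg.no3_pool_means[s] * _lognormal_factor(
                rng_pools, _cv_to_sd(cfg.inorganic_pool_cv), None
            )

            rows.append(
                {
                    "plot_id": plot.plot_id,
                    "temp_level": t,
                    "co2_level": c,
                    "drought": bool(plot.drought),
                    "season": s,
                    "faa_pool": float(faa_pool),
                    "depolymerization": float(depoly),
                    "aa_consumption": float(cons),
                    "nh4_pool": float(nh4_pool),
                    "gross_mineralization": float(mineral),
                    "nh4_consumption": float(nh4_cons),
                    "no3_pool": float(no3_pool),
                    "gross_nitrification": float(nitrif),
                    "no3_consumption": float(no3_cons),
                }
            )
    frame = pd.DataFrame(rows)

    # covariates: conditional Gaussian on the standardized within-plot
    # deviation of log depolymerization (a Gaussian copula on log scales)
    log_dep = np.log(frame["depolymerization"].to_numpy())
    centered = log_dep - frame.groupby("plot_id")["depolymerization"].transform(
        lambda x: np.mean(np.log(x))
    ).to_numpy()
    # standardize on the plots without the drought pulse: the July drought
    # spike is a treatment effect, not part of the covariate copula scale
    reference = centered[~frame["drought"].to_numpy()]
    sd = reference.std() if len(reference) else centered.std()
    z = centered / sd if sd > 1e-12 else np.zeros(n)

    plot_index = frame["plot_id"].astype("category").cat.codes.to_numpy()
    m = len(seasons)
    for name, spec in cfg.covariates.items():
        b = spec.between_sd * rng_cov.standard_normal(n_plots)
        eps = rng_cov.standard_normal(n)
        # center the noise within plots (z already is), so that the
        # within-plot correlation with log depolymerization is rho, not
        # rho inflated by the centering loss of 1/m of the noise variance
        eps = eps - pd.Series(eps).groupby(plot_index).transform("mean").to_numpy()
        eps *= np.sqrt(m / (m - 1)) if m > 1 else 1.0
        within = spec.rho * z + np.sqrt(max(0.0, 1 - spec.rho**2)) * eps
        log_val = (
            np.log(spec.mean)
            + b[plot_index]
            - 0.5 * spec.between_sd**2
            + spec.within_sd * within
            - 0.5 * spec.within_sd**2
        )
        frame[name] = np.exp(log_val)

    return SyntheticTruth(frame=frame, config=cfg, seed=seed)


def simulate_measurements(
    truth: SyntheticTruth,
    seed: int | None = None,
    pools: tuple[str, ...] = POOLS,
) -> dict[str, pd.DataFrame]:
    """Produce raw two-timepoint IPD tables from the truth via the forward model.

    For each plot × season × pool the tracer plan sets the post-addition pool
    and enrichment, the exact zero-order forward model propagates both to the
    two stop times, then multiplicative lognormal noise (CV
    ``conc_noise_cv``) is applied to concentrations and additive Gaussian
    noise (sd = ``atom_noise_cv`` × value) to atom% 15N.

    Returns a bundle of DataFrames: ``ipd_raw`` (long measurement format),
    ``native_pools``, and ``covariates``.
    """
    cfg = truth.config
    if seed is None:
        seed = truth.seed
    rng = substream(seed, "measure/noise")
    bg = cfg.background_atom_pct

    records = []
    natives = []
    for row in truth.frame.itertuples():
        for pool_id in pools:
            pool_col, gi_col, ge_col = TRUTH_RATE_COLUMNS[pool_id]
            native = getattr(row, pool_col)
            gi = getattr(row, gi_col)
            ge = getattr(row, ge_col)
            plan = ipd.plan_tracer_addition(
                native,
                cfg.tracer_target_fraction,
                cfg.tracer_enrichment,
                bg,
            )
            c0 = native + plan.amount_to_add
            ape0 = plan.predicted_post_atom_pct - bg
            times = (
                cfg.faa_times_min if pool_id == "FAA" else cfg.inorganic_times_min
            )
            natives.append(
                {
                    "plot_id": row.plot_id,
                    "season": row.season,
                    "pool_id": pool_id,
                    "native_pool": native,
                }
            )
            for t_min in times:
                c_t, ape_t = ipd.simulate_ipd(c0, ape0, gi, ge, t_min)
                conc = c_t * float(
                    _lognormal_factor(rng, _cv_to_sd(cfg.conc_noise_cv), None)
                )
                atom_true = bg + ape_t
                atom = atom_true + cfg.atom_noise_cv * atom_true * float(
                    rng.standard_normal()
                )
                records.append(
                    {
                        "plot_id": row.plot_id,
                        "season": row.season,
                        "pool_id": pool_id,
                        "time_min": t_min,
                        "conc_ugN_per_gdm": conc,
                        "atom_pct_15N": atom,
                    }
                )

    covariate_cols = ["plot_id", "season", "temp_level", "co2_level", "drought"]
    covariate_cols += list(cfg.covariates)
    return {
        "ipd_raw": pd.DataFrame(records),
        "native_pools": pd.DataFrame(natives),
        "covariates": truth.frame[covariate_cols].copy(),
    }


# ---------------------------------------------------------------------------
# Dataset bundle I/O

BUNDLE_SCHEMAS = {
    "design": ["plot_id", "temp_level", "co2_level", "sampled", "drought"],
    "truth": ["plot_id", "season", "depolymerization", "aa_consumption"],
    "ipd_raw": ipd.MEASUREMENT_COLUMNS,
    "native_pools": ["plot_id", "season", "pool_id", "native_pool"],
    "covariates": ["plot_id", "season"],
}


def write_dataset(bundle: dict, outdir: str | Path) -> None:
    """Write a dataset bundle (CSV tables + config.yaml) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(outdir / f"{name}.csv", index=False)
    cfg = bundle.get("config")
    if cfg is not None:
        payload = cfg.to_dict() if isinstance(cfg, EffectConfig) else dict(cfg)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_dataset(indir: str | Path) -> dict:
    """Read a dataset bundle back; validates required columns per table."""
    indir = Path(indir)
    bundle: dict = {}
    for name, required in BUNDLE_SCHEMAS.items():
        path = indir / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path} missing required columns: {missing}")
        bundle[name] = df
    cfg_path = indir / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            bundle["config"] = EffectConfig.from_dict(yaml.safe_load(fh))
    return bundle


def generate_dataset(
    design: pd.DataFrame,
    config: EffectConfig | None = None,
    seed: int = 0,
    pools: tuple[str, ...] = POOLS,
) -> dict:
    """Convenience: truth + measurements + design in one bundle."""
    truth = generate_truth(design, config, seed)
    bundle = simulate_measurements(truth, seed=seed, pools=pools)
    bundle["design"] = design
    bundle["truth"] = truth.frame
    bundle["config"] = truth.config
    return bundle
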