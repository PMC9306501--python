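"""Pipeline orchestration: generate -> estimate -> analyze -> report.

A run is a directory of CSV tables plus a JSON manifest.  Stages:

* ``design``  — facility layout, sampled subset, drought flags
* ``synth``   — synthetic truth and raw two-timepoint IPD measurements
* ``rates``   — Kirkham–Bartholomew gross rates + residence times per
  plot × season × pool
* ``stats``   — reduced response-surface GLS per response, seasonwise
  drought ANOVAs with Tukey letters, repeated-measures correlations of
  depolymerization with the covariates
* ``report``  — a term × response matrix of F and p in the style of the
  study's GLS summary table

Every stage draws randomness from a named substream of the master seed, so
reruns are reproducible and stages can be toggled without shifting streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, design as design_mod, ipd, stats, synthetic
from .gls import ALL_TERMS, ModelSpec
from .synthetic import EffectConfig, substream

logger = logging.getLogger("ipdflux.pipeline")

#: responses analyzed with the response-surface GLS, and their column sources
GLS_RESPONSES = (
    "faa_pool",
    "depolymerization",
    "aa_consumption",
    "mean_residence_time_h",
    "gross_mineralization",
    "gross_nitrification",
)

RATE_TO_POOL = {
    "depolymerization": ("FAA", "gross_influx"),
    "aa_consumption": ("FAA", "gross_efflux"),
    "mean_residence_time_h": ("FAA", "mean_residence_time_h"),
    "gross_mineralization": ("NH4", "gross_influx"),
    "gross_nitrification": ("NO3", "gross_influx"),
}


@dataclass
class RunConfig:
    outdir: str | Path = "run"
    seed: int = 0
    effect_config: EffectConfig = field(default_factory=EffectConfig)
    stages: tuple[str, ...] = ("design", "synth", "rates", "stats", "report")
    alpha: float = 0.05
    n_boot: int = 2000
    rmcorr_covariates: tuple[str, ...] = ("anpp", "swc", "root_biomass",
                                          "microbial_N", "total_soil_N")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "effect_config": self.effect_config.to_dict(),
                "stages": list(self.stages),
                "alpha": self.alpha,
                "n_boot": self.n_boot,
                "rmcorr_covariates": list(self.rmcorr_covariates),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def rates_to_wide(rates: pd.DataFrame, truth_like: pd.DataFrame) -> pd.DataFrame:
    """Join estimated rates (long by pool) into one row per plot × season."""
    wide = truth_like[
        ["plot_id", "season", "temp_level", "co2_level", "drought"]
    ].drop_duplicates()
    for resp, (pool, col) in RATE_TO_POOL.items():
        sub = rates[rates.pool_id == pool][["plot_id", "season", col]]
        sub = sub.rename(columns={col: resp})
        wide = wide.merge(sub, on=["plot_id", "season"], how="left")
    # estimated FAA pool: mean of the two timepoint concentrations is already
    # folded into MRT; for the pool response use the native pool estimate
    return wide


def analysis_frame(
    rates: pd.DataFrame,
    native_pools: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """One row per plot × season with responses and covariates."""
    wide = covariates.copy()
    for resp, (pool, col) in RATE_TO_POOL.items():
        sub = rates[rates.pool_id == pool][["plot_id", "season", col]].rename(
            columns={col: resp}
        )
        wide = wide.merge(sub, on=["plot_id", "season"], how="left")
    faa = native_pools[native_pools.pool_id == "FAA"][
        ["plot_id", "season", "native_pool"]
    ].rename(columns={"native_pool": "faa_pool"})
    return wide.merge(faa, on=["plot_id", "season"], how="left")


def drought_subset(frame: pd.DataFrame) -> pd.DataFrame:
    """Ambient and future-scenario plots (the drought experiment arms)."""
    mask = ((frame.temp_level == 0.0) & (frame.co2_level == 0.0)) | (
        (frame.temp_level == 3.0) & (frame.co2_level == 300.0)
    )
    out = frame[mask].copy()
    out["climate"] = np.where(out.temp_level == 0.0, "ambient", "future")
    return out


def report_effects(
    fits: dict[str, stats.ModelFitResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Term × response matrix of "F (p)" with dashes for dropped terms.

    Significant entries (p < alpha) carry a trailing ``*`` (the plain-text
    stand-in for bold).
    """
    rows = []
    for resp, fit in fits.items():
        tab = fit.anova.copy()
        tab.insert(0, "response", resp)
        rows.append(tab)
    terms_table = (
        pd.concat(rows) if rows else
        pd.DataFrame(columns=["response", "term", "num_df", "den_df", "F", "p"])
    )
    return report_effects_from_table(terms_table, alpha=alpha)


def report_effects_from_table(
    terms_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """As :func:`report_effects`, from a tidy (response, term, F, p) table."""
    responses = list(dict.fromkeys(terms_table.get("response", pd.Series(dtype=str))))
    rows = []
    for term in ALL_TERMS:
        row: dict[str, str] = {"term": term}
        for resp in responses:
            tab = terms_table[
                (terms_table.response == resp) & (terms_table.term == term)
            ]
            if len(tab) == 0:
                row[resp] = "-"
            else:
                f_val = float(tab.F.iloc[0])
                p_val = float(tab.p.iloc[0])
                mark = "*" if p_val < alpha else ""
                p_txt = "<.0001" if p_val < 1e-4 else f"{p_val:.4f}"
                row[resp] = f"{f_val:.2f} ({p_txt}){mark}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    seeds = {
        stage: int(substream(config.seed, f"stage/{stage}").integers(2**31))
        for stage in config.stages
    }

    try:
        if "design" in config.stages:
            logger.info("stage design: seed %d", seeds["design"])
            full = design_mod.generate_design(seed=seeds["design"])
            design_mod.write_design(full, outdir / "design.csv")
            manifest["stages"]["design"] = {"seed": seeds["design"], "n_plots": len(full)}

        if "synth" in config.stages:
            full = design_mod.read_design(outdir / "design.csv")
            sampled = full[full.sampled].reset_index(drop=True)
            logger.info("stage synth: %d sampled plots", len(sampled))
            bundle = synthetic.generate_dataset(
                sampled, config.effect_config, seed=seeds["synth"]
            )
            synthetic.write_dataset(
                {k: v for k, v in bundle.items() if k != "design"}, outdir
            )
            manifest["stages"]["synth"] = {
                "seed": seeds["synth"],
                "n_measurements": len(bundle["ipd_raw"]),
            }

        if "rates" in config.stages:
            raw = ipd.read_measurements(outdir / "ipd_raw.csv")
            bg = config.effect_config.background_atom_pct
            rates = ipd.estimate_rates_table(raw, background_atom_pct=bg)
            rates.to_csv(outdir / "rates.csv", index=False)
            manifest["stages"]["rates"] = {
                "n_pairs": len(rates),
                "n_flagged": int((rates.qc_flags != "").sum()),
            }
            logger.info("stage rates: %d pairs estimated", len(rates))

        if "stats" in config.stages:
            rates = pd.read_csv(outdir / "rates.csv")
            native = pd.read_csv(outdir / "native_pools.csv")
            covs = pd.read_csv(outdir / "covariates.csv")
            frame = analysis_frame(rates, native, covs)
            frame.to_csv(outdir / "analysis_frame.csv", index=False)

            surface = frame[~frame.drought]
            fits = {}
            for resp in GLS_RESPONSES:
                spec = ModelSpec(
                    response=resp,
                    transform=stats.default_transform(resp),
                    alpha=config.alpha,
                )
                fits[resp] = stats.reduce_by_marginality(surface, spec)
            manifest["stages"]["stats"] = {
                "gls_responses": list(fits),
                "n_surface_obs": len(surface),
            }
            gls_rows = []
            for resp, fit in fits.items():
                tab = fit.anova.copy()
                tab.insert(0, "response", resp)
                gls_rows.append(tab)
            pd.concat(gls_rows).to_csv(outdir / "gls_terms.csv", index=False)

            dsub = drought_subset(frame)
            anova_rows, tukey_rows = [], []
            for season in design_mod.SEASONS:
                sub = dsub[dsub.season == season].copy()
                for resp in ("depolymerization", "aa_consumption",
                             "mean_residence_time_h"):
                    tab = stats.two_way_anova(sub, resp, "climate", "drought")
                    tab.insert(0, "season", season)
                    tab.insert(0, "response", resp)
                    anova_rows.append(tab)
                    sub["group"] = sub.climate + "/" + np.where(
                        sub.drought, "drought", "control"
                    )
                    tk = stats.tukey_hsd(sub, resp, "group", alpha=config.alpha)
                    for grp, letter in tk.letters.items():
                        tukey_rows.append(
                            {
                                "response": resp,
                                "season": season,
                                "group": grp,
                                "mean": tk.group_means[grp],
                                "letters": letter,
                            }
                        )
            pd.concat(anova_rows).to_csv(outdir / "anova.csv", index=False)
            pd.DataFrame(tukey_rows).to_csv(outdir / "tukey.csv", index=False)

            rm_rows = []
            rng_seed = seeds["stats"]
            for cov_name in config.rmcorr_covariates:
                sub = frame[["plot_id", "depolymerization", cov_name]].copy()
                sub["log_dep"] = np.log(sub.depolymerization)
                sub["log_cov"] = np.log(sub[cov_name])
                res = stats.rmcorr(
                    sub, "plot_id", "log_cov", "log_dep",
                    n_boot=config.n_boot, seed=rng_seed,
                )
                rm_rows.append(
                    {
                        "covariate": cov_name,
                        "r_rm": res.r,
                        "df": res.df,
                        "p": res.p,
                        "p_boot": res.p_boot,
                        "ci_low": res.ci[0],
                        "ci_high": res.ci[1],
                    }
                )
            pd.DataFrame(rm_rows).to_csv(outdir / "rmcorr.csv", index=False)

        if "report" in config.stages:
            terms_table = pd.read_csv(outdir / "gls_terms.csv")
            table = report_effects_from_table(terms_table, alpha=config.alpha)
            table.to_csv(outdir / "table1_like.csv", index=False)
            logger.info("stage report: wrote table1_like.csv")
            manifest["stages"]["report"] = {"n_terms": len(table)}
    except FileNotFoundError as err:
        raise FileNotFoundError(
            f"pipeline stage input missing: {err.filename!r} — run the "
            "producing stage first or check the run directory"
        ) from err
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["stage_seeds"] = seeds
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
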