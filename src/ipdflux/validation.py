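"""End-to-end validation metrics: estimator properties, statistical
calibration, and recovery of the configured effect structure.

Every function recomputes its quantity from scratch by running the package
(forward model, estimators, generator, inference chain); nothing is cached
or looked up.  These routines back both the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design as design_mod
from . import ipd, stats, synthetic
from .gls import ModelSpec
from .pipeline import analysis_frame, drought_subset
from .synthetic import EffectConfig, substream


# ---------------------------------------------------------------------------
# Estimator properties

def _simulated_pair(c0, ape0, gi, ge, t1=15.0, t2=60.0, bg=0.0):
    c_1, a_1 = ipd.simulate_ipd(c0, ape0, gi, ge, t1)
    c_2, a_2 = ipd.simulate_ipd(c0, ape0, gi, ge, t2)
    return ipd.IPDPair(
        ipd.PoolMeasurement("FAA", t1, c_1, bg + a_1),
        ipd.PoolMeasurement("FAA", t2, c_2, bg + a_2),
        background_atom_pct=bg,
    )


def inversion_grid_max_rel_error(n_per_axis: int = 10) -> float:
    """Max relative error of estimator∘simulator over a (GI, GE) grid.

    The grid spans 0.5–60 µg N g⁻¹ dm d⁻¹ on both axes (≥ n² pairs) and
    includes the GI = GE diagonal, exercising both closed-form branches.
    """
    levels = np.linspace(0.5, 60.0, n_per_axis)
    worst = 0.0
    for gi in levels:
        for ge in list(levels) + [gi]:
            pair = _simulated_pair(8.0, 15.0, gi, ge)
            r = ipd.gross_rates(pair)
            worst = max(
                worst,
                abs(r.gross_influx - gi) / gi,
                abs(r.gross_efflux - ge) / max(ge, 1e-12),
            )
    return worst


def identity_max_error(n: int = 10_000, seed: int = 0) -> float:
    """Max |(GI−GE) − ΔC/Δt| over random valid pairs, relative to scale."""
    rng = substream(seed, "validate/identity")
    worst = 0.0
    for _ in range(n):
        c1 = rng.uniform(0.5, 30.0)
        c2 = c1 * rng.uniform(0.5, 2.0)
        ape1 = rng.uniform(1.0, 25.0)
        ape2 = ape1 * rng.uniform(0.3, 0.99)
        t1 = rng.uniform(0.0, 60.0)
        dt = rng.uniform(5.0, 1500.0)
        pair = ipd.IPDPair(
            ipd.PoolMeasurement("FAA", t1, c1, ape1),
            ipd.PoolMeasurement("FAA", t1 + dt, c2, ape2),
            background_atom_pct=0.0,
        )
        r = ipd.gross_rates(pair)
        dc_dt = (c2 - c1) / (dt / (60.0 * 24.0))
        scale = max(1.0, abs(r.gross_influx), abs(r.gross_efflux), abs(dc_dt))
        worst = max(worst, abs((r.gross_influx - r.gross_efflux) - dc_dt) / scale)
    return worst


def continuity_max_jump(tol: float = ipd.DEGENERATE_REL_TOL) -> float:
    """Max relative jump of GI across the degenerate-branch boundary.

    For APE ratios in [1.05, 5], compare the general formula just above the
    tolerance with the limit branch just below it.
    """
    worst = 0.0
    c1 = 5.0
    for ape_ratio in np.linspace(1.05, 5.0, 25):
        ape1 = 4.0 * ape_ratio
        ape2 = 4.0
        for sign in (+1.0, -1.0):
            above = ipd.gross_rates(
                _pair_with_gap(c1, sign * tol * 1.01, ape1, ape2)
            ).gross_influx
            below = ipd.gross_rates(
                _pair_with_gap(c1, sign * tol * 0.99, ape1, ape2)
            ).gross_influx
            worst = max(worst, abs(above - below) / abs(above))
    return worst


def _pair_with_gap(c1, rel_gap, ape1, ape2):
    return ipd.IPDPair(
        ipd.PoolMeasurement("FAA", 15.0, c1, ape1),
        ipd.PoolMeasurement("FAA", 60.0, c1 * (1 + rel_gap), ape2),
        background_atom_pct=0.0,
    )


def noise_recovery_median_bias(
    n_rep: int = 200, seed: int = 0, conc_cv: float = 0.05, atom_cv: float = 0.02
) -> dict[str, float]:
    """Median relative bias (%) of GI per pool condition under assay noise.

    Conditions reproduce the default tracer protocol for each pool: spring
    pool sizes, 20% tracer dose, 15/60 min (FAA) or 4/24 h (inorganic)
    stop times, multiplicative lognormal concentration noise and additive
    Gaussian atom% noise.
    """
    cfg = EffectConfig()
    rng = substream(seed, "validate/noise")
    bg = cfg.background_atom_pct
    conditions = {
        "FAA": (110.0, 104.5, 7.9, cfg.faa_times_min),
        "NH4": (4.0, 3.88, 2.5, cfg.inorganic_times_min),
        "NO3": (3.7, 3.33, 4.0, cfg.inorganic_times_min),
    }
    out = {}
    sd_log = np.sqrt(np.log1p(conc_cv**2))
    for pool, (gi, ge, native, times) in conditions.items():
        plan = ipd.plan_tracer_addition(native, 0.2, 97.0, bg)
        c0 = native + plan.amount_to_add
        ape0 = plan.predicted_post_atom_pct - bg
        rel = np.empty(n_rep)
        for rep in range(n_rep):
            meas = []
            for t in times:
                c, a = ipd.simulate_ipd(c0, ape0, gi, ge, t)
                c *= np.exp(sd_log * rng.standard_normal() - 0.5 * sd_log**2)
                atom = bg + a
                atom += atom_cv * atom * rng.standard_normal()
                meas.append(ipd.PoolMeasurement(pool, t, c, atom))
            r = ipd.gross_rates(ipd.IPDPair(meas[0], meas[1], bg))
            rel[rep] = (r.gross_influx - gi) / gi
        out[pool] = float(100.0 * np.median(rel))
    return out


# ---------------------------------------------------------------------------
# Statistical calibration

def _surface_rows(seed: int = 0) -> pd.DataFrame:
    d = design_mod.sampled_design(seed=seed)
    surface = d[~d.drought].reset_index(drop=True)
    rows = surface.loc[surface.index.repeat(3)].reset_index(drop=True)
    rows["season"] = list(design_mod.SEASONS) * len(surface)
    return rows


def gls_null_type1(
    n_sim: int = 1000, seed: int = 0, term: str = "co2", alpha: float = 0.05
) -> float:
    """Empirical type-I error of the response-surface GLS F-test for one
    term under a null with plot random effect and heterogeneous variances."""
    rows = _surface_rows()
    rng = substream(seed, "validate/gls-null")
    sds = {"May": 1.5, "Jul": 1.0, "Oct": 0.8}
    spec = ModelSpec(response="y", terms=("season", "co2", "temp"))
    n_plots = rows.plot_id.nunique()
    plot_codes = pd.Categorical(rows.plot_id).codes
    noise_sd = rows.season.map(sds).to_numpy()
    rejections = 0
    for _ in range(n_sim):
        u = rng.normal(0.0, 1.0, n_plots)
        df = rows.assign(
            y=u[plot_codes] + noise_sd * rng.standard_normal(len(rows))
        )
        fit = stats.fit_rs_gls(df, spec)
        if fit.term_p(term) < alpha:
            rejections += 1
    return rejections / n_sim


def anova_null_type1(
    n_sim: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Empirical type-I error of the drought main effect in the seasonwise
    two-way ANOVA on the 4+4 / 3+3 drought-experiment layout."""
    rng = substream(seed, "validate/anova-null")
    layout = pd.DataFrame(
        [("ambient", False)] * 4 + [("ambient", True)] * 4
        + [("future", False)] * 3 + [("future", True)] * 3,
        columns=["climate", "drought"],
    )
    rejections = 0
    for _ in range(n_sim):
        df = layout.assign(y=rng.standard_normal(len(layout)))
        table = stats.two_way_anova(df, "y", "climate", "drought")
        if float(table[table.term == "drought"].p.iloc[0]) < alpha:
            rejections += 1
    return rejections / n_sim


def rmcorr_oracle_max_diff(seed: int = 0) -> float:
    """Max |r_rm − oracle| over seeded fixtures, oracle = ANCOVA partial
    correlation computed by direct linear algebra (dummy projection)."""
    rng = substream(seed, "validate/rmcorr")
    worst = 0.0
    for rep in range(10):
        k = int(rng.integers(4, 9))
        rows = []
        for s in range(k):
            m = int(rng.integers(3, 6))
            x = rng.normal(2.0 * s, 1.0, m)
            y = 0.5 * x + rng.normal(0, 1.0, m) + 3.0 * s
            rows += [{"subject": f"s{s}", "x": xi, "y": yi}
                     for xi, yi in zip(x, y)]
        df = pd.DataFrame(rows)
        res = stats.rmcorr(df, "subject", "x", "y", n_boot=0)

        # oracle: project out subject dummies, correlate the residuals
        dummies = pd.get_dummies(df.subject).to_numpy(float)
        proj = dummies @ np.linalg.pinv(dummies)
        rx = df.x.to_numpy() - proj @ df.x.to_numpy()
        ry = df.y.to_numpy() - proj @ df.y.to_numpy()
        r_ref = float(
            rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))
        )
        worst = max(worst, abs(res.r - r_ref))
    return worst


# ---------------------------------------------------------------------------
# End-to-end power and effect recovery

def pipeline_power(
    n_runs: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict[str, float]:
    """Fraction of seeded end-to-end runs that flag the season-dependent
    warming effect (reduced GLS) and the July drought contrast (ANOVA)."""
    d = design_mod.sampled_design(seed=0)
    base = int(substream(seed, "validate/power").integers(2**30))
    hits_interaction = 0
    hits_drought = 0
    spec = ModelSpec(response="depolymerization")
    for k in range(n_runs):
        bundle = synthetic.generate_dataset(d, seed=base + k, pools=("FAA",))
        rates = ipd.estimate_rates_table(bundle["ipd_raw"])
        frame = analysis_frame(
            rates, bundle["native_pools"], bundle["covariates"]
        )
        fit = stats.reduce_by_marginality(frame[~frame.drought], spec)
        if "season:temp" in fit.terms and fit.term_p("season:temp") < alpha:
            hits_interaction += 1
        jul = drought_subset(frame)
        jul = jul[jul.season == "Jul"]
        table = stats.two_way_anova(jul, "depolymerization", "climate", "drought")
        if float(table[table.term == "drought"].p.iloc[0]) < alpha:
            hits_drought += 1
    return {
        "season_temp": hits_interaction / n_runs,
        "drought": hits_drought / n_runs,
    }


def design_and_dosing() -> dict[str, float]:
    """Design counts and tracer-protocol parameters, recomputed from the
    package's layout generator and dose planner."""
    full = design_mod.generate_design(seed=0)
    sampled = full[full.sampled]
    drought = sampled[sampled.drought]
    cfg = EffectConfig()
    plan = ipd.plan_tracer_addition(
        cfg.faa_pool_means["May"],
        cfg.tracer_target_fraction,
        cfg.tracer_enrichment,
        cfg.background_atom_pct,
    )
    return {
        "facility_plot_count": float(len(full)),
        "sampled_plot_count": float(len(sampled)),
        "treatment_combination_count": float(
            sampled.groupby(["temp_level", "co2_level"]).ngroups
        ),
        "drought_plot_count_ambient": float(
            len(drought[drought.temp_level == 0.0])
        ),
        "drought_plot_count_future": float(
            len(drought[drought.temp_level == 3.0])
        ),
        "tracer_target_fraction_pct": 100.0 * cfg.tracer_target_fraction,
        "tracer_dose_may_faa_ugN_per_gdm": plan.amount_to_add,
        "faa_incubation_stop_min": cfg.faa_times_min[1],
        "inorganic_incubation_stop_h": cfg.inorganic_times_min[1] / 60.0,
    }


def effect_recovery(seed: int = 0, n_design_reps: int = 20) -> dict[str, float]:
    """Recover the calibrated effect structure from a replicated synthetic
    study run through the full measurement + estimation chain.

    The default design is replicated ``n_design_reps`` times (preserving the
    treatment allocation and drought pairing) so group means are stable;
    effects are then measured exactly as the field study reports them:
    percentage change of estimated group-mean rates.  Residence times use
    the pre-tracer native pool as the pool size (the assayed amino-acid
    content), not the post-addition incubation pool.
    """
    base = design_mod.sampled_design(seed=0)
    reps = [base.assign(plot_id=base.plot_id + f"_r{k}")
            for k in range(n_design_reps)]
    big = pd.concat(reps, ignore_index=True)
    bundle = synthetic.generate_dataset(
        big, seed=int(substream(seed, "validate/effects").integers(2**30))
    )
    rates = ipd.estimate_rates_table(
        bundle["ipd_raw"],
        pool_size_basis="native",
        native_pools=bundle["native_pools"],
    )
    frame = analysis_frame(rates, bundle["native_pools"], bundle["covariates"])

    out: dict[str, float] = {}
    surface = frame[~frame.drought]

    # seasonal FAA pool means (ambient-condition average)
    for season, key in (("May", "faa_pool_mean_may"),
                        ("Jul", "faa_pool_mean_jul"),
                        ("Oct", "faa_pool_mean_oct")):
        out[key] = float(
            surface[surface.season == season].faa_pool.mean()
        )

    # season-dependent warming effect on depolymerization (+3 °C vs ambient)
    for season, key in (("May", "warming_depoly_effect_may_pct"),
                        ("Oct", "warming_depoly_effect_oct_pct")):
        sub = surface[surface.season == season]
        warm = sub[sub.temp_level == 3.0].depolymerization.mean()
        amb = sub[sub.temp_level == 0.0].depolymerization.mean()
        out[key] = float(100.0 * (warm / amb - 1.0))

    # drought effect at peak drought (July), per climate scenario
    dsub = drought_subset(frame)
    jul = dsub[dsub.season == "Jul"]
    for climate, key in (("ambient", "drought_depoly_effect_ambient_pct"),
                         ("future", "drought_depoly_effect_future_pct")):
        sub = jul[jul.climate == climate]
        dr = sub[sub.drought].depolymerization.mean()
        ctrl = sub[~sub.drought].depolymerization.mean()
        out[key] = float(100.0 * (dr / ctrl - 1.0))

    # May residence-time range over treatment-combination means
    may = surface[surface.season == "May"]
    mrt_means = may.groupby(["temp_level", "co2_level"]).mean_residence_time_h.mean()
    out["mrt_may_treatment_min_h"] = float(mrt_means.min())
    out["mrt_may_treatment_max_h"] = float(mrt_means.max())

    # fold excess of depolymerization over the inorganic gross rates
    by_season = surface.groupby("season")
    fold_min = by_season.depolymerization.mean() / by_season.gross_mineralization.mean()
    fold_nit = by_season.depolymerization.mean() / by_season.gross_nitrification.mean()
    out["depoly_inorganic_fold_min"] = float(min(fold_min.min(), fold_nit.min()))
    out["depoly_inorganic_fold_max"] = float(max(fold_min.max(), fold_nit.max()))

    # repeated-measures correlations with the key covariates
    frame = frame.assign(log_dep=np.log(frame.depolymerization))
    et = frame[~frame.drought].assign(log_cov=lambda d: np.log(d.anpp))
    out["rmcorr_depoly_anpp_et_eco2"] = stats.rmcorr(
        et, "plot_id", "log_cov", "log_dep", n_boot=0
    ).r
    full_d = frame.assign(log_cov=np.log(frame.swc))
    out["rmcorr_depoly_swc_all"] = stats.rmcorr(
        full_d, "plot_id", "log_cov", "log_dep", n_boot=0
    ).r
    return out
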