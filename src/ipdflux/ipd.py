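"""Isotope pool dilution (IPD) core: forward model and closed-form estimators.

A soil N pool (free amino acids, ammonium, or nitrate) is spiked with a
highly :sup:`15`\\ N-enriched tracer and extracted at two stop times.  Between
the two timepoints, gross influx (protein depolymerization, mineralization,
nitrification) enters the pool at natural :sup:`15`\\ N abundance and dilutes
the enrichment, while gross efflux (microbial consumption) removes N at the
pool's current enrichment.  Under zero-order kinetics over the incubation
interval the Kirkham–Bartholomew mass-balance equations invert this process
exactly, yielding gross influx (GI) and gross efflux (GE) in
µg N g⁻¹ dry mass d⁻¹ from the paired concentrations and atom% excesses.

This module provides the forward simulator, the closed-form estimators, the
mean-residence-time computation, tracer-dose planning, and long-format CSV
I/O for plot-level measurement tables.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: atom% 15N of atmospheric N2, the conventional natural-abundance reference.
ATMOSPHERIC_N2_ATOM_PCT = 0.3663

#: minutes per day; all rates are per day while stop times are in minutes.
MINUTES_PER_DAY = 60.0 * 24.0

#: relative pool change below which the estimators switch to the constant-pool
#: limit (chosen so the two branches join continuously well below measurement
#: precision).
DEGENERATE_REL_TOL = 1e-8

MEASUREMENT_COLUMNS = [
    "plot_id",
    "season",
    "pool_id",
    "time_min",
    "conc_ugN_per_gdm",
    "atom_pct_15N",
]


class UndefinedRateError(ValueError):
    """Raised when a gross rate is mathematically undefined (e.g. APE ≤ 0)."""


class QCFlag(str, enum.Enum):
    DEGENERATE_POOL = "DEGENERATE_POOL"
    NONDECREASING_APE = "NONDECREASING_APE"
    NEGATIVE_RATE = "NEGATIVE_RATE"
    UNDEFINED_RATE = "UNDEFINED_RATE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PoolMeasurement:
    """One pool observation: total N concentration and atom% 15N at one time.

    Parameters
    ----------
    pool_id : str
        One of ``FAA``, ``NH4``, ``NO3``.
    time_min : float
        Minutes since tracer addition (≥ 0).
    concentration : float
        Total (14N+15N) pool N, µg N g⁻¹ dry mass; must be > 0.
    atom_pct_15N : float
        Measured atom% 15N of the pool, in [0, 100].
    """

    pool_id: str
    time_min: float
    concentration: float
    atom_pct_15N: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")
        if not self.concentration > 0:
            raise ValueError(
                f"concentration must be > 0, got {self.concentration}"
            )
        if not 0.0 <= self.atom_pct_15N <= 100.0:
            raise ValueError(
                f"atom_pct_15N must be in [0, 100], got {self.atom_pct_15N}"
            )


@dataclass(frozen=True)
class IPDPair:
    """Paired timepoint measurements of one pool plus the background atom%."""

    first: PoolMeasurement
    second: PoolMeasurement
    background_atom_pct: float = ATMOSPHERIC_N2_ATOM_PCT

    def __post_init__(self) -> None:
        if self.first.pool_id != self.second.pool_id:
            raise ValueError(
                "IPDPair requires identical pool_ids, got "
                f"{self.first.pool_id!r} and {self.second.pool_id!r}"
            )
        if not self.second.time_min > self.first.time_min:
            raise ValueError("second.time_min must exceed first.time_min")
        if not 0.0 <= self.background_atom_pct < 100.0:
            raise ValueError("background_atom_pct must be in [0, 100)")

    @property
    def dt_days(self) -> float:
        return (self.second.time_min - self.first.time_min) / MINUTES_PER_DAY

    @property
    def ape_first(self) -> float:
        return atom_percent_excess(
            self.first.atom_pct_15N, self.background_atom_pct
        )

    @property
    def ape_second(self) -> float:
        return atom_percent_excess(
            self.second.atom_pct_15N, self.background_atom_pct
        )


@dataclass(frozen=True)
class GrossRates:
    """Gross influx/efflux (µg N g⁻¹ dm d⁻¹) and optional residence time (h)."""

    gross_influx: float
    gross_efflux: float
    mean_residence_time: float | None = None
    qc_flags: frozenset[QCFlag] = field(default_factory=frozenset)


@dataclass(frozen=True)
class TracerPlan:
    """Planned 15N tracer dose for one pool (the ~20%-of-native rule)."""

    native_pool: float
    target_fraction: float
    tracer_enrichment: float
    amount_to_add: float
    predicted_post_atom_pct: float


def atom_percent_excess(sample_atom_pct: float, background_atom_pct: float) -> float:
    """Atom% excess: measured atom% 15N minus the background atom% 15N.

    The result may be negative (isotopically depleted relative to background);
    callers flag, never clamp, such values.
    """
    for name, v in (
        ("sample_atom_pct", sample_atom_pct),
        ("background_atom_pct", background_atom_pct),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return sample_atom_pct - background_atom_pct


def _log_mean(c1: float, c2: float) -> float:
    """Logarithmic mean (c2-c1)/ln(c2/c1), computed stably via log1p."""
    d = c2 - c1
    return d / math.log1p(d / c1)


def gross_rates(pair: IPDPair, degenerate_tol: float = DEGENERATE_REL_TOL) -> GrossRates:
    """Kirkham–Bartholomew gross influx and efflux for one measurement pair.

    GI = (C_t2 − C_t1)/Δt × ln(APE_t1/APE_t2) / ln(C_t2/C_t1) and
    GE = (C_t1 − C_t2)/Δt × [1 + ln(APE_t2/APE_t1)/ln(C_t2/C_t1)], with Δt in
    days.  GI is evaluated through the equivalent logarithmic-mean form
    L(C_t1, C_t2)·ln(APE_t1/APE_t2)/Δt, and GE as GI − ΔC/Δt, which are
    algebraically identical but remain stable as C_t2 → C_t1.  When the
    relative pool change falls below ``degenerate_tol`` the constant-pool
    limit L → (C_t1+C_t2)/2 is used and ``DEGENERATE_POOL`` is flagged.

    Raises
    ------
    UndefinedRateError
        If either atom% excess is ≤ 0 (the dilution equations are undefined).
    """
    c1 = pair.first.concentration
    c2 = pair.second.concentration
    ape1 = pair.ape_first
    ape2 = pair.ape_second
    dt = pair.dt_days

    if ape1 <= 0 or ape2 <= 0:
        raise UndefinedRateError(
            f"atom% excess must be > 0 at both timepoints (got {ape1:.6g}, "
            f"{ape2:.6g}); check the background atom% and tracer addition"
        )

    flags: set[QCFlag] = set()
    rel_change = abs(c2 - c1) / c1
    if rel_change < degenerate_tol:
        pool_scale = 0.5 * (c1 + c2)
        flags.add(QCFlag.DEGENERATE_POOL)
    else:
        pool_scale = _log_mean(c1, c2)

    gi = pool_scale * math.log(ape1 / ape2) / dt
    ge = gi - (c2 - c1) / dt

    if ape2 >= ape1:
        flags.add(QCFlag.NONDECREASING_APE)
    if gi < 0 or ge < 0:
        flags.add(QCFlag.NEGATIVE_RATE)

    return GrossRates(
        gross_influx=gi, gross_efflux=ge, qc_flags=frozenset(flags)
    )


def gross_influx(pair: IPDPair, degenerate_tol: float = DEGENERATE_REL_TOL) -> float:
    """Gross influx rate (µg N g⁻¹ dm d⁻¹); see :func:`gross_rates`."""
    return gross_rates(pair, degenerate_tol).gross_influx


def gross_efflux(pair: IPDPair, degenerate_tol: float = DEGENERATE_REL_TOL) -> float:
    """Gross efflux rate (µg N g⁻¹ dm d⁻¹); see :func:`gross_rates`."""
    return gross_rates(pair, degenerate_tol).gross_efflux


def mean_residence_time(pool_size: float, gi: float, ge: float) -> float:
    """Mean residence time in hours: pool size over the mean of GI and GE.

    MRT(h) = pool / ((GI+GE)/2) × 24.  Returns NaN when GI+GE ≤ 0 (undefined).
    """
    if not pool_size > 0:
        raise ValueError(f"pool_size must be > 0, got {pool_size}")
    mean_flux = 0.5 * (gi + ge)
    if mean_flux <= 0:
        return math.nan
    return pool_size / mean_flux * 24.0


def simulate_ipd(
    c0: float,
    ape0: float,
    gi_true: float,
    ge_true: float,
    t_minutes: float,
) -> tuple[float, float]:
    """Forward zero-order IPD model: pool and atom% excess at time t.

    Influx enters at background abundance (zero excess), efflux removes N at
    the pool's current excess, both at constant rates.  The pool follows
    C(t) = C0 + (GI−GE)·t and the excess label obeys dE/dt = −GE·E/C(t),
    giving APE(t) = APE0·(C(t)/C0)^(−GE/(GI−GE)−1) for GI ≠ GE and
    APE(t) = APE0·exp(−GE·t/C0) for GI = GE (t in days).

    Returns ``(C_t, APE_t)``; concentrations in µg N g⁻¹ dm, APE in atom%.
    """
    if not c0 > 0:
        raise ValueError(f"c0 must be > 0, got {c0}")
    if not ape0 > 0:
        raise ValueError(f"ape0 must be > 0, got {ape0}")
    if gi_true < 0 or ge_true < 0:
        raise ValueError("rates must be >= 0")
    if t_minutes < 0:
        raise ValueError("t_minutes must be >= 0")

    t_days = t_minutes / MINUTES_PER_DAY
    net = gi_true - ge_true
    c_t = c0 + net * t_days
    if c_t <= 0:
        raise ValueError(
            f"pool depleted within the interval (C({t_minutes} min) = {c_t:.4g})"
        )
    if net == 0.0:
        ape_t = ape0 * math.exp(-ge_true * t_days / c0)
    else:
        exponent = -ge_true / net - 1.0
        ape_t = ape0 * (c_t / c0) ** exponent
    return c_t, ape_t


def plan_tracer_addition(
    native_pool: float,
    target_fraction: float = 0.20,
    tracer_enrichment: float = 97.0,
    background_atom_pct: float = ATMOSPHERIC_N2_ATOM_PCT,
) -> TracerPlan:
    """Plan a tracer dose of ``target_fraction`` of the native pool N.

    The standard dosing rule adds ~20% of the native pool as highly enriched
    (96–98 atom%) tracer; the predicted post-addition atom% follows the
    two-component isotope mixing equation.
    """
    if not native_pool > 0:
        raise ValueError(f"native_pool must be > 0, got {native_pool}")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(
            f"target_fraction must be in (0, 1), got {target_fraction}"
        )
    if not 0.0 <= background_atom_pct < tracer_enrichment <= 100.0:
        raise ValueError("need 0 <= background < tracer_enrichment <= 100")
    amount = native_pool * target_fraction
    predicted = (
        amount * tracer_enrichment + native_pool * background_atom_pct
    ) / (native_pool + amount)
    return TracerPlan(
        native_pool=native_pool,
        target_fraction=target_fraction,
        tracer_enrichment=tracer_enrichment,
        amount_to_add=amount,
        predicted_post_atom_pct=predicted,
    )


# ---------------------------------------------------------------------------
# Long-format measurement tables

def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a long-format IPD measurement table; validates required columns."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} missing columns: {missing}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df.to_csv(path, index=False)


def estimate_rates_table(
    measurements: pd.DataFrame,
    background_atom_pct: float = ATMOSPHERIC_N2_ATOM_PCT,
    pool_size_basis: str = "mean",
    native_pools: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Estimate GI/GE/MRT for every (plot, season, pool) measurement pair.

    Parameters
    ----------
    measurements : DataFrame
        Long format with :data:`MEASUREMENT_COLUMNS`; exactly two timepoints
        per (plot_id, season, pool_id) group.
    background_atom_pct : float
        Natural-abundance atom% 15N used for excess computation.
    pool_size_basis : {"mean", "t1", "t2", "native"}
        Which pool size enters the residence-time formula; ``mean`` averages
        the two timepoint concentrations, symmetric to the (GI+GE)/2 flux.
    native_pools : DataFrame, optional
        Columns (plot_id, season, pool_id, native_pool); required when
        ``pool_size_basis="native"``.

    Returns
    -------
    DataFrame with columns plot_id, season, pool_id, gross_influx,
    gross_efflux, mean_residence_time_h, qc_flags (semicolon-joined).
    Undefined pairs yield NaN rates with an ``UNDEFINED_RATE`` flag.
    """
    if pool_size_basis not in {"mean", "t1", "t2", "native"}:
        raise ValueError(f"unknown pool_size_basis {pool_size_basis!r}")
    if pool_size_basis == "native" and native_pools is None:
        raise ValueError("native_pools table required for basis 'native'")

    native_lookup: dict[tuple, float] = {}
    if native_pools is not None:
        native_lookup = {
            (r.plot_id, r.season, r.pool_id): r.native_pool
            for r in native_pools.itertuples()
        }

    rows = []
    for (plot_id, season, pool_id), grp in measurements.groupby(
        ["plot_id", "season", "pool_id"], sort=False
    ):
        grp = grp.sort_values("time_min")
        if len(grp) != 2:
            raise ValueError(
                f"expected 2 timepoints for ({plot_id}, {season}, {pool_id}), "
                f"got {len(grp)}"
            )
        t1, t2 = grp.iloc[0], grp.iloc[1]
        pair = IPDPair(
            first=PoolMeasurement(
                pool_id, t1.time_min, t1.conc_ugN_per_gdm, t1.atom_pct_15N
            ),
            second=PoolMeasurement(
                pool_id, t2.time_min, t2.conc_ugN_per_gdm, t2.atom_pct_15N
            ),
            background_atom_pct=background_atom_pct,
        )
        try:
            rates = gross_rates(pair)
        except UndefinedRateError:
            rows.append(
                {
                    "plot_id": plot_id,
                    "season": season,
                    "pool_id": pool_id,
                    "gross_influx": math.nan,
                    "gross_efflux": math.nan,
                    "mean_residence_time_h": math.nan,
                    "qc_flags": QCFlag.UNDEFINED_RATE.value,
                }
            )
            continue

        if pool_size_basis == "mean":
            pool = 0.5 * (t1.conc_ugN_per_gdm + t2.conc_ugN_per_gdm)
        elif pool_size_basis == "t1":
            pool = t1.conc_ugN_per_gdm
        elif pool_size_basis == "t2":
            pool = t2.conc_ugN_per_gdm
        else:
            pool = native_lookup[(plot_id, season, pool_id)]
        mrt = mean_residence_time(pool, rates.gross_influx, rates.gross_efflux)
        rows.append(
            {
                "plot_id": plot_id,
                "season": season,
                "pool_id": pool_id,
                "gross_influx": rates.gross_influx,
                "gross_efflux": rates.gross_efflux,
                "mean_residence_time_h": mrt,
                "qc_flags": ";".join(sorted(f.value for f in rates.qc_flags)),
            }
        )
    return pd.DataFrame(rows)
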