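"""Kirkham–Bartholomew estimators, forward model, and tracer planning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ipdflux import ipd
from ipdflux.ipd import (
    IPDPair,
    PoolMeasurement,
    QCFlag,
    UndefinedRateError,
    atom_percent_excess,
    gross_efflux,
    gross_influx,
    gross_rates,
    mean_residence_time,
    plan_tracer_addition,
    simulate_ipd,
)


def pair(c1, c2, ape1, ape2, t1=15.0, t2=60.0, bg=0.0):
    return IPDPair(
        PoolMeasurement("FAA", t1, c1, bg + ape1),
        PoolMeasurement("FAA", t2, c2, bg + ape2),
        background_atom_pct=bg,
    )


def ode_forward(c0, ape0, gi, ge, t_minutes):
    """Independent numeric oracle for the zero-order dilution model."""
    t_days = t_minutes / (60.0 * 24.0)

    def rhs(t, state):
        c, e = state
        return [gi - ge, -ge * e / c]

    sol = solve_ivp(
        rhs, (0.0, t_days), [c0, ape0 * c0 / 100.0],
        rtol=1e-12, atol=1e-14, dense_output=True,
    )
    c_t, e_t = sol.y[:, -1]
    return c_t, 100.0 * e_t / c_t


class TestAtomPercentExcess:
    @pytest.mark.parametrize(
        "sample,background,expected",
        [(0.3663, 0.3663, 0.0), (10.0, 0.3663, 9.6337), (0.30, 0.3663, -0.0663)],
    )
    def test_subtraction(self, sample, background, expected):
        assert atom_percent_excess(sample, background) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            atom_percent_excess(bad, 0.3663)
        with pytest.raises(ValueError):
            atom_percent_excess(5.0, bad)


class TestGrossRates:
    def test_worked_example(self):
        """Direct evaluation of the dilution equations on a shrinking pool."""
        p = pair(5.0, 4.5, 10.0, 8.0)
        r = gross_rates(p)
        assert r.gross_influx == pytest.approx(33.886478, rel=1e-6)
        assert r.gross_efflux == pytest.approx(49.886478, rel=1e-6)
        # net change identity: GI - GE = dC/dt
        assert r.gross_influx - r.gross_efflux == pytest.approx(-16.0, abs=1e-9)

    def test_worked_example_matches_ode_inverse(self):
        """The closed-form estimate inverts an independent ODE integration."""
        p = pair(5.0, 4.5, 10.0, 8.0)
        r = gross_rates(p)
        # push the estimated rates through the numeric forward model from t1
        c2, ape2 = ode_forward(
            5.0, 10.0, r.gross_influx, r.gross_efflux, 45.0
        )
        assert c2 == pytest.approx(4.5, rel=1e-8)
        assert ape2 == pytest.approx(8.0, rel=1e-8)

    def test_constant_pool_limit_branch(self):
        r = gross_rates(pair(5.0, 5.0, 10.0, 8.0))
        assert r.gross_influx == pytest.approx(35.702968, rel=1e-6)
        assert r.gross_efflux == pytest.approx(r.gross_influx)
        assert QCFlag.DEGENERATE_POOL in r.qc_flags

    def test_equal_ape_means_no_influx(self):
        r = gross_rates(pair(6.0, 4.0, 9.0, 9.0))
        assert r.gross_influx == pytest.approx(0.0, abs=1e-12)
        assert r.gross_efflux == pytest.approx((6.0 - 4.0) / 0.03125)
        assert QCFlag.NONDECREASING_APE in r.qc_flags

    def test_increasing_ape_flagged_not_clamped(self):
        r = gross_rates(pair(5.0, 4.8, 8.0, 9.0))
        assert r.gross_influx < 0
        assert QCFlag.NONDECREASING_APE in r.qc_flags
        assert QCFlag.NEGATIVE_RATE in r.qc_flags

    def test_nonpositive_ape_is_undefined(self):
        bad = IPDPair(
            PoolMeasurement("FAA", 15, 5.0, 0.30),
            PoolMeasurement("FAA", 60, 4.5, 0.25),
            background_atom_pct=0.3663,
        )
        with pytest.raises(UndefinedRateError):
            gross_rates(bad)

    @given(
        c1=st.floats(1.0, 50.0),
        c2=st.floats(1.0, 50.0),
        ape1=st.floats(2.0, 30.0),
        ratio=st.floats(0.3, 0.99),
        dt=st.floats(10.0, 2000.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_gi_minus_ge(self, c1, c2, ape1, ratio, dt):
        """GI − GE always equals the net pool change per day."""
        p = pair(c1, c2, ape1, ape1 * ratio, t1=5.0, t2=5.0 + dt)
        r = gross_rates(p)
        dc_dt = (c2 - c1) / (dt / (60.0 * 24.0))
        scale = max(1.0, abs(r.gross_influx), abs(dc_dt))
        assert abs((r.gross_influx - r.gross_efflux) - dc_dt) <= 1e-12 * scale

    def test_matches_literal_textbook_formulas(self):
        """The stable log-mean form equals the literal published expressions."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            c1 = rng.uniform(1, 30)
            c2 = c1 * rng.uniform(0.5, 2.0)
            if abs(c2 - c1) / c1 < 1e-6:
                continue
            ape1 = rng.uniform(2, 25)
            ape2 = ape1 * rng.uniform(0.3, 0.99)
            dtd = 45.0 / (60 * 24)
            gi_lit = (c2 - c1) / dtd * math.log(ape1 / ape2) / math.log(c2 / c1)
            ge_lit = (c1 - c2) / dtd * (
                1 + math.log(ape2 / ape1) / math.log(c2 / c1)
            )
            r = gross_rates(pair(c1, c2, ape1, ape2))
            assert r.gross_influx == pytest.approx(gi_lit, rel=1e-10)
            assert r.gross_efflux == pytest.approx(ge_lit, rel=1e-8)

    def test_time_unit_contract(self):
        """Rates depend on the interval only through its length in days."""
        base = gross_rates(pair(5.0, 4.5, 10.0, 8.0, t1=15.0, t2=60.0))
        shifted = gross_rates(pair(5.0, 4.5, 10.0, 8.0, t1=100.0, t2=145.0))
        assert base.gross_influx == pytest.approx(shifted.gross_influx)
        doubled = gross_rates(pair(5.0, 4.5, 10.0, 8.0, t1=15.0, t2=105.0))
        assert doubled.gross_influx == pytest.approx(base.gross_influx / 2)


class TestMeanResidenceTime:
    def test_worked_example(self):
        assert mean_residence_time(4.75, 33.886, 49.886) == pytest.approx(
            2.7217, rel=1e-4
        )

    def test_pool_turning_over_once_daily(self):
        # when mean flux equals the pool, residence time is one day
        assert mean_residence_time(3.3, 3.3, 3.3) == pytest.approx(24.0)

    @given(
        pool=st.floats(0.5, 20.0), gi=st.floats(0.1, 100.0), ge=st.floats(0.1, 100.0)
    )
    @settings(max_examples=100, deadline=None)
    def test_inverse_proportionality(self, pool, gi, ge):
        assert mean_residence_time(pool, 2 * gi, 2 * ge) == pytest.approx(
            mean_residence_time(pool, gi, ge) / 2
        )

    def test_undefined_for_zero_flux(self):
        assert math.isnan(mean_residence_time(4.0, 0.0, 0.0))


class TestSimulateIPD:
    def test_equal_rates_closed_form(self):
        c_t, ape_t = simulate_ipd(4.0, 10.0, 5.0, 5.0, 45.0)
        assert c_t == pytest.approx(4.0)
        assert ape_t == pytest.approx(10.0 * math.exp(-0.0390625), rel=1e-12)

    def test_no_efflux_conserves_label(self):
        c_t, ape_t = simulate_ipd(4.0, 10.0, 8.0, 0.0, 120.0)
        assert ape_t == pytest.approx(10.0 * 4.0 / c_t, rel=1e-12)

    @pytest.mark.parametrize(
        "gi,ge", [(5.0, 5.0), (12.0, 7.0), (0.0, 3.0), (40.0, 2.0)]
    )
    def test_agrees_with_ode_oracle(self, gi, ge):
        c_t, ape_t = simulate_ipd(6.0, 12.0, gi, ge, 90.0)
        c_ref, ape_ref = ode_forward(6.0, 12.0, gi, ge, 90.0)
        assert c_t == pytest.approx(c_ref, rel=1e-8)
        assert ape_t == pytest.approx(ape_ref, rel=1e-8)

    def test_round_trip_recovers_rates(self):
        c0, ape0 = 9.48, 16.1
        c1, a1 = simulate_ipd(c0, ape0, 12.0, 7.0, 15.0)
        c2, a2 = simulate_ipd(c0, ape0, 12.0, 7.0, 60.0)
        r = gross_rates(pair(c1, c2, a1, a2))
        assert r.gross_influx == pytest.approx(12.0, rel=1e-9)
        assert r.gross_efflux == pytest.approx(7.0, rel=1e-9)

    @given(
        gi=st.floats(0.5, 60.0),
        ge=st.floats(0.0, 60.0),
        t=st.floats(1.0, 200.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_dilution(self, gi, ge, t):
        """With positive influx the enrichment strictly decreases in time."""
        from hypothesis import assume

        # stay inside the model's domain: the pool must survive the interval
        assume(8.0 + (gi - ge) * (t + 5.0) / (60.0 * 24.0) > 0.5)
        _, ape_a = simulate_ipd(8.0, 15.0, gi, ge, t)
        _, ape_b = simulate_ipd(8.0, 15.0, gi, ge, t + 5.0)
        assert ape_b < ape_a

    def test_pool_depletion_raises(self):
        with pytest.raises(ValueError, match="depleted"):
            simulate_ipd(1.0, 10.0, 0.0, 50.0, 60.0)


class TestTracerPlan:
    def test_twenty_percent_of_spring_pool(self):
        plan = plan_tracer_addition(7.9, 0.20)
        assert plan.amount_to_add == pytest.approx(1.58)

    def test_mixing_prediction(self):
        plan = plan_tracer_addition(7.9, 0.20, 97.0, 0.3663)
        assert plan.predicted_post_atom_pct == pytest.approx(16.4719, rel=1e-4)
        assert 0.3663 < plan.predicted_post_atom_pct < 97.0

    def test_vanishing_dose_approaches_background(self):
        plan = plan_tracer_addition(7.9, 1e-9, 97.0, 0.3663)
        assert plan.predicted_post_atom_pct == pytest.approx(0.3663, abs=1e-6)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_domain(self, frac):
        with pytest.raises(ValueError):
            plan_tracer_addition(7.9, frac)


class TestDataTypes:
    def test_pair_requires_matching_pools(self):
        with pytest.raises(ValueError, match="pool_id"):
            IPDPair(
                PoolMeasurement("FAA", 15, 5.0, 10.0),
                PoolMeasurement("NH4", 60, 4.5, 8.0),
            )

    def test_pair_requires_time_order(self):
        with pytest.raises(ValueError, match="time"):
            IPDPair(
                PoolMeasurement("FAA", 60, 5.0, 10.0),
                PoolMeasurement("FAA", 15, 4.5, 8.0),
            )

    def test_measurement_invariants(self):
        with pytest.raises(ValueError):
            PoolMeasurement("FAA", 15, -1.0, 10.0)
        with pytest.raises(ValueError):
            PoolMeasurement("FAA", 15, 5.0, 101.0)


class TestRatesTable:
    def test_round_trip_table(self, tmp_path):
        import pandas as pd

        rows = []
        for t, (c, a) in zip(
            (15.0, 60.0),
            [simulate_ipd(9.48, 16.1, 12.0, 7.0, t) for t in (15.0, 60.0)],
        ):
            rows.append(
                {
                    "plot_id": "P01",
                    "season": "May",
                    "pool_id": "FAA",
                    "time_min": t,
                    "conc_ugN_per_gdm": c,
                    "atom_pct_15N": a,
                }
            )
        df = pd.DataFrame(rows)
        path = tmp_path / "meas.csv"
        ipd.write_measurements(df, path)
        table = ipd.estimate_rates_table(
            ipd.read_measurements(path), background_atom_pct=0.0
        )
        assert len(table) == 1
        assert table.gross_influx.iloc[0] == pytest.approx(12.0, rel=1e-6)
        assert table.gross_efflux.iloc[0] == pytest.approx(7.0, rel=1e-6)
        # residence time from the mean of both timepoint pools
        pool = df.conc_ugN_per_gdm.mean()
        assert table.mean_residence_time_h.iloc[0] == pytest.approx(
            pool / 9.5 * 24, rel=1e-6
        )

    def test_missing_column_rejected(self, tmp_path):
        import pandas as pd

        bad = pd.DataFrame({"plot_id": ["P01"], "season": ["May"]})
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            ipd.read_measurements(path)
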