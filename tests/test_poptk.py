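"""One-compartment kinetics: analytic oracles, mass balance, ensembles."""

import numpy as np
import pandas as pd
import pytest

from herdtk import (
    Normal,
    TKDraw,
    TKParams,
    draw_params,
    elimination_rate,
    mean_draw,
    simulate_ensemble,
    simulate_trajectory,
    tk_step,
    vd_sensitivity,
)


DRAW = TKDraw(dt50=50.0, vd=0.085, pm=0.08, pmilk=0.015, maternal_transfer=0.5)


def _run(dose, bw, draw=DRAW, initial_serum=0.0):
    n = len(dose)
    return simulate_trajectory(
        np.asarray(dose, float), np.full(n, bw, dtype=float), draw, initial_serum
    )


class TestEliminationRate:
    @pytest.mark.parametrize(
        "dt50, expected",
        [(74.1, 0.009355), (60.4, 0.011476), (np.log(2.0), 1.0)],
    )
    def test_ln2_over_dt50(self, dt50, expected):
        assert elimination_rate(dt50) == pytest.approx(expected, rel=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            elimination_rate(0.0)


class TestTkStep:
    def test_zero_dose_halves_in_dt50_days(self):
        k = elimination_rate(50.0)
        a = 1000.0
        for _ in range(50):
            a = tk_step(a, 0.0, k)
        assert a == pytest.approx(500.0, rel=1e-12)

    def test_geometric_steady_state(self):
        k = elimination_rate(50.0)
        a = 0.0
        for _ in range(1500):
            a = tk_step(a, 100.0, k)
        assert a == pytest.approx(100.0 / (1.0 - np.exp(-k)), rel=1e-3)

    def test_no_elimination_limit_accumulates_doses(self):
        a = 5.0
        for _ in range(10):
            a = tk_step(a, 2.0, k=0.0)
        assert a == pytest.approx(25.0)


class TestTrajectory:
    def test_zero_everything_is_identically_zero(self):
        traj = _run(np.zeros(100), 500.0, initial_serum=0.0)
        assert (traj.to_numpy() == 0).all()

    def test_pure_decay_recovers_half_life(self):
        traj = _run(np.zeros(400), 500.0, initial_serum=30.0)
        y = np.log(traj["serum_ng_ml"].to_numpy())
        slope = np.polyfit(np.arange(400), y, 1)[0]
        assert np.log(2) / -slope == pytest.approx(50.0, rel=1e-6)
        assert traj["serum_ng_ml"].iloc[0] == pytest.approx(30.0)

    def test_constant_dose_plateau_matches_continuous_form(self):
        bw, dose = 500.0, 50_000.0
        traj = _run(np.full(3000, dose), bw)
        k = DRAW.k
        plateau = traj["serum_ng_ml"].iloc[-1]
        continuous = dose / (k * DRAW.vd * bw * 1000.0)
        assert plateau == pytest.approx(continuous, rel=0.02)

    def test_growth_dilution(self):
        """A fixed burden with rising BW yields falling serum."""
        bw = np.linspace(100, 500, 300)
        traj = simulate_trajectory(np.zeros(300), bw, TKDraw(1e9, 0.085, 0.08, 0.015, 0.5), 10.0)
        assert (np.diff(traj["serum_ng_ml"]) < 0).all()

    def test_partitions_exact_every_day(self):
        traj = _run(np.full(500, 1000.0), 400.0, initial_serum=5.0)
        assert np.array_equal(
            traj["muscle_ng_g"].to_numpy(), DRAW.pm * traj["serum_ng_ml"].to_numpy()
        )
        assert np.array_equal(
            traj["milk_ng_ml"].to_numpy(), DRAW.pmilk * traj["serum_ng_ml"].to_numpy()
        )

    def test_mass_balance(self):
        rng = np.random.default_rng(3)
        dose = rng.uniform(0, 5000, 600)
        traj = _run(dose, 450.0, initial_serum=8.0)
        a = traj["body_burden_ng"].to_numpy()
        q = np.exp(-DRAW.k)
        eliminated = (a[:-1] * (1 - q)).sum()
        credited = dose[1:].sum()  # dosing starts on day 1; day 0 is initial
        assert credited == pytest.approx(a[-1] - a[0] + eliminated, rel=1e-9)

    def test_linearity_in_dose(self):
        rng = np.random.default_rng(4)
        dose = rng.uniform(0, 5000, 300)
        t1 = _run(dose, 450.0, initial_serum=3.0)
        t2 = _run(2 * dose, 450.0, initial_serum=6.0)
        assert np.allclose(t2["serum_ng_ml"], 2 * t1["serum_ng_ml"])
        assert np.allclose(t2["muscle_ng_g"], 2 * t1["muscle_ng_g"])

    def test_mismatched_series_lengths(self):
        with pytest.raises(ValueError, match="different dates"):
            simulate_trajectory(np.zeros(10), np.ones(9), DRAW)


class TestDraws:
    def test_mean_draw_uses_means(self):
        p = TKParams(
            dt50_days=Normal(mean=74.1, sd=13.4),
            vd_l_per_kg=Normal(mean=0.085, sd=0.01),
            pm=Normal(mean=0.08, sd=0.02),
            pmilk=Normal(mean=0.015, sd=0.004),
        )
        d = mean_draw(p)
        assert (d.dt50, d.vd, d.pm, d.pmilk) == (74.1, 0.085, 0.08, 0.015)

    def test_draws_truncated_positive(self):
        p = TKParams(
            dt50_days=Normal(mean=10.0, sd=50.0),
            vd_l_per_kg=Normal(mean=0.085, sd=0.5),
            pm=Normal(mean=0.08, sd=0.5),
            pmilk=Normal(mean=0.015, sd=0.1),
        )
        draws = draw_params(p, 2000, np.random.default_rng(0))
        assert min(d.dt50 for d in draws) > 0
        assert min(d.vd for d in draws) > 0


class TestEnsemble:
    def test_degenerate_ensemble_is_deterministic(self, default_scenario):
        scen = default_scenario
        zero_sd = {
            a: TKParams(
                dt50_days=Normal(mean=p.dt50_days.mean, sd=0.0),
                vd_l_per_kg=Normal(mean=p.vd_l_per_kg.mean, sd=0.0),
                pm=Normal(mean=p.pm.mean, sd=0.0),
                pmilk=Normal(mean=p.pmilk.mean, sd=0.0),
                maternal_transfer=p.maternal_transfer,
            )
            for a, p in scen.tk_params.items()
        }
        from herdtk.scenario_io import SimulationSettings

        frozen = type(scen).model_validate(
            dict(
                scen,
                tk_params=zero_sd,
                settings=SimulationSettings(n_draws=5, seed=1, intake_cv=0.0),
            )
        )
        ens = simulate_ensemble(frozen, "PFOS")
        vals = ens.values("serum")
        assert np.allclose(vals, vals[0][None, :])
        assert np.allclose(ens.summary("serum")["sd"], 0.0)

    def test_same_seed_bit_identical(self, default_scenario):
        a = simulate_ensemble(default_scenario, "PFOS", n=10, seed=9)
        b = simulate_ensemble(default_scenario, "PFOS", n=10, seed=9)
        assert np.array_equal(a.values("serum"), b.values("serum"))
        assert a.draws.equals(b.draws)

    def test_summary_consistent_with_members(self, default_scenario):
        ens = simulate_ensemble(default_scenario, "PFOS", n=20, seed=2)
        s = ens.summary("muscle")
        vals = ens.values("muscle")
        assert np.allclose(s["mean"].to_numpy(), vals.mean(axis=0))
        assert np.allclose(s["sd"].to_numpy(), vals.std(axis=0, ddof=1))
        assert np.allclose(s["q50"].to_numpy(), np.median(vals, axis=0))


class TestVdSensitivity:
    def test_factor_one_reproduces_baseline(self, default_scenario):
        base = simulate_ensemble(default_scenario, "PFOS", n=8, seed=5)
        sens = vd_sensitivity(default_scenario, "PFOS", factors=(1.0,), n=8, seed=5)
        assert np.array_equal(base.values("serum"), sens[1.0].values("serum"))

    def test_plateau_serum_inverse_in_vd(self):
        """At a constant-dose steady state serum scales as 1/Vd."""
        bw, dose = 500.0, 50_000.0
        lo = simulate_trajectory(
            np.full(2000, dose), np.full(2000, bw), TKDraw(50, 0.0425, 0.08, 0.015, 0.5)
        )
        mid = simulate_trajectory(
            np.full(2000, dose), np.full(2000, bw), TKDraw(50, 0.085, 0.08, 0.015, 0.5)
        )
        hi = simulate_trajectory(
            np.full(2000, dose), np.full(2000, bw), TKDraw(50, 0.17, 0.08, 0.015, 0.5)
        )
        assert hi["serum_ng_ml"].iloc[-1] == pytest.approx(
            0.5 * mid["serum_ng_ml"].iloc[-1], rel=1e-9
        )
        assert lo["serum_ng_ml"].iloc[-1] == pytest.approx(
            2.0 * mid["serum_ng_ml"].iloc[-1], rel=1e-9
        )
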