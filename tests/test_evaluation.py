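"""Agreement statistics, partition-coefficient meta-analysis, exceedance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdtk import (
    exceedance_fraction,
    fit_dt50_loglinear,
    fold_ratio,
    mape,
    meta_pm,
    percentage_error,
    plasma_to_serum,
    evaluate_scenario,
    simulate_ensemble,
    generate_biomonitoring,
)
from herdtk.poptk import Ensemble


def constant_ensemble(values, dates=None, analyte="PFOS"):
    """Ensemble whose draws are flat lines at the given values."""
    values = np.asarray(values, float)
    if dates is None:
        dates = pd.date_range("2021-01-01", periods=3, freq="D")
    mat = np.tile(values[:, None], (1, len(dates)))
    draws = pd.DataFrame({"dt50": np.full(len(values), 74.1)})
    return Ensemble(dates, draws, mat, 0.08 * mat, 0.015 * mat, mat, analyte)


class TestPlasmaToSerum:
    @pytest.mark.parametrize(
        "conc, analyte, expected", [(10.0, "PFOS", 10.60), (10.0, "PFDA", 10.47), (0.0, "PFOS", 0.0)]
    )
    def test_ratio_applied(self, conc, analyte, expected):
        assert plasma_to_serum(conc, analyte) == pytest.approx(expected)

    def test_unknown_analyte(self):
        with pytest.raises(KeyError):
            plasma_to_serum(1.0, "PFHxS")


class TestPercentageError:
    @pytest.mark.parametrize(
        "modeled, measured, expected",
        [(2.33, 2.87, -18.8), (256.0, 202.0, 26.7), (5.0, 5.0, 0.0)],
    )
    def test_signed_error(self, modeled, measured, expected):
        assert percentage_error(modeled, measured) == pytest.approx(expected, abs=0.05)

    def test_zero_measured_undefined(self):
        with pytest.raises(ValueError):
            percentage_error(1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(m=st.floats(0.01, 1e3), o=st.floats(0.01, 1e3))
    def test_agreement_with_fold_ratio(self, m, o):
        pe = percentage_error(m, o)
        r = fold_ratio(m, o)
        if m >= o:
            assert abs(pe) == pytest.approx(100 * (r - 1), rel=1e-9)
        else:
            assert abs(pe) == pytest.approx(100 * (1 - 1 / r), rel=1e-9)


class TestMape:
    def test_published_style_hand_value(self):
        assert mape([-19, -34, -29, 67, 68]) == pytest.approx(43.4)

    @pytest.mark.parametrize("errs, expected", [([0], 0.0), ([-7.0, 7.0], 7.0)])
    def test_degenerate_cases(self, errs, expected):
        assert mape(errs) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(errs=st.lists(st.floats(-100, 100), min_size=1, max_size=10))
    def test_sign_and_permutation_invariance(self, errs):
        flipped = [-e for e in errs]
        assert mape(errs) == pytest.approx(mape(flipped))
        assert mape(errs) == pytest.approx(mape(list(reversed(errs))))


class TestFoldRatio:
    @pytest.mark.parametrize(
        "m, o, expected", [(150.0, 89.1, 1.68), (3.0, 3.0, 1.0), (1.0, 4.0, 4.0)]
    )
    def test_symmetric_ratio(self, m, o, expected):
        assert fold_ratio(m, o) == pytest.approx(expected, abs=0.01)


class TestExceedance:
    def test_constructed_fraction(self):
        vals = np.concatenate([np.full(15, 5.0), np.full(85, 1.0)])
        ens = constant_ensemble(vals)
        assert exceedance_fraction(ens, "serum", 3.4, ens.dates[0]) == pytest.approx(0.15)

    def test_extreme_thresholds(self):
        ens = constant_ensemble(np.linspace(1, 2, 10))
        d = ens.dates[0]
        assert exceedance_fraction(ens, "serum", 0.0, d) == 1.0
        assert exceedance_fraction(ens, "serum", 99.0, d) == 0.0

    def test_monotone_in_threshold(self):
        ens = constant_ensemble(np.linspace(0.1, 10, 50))
        d = ens.dates[0]
        fr = [exceedance_fraction(ens, "serum", t, d) for t in np.linspace(0, 12, 30)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_date_outside_range(self):
        ens = constant_ensemble(np.ones(3))
        with pytest.raises(KeyError):
            exceedance_fraction(ens, "serum", 1.0, "1999-01-01")


class TestMetaPm:
    def test_identical_ratios_recovered_exactly(self):
        ds = {"one": pd.DataFrame({"tissue": [2.0, 1.6], "serum": [25.0, 20.0]})}
        out = meta_pm(ds)
        assert out["meta_mean"] == pytest.approx(0.08)
        assert out["between_sd"] == 0.0

    def test_weighted_mean_of_dataset_means(self):
        ds = {
            "a": pd.DataFrame({"tissue": np.full(10, 0.6), "serum": np.full(10, 10.0)}),
            "b": pd.DataFrame({"tissue": np.full(10, 1.0), "serum": np.full(10, 10.0)}),
        }
        assert meta_pm(ds)["meta_mean"] == pytest.approx(0.08)

    def test_plasma_dataset_converted_before_ratios(self):
        serum_ds = {"x": pd.DataFrame({"tissue": [0.8], "serum": [10.0]})}
        plasma_ds = {
            "x": pd.DataFrame({"tissue": [0.8], "serum": [10.0], "matrix": ["plasma"]})
        }
        base = meta_pm(serum_ds)["meta_mean"]
        conv = meta_pm(plasma_ds, analyte="PFOS")["meta_mean"]
        assert conv == pytest.approx(base / 1.060)

    def test_zero_serum_pairs_excluded_with_count(self):
        ds = {"x": pd.DataFrame({"tissue": [0.8, 0.5], "serum": [10.0, 0.0]})}
        out = meta_pm(ds)
        assert out["n_excluded"] == 1
        assert out["n_pairs"] == 1


class TestEvaluateScenario:
    def test_exact_match_gives_zero_errors(self):
        ens = constant_ensemble(np.full(10, 12.0))
        bio = pd.DataFrame(
            {
                "animal_id": ["A1", "A2"],
                "date": [ens.dates[1]] * 2,
                "matrix": ["serum"] * 2,
                "analyte": ["PFOS"] * 2,
                "conc": [12.0, 12.0],
            }
        )
        report = evaluate_scenario(ens, bio)
        assert report["pct_error"].iloc[0] == pytest.approx(0.0)
        assert report["fold_ratio"].iloc[0] == pytest.approx(1.0)

    def test_plasma_records_flagged_and_converted(self):
        ens = constant_ensemble(np.full(10, 10.60))
        bio = pd.DataFrame(
            {
                "animal_id": ["A1"],
                "date": [ens.dates[0]],
                "matrix": ["plasma"],
                "analyte": ["PFOS"],
                "conc": [10.0],
            }
        )
        report = evaluate_scenario(ens, bio)
        assert bool(report["plasma_converted"].iloc[0])
        assert report["measured_mean"].iloc[0] == pytest.approx(10.60)
        assert report["pct_error"].iloc[0] == pytest.approx(0.0)

    def test_date_outside_simulation_is_an_error(self):
        ens = constant_ensemble(np.ones(5))
        bio = pd.DataFrame(
            {
                "animal_id": ["A1"],
                "date": ["1999-01-01"],
                "matrix": ["serum"],
                "analyte": ["PFOS"],
                "conc": [1.0],
            }
        )
        with pytest.raises(ValueError, match="outside"):
            evaluate_scenario(ens, bio)

    def test_synthetic_truth_fixture_reproduces_hand_values(self, default_scenario):
        """Noise-free records from the known-parameter trajectory match the
        mean-parameter ensemble closely."""
        lh = default_scenario.life_history
        date = lh.end_date
        bio = generate_biomonitoring(
            default_scenario, [date], n_animals=3, noise_cv=0.0, seed=0,
            analytes=["PFOS"],
        )
        ens = simulate_ensemble(default_scenario, "PFOS", n=60, seed=3)
        report = evaluate_scenario(ens, bio)
        # measured equals the deterministic truth; the stochastic ensemble
        # mean should sit within ~25 % of it
        assert (report["fold_ratio"] < 1.35).all()


class TestDt50Fit:
    def test_recovers_exact_decay(self):
        days = pd.date_range("2022-01-01", periods=5, freq="28D")
        k = np.log(2) / 74.1
        conc = 30.0 * np.exp(-k * np.arange(0, 5 * 28, 28))
        rec = pd.DataFrame({"date": days, "conc": conc})
        fit = fit_dt50_loglinear(rec)
        assert fit["dt50_days"] == pytest.approx(74.1, rel=1e-9)

    def test_rising_series_not_estimable(self):
        days = pd.date_range("2022-01-01", periods=4, freq="10D")
        rec = pd.DataFrame({"date": days, "conc": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="no decline"):
            fit_dt50_loglinear(rec)
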