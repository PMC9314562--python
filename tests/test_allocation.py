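"""Age allocation of national mileage and the constrained e-bike split."""

import numpy as np
import pandas as pd
import pytest

from active_travel_hia import (
    AgeShape,
    allocate_mileage,
    build_reference_scenario,
    gen_age_distribution,
    mean_age_of_mileage,
    split_ebike,
)
from conftest import toy_demography


def traj_frame(**cols):
    return pd.DataFrame({"year": [2021], **{k: [v] for k, v in cols.items()}})


def dist_frame(shares, mode="cycle"):
    return pd.DataFrame({"mode": mode, "age": range(len(shares)), "share": shares})


class TestReferenceScenario:
    def test_freezes_every_column_at_base_year(self):
        traj = pd.DataFrame({"year": [2021, 2022, 2023],
                             "walk_km_pc": [6.0, 6.1, 6.2],
                             "cycle_km_pc": [2.4, 3.0, 4.0],
                             "ebike_share": [0.033, 0.1, 0.2]})
        ref = build_reference_scenario(traj, 2021)
        assert (ref["cycle_km_pc"] == 2.4).all()
        assert (ref["ebike_share"] == 0.033).all()
        assert list(ref["year"]) == [2021, 2022, 2023]

    def test_idempotent_on_constant_trajectory(self):
        traj = pd.DataFrame({"year": [2021, 2022], "cycle_km_pc": [2.4, 2.4]})
        pd.testing.assert_frame_equal(build_reference_scenario(traj, 2021), traj,
                                      check_dtype=False)

    def test_missing_base_year_rejected(self):
        with pytest.raises(ValueError, match="base year"):
            build_reference_scenario(pd.DataFrame({"year": [2022], "x": [1.0]}), 2021)


class TestAllocateMileage:
    def test_two_age_arithmetic(self):
        demo = toy_demography([2021], [100, 100], [0.01, 0.01])
        out = allocate_mileage(traj_frame(km=10.0), "km", dist_frame([0.8, 0.2]),
                               demo, "bike_total")
        assert list(out["km_pc"]) == [16.0, 4.0]
        # population-weighted mean recovers the national value
        assert np.average(out["km_pc"], weights=[100, 100]) == pytest.approx(10.0)

    def test_uniform_distribution_equal_populations_is_flat(self):
        demo = toy_demography([2021], [50, 50, 50, 50], [0.01] * 4)
        out = allocate_mileage(traj_frame(km=7.0), "km", dist_frame([0.25] * 4),
                               demo, "walk")
        assert np.allclose(out["km_pc"], 7.0)

    def test_population_proportional_distribution_is_flat(self):
        # d proportional to population -> per-capita uniform at the national value;
        # cross-checked by brute-force distribution of total kilometres
        demo = toy_demography([2021], [50, 100, 50], [0.01] * 3)
        out = allocate_mileage(traj_frame(km=8.0), "km", dist_frame([0.25, 0.5, 0.25]),
                               demo, "bike_total")
        total_km = 8.0 * 200
        brute = [total_km * d / n for d, n in zip([0.25, 0.5, 0.25], [50, 100, 50])]
        assert np.allclose(out["km_pc"], brute)
        assert np.allclose(out["km_pc"], 8.0)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_ages = rng.integers(3, 30)
            pops = rng.uniform(10, 1e5, n_ages)
            shares = rng.dirichlet(np.ones(n_ages))
            km = rng.uniform(0.1, 50)
            demo = toy_demography([2021], pops, np.full(n_ages, 0.01))
            out = allocate_mileage(traj_frame(km=km), "km", dist_frame(shares),
                                   demo, "walk")
            recovered = np.average(out["km_pc"], weights=pops)
            assert recovered == pytest.approx(km, rel=1e-9)

    def test_linear_in_national_trajectory(self):
        demo = toy_demography([2021], [30, 60, 10], [0.01] * 3)
        dist = dist_frame([0.5, 0.3, 0.2])
        one = allocate_mileage(traj_frame(km=5.0), "km", dist, demo, "walk")
        two = allocate_mileage(traj_frame(km=10.0), "km", dist, demo, "walk")
        assert np.allclose(two["km_pc"], 2 * one["km_pc"])

    def test_zero_population_with_positive_share_rejected(self):
        demo = toy_demography([2021], [100, 0], [0.01, 0.01])
        with pytest.raises(ValueError, match="zero population"):
            allocate_mileage(traj_frame(km=1.0), "km", dist_frame([0.5, 0.5]),
                             demo, "walk")


class TestMeanAge:
    @pytest.mark.parametrize("ages,km,pops,expected", [
        ([30], [5.0], [100], 30.0),                      # point mass
        ([20, 40], [1.0, 1.0], [100, 100], 30.0),        # midpoint
        ([20, 30, 40], [1.0, 2.0, 1.0], [10, 10, 10], 30.0),  # hand-computed
    ])
    def test_weighted_mean(self, ages, km, pops, expected):
        km_df = pd.DataFrame({"year": 2021, "age": ages, "km_pc": km})
        demo = pd.DataFrame({"year": 2021, "age": ages, "population": pops})
        assert mean_age_of_mileage(km_df, demo) == pytest.approx(expected)

    def test_zero_total_km_rejected(self):
        km_df = pd.DataFrame({"year": [2021], "age": [30], "km_pc": [0.0]})
        demo = pd.DataFrame({"year": [2021], "age": [30], "population": [10.0]})
        with pytest.raises(ValueError, match="zero"):
            mean_age_of_mileage(km_df, demo)


def _cycle_frame(ages, km):
    return pd.DataFrame({"year": 2021, "age": ages, "mode": "bike_total", "km_pc": km})


def _split(cycle, demo, share, gap, **kw):
    return split_ebike(cycle, pd.Series({2021: share}), gap, demo, **kw)


class TestSplitEbike:
    def test_two_age_closed_form(self):
        # equal km and population at ages 20 and 70: s20 + s70 = 1 and
        # gap = 50 - 100*s20, so gap 6.7 forces s20 = 0.433 exactly
        demo = pd.DataFrame({"year": 2021, "age": [20, 70], "population": [100.0, 100.0]})
        diag, rows = _split(_cycle_frame([20, 70], [1.0, 1.0]), demo, 0.5, 6.7)
        s = (rows.query("mode == 'bike_e'").set_index("age")["km_pc"]
             / _cycle_frame([20, 70], [1.0, 1.0]).set_index("age")["km_pc"])
        assert s[20] == pytest.approx(0.433, abs=1e-6)
        assert s[70] == pytest.approx(0.567, abs=1e-6)
        assert diag["achieved_age_gap"].iloc[0] == pytest.approx(6.7, abs=1e-3)

    def test_zero_gap_target_gives_flat_share(self):
        demo = pd.DataFrame({"year": 2021, "age": [20, 40, 70],
                             "population": [50.0, 80.0, 30.0]})
        diag, rows = _split(_cycle_frame([20, 40, 70], [2.0, 1.0, 0.5]), demo, 0.3, 0.0)
        assert diag["beta"].iloc[0] == 0.0
        e = rows.query("mode == 'bike_e'")["km_pc"].to_numpy()
        tot = _cycle_frame([20, 40, 70], [2.0, 1.0, 0.5])["km_pc"].to_numpy()
        assert np.allclose(e / tot, 0.3, atol=1e-12)

    def test_solver_recovery_on_randomized_unimodal_instances(self):
        rng = np.random.default_rng(3)
        ages = np.arange(0, 101)
        for _ in range(15):
            shape = AgeShape(rng.uniform(20, 50), rng.uniform(8, 30), rng.uniform(0.05, 0.5))
            km = gen_age_distribution("cycle", shape, 100)["share"].to_numpy() * 100
            pops = rng.uniform(1e3, 1e4, len(ages))
            demo = pd.DataFrame({"year": 2021, "age": ages, "population": pops})
            share = rng.uniform(0.1, 0.9)
            gap = rng.uniform(0.0, 10.0)
            diag, _ = _split(_cycle_frame(ages, km), demo, share, gap)
            assert diag["achieved_share"].iloc[0] == pytest.approx(share, abs=1e-6)
            if gap > 0:
                assert diag["achieved_age_gap"].iloc[0] == pytest.approx(gap, abs=0.05)
            assert diag["beta"].iloc[0] >= 0

    def test_split_additivity_exact(self, default_inputs):
        ages = np.arange(0, 111)
        dist = default_inputs.age_distribution.query("mode == 'cycle'")
        km = dist["share"].to_numpy() * 500
        demo = default_inputs.demography.query("year == 2021")
        _, rows = _split(_cycle_frame(ages, km), demo, 0.7, 6.7)
        total = rows.groupby("age")["km_pc"].sum().to_numpy()
        # classical = km - e by construction, so the sum is bit-exact
        assert np.array_equal(total, km)

    def test_degenerate_share_falls_back_to_constant(self, caplog):
        demo = pd.DataFrame({"year": 2021, "age": [20, 70], "population": [100.0, 100.0]})
        with caplog.at_level("WARNING"):
            diag, rows = _split(_cycle_frame([20, 70], [1.0, 1.0]), demo, 1.0, 6.7)
        assert "degenerate" in caplog.text
        assert np.isnan(diag["achieved_age_gap"].iloc[0])
        assert (rows.query("mode == 'bike_e'")["km_pc"] == 1.0).all()

    def test_calibrate_once_mode_holds_beta_fixed(self, default_inputs):
        ages = np.arange(0, 111)
        dist = default_inputs.age_distribution.query("mode == 'cycle'")
        demo = default_inputs.demography
        cycle = pd.concat([
            pd.DataFrame({"year": y, "age": ages, "mode": "bike_total",
                          "km_pc": dist["share"].to_numpy() * vol})
            for y, vol in [(2021, 100), (2022, 500)]], ignore_index=True)
        shares = pd.Series({2021: 0.1, 2022: 0.7})
        diag, _ = split_ebike(cycle, shares, 6.7, demo, enforce_gap_each_year=False)
        assert diag["beta"].nunique() == 1
        assert np.allclose(diag["achieved_share"], [0.1, 0.7], atol=1e-6)
        # beta calibrated in the larger-volume year, so its gap is exact there
        assert diag.set_index("year")["achieved_age_gap"][2022] == pytest.approx(6.7, abs=1e-3)
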