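import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from phenopipe.growth import GrowthFit, fit_growth
from phenopipe.water import (
    WaterReleaseParams,
    evaporation_estimates,
    fit_water_release,
    relative_response,
    soil_water_content,
    soil_water_potential,
    transpiration_traits,
    water_balance,
    water_content_from_potential,
)

VG = WaterReleaseParams(theta_r=0.05, theta_s=0.45, a_vg=25.0, n_vg=2.0)


class TestReleaseCurve:
    def test_saturation_limit(self):
        assert water_content_from_potential(0.0, VG) == pytest.approx(VG.theta_s)
        assert water_content_from_potential(-1e-9, VG) == pytest.approx(
            VG.theta_s, rel=1e-6)

    def test_strictly_decreasing_with_suction(self):
        psi = -np.geomspace(1e-3, 2.0, 100)
        theta = water_content_from_potential(psi, VG)
        # psi ordered from wet to dry
        assert np.all(np.diff(theta) < 0)

    def test_noiseless_fit_recovers_parameters(self):
        psi = -np.geomspace(0.01, 1.6, 20)
        theta = water_content_from_potential(psi, VG)
        fit = fit_water_release(theta, psi)
        assert fit.theta_r == pytest.approx(VG.theta_r, rel=1e-4)
        assert fit.theta_s == pytest.approx(VG.theta_s, rel=1e-4)
        assert fit.a_vg == pytest.approx(VG.a_vg, rel=1e-4)
        assert fit.n_vg == pytest.approx(VG.n_vg, rel=1e-4)

    def test_minimum_observation_count(self):
        with pytest.raises(ValueError):
            fit_water_release([0.4, 0.3], [-0.01, -0.5])


class TestPotentialInversion:
    def test_zero_at_saturation(self):
        assert soil_water_potential(VG.theta_s, VG) == pytest.approx(0.0)

    def test_round_trip(self):
        theta = np.linspace(VG.theta_r + 0.02, VG.theta_s, 50)
        psi = soil_water_potential(theta, VG)
        back = water_content_from_potential(psi, VG)
        np.testing.assert_allclose(back, theta, rtol=1e-10)

    def test_matches_bisection_oracle(self):
        """Closed-form inversion agrees with a numeric root of the
        forward curve at a mid-range content."""
        theta = 0.30
        psi = soil_water_potential(theta, VG)
        oracle = brentq(
            lambda x: water_content_from_potential(x, VG) - theta, -50.0, -1e-9,
            xtol=1e-12)
        assert psi == pytest.approx(oracle, rel=1e-8)

    def test_slightly_wet_clamped_with_flag(self):
        psi, flag = soil_water_potential(VG.theta_s + 0.001, VG, return_flags=True)
        assert psi == 0.0 and flag

    def test_far_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            soil_water_potential(VG.theta_s + 0.1, VG)

    def test_fit_recovery_under_noise(self):
        """1% content noise: parameters recovered within 5% relative in
        >= 95% of seeds."""
        ok = 0
        n_seeds = 60
        psi = np.tile(-np.geomspace(0.01, 1.6, 15), 5)  # five drying pots
        theta0 = water_content_from_potential(psi, VG)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            theta = theta0 * (1 + rng.normal(0, 0.01, theta0.size))
            try:
                f = fit_water_release(theta, psi)
            except RuntimeError:
                continue
            rel = max(abs(f.theta_r - VG.theta_r) / VG.theta_r,
                      abs(f.theta_s - VG.theta_s) / VG.theta_s,
                      abs(f.a_vg - VG.a_vg) / VG.a_vg,
                      abs(f.n_vg - VG.n_vg) / VG.n_vg)
            ok += rel < 0.05
        assert ok / n_seeds >= 0.95


class TestSoilWaterContent:
    def test_plain_arithmetic(self):
        # 300 g of water on 1500 g of dry soil
        theta = soil_water_content(200.0 + 1500.0 + 300.0, 200.0, 1500.0, 0.0)
        assert theta == pytest.approx(0.2)

    def test_plant_growth_reduces_inferred_content(self):
        t1 = soil_water_content(2500.0, 200.0, 1500.0, 10.0)
        t2 = soil_water_content(2500.0, 200.0, 1500.0, 80.0)
        assert t2 < t1

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="water mass"):
            soil_water_content(1600.0, 200.0, 1500.0, 0.0)


def simple_pot_log():
    rows = []
    for pid, art in [("p1", False), ("a1", True), ("a2", True)]:
        for i, d in enumerate([21.0, 23.0, 25.0]):
            before = 3000.0 - (10 + 4 * i if not art else 10)
            rows.append((pid, "well_watered", d, before, 3000.0,
                         3000.0 - before, art))
    return pd.DataFrame(rows, columns=["plant_id", "treatment", "time_d",
                                       "weight_before_g", "weight_after_g",
                                       "water_added_g", "is_artificial"])


class TestEvaporation:
    def test_mean_of_artificial_pots(self):
        logs = simple_pot_log()
        # make the two artificial pots lose 10 and 14 g
        logs.loc[(logs.plant_id == "a2") & (logs.time_d > 21),
                 "weight_before_g"] = 3000.0 - 14.0
        ev = evaporation_estimates(logs)
        assert ev["evaporation_g"].iloc[0] == pytest.approx(12.0)

    def test_no_artificial_pots_rejected(self):
        logs = simple_pot_log()
        with pytest.raises(ValueError):
            evaporation_estimates(logs[~logs.is_artificial])

    def test_drought_evaporation_below_well_watered(self, sim_clean):
        _, data = sim_clean
        ev = evaporation_estimates(data["pot_logs"])
        means = ev.groupby("treatment")["evaporation_g"].mean()
        assert means["drought"] < means["well_watered"]


class TestWaterBalance:
    def test_zero_evaporation_means_transpiration_equals_loss(self):
        logs = simple_pot_log()
        # artificial pots lose nothing
        logs.loc[logs.is_artificial, "weight_before_g"] = 3000.0
        logs.loc[logs.is_artificial, "water_added_g"] = 0.0
        bal = water_balance(logs, VG, 200.0, 2000.0, lambda pid, trt, t: 0.0)
        np.testing.assert_allclose(bal["transpiration_g"], bal["water_loss_g"])

    def test_negative_transpiration_floored_and_flagged(self):
        logs = simple_pot_log()
        # plant loses less than the artificial pots -> negative estimate
        logs.loc[(logs.plant_id == "p1"), "weight_before_g"] = 2998.0
        logs.loc[(logs.plant_id == "p1") & (logs.time_d == 21.0),
                 "weight_before_g"] = 3000.0
        bal = water_balance(logs, VG, 200.0, 2000.0, lambda pid, trt, t: 0.0)
        assert (bal["transpiration_g"] >= 0).all()
        assert bal["floored"].any()

    def test_internal_closure_identity(self, result_clean):
        """water loss decomposes exactly into transpiration +
        evaporation for every interval (no flooring on clean data)."""
        bal = result_clean.water_balance
        assert not bal["floored"].any()
        np.testing.assert_allclose(
            bal["water_loss_g"],
            bal["transpiration_g"] + bal["evaporation_g"], atol=1e-8)

    def test_soil_potential_negative_and_ordered(self, result_clean):
        bal = result_clean.water_balance
        assert (bal["psi_mean"] <= 0).all()
        means = bal.groupby("treatment")["psi_mean"].mean()
        assert means["drought"] < means["well_watered"]


class TestTranspirationTraits:
    def make_fits(self, slope=0.12, leaf_area=20_000.0):
        t = np.linspace(20, 62, 22)
        bio = fit_growth(t, slope * t, "linear")
        la = fit_growth(t, np.full(t.size, leaf_area) + 1e-6 * t, "linear")
        return bio, la

    def make_balance(self, total=600.0, n=6):
        t = np.linspace(33.0, 53.0, n + 1)
        per = total * np.diff(t) / (t[-1] - t[0])
        # intervals span [33, 53]; the window [35, 50] takes a pro-rata cut
        return pd.DataFrame({
            "plant_id": "p", "treatment": "ww",
            "t_start": t[:-1], "t_end": t[1:],
            "water_loss_g": per + 2.0, "evaporation_g": 2.0,
            "transpiration_g": per,
            "psi_mean": -0.03, "floored": False, "evap_carried": False,
            "theta_clamped": False,
        })

    def test_worked_wue_example(self):
        """15 d window, 600 g transpired, 1.8 g biomass gain -> WUE 0.003."""
        bio, la = self.make_fits(slope=0.12)          # gains 1.8 g over 15 d
        bal = self.make_balance(total=600.0 * 20.0 / 15.0)  # 600 g inside window
        out = transpiration_traits(bal, lambda d: d, bio, la, (35.0, 50.0))
        assert out["total_transpiration_g"] == pytest.approx(600.0, rel=1e-9)
        assert out["WUE"] == pytest.approx(0.003, rel=1e-9)
        assert out["TR"] == pytest.approx(40.0, rel=1e-9)

    def test_identity_growth_equals_wue_times_tr(self):
        bio, la = self.make_fits()
        bal = self.make_balance()
        out = transpiration_traits(bal, lambda d: d, bio, la, (35.0, 50.0))
        assert out["WUE"] * out["TR"] == pytest.approx(0.12, abs=1e-10)

    def test_doubling_leaf_area_halves_tr_area(self):
        bio, la1 = self.make_fits(leaf_area=20_000.0)
        _, la2 = self.make_fits(leaf_area=40_000.0)
        bal = self.make_balance()
        o1 = transpiration_traits(bal, lambda d: d, bio, la1, (35.0, 50.0))
        o2 = transpiration_traits(bal, lambda d: d, bio, la2, (35.0, 50.0))
        assert o2["TR_area"] == pytest.approx(o1["TR_area"] / 2, rel=1e-6)

    def test_pro_rata_totals_conserved(self):
        """A window covering all intervals exactly reproduces the summed
        transpiration."""
        bio, la = self.make_fits()
        bal = self.make_balance(total=500.0)
        out = transpiration_traits(bal, lambda d: d, bio, la, (33.0, 53.0))
        assert out["total_transpiration_g"] == pytest.approx(500.0, rel=1e-12)

    def test_too_few_overlapping_intervals_rejected(self):
        bio, la = self.make_fits()
        bal = self.make_balance().iloc[:1]
        with pytest.raises(ValueError, match="intervals"):
            transpiration_traits(bal, lambda d: d, bio, la, (35.0, 50.0))


class TestRelativeResponse:
    def test_zero_when_values_equal(self):
        resp, undef = relative_response(1.0, 1.0, -0.02, -0.05)
        assert resp == 0.0 and not undef

    def test_hand_computed_example(self):
        # value halves as psi drops from -0.02 to -0.05 MPa
        resp, _ = relative_response(1.0, 0.5, -0.02, -0.05)
        assert resp == pytest.approx((0.5 - 1.0) / (-0.05 + 0.02), rel=1e-12)
        assert resp == pytest.approx(16.667, rel=1e-3)

    def test_antisymmetric_under_treatment_swap(self):
        r1, _ = relative_response(1.0, 0.4, -0.02, -0.05)
        r2, _ = relative_response(0.4, 1.0, -0.05, -0.02)
        assert r1 == pytest.approx(r2)

    def test_undefined_when_potentials_coincide(self):
        resp, undef = relative_response(1.0, 0.5, -0.030, -0.032)
        assert undef and np.isnan(resp)
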