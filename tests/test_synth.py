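"""Synthetic trial-data generators: determinism, structure and round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from phenokit.competition import HyperbolicModel
from phenokit.emergence import EmergenceModel
from phenokit.fecundity import (calibrate, estimate_plant,
                                fecundity_ratio_test, parse_length_list)
from phenokit.growth import GrowthModel, suppression_ratio
from phenokit.phenology import mc_permutation_test
from phenokit.synth import (gen_biomass, gen_competition, gen_emergence,
                            gen_fecundity, gen_stage_intervals, gen_weather,
                            sample_emergence_times, scenario, write_scenario)
from phenokit.thermal import accumulate


@pytest.fixture(scope="module")
def cfg():
    return scenario("table1-2017")


def test_scenario_registry_roundtrip():
    for name in ("table1-2017", "table1-2019", "table3-2019", "table5-2017"):
        c = scenario(name)
        c.validate()
    with pytest.raises(KeyError):
        scenario("no-such-scenario")


class TestWeather:
    def test_passes_thermal_validation_and_accumulates(self, cfg):
        df = gen_weather(cfg, np.random.default_rng(1))
        for source in ("air", "soil"):
            series = accumulate(df, origin=cfg.sowing_date, source=source)
            vals = series.values.to_numpy()
            assert np.all(np.diff(vals) >= 0)
            assert len(series) == cfg.n_days

    def test_summer_warmer_than_winter(self, cfg):
        df = gen_weather(cfg, np.random.default_rng(2))
        air = df[df.source == "air"].copy()
        air["date"] = pd.to_datetime(air["date"])
        air["mean"] = (air.tmin_c + air.tmax_c) / 2
        month = air["date"].dt.month
        summer = air.loc[month.isin([6, 7]), "mean"].mean()
        winter = air.loc[month.isin([1, 2]), "mean"].mean()
        assert summer > winter + 5


class TestEmergence:
    def test_event_time_law(self):
        """Empirical CDF at the half-emergence time is ~0.5 for N=1e4."""
        t = sample_emergence_times(-5.0, 197.0, 10000,
                                   np.random.default_rng(3))
        frac = np.mean(t <= 197.0)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_round_trip_recovery(self, cfg):
        df = gen_emergence(cfg, np.random.default_rng(4))
        sub = df[df.species == "V. myuros"]
        res = EmergenceModel.from_dataframe(sub, use_censoring=True).fit()
        assert abs(res.b - (-5.0)) < 3 * res.bse["b"]
        assert abs(res.g50 - 197.0) < 3 * res.bse["g50"]

    def test_zero_seeds_give_zero_counts(self, cfg):
        import dataclasses
        empty = dataclasses.replace(cfg, seeds_per_unit=0)
        df = gen_emergence(empty, np.random.default_rng(5))
        assert (df.cum_count == 0).all()


class TestBiomass:
    def test_round_trip_recovers_suppression_ratio(self, cfg):
        df = gen_biomass(cfg, np.random.default_rng(6))
        sub = df[df.species == "V. myuros"]
        fits = {crop: GrowthModel.from_dataframe(g, "weibull").fit()
                for crop, g in sub.groupby("crop")}
        r = suppression_ratio(fits[0], fits[1])
        # generating truth: 1.5 / 14.8
        assert r.ratio == pytest.approx(1.5 / 14.8, abs=0.05)

    def test_zero_noise_exact_refit(self, cfg):
        import dataclasses
        clean = dataclasses.replace(cfg, growth_noise_frac=0.0)
        df = gen_biomass(clean, np.random.default_rng(7))
        sub = df[(df.species == "V. myuros") & (df.crop == 0)]
        res = GrowthModel.from_dataframe(sub, "weibull").fit()
        assert res.d == pytest.approx(14.8, rel=1e-3)

    def test_nonnegative(self, cfg):
        df = gen_biomass(cfg, np.random.default_rng(8))
        assert (df.dm_per_plant_g >= 0).all()


class TestStages:
    def test_intervals_bracket_on_grid(self, cfg):
        df = gen_stage_intervals(cfg, np.random.default_rng(9))
        assert ((df.tt_hi_c - df.tt_lo_c) == cfg.stage_grid_step).all()
        assert (df.tt_lo_c >= 0).all()
        assert (df.tt_lo_c % cfg.stage_grid_step == 0).all()

    def test_wider_grid_widens_intervals(self, cfg):
        import dataclasses
        wide = dataclasses.replace(cfg, stage_grid_step=200.0)
        df_narrow = gen_stage_intervals(cfg, np.random.default_rng(10))
        df_wide = gen_stage_intervals(wide, np.random.default_rng(10))
        assert ((df_wide.tt_hi_c - df_wide.tt_lo_c).mean()
                > (df_narrow.tt_hi_c - df_narrow.tt_lo_c).mean())

    def test_equal_mean_species_null_rejection(self, cfg):
        """Two species with identical stage means reject at ~5%."""
        import dataclasses
        means = {"spA": {51: 1200}, "spB": {51: 1200}}
        null_cfg = dataclasses.replace(cfg, stage_means=means)
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            df = gen_stage_intervals(null_cfg, np.random.default_rng(100 + k))
            a = df[df.species == "spA"]
            b = df[df.species == "spB"]
            res = mc_permutation_test(a.tt_lo_c, a.tt_hi_c, b.tt_lo_c,
                                      b.tt_hi_c, n_iter=200, seed=500 + k)
            rejections += res.pvalue <= 0.05
        assert rejections / n_rep <= 0.09


class TestFecundity:
    def test_calibration_recovers_slope(self, cfg):
        calib, _ = gen_fecundity(cfg, np.random.default_rng(11))
        sub = calib[calib.species == "V. myuros"]
        cal = calibrate(sub.length_cm, sub.seed_count)
        resid = sub.seed_count - (cal.slope * sub.length_cm + cal.intercept)
        s2 = (resid @ resid) / (len(sub) - 2)
        se = np.sqrt(s2 / ((sub.length_cm - sub.length_cm.mean()) ** 2).sum())
        assert abs(cal.slope - 50.0) < 3 * se

    def test_configured_suppression_recovered(self, cfg):
        """The generating ratio lands inside the bootstrap CI in >=90% of
        seeded runs."""
        hits = 0
        n_rep = 30
        for k in range(n_rep):
            gen = np.random.default_rng(200 + k)
            calib, plants = gen_fecundity(cfg, gen)
            cal = calibrate(calib[calib.species == "V. myuros"].length_cm,
                            calib[calib.species == "V. myuros"].seed_count)
            sub = plants[plants.species == "V. myuros"]
            seeds = {
                crop: np.array([estimate_plant(cal, parse_length_list(v))
                                for v in g.panicle_lengths])
                for crop, g in sub.groupby("crop")
            }
            res = fecundity_ratio_test(seeds[0], seeds[1], n_perm=50,
                                       n_boot=500, seed=300 + k)
            hits += res.ci_lo <= 0.11 <= res.ci_hi
        assert hits / n_rep >= 0.9


class TestCompetition:
    def test_zero_density_cell_near_a(self, cfg):
        df = gen_competition(cfg, np.random.default_rng(12))
        cell = df[(df.species == "V. myuros") & (df.crop_stage == "2-leaf")
                  & (df.harvest == "BBCH 81-90") & (df.response_type == "dm_g")]
        at_zero = cell[cell.density_m2 == 0].response
        assert at_zero.mean() == pytest.approx(20.0, abs=4.0)

    def test_round_trip_fit(self, cfg):
        df = gen_competition(cfg, np.random.default_rng(13))
        cell = df[(df.species == "V. myuros") & (df.crop_stage == "2-leaf")
                  & (df.harvest == "BBCH 26-29") & (df.response_type == "dm_g")]
        res = HyperbolicModel.from_dataframe(cell).fit()
        assert res.converged
        assert abs(res.dens50 - 104.0) / 104.0 < 0.5


def test_write_scenario_byte_identical(tmp_path, cfg):
    """Same (config, seed) regenerates byte-identical files."""
    m1 = write_scenario(cfg, 123, tmp_path / "a")
    m2 = write_scenario(cfg, 123, tmp_path / "b")
    assert m1["files"] == m2["files"]
    for fname in m1["files"].values():
        assert ((tmp_path / "a" / fname).read_bytes()
                == (tmp_path / "b" / fname).read_bytes())
    manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
    assert manifest["seed"] == 123
    assert "truth" in manifest
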