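"""Generator contracts: shapes, reproducibility, bias convergence, closure."""

import numpy as np
import pandas as pd
import pytest

import thermopheno as tp
from thermopheno.degree_days import GDDParams
from thermopheno.synthetic_data import (LocationClimate, SyntheticWorldConfig,
                                        default_thresholds, true_ranks)


def test_default_world_matches_study_shape(default_world):
    world = default_world
    obs = world.observations
    assert obs["location_id"].nunique() == 22
    assert sorted(obs["date"].dt.year.unique()) == [2008, 2009, 2010]
    assert 700 <= len(obs) <= 900  # ~800 observations
    # gap-free daily coverage incl. the 2008 leap year
    days = world.station.groupby(
        [world.station["location_id"], world.station["date"].dt.year]
    ).size()
    assert set(days.unique()) == {365, 366}
    assert len(world.station) == 22 * (366 + 365 + 365)


def test_reproducible_given_seed():
    a = tp.generate_world(seed=4)
    b = tp.generate_world(seed=4)
    pd.testing.assert_frame_equal(a.station, b.station)
    pd.testing.assert_frame_equal(a.observations, b.observations)
    c = tp.generate_world(seed=5)
    assert not a.station["tmin"].equals(c.station["tmin"])


def test_zero_amplitude_zero_noise_constant_weather():
    loc = LocationClimate("flat", 15.0, 0.0, 8.0, 0.0, 0.0, 0.5)
    cfg = SyntheticWorldConfig(locations=(loc,), years=(2009,),
                               thresholds=default_thresholds(6.0))
    weather = tp.generate_weather(cfg)
    assert np.allclose(weather["tmin"], 11.0)
    assert np.allclose(weather["tmax"], 19.0)


def test_era5_zero_bias_identical_series(default_world):
    cfg = default_world.config
    loc0 = cfg.locations[0]
    unbiased = SyntheticWorldConfig(
        locations=(LocationClimate(loc0.location_id, loc0.annual_mean,
                                   loc0.amplitude, loc0.diurnal_range,
                                   loc0.noise_sd, loc0.ar1, 0.0),),
        years=cfg.years, thresholds=cfg.thresholds, seed=cfg.seed)
    station = tp.generate_weather(unbiased)
    era5 = tp.generate_era5_like(station, unbiased)
    np.testing.assert_allclose(era5["tmin"], station["tmin"])
    np.testing.assert_allclose(era5["tmax"], station["tmax"])
    assert (era5["source"] == "era5").all()


def test_positive_offset_gdd_strictly_above():
    """+1 °C offset: ERA5 cumulative GDD above station at every DOY
    (base below every tmin, so daily degree-days shift by exactly 1)."""
    loc = LocationClimate("warm", 15.0, 3.0, 6.0, 0.5, 0.3, 1.0)
    cfg = SyntheticWorldConfig(locations=(loc,), years=(2009,),
                               thresholds=default_thresholds(6.0), seed=8)
    station = tp.generate_weather(cfg)
    era5 = tp.generate_era5_like(station, cfg)
    base = float(min(station["tmin"].min(), era5["tmin"].min())) - 1.0
    base = max(base, 0.0)
    g_st = tp.accumulate_gdd(station, GDDParams(base, "allen"))
    g_e5 = tp.accumulate_gdd(era5, GDDParams(base, "allen"))
    assert np.all(g_e5["cum_gdd"].to_numpy() > g_st["cum_gdd"].to_numpy())


def test_relative_error_converges_per_location(default_world):
    """Late-season relative error flattens: sd < 20% of its mean, per location."""
    world = default_world
    for method in ("tavg", "allen"):
        g_st = tp.accumulate_gdd(world.station, GDDParams(10.0, method))
        g_e5 = tp.accumulate_gdd(world.era5, GDDParams(10.0, method))
        comp = tp.gdd_source_comparison(g_st, g_e5)
        conv = tp.relative_error_convergence(comp, doy_range=(180, 365))
        assert (conv["cv"] < 0.20).all(), conv

    # and the bias never cancels: same sign as the injected offset
    offsets = world.truth()["era5_offsets"]
    signs = conv.set_index("location_id")["mean"]
    for loc_id, off in offsets.items():
        assert np.sign(signs[loc_id]) == np.sign(off)


def test_true_ranks_threshold_semantics():
    th = [100.0, 200.0, 300.0]
    assert list(true_ranks([50, 100, 250, 400], th)) == [1, 1, 2, 3]


def test_ranks_nondecreasing_without_noise():
    cfg = tp.default_config(n_locations=4, years=(2009,), seed=6, p_noise=0.0)
    world = tp.generate_world(cfg)
    for _, grp in world.observations.sort_values("date").groupby("location_id"):
        assert np.all(np.diff(grp["rank"]) >= 0)


def test_noiseless_closure_single_point_bands():
    """One visit per stage band: the threshold benchmark reproduces every
    observation exactly (accuracy 1.0)."""
    loc = LocationClimate("solo", 14.0, 8.0, 9.0, 0.0, 0.0, 0.0)
    base_cfg = SyntheticWorldConfig(locations=(loc,), years=(2009,),
                                    thresholds=default_thresholds(6.0),
                                    p_noise=0.0, visit_jitter=0, seed=0)
    station = tp.generate_weather(base_cfg)
    gdd = tp.accumulate_gdd(station, GDDParams(6.0, "allen"))
    # place one threshold just below the accumulation at each visit date
    visit_dates = [pd.Timestamp("2009-01-01") + pd.Timedelta(days=d - 1)
                   for d in base_cfg.visit_doys]
    cums = np.sort([tp.gdd_at(gdd, "solo", d) for d in visit_dates])
    thresholds = tuple(np.unique(cums - 1e-6))
    rank_map = tp.BBCHRankMap(tuple(f"S{k:02d}" for k in
                                    range(1, len(thresholds) + 1)))
    cfg = SyntheticWorldConfig(locations=(loc,), years=(2009,),
                               thresholds=thresholds, p_noise=0.0,
                               visit_jitter=0, seed=0)
    obs = tp.generate_phenology(station, cfg, rank_map)
    table = tp.build_feature_table(obs, [gdd], ["GDD_allen"])
    model = tp.BaselineModel().fit(table)
    assert tp.score(model.predict(table), table["rank"]).accuracy == 1.0


def test_noiseless_default_world_high_accuracy():
    """Multi-location bands overlap, so closure is high but not exact."""
    cfg = tp.default_config(seed=2, p_noise=0.0)
    world = tp.generate_world(cfg)
    gdd = tp.accumulate_gdd(world.station,
                            GDDParams(cfg.base_temp_true, "allen"))
    table = tp.build_feature_table(world.observations, [gdd], ["GDD_allen"])
    model = tp.BaselineModel().fit(table)
    rep = tp.score(model.predict(table), table["rank"])
    assert rep.accuracy > 0.5


def test_visit_outside_coverage_rejected():
    cfg = tp.default_config(n_locations=2, years=(2009,), seed=1)
    world = tp.generate_world(cfg)
    truncated = world.station[world.station["date"] < "2009-06-01"]
    with pytest.raises(ValueError, match="coverage"):
        tp.generate_phenology(truncated, cfg)


def test_config_validation():
    loc = LocationClimate("x", 14.0, 8.0, 9.0, 1.0, 0.5, 0.5)
    with pytest.raises(ValueError, match="increasing"):
        SyntheticWorldConfig(locations=(loc,), thresholds=(5.0, 5.0))
    with pytest.raises(ValueError, match="p_noise"):
        SyntheticWorldConfig(locations=(loc,),
                             thresholds=default_thresholds(6.0), p_noise=0.6)
    with pytest.raises(ValueError, match="diurnal"):
        LocationClimate("y", 14.0, 8.0, 0.0, 1.0, 0.5, 0.5)


def test_thresholds_scale_with_true_base():
    low = default_thresholds(0.0)
    high = default_thresholds(10.0)
    assert low[-1] > high[-1]  # more heat accumulates above a lower base
    assert len(low) == len(high) == 20
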