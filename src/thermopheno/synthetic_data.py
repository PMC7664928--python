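"""Synthetic worlds: paired station/reanalysis weather + threshold phenology.

The generator emulates the structure of a regional olive-phenology
monitoring campaign: a couple of dozen locations observed over a few years,
each with a nearby weather station recording daily Tmin/Tmax, a paired
"ERA5-like" gridded series that carries a location-specific systematic
temperature bias, and repeated orchard visits whose recorded BBCH stage is
driven by a latent cumulative-GDD threshold process plus observation noise.

Daily mean temperature at location ℓ on day-of-year d is

    T(d) = annual_mean_ℓ + amplitude_ℓ · sin(2π (d − lag)/365) + ε(d)

with AR(1) noise ε; tmin/tmax are mean ∓ half the (fixed) diurnal range.
The ERA5-like series is the station series shifted by a per-location
additive offset, which makes the cumulative-GDD relative error converge to
a per-location constant late in the season.

Ground truth: the true rank at a visit is the number of thresholds
θ*₁ < … < θ*_K (on cumulative single-sine GDD at the true base temperature)
that the accumulation has crossed, at least 1; the observed rank is shifted
by ±1 with probability ``p_noise``.

All defaults mirror a Tuscany-like campaign: 22 locations × 3 years × 12
visits ≈ 800 observations, annual mean ≈ 14 °C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degree_days import ERA5, STATION, GDDParams, accumulate_gdd
from .phenology_targets import BBCHRankMap, default_olive_rank_map, encode_ranks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocationClimate:
    """Per-location climatology and reanalysis bias."""

    location_id: str
    annual_mean: float      # °C
    amplitude: float        # °C, seasonal half-range
    diurnal_range: float    # °C, tmax - tmin (constant, > 0)
    noise_sd: float         # °C, marginal sd of AR(1) day-to-day noise
    ar1: float              # AR(1) coefficient in [0, 1)
    era5_offset: float      # °C, additive bias of the ERA5-like series

    def __post_init__(self) -> None:
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be > 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


def climatological_annual_gdd(base_temp: float, annual_mean: float = 14.0,
                              amplitude: float = 8.0,
                              diurnal_range: float = 9.0,
                              season_lag: float = 110.0) -> float:
    """Noise-free annual cumulative single-sine GDD of the nominal climate.

    Used to anchor default development thresholds: a plant traverses its
    whole stage scale over one season, so the thresholds live on the scale
    of the seasonal heat total at the organism's own base temperature.
    """
    from .degree_days import daily_dd_allen

    doy = np.arange(1, 366, dtype=float)
    mean_t = annual_mean + amplitude * np.sin(2 * np.pi * (doy - season_lag) / 365.0)
    return float(np.sum(daily_dd_allen(mean_t - diurnal_range / 2.0,
                                       mean_t + diurnal_range / 2.0, base_temp)))


#: Default positions of the K=20 stage thresholds as fractions of the
#: climatological annual GDD total at the true base temperature.
DEFAULT_THRESHOLD_FRACTIONS = tuple(np.linspace(0.02, 0.90, 20))


def default_thresholds(base_temp_true: float, n_ranks: int = 20) -> tuple:
    """Stage thresholds spanning the season at the given true base temp."""
    total = climatological_annual_gdd(base_temp_true)
    fracs = np.linspace(0.02, 0.90, n_ranks)
    return tuple(float(f * total) for f in fracs)


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Full specification of one synthetic world.

    ``thresholds`` are the K strictly increasing cumulative-GDD levels (°C·day,
    single-sine method at ``base_temp_true``) at which the plant advances one
    rank; ``visit_doys`` the nominal orchard-visit days of year (jittered by
    ±``visit_jitter`` days per location-year).
    """

    locations: tuple            # of LocationClimate
    years: tuple = (2008, 2009, 2010)
    season_lag: float = 110.0   # sin peak near DOY 201 (late July)
    base_temp_true: float = 6.0
    thresholds: tuple = tuple(np.linspace(60.0, 2600.0, 20))
    p_noise: float = 0.1
    visit_doys: tuple = tuple(int(d) for d in np.linspace(20, 340, 12))
    visit_jitter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if not 0 <= self.p_noise < 0.5:
            raise ValueError("p_noise must be in [0, 0.5)")

    @property
    def n_ranks(self) -> int:
        return len(self.thresholds)


def default_config(n_locations: int = 22, years=(2008, 2009, 2010),
                   seed: int = 0, **overrides) -> SyntheticWorldConfig:
    """A Tuscany-like default world; location parameters drawn from ``seed``.

    Annual means ~N(14, 1.5) °C, seasonal amplitudes ~N(8, 0.8) °C, diurnal
    ranges ~U(7, 11) °C, day-to-day AR(1) noise sd 2.5 °C (coefficient 0.6),
    ERA5 offsets ±U(0.4, 1.6) °C with random sign (a grid-cell bias at a
    point location is systematic and rarely negligible, and it can fall on
    either side of the station).  Unless explicitly overridden, the stage
    thresholds are placed at fixed fractions of the climatological annual
    GDD total at ``base_temp_true`` (see :func:`default_thresholds`), so the
    full stage scale is traversed each season whatever the true base is.
    Keyword overrides go to the config (e.g. ``base_temp_true=4.0``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    locs = []
    for i in range(n_locations):
        locs.append(LocationClimate(
            location_id=f"loc{i + 1:02d}",
            annual_mean=float(rng.normal(14.0, 1.5)),
            amplitude=float(rng.normal(8.0, 0.8)),
            diurnal_range=float(rng.uniform(7.0, 11.0)),
            noise_sd=2.5,
            ar1=0.6,
            era5_offset=float(rng.choice([-1, 1]) * rng.uniform(0.4, 1.6)),
        ))
    if "thresholds" not in overrides:
        base = overrides.get("base_temp_true", 6.0)
        overrides["thresholds"] = default_thresholds(base)
    return SyntheticWorldConfig(locations=tuple(locs), years=tuple(years),
                                seed=seed, **overrides)


def generate_weather(config: SyntheticWorldConfig) -> pd.DataFrame:
    """Gap-free daily station Tmin/Tmax for every location-year."""
    frames = []
    for li, loc in enumerate(config.locations):
        for year in config.years:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 11, li, int(year)]))
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy(float)
            seasonal = loc.annual_mean + loc.amplitude * np.sin(
                2 * np.pi * (doy - config.season_lag) / 365.0)
            if loc.noise_sd > 0:
                innov_sd = loc.noise_sd * np.sqrt(1.0 - loc.ar1 ** 2)
                eps = np.empty(len(doy))
                eps[0] = rng.normal(0.0, loc.noise_sd)
                shocks = rng.normal(0.0, innov_sd, size=len(doy) - 1)
                for t in range(1, len(doy)):
                    eps[t] = loc.ar1 * eps[t - 1] + shocks[t - 1]
            else:
                eps = np.zeros(len(doy))
            mean_t = seasonal + eps
            frames.append(pd.DataFrame({
                "location_id": loc.location_id,
                "date": dates,
                "tmin": mean_t - loc.diurnal_range / 2.0,
                "tmax": mean_t + loc.diurnal_range / 2.0,
                "source": STATION,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_era5_like(station: pd.DataFrame,
                       config: SyntheticWorldConfig) -> pd.DataFrame:
    """ERA5-like series: station temperatures plus a per-location offset.

    A constant additive temperature offset shifts every day's degree-day
    contribution in the same direction, so the cumulative-GDD relative error
    against the station series settles to a per-location constant once
    substantial heat has accumulated.
    """
    offsets = {loc.location_id: loc.era5_offset for loc in config.locations}
    era5 = station.copy()
    shift = era5["location_id"].map(offsets).to_numpy(float)
    era5["tmin"] = era5["tmin"] + shift
    era5["tmax"] = era5["tmax"] + shift
    era5["source"] = ERA5
    return era5


def true_ranks(cum_gdd, thresholds) -> np.ndarray:
    """Rank = number of thresholds crossed, floored at 1."""
    th = np.asarray(thresholds, dtype=float)
    r = np.searchsorted(th, np.asarray(cum_gdd, dtype=float), side="right")
    return np.maximum(r, 1)


def generate_phenology(station: pd.DataFrame, config: SyntheticWorldConfig,
                       rank_map: BBCHRankMap | None = None) -> pd.DataFrame:
    """Visit observations with threshold-process targets and ±1 rank noise.

    Truth is computed on the *station* series with the single-sine method at
    ``config.base_temp_true``.  Returns rank-encoded observations
    (``location_id, date, bbch_code, rank``) with ``n_ranks`` in ``.attrs``.
    """
    rank_map = rank_map or default_olive_rank_map()
    if rank_map.n_ranks != config.n_ranks:
        raise ValueError("rank map size must match the number of thresholds")
    gdd = accumulate_gdd(
        station, GDDParams(base_temp=config.base_temp_true, method="allen"))
    gdd_idx = gdd.set_index(["location_id", "date"])["cum_gdd"]

    rows = []
    for li, loc in enumerate(config.locations):
        for year in config.years:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 13, li, int(year)]))
            year_len = pd.Timestamp(f"{year}-12-31").dayofyear
            for doy in config.visit_doys:
                d = doy + int(rng.integers(-config.visit_jitter,
                                           config.visit_jitter + 1))
                d = min(max(d, 1), year_len)
                date = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=d - 1)
                try:
                    cum = float(gdd_idx.loc[(loc.location_id, date)])
                except KeyError:
                    raise ValueError(
                        f"visit {loc.location_id} {date.date()} outside "
                        "weather coverage") from None
                rank = int(true_ranks(cum, config.thresholds))
                if config.p_noise > 0 and rng.random() < config.p_noise:
                    rank += int(rng.choice([-1, 1]))
                    rank = min(max(rank, 1), config.n_ranks)
                rows.append({"location_id": loc.location_id, "date": date,
                             "bbch_code": rank_map.code_of(rank)})
    obs = pd.DataFrame(rows)
    obs = encode_ranks(obs, rank_map)
    obs.attrs["n_ranks"] = rank_map.n_ranks
    return obs


@dataclass
class SyntheticWorld:
    """A complete generated world plus its ground truth."""

    config: SyntheticWorldConfig
    station: pd.DataFrame
    era5: pd.DataFrame
    observations: pd.DataFrame
    rank_map: BBCHRankMap

    @property
    def weather(self) -> pd.DataFrame:
        """Station and ERA5-like rows in one table."""
        return pd.concat([self.station, self.era5], ignore_index=True)

    def truth(self) -> dict:
        return {
            "base_temp_true": self.config.base_temp_true,
            "thresholds": list(self.config.thresholds),
            "p_noise": self.config.p_noise,
            "era5_offsets": {loc.location_id: loc.era5_offset
                             for loc in self.config.locations},
        }


def generate_world(config: SyntheticWorldConfig | None = None,
                   rank_map: BBCHRankMap | None = None,
                   seed: int = 0) -> SyntheticWorld:
    """Generate station + ERA5-like weather and phenology in one call."""
    config = config or default_config(seed=seed)
    rank_map = rank_map or default_olive_rank_map()
    station = generate_weather(config)
    era5 = generate_era5_like(station, config)
    observations = generate_phenology(station, config, rank_map)
    logger.info("synthetic world: %d locations, %d years, %d observations",
                len(config.locations), len(config.years), len(observations))
    return SyntheticWorld(config, station, era5, observations, rank_map)
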