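"""Base-temperature optimisation by grid search with resampled CIs.

For every candidate base temperature the whole thermal-time pipeline is
re-run: GDD features are recomputed at that base, the scenario's model is
re-fitted over repeated stratified splits, and the mean, standard error and
confidence interval of each metric are recorded.  The same split sequence is
used at every grid point (paired resampling), so the metric-vs-temperature
curves are not confounded by split noise.  Per metric the optimum is the
grid member with maximum mean accuracy / minimum mean RMSE / minimum mean
combined metric; ties resolve to the lower temperature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .degree_days import ERA5, STATION, GDDParams, accumulate_gdd, validate_weather
from .evaluation import METRICS, SplitSpec, resample_evaluate
from .phenology_targets import FEATURE_DOY, build_feature_table

logger = logging.getLogger(__name__)


def default_grid(start: float = 0.0, stop: float = 10.0,
                 step: float = 0.5) -> np.ndarray:
    """Candidate base temperatures, by default 0.0–10.0 °C in 0.5 °C steps."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 6)


def _series_requirements(features) -> list:
    """(source, method) pairs needed to build the requested features."""
    spec = {
        "GDD_tavg": (STATION, "tavg"),
        "GDD_allen": (STATION, "allen"),
        "ERA5_GDD_tavg": (ERA5, "tavg"),
        "ERA5_GDD_allen": (ERA5, "allen"),
    }
    return [spec[f] for f in features if f != FEATURE_DOY]


@dataclass
class BaseTempGridResult:
    """Per-temperature resampled metric distributions and per-metric optima."""

    grid: np.ndarray
    distributions: dict  # base_temp -> ResampleDistribution
    failed: list

    def summary(self) -> pd.DataFrame:
        rows = []
        for temp in self.grid:
            if temp in self.failed:
                continue
            s = self.distributions[temp].summary()
            s.insert(0, "base_temp", temp)
            rows.append(s)
        return pd.concat(rows, ignore_index=True)

    def optima(self) -> dict:
        """Per-metric optimal base temperature (ties → lower temperature)."""
        temps = [t for t in self.grid if t not in self.failed]
        out = {}
        for metric in METRICS:
            means = np.array([self.distributions[t].mean(metric) for t in temps])
            if metric == "accuracy":
                best = int(np.argmax(means))  # first max → lowest temp on tie
            else:
                best = int(np.argmin(means))
            if np.sum(means == means[best]) > 1:
                logger.info("tie on %s across base temps; lower temp kept", metric)
            out[metric] = float(temps[best])
        return out


def optimize_base_temp(
    weather: pd.DataFrame,
    observations: pd.DataFrame,
    model_factory_builder,
    features,
    grid=None,
    split_spec: SplitSpec | None = None,
    polynomial_degree: int | None = None,
    ci_level: float = 0.95,
) -> BaseTempGridResult:
    """Grid search over base temperatures with full GDD re-computation.

    Parameters
    ----------
    weather:
        Daily weather table (station and/or era5 rows as the features need).
    observations:
        Rank-encoded phenology observations.
    model_factory_builder:
        Zero-arg callable returning a fresh fit/predict model (passed through
        to ``resample_evaluate``), e.g. ``BaselineModel`` or a
        ``make_model_factory(...)`` result.
    features:
        Feature names for the scenario (e.g. ``("DOY", "GDD_allen")``;
        the baseline scenario uses a single GDD feature).
    grid:
        Candidate base temperatures; default 0–10 °C step 0.5.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("base-temperature grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    split_spec = split_spec or SplitSpec()

    weather = validate_weather(weather)
    needs = _series_requirements(features)
    distributions, failed = {}, []
    for temp in grid:
        series = []
        for source, method in needs:
            sub = weather[weather["source"] == source]
            if sub.empty:
                raise ValueError(f"weather table has no rows with source={source!r}")
            series.append(
                accumulate_gdd(sub, GDDParams(base_temp=float(temp), method=method),
                               validate=False)
            )
        table = build_feature_table(observations, series, features,
                                    polynomial_degree=polynomial_degree)
        if "n_ranks" in observations.attrs:
            table.attrs["n_ranks"] = observations.attrs["n_ranks"]
        try:
            distributions[float(temp)] = resample_evaluate(
                table, model_factory_builder, split_spec, ci_level)
        except Exception as exc:  # noqa: BLE001 — flag and continue
            logger.warning("all repeats failed at base %.1f °C: %s", temp, exc)
            failed.append(float(temp))
    if len(failed) == len(grid):
        raise RuntimeError("every grid point failed")
    return BaseTempGridResult(np.asarray([float(t) for t in grid]),
                              distributions, failed)
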