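"""CSV/YAML readers and writers, run configuration, and the pipeline driver.

All tabular artifacts are plain CSV (ISO-8601 dates, header row mandatory).
Files written by this module carry a comment header (lines starting with
``#``) recording the run seed and a hash of the configuration; the readers
skip such comment lines, so every format round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline_model import BaselineModel, ThresholdModel
from .degree_days import (GDDParams, InvalidRecordError, WEATHER_COLUMNS,
                          accumulate_gdd, validate_weather)
from .evaluation import (SplitSpec, gdd_source_comparison,
                         relative_error_convergence, resample_evaluate,
                         residual_diagnostics, stratified_split)
from .ml_harness import ModelSpec, make_model_factory, select_model
from .phenology_targets import (BBCHRankMap, build_feature_table,
                                default_olive_rank_map, encode_ranks)

logger = logging.getLogger(__name__)

PHENOLOGY_COLUMNS = ("location_id", "date", "bbch_code")


class SchemaError(ValueError):
    """An input file does not conform to the documented CSV schema."""


def write_csv(df: pd.DataFrame, path, seed: int | None = None,
              config_hash: str | None = None, **metadata) -> None:
    """Write a CSV with a ``#``-comment metadata header (seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"generator": f"thermopheno {__version__}"}
    if seed is not None:
        meta["seed"] = seed
    if config_hash is not None:
        meta["config_hash"] = config_hash
    meta.update(metadata)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (comment lines skipped)."""
    return pd.read_csv(path, comment="#", **kwargs)


def read_weather(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV.

    Schema: ``location_id,date,tmin,tmax,source`` with ISO-8601 dates.
    Coercion failures are reported with 1-based data row numbers.
    """
    raw = read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    dates = pd.to_datetime(raw["date"], errors="coerce")
    if dates.isna().any():
        rows = (np.flatnonzero(dates.isna()) + 1).tolist()[:5]
        raise SchemaError(f"{path}: unparseable dates at data rows {rows}")
    raw["date"] = dates
    for col in ("tmin", "tmax"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            rows = (np.flatnonzero(vals.isna()) + 1).tolist()[:5]
            raise SchemaError(f"{path}: non-numeric {col} at data rows {rows}")
        raw[col] = vals
    bad = raw["tmax"] < raw["tmin"]
    if bad.any():
        rows = (np.flatnonzero(bad) + 1).tolist()[:5]
        raise SchemaError(f"{path}: tmax < tmin at data rows {rows}")
    return validate_weather(raw)


def read_phenology(path, rank_map: BBCHRankMap) -> pd.DataFrame:
    """Read a phenology CSV (``location_id,date,bbch_code``) and rank-encode it."""
    raw = read_csv(path, dtype={"bbch_code": str})  # keep leading zeros
    missing = set(PHENOLOGY_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if raw.empty:
        logger.warning("%s: phenology file is empty", path)
        obs = raw.copy()
        obs["rank"] = pd.Series(dtype=int)
        obs.attrs["n_ranks"] = rank_map.n_ranks
        return obs
    dates = pd.to_datetime(raw["date"], errors="coerce")
    if dates.isna().any():
        rows = (np.flatnonzero(dates.isna()) + 1).tolist()[:5]
        raise SchemaError(f"{path}: unparseable dates at data rows {rows}")
    raw["date"] = dates
    obs = encode_ranks(raw, rank_map)
    obs.attrs["n_ranks"] = rank_map.n_ranks
    return obs


def read_rank_map(path) -> BBCHRankMap:
    """Read an ordered BBCH code list from YAML (a list) or CSV (one column)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            codes = yaml.safe_load(fh)
        if not isinstance(codes, list):
            raise SchemaError(f"{path}: rank map YAML must be an ordered list")
    else:
        df = read_csv(path, dtype=str)
        codes = df.iloc[:, 0].tolist()
    return BBCHRankMap(tuple(str(c) for c in codes))


def write_threshold_model(model: ThresholdModel, path, **metadata) -> None:
    write_csv(model.to_frame(), path, **metadata)


def read_threshold_model(path) -> ThresholdModel:
    return ThresholdModel.from_frame(read_csv(path))


# --------------------------------------------------------------------------
# Run configuration and pipeline driver

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``scenario`` names the features and the model: ``features`` is a list of
    feature names, ``model`` is ``"baseline"`` or a family name (optionally
    with ``polynomial: true``).
    """

    weather_path: str
    phenology_path: str
    out_dir: str
    rank_map_path: str | None = None
    features: tuple = ("GDD_tavg",)
    model: str = "baseline"
    polynomial: bool = False
    base_temp: float = 10.0
    method: str = "tavg"
    n_repeats: int = 100
    train_fraction: float = 0.70
    grid: tuple | None = None          # base-temp grid; None → no optimisation
    compare_sources: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for p in (cfg.weather_path, cfg.phenology_path, cfg.rank_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _model_factory_for(config: RunConfig, seed: int):
    if config.model == "baseline":
        return BaselineModel
    return make_model_factory(
        ModelSpec(config.model, polynomial_features=config.polynomial), seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute compute-gdd → features → evaluate (→ optimise) for one config.

    Writes all artifacts under ``config.out_dir`` plus a machine-readable
    ``manifest.json`` (inputs, seed, package version, config hash) and
    returns a dict of the written paths.  Any stage failure aborts with an
    error naming the stage.
    """
    logging.getLogger("thermopheno").setLevel(config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"seed": config.seed, "config_hash": chash}
    artifacts = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    logger.info("stage: read inputs")
    rank_map = (read_rank_map(config.rank_map_path)
                if config.rank_map_path else default_olive_rank_map())
    weather = stage("read-weather", lambda: read_weather(config.weather_path))
    obs = stage("read-phenology",
                lambda: read_phenology(config.phenology_path, rank_map))

    logger.info("stage: compute GDD")
    series = []
    for source in weather["source"].unique():
        for method in ("tavg", "allen"):
            sub = weather[weather["source"] == source]
            g = accumulate_gdd(sub, GDDParams(config.base_temp, method),
                               validate=False)
            series.append(g)
            p = out / f"gdd_{source}_{method}.csv"
            gout = g.copy()
            gout["method"] = method
            gout["base_temp"] = config.base_temp
            write_csv(gout, p, **meta)
            artifacts[f"gdd_{source}_{method}"] = str(p)

    logger.info("stage: build features")
    table = stage("build-features", lambda: build_feature_table(
        obs, series, config.features,
        polynomial_degree=4 if config.polynomial else None))
    table.attrs["n_ranks"] = rank_map.n_ranks
    p = out / "feature_table.csv"
    write_csv(table, p, **meta)
    artifacts["feature_table"] = str(p)

    logger.info("stage: evaluate %s", config.model)
    split = SplitSpec(train_fraction=config.train_fraction,
                      n_repeats=config.n_repeats, seed=config.seed)
    factory = _model_factory_for(config, config.seed)
    dist = stage("evaluate", lambda: resample_evaluate(table, factory, split))
    write_csv(dist.metrics, out / "metrics_per_repeat.csv", **meta)
    write_csv(dist.summary(), out / "metrics_summary.csv", **meta)
    artifacts["metrics_per_repeat"] = str(out / "metrics_per_repeat.csv")
    artifacts["metrics_summary"] = str(out / "metrics_summary.csv")

    # residual diagnostics on the first split's test set
    train_idx, test_idx = stratified_split(table, split, 0)
    model = factory()
    tr, te = table.iloc[train_idx], table.iloc[test_idx]
    tr.attrs.update(table.attrs); te.attrs.update(table.attrs)
    model.fit(tr)
    pred = model.predict(te)
    diags = residual_diagnostics(pred, te["rank"].to_numpy(int),
                                 te[["doy", "rank", "location_id"]])
    for name, frame in diags.items():
        p = out / f"residuals_{name}.csv"
        write_csv(frame, p, **meta)
        artifacts[f"residuals_{name}"] = str(p)

    if config.compare_sources:
        logger.info("stage: compare GDD sources")
        by = {(g["source"].iloc[0], g.attrs["method"]): g for g in series}
        for method in ("tavg", "allen"):
            if ("station", method) in by and ("era5", method) in by:
                comp = gdd_source_comparison(by[("station", method)],
                                             by[("era5", method)])
                conv = relative_error_convergence(comp)
                write_csv(comp, out / f"source_comparison_{method}.csv", **meta)
                write_csv(conv, out / f"source_convergence_{method}.csv", **meta)
                artifacts[f"source_comparison_{method}"] = str(
                    out / f"source_comparison_{method}.csv")

    if config.grid is not None:
        from .base_temp_optimizer import optimize_base_temp
        logger.info("stage: optimise base temperature")
        result = stage("optimize-base-temp", lambda: optimize_base_temp(
            weather, obs, factory, config.features,
            grid=np.asarray(config.grid, float), split_spec=split))
        write_csv(result.summary(), out / "base_temp_grid.csv", **meta)
        optima = pd.DataFrame(
            [{"metric": m, "optimal_base_temp": t}
             for m, t in result.optima().items()])
        write_csv(optima, out / "base_temp_optima.csv", **meta)
        artifacts["base_temp_grid"] = str(out / "base_temp_grid.csv")
        artifacts["base_temp_optima"] = str(out / "base_temp_optima.csv")

    manifest = {
        "inputs": {"weather": config.weather_path,
                   "phenology": config.phenology_path,
                   "rank_map": config.rank_map_path},
        "seed": config.seed,
        "config_hash": chash,
        "version": __version__,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
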