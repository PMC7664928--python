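"""Metrics, stratified repeated splitting, resampling and diagnostics.

The evaluation protocol: the data set is repeatedly split (100 times by
default) into disjoint training (70%) and test (30%) sets, stratified by
year and location; each repeat yields accuracy, RMSE (on the integer rank
scale) and the combined metric

    combined = (1 - accuracy) * rmse

which is 0 exactly when classification is perfect, and otherwise weights the
error-rate by how far wrong predictions land.  Over the repeats a Student-t
confidence interval for each metric's mean is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "rmse", "combined")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified repeated train/test split specification.

    Strata are (year, location_id) cells; within every stratum the train
    share is round-half-up(train_fraction * n)/n.  Splits are deterministic
    given (seed, repeat_index).
    """

    train_fraction: float = 0.70
    n_repeats: int = 100
    seed: int = 0
    strata: tuple = ("year", "location_id")

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    rmse: float
    combined: float
    n_test: int

    def __post_init__(self) -> None:
        expected = (1.0 - self.accuracy) * self.rmse
        if not np.isclose(self.combined, expected, rtol=0, atol=1e-12):
            raise ValueError("combined must equal (1 - accuracy) * rmse")


def score(predictions, truth) -> MetricReport:
    """Accuracy, RMSE and combined metric for one prediction vector."""
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truth, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must have equal length")
    if pred.size == 0:
        raise ValueError("cannot score an empty prediction vector")
    accuracy = float(np.mean(pred == true))
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    return MetricReport(accuracy, rmse, (1.0 - accuracy) * rmse, int(pred.size))


def stratified_split(table: pd.DataFrame, spec: SplitSpec, repeat_index: int):
    """One stratified 70/30 partition; returns (train, test) positional indices.

    Strata of size 1 go entirely to train (with a warning): no test-side
    leakage is possible and every row stays in the partition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, repeat_index]))
    groups = table.groupby(list(spec.strata), sort=True, observed=True).indices
    train_parts, test_parts = [], []
    for key in sorted(groups, key=str):
        idx = np.sort(np.asarray(groups[key]))
        n = len(idx)
        if n == 1:
            logger.warning("stratum %s has a single row; assigned to train", (key,))
            train_parts.append(idx)
            continue
        n_train = int(np.floor(spec.train_fraction * n + 0.5))  # round half up
        n_train = min(max(n_train, 1), n)  # keep both sides sensible
        perm = rng.permutation(n)
        train_parts.append(idx[perm[:n_train]])
        test_parts.append(idx[perm[n_train:]])
    train = np.sort(np.concatenate(train_parts)) if train_parts else np.array([], int)
    test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    return train, test


@dataclass
class ResampleDistribution:
    """Per-repeat metric reports plus t-based CIs for each metric's mean."""

    reports: list
    ci_level: float = 0.95

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"repeat": i, "accuracy": r.accuracy, "rmse": r.rmse,
              "combined": r.combined, "n_test": r.n_test}
             for i, r in enumerate(self.reports)]
        )

    def mean(self, metric: str) -> float:
        return float(self.metrics[metric].mean())

    def summary(self) -> pd.DataFrame:
        """mean, standard error and CI of the mean, one row per metric."""
        rows = []
        n = len(self.reports)
        for metric in METRICS:
            vals = self.metrics[metric].to_numpy(float)
            mean = float(vals.mean())
            if n > 1:
                se = float(vals.std(ddof=1) / np.sqrt(n))
                half = stats.t.ppf(0.5 + self.ci_level / 2.0, df=n - 1) * se
                lo, hi = mean - half, mean + half
            else:
                se, lo, hi = float("nan"), float("nan"), float("nan")
            rows.append({"metric": metric, "mean": mean, "se": se,
                         "ci_low": lo, "ci_high": hi, "n_repeats": n})
        return pd.DataFrame(rows)


def resample_evaluate(table: pd.DataFrame, model_factory, spec: SplitSpec,
                      ci_level: float = 0.95) -> ResampleDistribution:
    """Fit/score a model over repeated stratified splits.

    ``model_factory`` is a zero-argument callable returning an object with
    ``fit(table)`` and ``predict(table) -> integer ranks``.  Repeats with an
    empty test set are skipped with a warning; if all are skipped an error
    is raised.  With ``n_repeats == 1`` the CI is undefined and flagged as
    NaN in the summary.
    """
    if spec.n_repeats == 1:
        logger.warning("n_repeats=1: confidence intervals are undefined")
    reports = []
    for rep in range(spec.n_repeats):
        train_idx, test_idx = stratified_split(table, spec, rep)
        if len(test_idx) == 0:
            logger.warning("repeat %d has an empty test set; skipped", rep)
            continue
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        train.attrs.update(table.attrs)
        test.attrs.update(table.attrs)
        model = model_factory()
        model.fit(train)
        pred = model.predict(test)
        reports.append(score(pred, test["rank"].to_numpy(int)))
    if not reports:
        raise ValueError("all resampling repeats were skipped (no test data)")
    return ResampleDistribution(reports, ci_level)


def residual_diagnostics(predictions, truth, covariates: pd.DataFrame,
                         doy_bin_width: int = 30) -> dict:
    """Residual breakdowns: magnitude histogram, and by DOY bin / rank / location.

    ``covariates`` supplies per-observation ``doy``, ``rank`` (optional —
    defaults to ``truth``) and ``location_id`` columns; any subset may be
    present.  Residual = prediction - truth.
    """
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape or len(pred) != len(covariates):
        raise ValueError("predictions, truth and covariates must align")
    resid = pred - true
    out = {}
    mags = pd.Series(np.abs(resid), name="count")
    out["magnitude_histogram"] = (
        mags.value_counts().sort_index().rename_axis("magnitude").reset_index()
    )
    df = covariates.copy()
    df["residual"] = resid
    if "doy" in df.columns:
        bins = (df["doy"].astype(int) - 1) // doy_bin_width * doy_bin_width + 1
        out["by_doy"] = (
            df.groupby(bins.rename("doy_bin"))["residual"]
            .agg(["count", "mean", "std", "min", "max"]).reset_index()
        )
    key = "rank" if "rank" in df.columns else None
    if key is None:
        df["rank"] = true
        key = "rank"
    out["by_rank"] = (
        df.groupby(key)["residual"]
        .agg(["count", "mean", "std", "min", "max"]).reset_index()
    )
    if "location_id" in df.columns:
        out["by_location"] = (
            df.groupby("location_id")["residual"]
            .agg(["count", "mean", "std", "min", "max"]).reset_index()
        )
    return out


def gdd_source_comparison(series_a: pd.DataFrame,
                          series_b: pd.DataFrame) -> pd.DataFrame:
    """Per-location error trajectories of one cumulative-GDD series vs another.

    ``error = b - a`` and ``rel_error = (b - a)/a`` (where a > 0), tabulated
    by location and day-of-year.  Both series must cover exactly the same
    (location, date) pairs.
    """
    a = series_a[["location_id", "date", "doy", "cum_gdd"]]
    b = series_b[["location_id", "date", "cum_gdd"]]
    merged = a.merge(b, on=["location_id", "date"], how="outer",
                     suffixes=("_a", "_b"), indicator=True)
    if (merged["_merge"] != "both").any():
        n = int((merged["_merge"] != "both").sum())
        raise ValueError(f"series coverage mismatch on {n} (location, date) pairs")
    out = merged.drop(columns="_merge").rename(
        columns={"cum_gdd_a": "cum_gdd_ref", "cum_gdd_b": "cum_gdd_alt"})
    out["error"] = out["cum_gdd_alt"] - out["cum_gdd_ref"]
    out["rel_error"] = np.where(out["cum_gdd_ref"] > 0,
                                out["error"] / out["cum_gdd_ref"], np.nan)
    return out.sort_values(["location_id", "date"]).reset_index(drop=True)


def relative_error_convergence(comparison: pd.DataFrame,
                               doy_range=(180, 365)) -> pd.DataFrame:
    """Flatness of the late-season relative-error trajectory per location.

    For each location, the mean and sd of ``rel_error`` over the given DOY
    window and their ratio ``cv = sd/|mean|``; a small cv means the relative
    error has converged to a per-location constant.
    """
    lo, hi = doy_range
    window = comparison[(comparison["doy"] >= lo) & (comparison["doy"] <= hi)]
    grp = window.groupby("location_id")["rel_error"]
    out = grp.agg(mean="mean", sd="std").reset_index()
    out["cv"] = out["sd"] / out["mean"].abs()
    return out
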