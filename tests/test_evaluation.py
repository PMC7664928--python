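"""Metric algebra, split contracts, resampling CIs and diagnostics."""

import logging

import numpy as np
import pandas as pd
import pytest

import thermopheno as tp
from thermopheno.degree_days import GDDParams
from thermopheno.evaluation import SplitSpec

from conftest import make_weather


def feature_table(n_per_stratum=10, years=(2008, 2009), locations=("a", "b"),
                  seed=0):
    """A labelled table with explicit strata for split tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for y in years:
        for loc in locations:
            for _ in range(n_per_stratum):
                rows.append({"x": rng.uniform(0, 1), "rank": rng.integers(1, 5),
                             "year": y, "location_id": loc})
    df = pd.DataFrame(rows)
    df.attrs["feature_cols"] = ["x"]
    return df


class ConstantModel:
    def __init__(self, value=1):
        self.value = value

    def fit(self, table):
        return self

    def predict(self, table):
        return np.full(len(table), self.value, dtype=int)


class OracleModel:
    """Predicts the truth (the rank column) — a perfect model."""

    def fit(self, table):
        return self

    def predict(self, table):
        return table["rank"].to_numpy(int)


class TestScore:
    def test_perfect_predictions(self):
        rep = tp.score([3, 1, 4], [3, 1, 4])
        assert (rep.accuracy, rep.rmse, rep.combined) == (1.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        rep = tp.score([1, 1, 3, 3], [1, 2, 3, 4])
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.rmse == pytest.approx(np.sqrt(0.5))
        assert rep.combined == pytest.approx(0.5 * np.sqrt(0.5))

    def test_single_pair(self):
        rep = tp.score([2], [5])
        assert (rep.accuracy, rep.rmse, rep.combined) == (0.0, 3.0, 3.0)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            tp.score([], [])
        with pytest.raises(ValueError):
            tp.score([1, 2], [1])

    def test_combined_bounds_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(1, 50)
            pred = rng.integers(1, 21, n)
            true = rng.integers(1, 21, n)
            rep = tp.score(pred, true)
            assert rep.combined == pytest.approx((1 - rep.accuracy) * rep.rmse)
            assert 0.0 <= rep.combined <= rep.rmse + 1e-12
            if rep.accuracy == 1.0:
                assert rep.combined == 0.0


class TestStratifiedSplit:
    def test_stratum_of_ten_gives_seven_three(self):
        table = feature_table(n_per_stratum=10)
        spec = SplitSpec(seed=1)
        train, test = tp.stratified_split(table, spec, 0)
        for y in (2008, 2009):
            for loc in ("a", "b"):
                mask = (table["year"] == y) & (table["location_id"] == loc)
                assert np.isin(train, np.flatnonzero(mask)).sum() == 7
                assert np.isin(test, np.flatnonzero(mask)).sum() == 3

    def test_partition_exact(self):
        table = feature_table(n_per_stratum=7)
        train, test = tp.stratified_split(table, SplitSpec(seed=2), 5)
        assert len(np.intersect1d(train, test)) == 0
        assert sorted(np.concatenate([train, test])) == list(range(len(table)))

    def test_singleton_stratum_to_train_with_warning(self, caplog):
        table = feature_table(n_per_stratum=1)
        with caplog.at_level(logging.WARNING, logger="thermopheno.evaluation"):
            train, test = tp.stratified_split(table, SplitSpec(seed=0), 0)
        assert "single row" in caplog.text
        assert len(train) == len(table) and len(test) == 0

    def test_deterministic_given_seed_and_repeat(self):
        table = feature_table()
        a = tp.stratified_split(table, SplitSpec(seed=9), 3)
        b = tp.stratified_split(table, SplitSpec(seed=9), 3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = tp.stratified_split(table, SplitSpec(seed=9), 4)
        assert not np.array_equal(a[0], c[0])

    def test_per_stratum_fraction_within_tolerance(self):
        rng = np.random.default_rng(8)
        sizes = rng.integers(2, 30, size=12)
        rows = []
        for i, n in enumerate(sizes):
            for _ in range(n):
                rows.append({"x": 0.0, "rank": 1, "year": 2008,
                             "location_id": f"loc{i}"})
        table = pd.DataFrame(rows)
        train, _ = tp.stratified_split(table, SplitSpec(seed=4), 0)
        for i, n in enumerate(sizes):
            idx = np.flatnonzero(table["location_id"] == f"loc{i}")
            frac = np.isin(train, idx).sum() / n
            assert abs(frac - 0.70) <= 1.0 / n + 1e-12

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)
        with pytest.raises(ValueError):
            SplitSpec(n_repeats=0)


class TestResampleEvaluate:
    def test_constant_model_single_class(self):
        table = feature_table()
        table["rank"] = 1
        dist = tp.resample_evaluate(table, ConstantModel,
                                    SplitSpec(n_repeats=10, seed=0))
        assert all(r.accuracy == 1.0 for r in dist.reports)
        s = dist.summary().set_index("metric")
        assert s.loc["accuracy", "ci_low"] == s.loc["accuracy", "ci_high"] == 1.0

    def test_single_repeat_ci_flagged_nan(self):
        table = feature_table()
        dist = tp.resample_evaluate(table, OracleModel,
                                    SplitSpec(n_repeats=1, seed=0))
        s = dist.summary().set_index("metric")
        assert np.isnan(s.loc["rmse", "ci_low"])
        assert s.loc["accuracy", "mean"] == dist.reports[0].accuracy

    def test_all_skipped_raises(self):
        table = feature_table(n_per_stratum=1)  # all strata go to train
        with pytest.raises(ValueError, match="skipped"):
            tp.resample_evaluate(table, OracleModel, SplitSpec(n_repeats=3))

    def test_ci_width_shrinks_with_more_repeats(self):
        """Mean CI width over independent trials shrinks roughly as 1/sqrt(n)."""
        table = feature_table(n_per_stratum=12, seed=1)
        rng = np.random.default_rng(0)
        table["rank"] = rng.integers(1, 4, len(table))

        class NoisyModel:
            """imperfect: predicts a shuffled copy of train's rank marginal"""

            def fit(self, t):
                self.vals = t["rank"].to_numpy(int)
                return self

            def predict(self, t):
                reps = int(np.ceil(len(t) / len(self.vals)))
                return np.tile(self.vals, reps)[:len(t)]

        widths = {}
        for n in (8, 32):
            w = []
            for trial in range(20):
                dist = tp.resample_evaluate(
                    table, NoisyModel, SplitSpec(n_repeats=n, seed=100 + trial))
                s = dist.summary().set_index("metric")
                w.append(s.loc["combined", "ci_high"]
                         - s.loc["combined", "ci_low"])
            widths[n] = np.mean(w)
        assert widths[32] < widths[8]

    def test_baseline_perfect_on_degenerate_band_world(self):
        """Disjoint single-valued per-rank GDD bands: mean accuracy 1.0."""
        rng = np.random.default_rng(2)
        levels = np.array([100.0, 400.0, 900.0, 1600.0])
        rows = []
        for y in (2008, 2009):
            for loc in ("a", "b"):
                for k, g in enumerate(levels, start=1):
                    for _ in range(3):
                        rows.append({"GDD_tavg": g, "rank": k, "year": y,
                                     "location_id": loc})
        table = pd.DataFrame(rows)
        table.attrs["feature_cols"] = ["GDD_tavg"]
        dist = tp.resample_evaluate(table, tp.BaselineModel,
                                    SplitSpec(n_repeats=20, seed=1))
        assert dist.mean("accuracy") == 1.0
        assert dist.mean("combined") == 0.0


class TestDiagnostics:
    def test_perfect_predictions_all_zero(self):
        cov = pd.DataFrame({"doy": [10, 200], "location_id": ["a", "b"]})
        out = tp.residual_diagnostics([1, 3], [1, 3], cov)
        hist = out["magnitude_histogram"]
        assert list(hist["magnitude"]) == [0] and list(hist["count"]) == [2]

    def test_magnitude_counts(self):
        cov = pd.DataFrame({"doy": [10, 20], "location_id": ["a", "a"]})
        out = tp.residual_diagnostics([1, 3], [2, 1], cov)
        hist = out["magnitude_histogram"].set_index("magnitude")["count"]
        assert hist.to_dict() == {1: 1, 2: 1}

    def test_by_location_partitions(self):
        cov = pd.DataFrame({"doy": [1, 2, 3, 4],
                            "location_id": ["a", "a", "b", "b"]})
        out = tp.residual_diagnostics([1, 2, 3, 4], [1, 1, 1, 1], cov)
        assert out["by_location"]["count"].sum() == 4
        assert set(out["by_location"]["location_id"]) == {"a", "b"}


class TestSourceComparison:
    def test_identical_series_zero_error(self, constant_weather):
        g = tp.accumulate_gdd(constant_weather, GDDParams(10.0, "tavg"))
        comp = tp.gdd_source_comparison(g, g)
        assert np.allclose(comp["error"], 0.0)

    def test_scaled_series_constant_relative_error(self, constant_weather):
        g = tp.accumulate_gdd(constant_weather, GDDParams(10.0, "tavg"))
        g2 = g.copy()
        g2["cum_gdd"] = 1.1 * g2["cum_gdd"]
        comp = tp.gdd_source_comparison(g, g2)
        np.testing.assert_allclose(comp["rel_error"], 0.10)

    def test_coverage_mismatch_rejected(self, constant_weather):
        g = tp.accumulate_gdd(constant_weather, GDDParams(10.0, "tavg"))
        with pytest.raises(ValueError, match="coverage"):
            tp.gdd_source_comparison(g, g.iloc[:-10])
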