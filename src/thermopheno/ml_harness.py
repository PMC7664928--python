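"""Registry of ML model families with a uniform fit/predict contract.

Targets are numeric ranks; every family is fitted in a regression framing
and its continuous output discretised back to integer ranks (classification
framing is available for the tree families where it is natural).  Each
family can be run with raw features or with a degree-4 polynomial expansion.
When a hyperparameter grid is supplied, tuning runs inside the training
split only (3 repeats of 10-fold cross-validation); the default grids are
size-1 (library defaults), a documented approximation of generic automatic
tuning.

Model selection: every candidate is evaluated on the *same* sequence of
stratified splits (paired comparison) and the candidate with the minimum
mean combined metric wins; ties break by candidate order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baseline_model import BaselineModel
from .evaluation import ResampleDistribution, SplitSpec, resample_evaluate
from .phenology_targets import discretise_output, feature_cols, polynomial_expand

logger = logging.getLogger(__name__)


class CapabilityError(KeyError):
    """Requested model family is not available in the registry."""


def _make_estimator(family: str, seed: int):
    if family == "linear_regression":
        from sklearn.linear_model import LinearRegression
        return LinearRegression()
    if family == "cart":
        from sklearn.tree import DecisionTreeRegressor
        return DecisionTreeRegressor(random_state=seed)
    if family == "random_forest":
        from sklearn.ensemble import RandomForestRegressor
        return RandomForestRegressor(n_estimators=100, random_state=seed)
    if family == "neural_net":
        from sklearn.neural_network import MLPRegressor
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(32,), max_iter=1000,
                         random_state=seed),
        )
    if family == "gbm":
        from sklearn.ensemble import GradientBoostingRegressor
        return GradientBoostingRegressor(random_state=seed)
    if family == "xgboost_linear":
        from xgboost import XGBRegressor
        return XGBRegressor(booster="gblinear", random_state=seed,
                            n_estimators=100, verbosity=0)
    if family == "xgboost_tree":
        from xgboost import XGBRegressor
        return XGBRegressor(booster="gbtree", random_state=seed,
                            n_estimators=100, verbosity=0)
    raise CapabilityError(f"unknown model family {family!r}; "
                          f"available: {sorted(FAMILIES)}")


FAMILIES = (
    "linear_regression", "cart", "random_forest", "neural_net",
    "gbm", "xgboost_linear", "xgboost_tree",
)

#: Small documented tuning grids (approximations of generic automatic
#: tuning; deliberately modest so a full model comparison stays cheap).
DEFAULT_GRIDS = {
    "cart": {"max_depth": [3, 6, None]},
    "random_forest": {"max_features": [1.0, "sqrt"]},
    "gbm": {"n_estimators": [100, 300]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: a family, optionally with degree-4 polynomial features.

    ``param_grid``: hyperparameter grid for inner tuning (None → library
    defaults, no inner CV).  ``discretise_mode``: how continuous outputs map
    back to ranks.
    """

    family: str
    polynomial_features: bool = False
    discretise_mode: str = "round"
    param_grid: tuple = None  # mapping stored as tuple of (key, tuple) pairs

    @property
    def name(self) -> str:
        return self.family + ("+poly4" if self.polynomial_features else "")

    def grid_dict(self):
        return None if self.param_grid is None else {
            k: list(v) for k, v in self.param_grid
        }


def default_candidates(polynomial: bool = True):
    """Every registry family, with and without polynomial features."""
    specs = [ModelSpec(f) for f in FAMILIES]
    if polynomial:
        specs += [ModelSpec(f, polynomial_features=True) for f in FAMILIES]
    return specs


class RankRegressor:
    """Uniform wrapper: numeric-rank regression + discretisation to [1, K].

    K (the number of ranks) is taken from the table's
    ``.attrs["n_ranks"]`` when present, otherwise from the maximum training
    rank.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.estimator_ = None
        self._cols = None
        self._n_ranks = None

    def _design(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[self._cols].astype(float)
        if self.spec.polynomial_features:
            X = polynomial_expand(X, degree=4)
        return X

    def fit(self, table: pd.DataFrame) -> "RankRegressor":
        self._cols = feature_cols(table)
        self._n_ranks = int(table.attrs.get("n_ranks")
                            or table["rank"].max())
        X = self._design(table)
        y = table["rank"].to_numpy(float)
        est = _make_estimator(self.spec.family, self.seed)
        grid = self.spec.grid_dict()
        if grid:
            from sklearn.model_selection import GridSearchCV, RepeatedKFold
            cv = RepeatedKFold(n_splits=10, n_repeats=3, random_state=self.seed)
            est = GridSearchCV(est, grid, cv=cv,
                               scoring="neg_root_mean_squared_error")
        est.fit(X.to_numpy(float), y)
        self.estimator_ = est
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.estimator_ is None:
            raise RuntimeError("RankRegressor is not fitted")
        y = self.estimator_.predict(self._design(table).to_numpy(float))
        return np.asarray(
            discretise_output(y, self._n_ranks, self.spec.discretise_mode)
        )


def make_model_factory(spec, seed: int = 0):
    """Zero-arg factory for resample_evaluate; 'baseline' maps to the
    threshold benchmark, anything else to a :class:`RankRegressor`."""
    if spec == "baseline":
        return BaselineModel
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    _make_estimator(spec.family, seed)  # fail fast on unknown families
    return lambda: RankRegressor(spec, seed)


def fit_predict(spec: ModelSpec, train: pd.DataFrame, test: pd.DataFrame,
                seed: int = 0) -> np.ndarray:
    """Fit one spec on the training table and predict integer ranks for test."""
    model = RankRegressor(spec, seed).fit(train)
    return model.predict(test)


@dataclass
class SelectionResult:
    """Ranking of candidate specs by mean combined metric (minimum wins)."""

    candidates: list
    distributions: list
    selected_index: int

    @property
    def selected(self):
        return self.candidates[self.selected_index]

    def table(self) -> pd.DataFrame:
        rows = []
        for spec, dist in zip(self.candidates, self.distributions):
            rows.append({
                "model": spec.name if isinstance(spec, ModelSpec) else str(spec),
                "mean_accuracy": dist.mean("accuracy"),
                "mean_rmse": dist.mean("rmse"),
                "mean_combined": dist.mean("combined"),
            })
        return pd.DataFrame(rows)


def select_model(table: pd.DataFrame, candidates, split_spec: SplitSpec,
                 seed: int = 0, ci_level: float = 0.95) -> SelectionResult:
    """Evaluate candidates on identical split sequences; argmin mean combined.

    The split sequence is fixed by ``split_spec.seed``, so every candidate
    sees exactly the same partitions and the comparison is paired.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate models given")
    dists, failures = [], []
    for spec in candidates:
        try:
            factory = make_model_factory(spec, seed)
            dists.append(resample_evaluate(table, factory, split_spec, ci_level))
        except Exception as exc:  # noqa: BLE001 — candidate failure is data
            logger.warning("candidate %s failed: %s", spec, exc)
            dists.append(None)
            failures.append(spec)
    means = [d.mean("combined") if d is not None else np.inf for d in dists]
    if not np.isfinite(min(means)):
        raise RuntimeError(f"all candidate models failed: {failures}")
    best = int(np.argmin(means))  # first minimum → earliest candidate on ties
    if means.count(min(means)) > 1:
        logger.info("tie on mean combined metric; kept candidate order winner")
    return SelectionResult(candidates, dists, best)
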