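"""Benchmark threshold model: per-phase mean GDD, interval-lookup prediction.

For each rank observed in training the threshold is the mean cumulative GDD
of the training points with that rank.  Prediction returns the largest rank
whose threshold is <= the given GDD but below the next rank's threshold;
values below the first threshold map to the smallest fitted rank, values at
or above the last threshold map to the largest fitted rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology_targets import feature_cols

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdModel:
    """Fitted per-rank GDD thresholds.

    ``ranks`` are the (sorted) ranks present in training; ``thresholds``
    the raw per-rank means; ``monotone_thresholds`` the running maximum over
    rank order actually used for prediction.  Ranks absent from training
    have no threshold and are never predicted.
    """

    ranks: np.ndarray
    thresholds: np.ndarray
    monotone_thresholds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ranks) == 0:
            raise ValueError("cannot fit a threshold model on an empty training set")
        mono = np.maximum.accumulate(self.thresholds)
        if np.any(mono != self.thresholds):
            logger.warning(
                "non-monotone fitted thresholds; replaced by running maximum "
                "over rank order"
            )
        object.__setattr__(self, "monotone_thresholds", mono)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": self.ranks, "threshold": self.thresholds})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ThresholdModel":
        frame = frame.sort_values("rank")
        return cls(frame["rank"].to_numpy(int), frame["threshold"].to_numpy(float))


def fit_baseline(gdd, ranks=None) -> ThresholdModel:
    """Fit per-rank mean-GDD thresholds.

    Accepts either a feature table with a single GDD feature column and a
    ``rank`` column, or two aligned arrays ``(gdd, ranks)``.
    """
    if ranks is None:
        table = gdd
        cols = [c for c in feature_cols(table) if c != "DOY"]
        if len(cols) != 1:
            raise ValueError(
                f"baseline model needs exactly one GDD feature column, got {cols}"
            )
        gdd = table[cols[0]].to_numpy(float)
        ranks = table["rank"].to_numpy(int)
    gdd = np.asarray(gdd, dtype=float)
    ranks = np.asarray(ranks, dtype=int)
    if gdd.size == 0:
        raise ValueError("cannot fit a threshold model on an empty training set")
    means = pd.Series(gdd).groupby(pd.Series(ranks)).mean()
    return ThresholdModel(means.index.to_numpy(int), means.to_numpy(float))


def predict_baseline(model: ThresholdModel, gdd):
    """Interval lookup of ranks for the given GDD value(s).

    A GDD exactly equal to the next rank's threshold resolves upward (the
    interval is closed on the left, open on the right).
    """
    gdd = np.asarray(gdd, dtype=float)
    # index of the last threshold <= gdd; -1 (below all) clamps to rank 0
    idx = np.searchsorted(model.monotone_thresholds, gdd, side="right") - 1
    idx = np.clip(idx, 0, len(model.ranks) - 1)
    out = model.ranks[idx]
    return int(out) if out.ndim == 0 else out


class BaselineModel:
    """fit/predict wrapper over the threshold model for the evaluation harness.

    Uses the table's single GDD feature column (DOY, if present, is ignored —
    the benchmark is a pure thermal-time model).
    """

    def __init__(self) -> None:
        self.model_: ThresholdModel | None = None
        self._col: str | None = None

    def fit(self, table: pd.DataFrame) -> "BaselineModel":
        cols = [c for c in feature_cols(table) if c != "DOY"]
        if len(cols) != 1:
            raise ValueError(
                f"baseline model needs exactly one GDD feature column, got {cols}"
            )
        self._col = cols[0]
        self.model_ = fit_baseline(table[self._col].to_numpy(float),
                                   table["rank"].to_numpy(int))
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("BaselineModel is not fitted")
        return np.asarray(predict_baseline(self.model_,
                                           table[self._col].to_numpy(float)))
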