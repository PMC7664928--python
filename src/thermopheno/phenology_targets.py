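"""BBCH rank encoding and feature-table construction.

The BBCH scale labels developmental stages with codes whose numeric values
are not quantitatively meaningful, so models are trained on the *rank* of
each code within an ordered (simplified) scale: the first code in the scale
gets rank 1, the last gets rank K.  Regression models produce continuous
outputs that are discretised back to integer ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import PolynomialFeatures

from .degree_days import ERA5, STATION, MissingCoverageError

logger = logging.getLogger(__name__)

#: Feature names understood by :func:`build_feature_table`.
FEATURE_DOY = "DOY"
GDD_FEATURES = ("GDD_tavg", "GDD_allen", "ERA5_GDD_tavg", "ERA5_GDD_allen")
ALL_FEATURES = (FEATURE_DOY,) + GDD_FEATURES


class UnknownCodeError(KeyError):
    """An observed BBCH code is absent from the rank map."""


@dataclass(frozen=True)
class BBCHRankMap:
    """Ordered list of BBCH codes defining the rank encoding (1..K)."""

    codes: tuple

    def __post_init__(self) -> None:
        if len(self.codes) < 2:
            raise ValueError("a rank map needs at least 2 codes")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("rank map codes must be unique")

    @property
    def n_ranks(self) -> int:
        return len(self.codes)

    def rank_of(self, code) -> int:
        try:
            return self.codes.index(code) + 1
        except ValueError:
            raise UnknownCodeError(f"BBCH code {code!r} not in rank map") from None

    def code_of(self, rank: int):
        if not 1 <= rank <= self.n_ranks:
            raise ValueError(f"rank {rank} outside [1, {self.n_ranks}]")
        return self.codes[rank - 1]


#: A 20-stage simplified olive BBCH scale used as the package default and by
#: the synthetic-data generator.  The stage composition is a synthetic
#: stand-in ordered along the olive season (bud development → dormancy);
#: users with a real monitoring protocol should supply their own map.
DEFAULT_OLIVE_CODES = (
    "00", "01", "03", "07", "09", "11", "15", "19", "31", "33",
    "50", "51", "54", "57", "60", "65", "68", "71", "75", "89",
)


def default_olive_rank_map() -> BBCHRankMap:
    """The default 20-stage simplified olive scale (see DEFAULT_OLIVE_CODES)."""
    return BBCHRankMap(DEFAULT_OLIVE_CODES)


def encode_ranks(observations: pd.DataFrame, rank_map: BBCHRankMap) -> pd.DataFrame:
    """Attach an integer ``rank`` column from ``bbch_code``.

    All codes must be present in the map; unknown codes raise
    :class:`UnknownCodeError` listing the offenders.  The original code
    column is retained.
    """
    obs = observations.copy()
    codes = obs["bbch_code"].astype(str)
    lookup = {str(c): i + 1 for i, c in enumerate(rank_map.codes)}
    unknown = sorted(set(codes) - set(lookup))
    if unknown:
        raise UnknownCodeError(f"BBCH codes not in rank map: {unknown}")
    obs["rank"] = codes.map(lookup).astype(int)
    return obs


def discretise_output(y, n_ranks: int, mode: str = "round"):
    """Discretise continuous model output to integer ranks in [1, n_ranks].

    ``mode`` is one of ``round`` (half away from zero is irrelevant here;
    numpy banker's rounding is *not* used — standard arithmetic rounding
    via floor(y+0.5) applies), ``floor`` or ``ceiling``.
    """
    if n_ranks < 2:
        raise ValueError("n_ranks must be >= 2")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite model output cannot be discretised")
    if mode == "round":
        r = np.floor(y + 0.5)
    elif mode == "floor":
        r = np.floor(y)
    elif mode == "ceiling":
        r = np.ceil(y)
    else:
        raise ValueError(f"unknown discretisation mode {mode!r}")
    r = np.clip(r, 1, n_ranks).astype(int)
    return int(r) if r.ndim == 0 else r


def polynomial_expand(X: pd.DataFrame, degree: int = 4) -> pd.DataFrame:
    """All monomials of total degree 1..degree in the given columns.

    No constant term.  For 2 input columns and degree 4 this yields 14
    columns (2 + 3 + 4 + 5 monomials of degree 1, 2, 3, 4).
    """
    poly = PolynomialFeatures(degree=degree, include_bias=False)
    arr = poly.fit_transform(X.to_numpy(float))
    names = poly.get_feature_names_out(X.columns)
    return pd.DataFrame(arr, columns=names, index=X.index)


def _series_feature_name(gdd: pd.DataFrame) -> str:
    src = gdd["source"].iloc[0]
    method = gdd.attrs.get("method")
    if method is None:
        raise ValueError("GDD series lacks 'method' in .attrs; "
                         "produce it with accumulate_gdd")
    prefix = {STATION: "GDD", ERA5: "ERA5_GDD"}[src]
    return f"{prefix}_{method}"


def build_feature_table(
    observations: pd.DataFrame,
    gdd_series: list,
    features,
    polynomial_degree: int | None = None,
) -> pd.DataFrame:
    """One row per observation with the requested features and the target.

    Parameters
    ----------
    observations:
        Rank-encoded observations (``location_id, date, rank``, typically
        from :func:`encode_ranks`).
    gdd_series:
        Cumulative-GDD tables from ``accumulate_gdd``; each is matched to a
        feature name from its source tag and method (station → ``GDD_tavg``
        / ``GDD_allen``, era5 → ``ERA5_GDD_tavg`` / ``ERA5_GDD_allen``).
    features:
        Subset of ``ALL_FEATURES`` to include.
    polynomial_degree:
        If given, replace the feature columns by all monomials of total
        degree 1..degree.

    The result keeps ``rank`` (target), ``year`` and ``location_id`` (the
    stratification keys) and ``date``/``doy`` for diagnostics; the feature
    column names are recorded in ``.attrs["feature_cols"]``.  Every
    observation must be covered by every requested GDD series — uncovered
    rows raise :class:`MissingCoverageError`; nothing is dropped silently.
    """
    features = list(features)
    unknown = set(features) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}; "
                         f"choose from {ALL_FEATURES}")
    by_name = {}
    for g in gdd_series:
        by_name[_series_feature_name(g)] = g

    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"])
    table = obs[["location_id", "date", "rank"]].copy()
    table["year"] = table["date"].dt.year
    table["doy"] = table["date"].dt.dayofyear

    feat = pd.DataFrame(index=table.index)
    for name in features:
        if name == FEATURE_DOY:
            feat[FEATURE_DOY] = table["doy"].astype(float)
            continue
        if name not in by_name:
            raise ValueError(f"feature {name!r} requested but no matching "
                             f"GDD series supplied (have {sorted(by_name)})")
        g = by_name[name]
        merged = table[["location_id", "date"]].merge(
            g[["location_id", "date", "cum_gdd"]],
            on=["location_id", "date"], how="left",
        )
        if merged["cum_gdd"].isna().any():
            miss = merged[merged["cum_gdd"].isna()].head(5)
            raise MissingCoverageError(
                f"observations not covered by GDD series {name}: "
                + "; ".join(f"{r.location_id} {r.date.date()}"
                            for r in miss.itertuples())
            )
        feat[name] = merged["cum_gdd"].to_numpy()

    if polynomial_degree is not None:
        feat = polynomial_expand(feat, polynomial_degree)

    out = pd.concat([feat, table[["rank", "year", "location_id", "date", "doy"]]],
                    axis=1)
    out.attrs["feature_cols"] = list(feat.columns)
    if len(out) != len(observations):
        raise AssertionError("feature table must have one row per observation")
    return out


def feature_cols(table: pd.DataFrame) -> list:
    """The feature columns of a table built by :func:`build_feature_table`."""
    cols = table.attrs.get("feature_cols")
    if cols is None:
        reserved = {"rank", "year", "location_id", "date", "doy"}
        cols = [c for c in table.columns if c not in reserved]
    return list(cols)
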