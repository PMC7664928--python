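"""Shared fixtures: tiny hand-built tables and reusable synthetic worlds."""

import numpy as np
import pandas as pd
import pytest

import thermopheno as tp


def make_weather(location_id="locA", year=2009, n_days=365, tmin=8.0,
                 tmax=18.0, source="station"):
    """Gap-free constant-temperature weather for one location-year."""
    dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
    return pd.DataFrame({
        "location_id": location_id,
        "date": dates,
        "tmin": float(tmin),
        "tmax": float(tmax),
        "source": source,
    })


@pytest.fixture
def constant_weather():
    return make_weather()


@pytest.fixture(scope="session")
def default_world():
    """The package's default synthetic world (22 locations x 3 years)."""
    return tp.generate_world(seed=1)


@pytest.fixture(scope="session")
def small_world():
    """A smaller world for pipeline smoke tests."""
    cfg = tp.default_config(n_locations=6, years=(2009, 2010), seed=3)
    return tp.generate_world(cfg)


def numeric_sine_dd(tmin, tmax, base, n_steps=30_000):
    """Independent oracle: day-average of degree-hours above base for a
    single sine wave, by trapezoidal integration over one full period."""
    tmin = np.atleast_1d(np.asarray(tmin, dtype=float))
    tmax = np.atleast_1d(np.asarray(tmax, dtype=float))
    m = (tmin + tmax) / 2.0
    a = (tmax - tmin) / 2.0
    t = np.linspace(0.0, 2.0 * np.pi, n_steps + 1)
    vals = np.maximum(0.0, m[:, None] + a[:, None] * np.sin(t)[None, :]
                      - np.asarray(base, dtype=float).reshape(-1, 1))
    out = np.trapezoid(vals, t, axis=1) / (2.0 * np.pi)
    return out if out.size > 1 else float(out[0])


def random_triples(rng, n):
    """Random (tmin, tmax, base) with tmax >= tmin, spanning all branches."""
    tmin = rng.uniform(-15.0, 25.0, n)
    tmax = tmin + rng.uniform(0.0, 25.0, n)
    base = rng.uniform(0.0, 45.0, n)
    return tmin, tmax, base
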