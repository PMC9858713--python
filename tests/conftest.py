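"""Shared fixtures: synthetic series, covariate specs and pair-mode data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossrisk import (
    CovariateSpec,
    CovariateTerm,
    EnvSimConfig,
    EnvironmentalSeries,
    EventSimConfig,
    generate_fixture_bundle,
    northern_covariates,
    simulate_environment,
    simulate_events_pair_mode,
)


@pytest.fixture(scope="session")
def env_series() -> EnvironmentalSeries:
    """Two-plus years of synthetic subtropical weather, fixed seed."""
    return simulate_environment(EnvSimConfig(n_days=800, seed=3))


@pytest.fixture(scope="session")
def northern_spec() -> CovariateSpec:
    return northern_covariates()


@pytest.fixture(scope="session")
def two_term_spec() -> CovariateSpec:
    """Minimal two-coefficient model (no season crossing) for recovery tests."""
    return CovariateSpec(
        region="Northern",
        terms=(
            CovariateTerm("min_temp", 0, season_crossed=False),
            CovariateTerm("ave_rh", 0, season_crossed=False),
        ),
    )


@pytest.fixture(scope="session")
def recovery_pairs(env_series, two_term_spec):
    """Pair-mode data with known truth beta = (-0.3, 0.1), n = 2000."""
    ev = EventSimConfig(
        n_events=500,
        beta_true={"min_temp_lag0": -0.3, "ave_rh_lag0": 0.1},
        seed=11,
    )
    return simulate_events_pair_mode(env_series, two_term_spec, ev)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    generate_fixture_bundle(out, seed=1)
    return out


def constant_series(region: str = "Northern", n_days: int = 60,
                    min_temp: float = 20.0) -> EnvironmentalSeries:
    """A series with every variable constant in time."""
    idx = pd.date_range("2010-01-01", periods=n_days, freq="D")
    frame = pd.DataFrame(
        {
            "min_temp": min_temp,
            "max_temp": min_temp + 6.0,
            "ave_rh": 75.0,
            "max_rh": 88.0,
            "ave_o3": 30.0,
        },
        index=idx,
    )
    return EnvironmentalSeries(region=region, frame=frame)


def sinusoid_series(region: str = "Northern", n_days: int = 1500,
                    mean: float = 20.0, amplitude: float = 5.0,
                    phase: float = 0.7) -> EnvironmentalSeries:
    """Purely sinusoidal temperatures (period 365.25 d), constant humidity/O3."""
    d = np.arange(n_days)
    omega = 2 * np.pi / 365.25
    mt = mean + amplitude * np.sin(omega * d + phase)
    idx = pd.date_range("2008-01-01", periods=n_days, freq="D")
    frame = pd.DataFrame(
        {"min_temp": mt, "max_temp": mt + 6.0, "ave_rh": 75.0,
         "max_rh": 88.0, "ave_o3": 30.0},
        index=idx,
    )
    return EnvironmentalSeries(region=region, frame=frame)
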