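"""Synthetic environmental series and case-crossover events.

The study data behind this kind of analysis (insurance onset records plus
weather-bureau and air-quality monitoring series) are restricted, so this
module generates stand-ins with known ground truth:

* daily exposure series as annual sinusoid + AR(1) noise, bounded to their
  physical ranges (humidity in [0, 100], ozone nonnegative, max >= min
  temperature enforced constructively);
* events whose case-vs-referent day follows the matched-pair conditional
  logistic model with a chosen true coefficient vector.

Two event modes are provided. *Pair mode* draws an index day t and referent
day t-7, computes the case-minus-referent difference vector d exactly as the
design-matrix builder would, and places the event at t with probability
sigma(d . beta_true) — the exact inverse of the conditional likelihood, so
fitting recovers beta_true. *Study mode* samples onset dates from a hazard
proportional to exp(x_day . beta_true) over the timeline and emits plain
onset records, exercising the full pipeline end to end.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import (
    SEASONS,
    ConfigurationError,
    CovariateSpec,
    SeasonMap,
    WindowSpec,
    central_southern_covariates,
    eastern_covariates,
    northern_covariates,
)
from .series import EnvironmentalSeries, write_series_csv
from .windows import (
    MatchedPairDesign,
    META_COLUMNS,
    MissingExposureError,
    SineFit,
    assign_season,
    event_difference_row,
)

__all__ = [
    "VarParams",
    "SpreadParams",
    "EnvSimConfig",
    "EventSimConfig",
    "simulate_environment",
    "simulate_events_pair_mode",
    "simulate_events_study_mode",
    "generate_fixture_bundle",
]

logger = logging.getLogger(__name__)


def _check_finite(name: str, *vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ConfigurationError(f"non-finite parameter in {name}")


@dataclass(frozen=True)
class VarParams:
    """Sinusoid + AR(1) parameters for one daily variable.

    value(d) = mean + amplitude * sin(2*pi*d/365.25 + phase) + e_d, with
    e_d = ar_coef * e_{d-1} + N(0, innovation_sd) started at stationarity.
    """

    mean: float
    amplitude: float = 0.0
    phase: float = 0.0
    ar_coef: float = 0.7
    innovation_sd: float = 1.0

    def __post_init__(self) -> None:
        _check_finite("VarParams", self.mean, self.amplitude, self.phase,
                      self.ar_coef, self.innovation_sd)
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigurationError("AR(1) coefficient must be in [0, 1)")
        if self.innovation_sd < 0:
            raise ConfigurationError("innovation SD must be nonnegative")


@dataclass(frozen=True)
class SpreadParams:
    """Positive gap added to a base variable (e.g. max - min temperature):
    gap = max(floor, N(mean, sd))."""

    mean: float
    sd: float = 0.0
    floor: float = 0.5

    def __post_init__(self) -> None:
        _check_finite("SpreadParams", self.mean, self.sd, self.floor)
        if self.floor <= 0:
            raise ConfigurationError("spread floor must be positive")
        if self.sd < 0:
            raise ConfigurationError("spread SD must be nonnegative")


# Annual phase putting the sinusoid peak in mid July for a Jan-1 start.
_SUMMER_PEAK_PHASE = math.pi / 2 - 2 * math.pi * 195 / 365.25


@dataclass(frozen=True)
class EnvSimConfig:
    """Configuration of one region's synthetic exposure series.

    Defaults emulate a subtropical coastal climate: minimum temperature
    around 19 degC with a 5.5 degC annual swing, a 6-7 degC diurnal spread,
    humid (~77% average RH) with maxima ~15 points higher, and ozone around
    30 concentration units with a modest seasonal cycle.
    """

    region: str = "Northern"
    n_days: int = 730
    start_date: date = date(2006, 1, 1)
    min_temp: VarParams = field(default_factory=lambda: VarParams(
        mean=19.0, amplitude=5.5, phase=_SUMMER_PEAK_PHASE,
        ar_coef=0.7, innovation_sd=1.5))
    temp_spread: SpreadParams = field(default_factory=lambda: SpreadParams(
        mean=6.5, sd=1.5, floor=1.0))
    ave_rh: VarParams = field(default_factory=lambda: VarParams(
        mean=77.0, amplitude=3.0, phase=_SUMMER_PEAK_PHASE,
        ar_coef=0.5, innovation_sd=4.0))
    rh_spread: SpreadParams = field(default_factory=lambda: SpreadParams(
        mean=15.0, sd=4.0, floor=1.0))
    ave_o3: VarParams = field(default_factory=lambda: VarParams(
        mean=30.0, amplitude=8.0, phase=0.0, ar_coef=0.6, innovation_sd=6.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 15:
            raise ConfigurationError(
                "n_days must be >= 15 (one event needs 13 days of history)"
            )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / math.sqrt(1.0 - rho * rho))
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov[t - 1]
    return e


def _signal(params: VarParams, d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    omega = 2.0 * math.pi / 365.25
    return (
        params.mean
        + params.amplitude * np.sin(omega * d + params.phase)
        + _ar1(rng, d.size, params.ar_coef, params.innovation_sd)
    )


def simulate_environment(config: EnvSimConfig) -> EnvironmentalSeries:
    """Generate one region's contiguous daily exposure series.

    Humidity values are generated on an unbounded scale and clipped to
    [0, 100]; ozone is clipped at 0. Clipping is rare under the default
    parameters and is logged when it happens. The max-min temperature and
    max-ave humidity orderings are enforced constructively by adding a
    floored positive spread.
    """
    rng = np.random.default_rng(config.seed)
    d = np.arange(config.n_days, dtype=float)

    min_temp = _signal(config.min_temp, d, rng)
    gap = np.maximum(
        config.temp_spread.floor,
        rng.normal(config.temp_spread.mean, config.temp_spread.sd, size=config.n_days),
    )
    max_temp = min_temp + gap

    ave_rh = _signal(config.ave_rh, d, rng)
    rh_gap = np.maximum(
        config.rh_spread.floor,
        rng.normal(config.rh_spread.mean, config.rh_spread.sd, size=config.n_days),
    )
    max_rh = ave_rh + rh_gap
    n_clip = int((ave_rh < 0).sum() + (ave_rh > 100).sum() + (max_rh > 100).sum())
    ave_rh = np.clip(ave_rh, 0.0, 100.0)
    max_rh = np.clip(max_rh, 0.0, 100.0)
    max_rh = np.maximum(max_rh, ave_rh)

    ave_o3 = _signal(config.ave_o3, d, rng)
    n_clip += int((ave_o3 < 0).sum())
    ave_o3 = np.maximum(ave_o3, 0.0)
    if n_clip:
        logger.info("clipped %d out-of-bound values in region %s", n_clip, config.region)

    idx = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    frame = pd.DataFrame(
        {"min_temp": min_temp, "max_temp": max_temp, "ave_rh": ave_rh,
         "max_rh": max_rh, "ave_o3": ave_o3},
        index=idx,
    )
    return EnvironmentalSeries(region=config.region, frame=frame)


@dataclass(frozen=True)
class EventSimConfig:
    """Event-generation configuration.

    ``beta_true`` is keyed by expanded design-column name (terms not listed
    default to coefficient 0); unknown keys are rejected. ``n_events`` is
    the number of events per region-season stratum in pair mode; study mode
    samples ``4 * n_events`` onsets over the full timeline from the
    exp(x . beta) hazard, since imposing per-season counts would distort it.
    """

    n_events: int = 100
    beta_true: Mapping[str, float] = field(default_factory=dict)
    mode: str = "pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if self.mode not in ("pair", "study"):
            raise ConfigurationError("mode must be 'pair' or 'study'")
        for v in self.beta_true.values():
            _check_finite("beta_true", v)

    def beta_vector(self, columns: Sequence[str]) -> np.ndarray:
        unknown = [k for k in self.beta_true if k not in columns]
        if unknown:
            raise ConfigurationError(
                f"beta_true keys {unknown} do not match configured terms"
            )
        return np.array([float(self.beta_true.get(c, 0.0)) for c in columns])


def _eligible_days(series: EnvironmentalSeries, window: WindowSpec) -> list[date]:
    start = series.start_date + timedelta(days=window.required_history)
    n = (series.end_date - start).days + 1
    if n <= 0:
        raise ConfigurationError("series too short: no eligible onset days")
    return [start + timedelta(days=i) for i in range(n)]


def simulate_events_pair_mode(
    series: EnvironmentalSeries,
    cov: CovariateSpec,
    ev: EventSimConfig,
    season_map: SeasonMap | None = None,
    window_spec: WindowSpec | None = None,
    sine_fits: Mapping[str, SineFit] | None = None,
    detrend_variables: Sequence[str] = (),
) -> MatchedPairDesign:
    """Labeled day-pairs drawn from the exact conditional likelihood.

    For each event a candidate index day t is drawn (uniformly within the
    stratum's eligible days); d is the case-minus-referent difference vector
    for onset t, and the label is 1 (event at t) with probability
    sigma(d . beta_true), else 0 (event at the referent day t-7). Candidate
    days lacking full lag history are skipped and counted.
    """
    season_map = season_map or SeasonMap()
    window_spec = window_spec or WindowSpec()
    columns = cov.column_names
    beta = ev.beta_vector(columns)
    rng = np.random.default_rng(ev.seed)

    eligible = _eligible_days(series, window_spec)
    by_season: dict[str, list[date]] = {s: [] for s in SEASONS}
    for day in eligible:
        by_season[assign_season(day, season_map)].append(day)

    rows = []
    n_skipped = 0
    eid = 0
    for season in SEASONS:
        days = by_season[season]
        if not days:
            continue
        picks = rng.integers(0, len(days), size=ev.n_events)
        for i in picks:
            onset = days[int(i)]
            try:
                _, diff = event_difference_row(
                    onset, series, cov, season_map, window_spec,
                    sine_fits, detrend_variables,
                )
            except MissingExposureError:
                n_skipped += 1
                continue
            d = np.array([diff[c] for c in columns])
            p_case = 1.0 / (1.0 + math.exp(-float(d @ beta)))
            label = int(rng.random() < p_case)
            eid += 1
            rows.append(
                {"event_id": f"P{eid:05d}", "region": series.region,
                 "season": season, "label": label, **diff}
            )
    if n_skipped:
        logger.info("pair mode skipped %d candidate days lacking lag history", n_skipped)
    frame = pd.DataFrame(rows, columns=[*META_COLUMNS, *columns])
    return MatchedPairDesign(frame=frame, terms=columns)


def simulate_events_study_mode(
    series: EnvironmentalSeries,
    cov: CovariateSpec,
    ev: EventSimConfig,
    season_map: SeasonMap | None = None,
    window_spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Onset records sampled from a hazard proportional to exp(x . beta_true).

    x is the day's case-window covariate vector (season-crossed expansion at
    the day's own season). Returns ``subject_id, region, onset_date`` rows
    sorted by onset date — the raw-material input of the full pipeline.
    """
    season_map = season_map or SeasonMap()
    window_spec = window_spec or WindowSpec()
    columns = cov.column_names
    beta = ev.beta_vector(columns)
    rng = np.random.default_rng(ev.seed)

    eligible = _eligible_days(series, window_spec)
    scores = np.empty(len(eligible))
    for i, day in enumerate(eligible):
        season = assign_season(day, season_map)
        x = np.zeros(len(columns))
        for term in cov.terms:
            val = series.value(term.variable, day - timedelta(days=term.lag))
            if term.season_crossed:
                x[columns.index(f"{term.variable}_lag{term.lag}_{season}")] = val
            else:
                x[columns.index(f"{term.variable}_lag{term.lag}")] = val
        scores[i] = float(x @ beta)
    w = np.exp(scores - scores.max())
    w /= w.sum()

    n_total = 4 * ev.n_events
    picks = rng.choice(len(eligible), size=n_total, replace=True, p=w)
    picks.sort()
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n_total)],
            "region": series.region,
            "onset_date": [eligible[int(i)] for i in picks],
        }
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

_BUNDLE_REGIONS = {
    "Northern": northern_covariates,
    "CentralSouthern": central_southern_covariates,
    "Eastern": eastern_covariates,
}


def generate_fixture_bundle(
    out_dir: str | Path,
    seed: int = 1,
    n_days: int = 730,
    n_events_per_region: int = 200,
    beta_true: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write the small deterministic CSV/config fixture set used by tests
    and examples: three regions of two-year daily series, ~200 study-mode
    onsets in total, a pair-mode validation table for the Northern region,
    and a pipeline config YAML. Returns the paths keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if beta_true is None:
        # Mild effects on raw exposure levels: strong coefficients on a
        # ~20 degC or ~77% level would concentrate the exp(x.beta) hazard
        # in one season and starve the others of events.
        beta_true = {"min_temp_lag0_Spring": -0.05, "min_temp_lag3_Summer": -0.04,
                     "ave_rh_lag0_Winter": -0.01}

    series_list = []
    onset_frames = []
    for i, (region, factory) in enumerate(_BUNDLE_REGIONS.items()):
        env_cfg = EnvSimConfig(region=region, n_days=n_days,
                               seed=int(rng.integers(0, 2**31 - 1)))
        series = simulate_environment(env_cfg)
        series_list.append(series)
        cov = factory(region)
        usable = {k: v for k, v in beta_true.items() if k in cov.column_names}
        ev_cfg = EventSimConfig(
            n_events=max(1, n_events_per_region // 4),
            beta_true=usable, mode="study",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        onset_frames.append(simulate_events_study_mode(series, cov, ev_cfg))

    paths: dict[str, Path] = {}
    paths["series"] = out / "series.csv"
    write_series_csv(series_list, paths["series"])
    onsets = pd.concat(onset_frames, ignore_index=True)
    onsets["onset_date"] = pd.to_datetime(onsets["onset_date"]).dt.strftime("%Y-%m-%d")
    paths["onsets"] = out / "onsets.csv"
    onsets.to_csv(paths["onsets"], index=False)

    north_cov = northern_covariates()
    pair_cfg = EventSimConfig(
        n_events=50,
        beta_true={k: v for k, v in beta_true.items()
                   if k in north_cov.column_names},
        mode="pair", seed=int(rng.integers(0, 2**31 - 1)),
    )
    pairs = simulate_events_pair_mode(series_list[0], north_cov, pair_cfg)
    paths["pairs"] = out / "pairs_northern.csv"
    pairs.to_csv(paths["pairs"])

    config = {
        "series_csv": str(paths["series"]),
        "onsets_csv": str(paths["onsets"]),
        "output_dir": str(out / "results"),
        "covariates": {"Northern": "northern",
                       "CentralSouthern": "central_southern",
                       "Eastern": "eastern"},
        "mcmc": {"iterations": 4000, "burn_in": 1000, "thinning": 3, "seed": seed},
    }
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    logger.info("fixture bundle written to %s (seed %d)", out, seed)
    return paths


def file_sha256(path: str | Path) -> str:
    """Content hash helper for determinism checks on fixture files."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
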