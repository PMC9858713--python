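"""Configuration types for the case-crossover risk pipeline.

Everything the pipeline needs to know that is not data lives here: the
case/control lag scheme, the month-to-season mapping, per-region covariate
specifications (which variables, at which lags, crossed with season or not),
the Normal prior on the regression coefficients, and the MCMC schedule.

All types are plain frozen dataclasses validated on construction, and every
one of them can be built from a plain dict so that a whole pipeline can be
described in one YAML or JSON file (see :class:`PipelineConfig`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SEASONS",
    "VARIABLES",
    "ConfigurationError",
    "WindowSpec",
    "SeasonMap",
    "CovariateTerm",
    "CovariateSpec",
    "PriorSpec",
    "MCMCSettings",
    "PipelineConfig",
    "northern_covariates",
    "central_southern_covariates",
    "eastern_covariates",
    "default_region_covariates",
]

#: Fixed season ordering used for deterministic design-matrix column order.
SEASONS: tuple[str, ...] = ("Spring", "Summer", "Autumn", "Winter")

#: Canonical environmental-series variables (units: degC, degC, %, %, conc.).
VARIABLES: tuple[str, ...] = ("min_temp", "max_temp", "ave_rh", "max_rh", "ave_o3")


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class WindowSpec:
    """Case/control lag scheme of the self-matched design.

    Each pair ``(case_lag, control_lag)`` means the case exposure is read on
    day ``-case_lag`` relative to onset and the matched control exposure on
    day ``-control_lag``; the control day is always exactly one week before
    the case day, so ``control_lag = case_lag + 7``.
    """

    lag_pairs: tuple[tuple[int, int], ...] = ((0, 7), (1, 8), (3, 10))

    def __post_init__(self) -> None:
        _require(len(self.lag_pairs) > 0, "need at least one lag pair")
        for case_lag, control_lag in self.lag_pairs:
            _require(case_lag >= 0, f"negative case lag {case_lag}")
            _require(
                control_lag == case_lag + 7,
                f"control lag must be case lag + 7, got ({case_lag}, {control_lag})",
            )
            _require(control_lag <= 13, f"max lag is 13 days, got {control_lag}")

    @property
    def case_lags(self) -> tuple[int, ...]:
        return tuple(p[0] for p in self.lag_pairs)

    @property
    def max_lag(self) -> int:
        return max(p[1] for p in self.lag_pairs)

    #: Days of history an onset must have available to be retained.
    required_history: int = field(default=13, init=False, repr=False)

    def control_lag_for(self, case_lag: int) -> int:
        for cl, kl in self.lag_pairs:
            if cl == case_lag:
                return kl
        raise ConfigurationError(f"case lag {case_lag} not in window spec")


_DEFAULT_MONTH_SEASON = {
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
    12: "Winter", 1: "Winter", 2: "Winter",
}


@dataclass(frozen=True)
class SeasonMap:
    """Total mapping month (1-12) -> season label.

    The default is the standard meteorological convention for subtropical
    Taiwan: Mar-May Spring, Jun-Aug Summer, Sep-Nov Autumn, Dec-Feb Winter.
    """

    month_to_season: Mapping[int, str] = field(
        default_factory=lambda: dict(_DEFAULT_MONTH_SEASON)
    )

    def __post_init__(self) -> None:
        _require(
            set(self.month_to_season) == set(range(1, 13)),
            "season map must assign every month 1-12 exactly once",
        )
        bad = set(self.month_to_season.values()) - set(SEASONS)
        _require(not bad, f"unknown season labels {sorted(bad)}")

    def season_of(self, day: date) -> str:
        return self.month_to_season[day.month]

    def months_in(self, season: str) -> tuple[int, ...]:
        return tuple(m for m, s in self.month_to_season.items() if s == season)


@dataclass(frozen=True)
class CovariateTerm:
    """One base regression term: a variable at a case lag, optionally
    crossed with season (one coefficient per season, nonzero only in the
    event's season)."""

    variable: str
    lag: int
    season_crossed: bool = True

    def __post_init__(self) -> None:
        _require(self.variable in VARIABLES, f"unknown variable {self.variable!r}")
        _require(self.lag >= 0, "lag must be nonnegative")

    def column_names(self) -> tuple[str, ...]:
        base = f"{self.variable}_lag{self.lag}"
        if self.season_crossed:
            return tuple(f"{base}_{s}" for s in SEASONS)
        return (base,)


@dataclass(frozen=True)
class CovariateSpec:
    """Per-region list of covariate terms, expanded deterministically into
    design-matrix columns (base terms in declared order, seasons in the
    fixed order Spring, Summer, Autumn, Winter)."""

    region: str
    terms: tuple[CovariateTerm, ...]

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            key = (t.variable, t.lag)
            _require(key not in seen, f"duplicate term {key}")
            seen.add(key)

    def validate_against_window(self, window: WindowSpec) -> None:
        for t in self.terms:
            if t.lag not in window.case_lags:
                raise ConfigurationError(
                    f"term lag {t.lag} not present in window spec {window.case_lags}"
                )

    @property
    def column_names(self) -> tuple[str, ...]:
        cols: list[str] = []
        for t in self.terms:
            cols.extend(t.column_names())
        return tuple(cols)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)


def northern_covariates(region: str = "Northern") -> CovariateSpec:
    """Northern-style specification: six season-crossed terms (24 columns)."""
    return CovariateSpec(
        region=region,
        terms=(
            CovariateTerm("min_temp", 0),
            CovariateTerm("min_temp", 3),
            CovariateTerm("max_temp", 0),
            CovariateTerm("max_temp", 1),
            CovariateTerm("ave_rh", 0),
            CovariateTerm("max_rh", 3),
        ),
    )


def central_southern_covariates(region: str = "CentralSouthern") -> CovariateSpec:
    """Central/Southern-style specification: the Northern terms plus average
    ozone at day 0 entered without season crossing (25 columns)."""
    base = northern_covariates(region)
    return replace(
        base, terms=base.terms + (CovariateTerm("ave_o3", 0, season_crossed=False),)
    )


def eastern_covariates(region: str = "Eastern") -> CovariateSpec:
    """Eastern-style specification: five season-crossed terms (20 columns)."""
    return CovariateSpec(
        region=region,
        terms=(
            CovariateTerm("min_temp", 0),
            CovariateTerm("min_temp", 3),
            CovariateTerm("max_temp", 0),
            CovariateTerm("max_rh", 0),
            CovariateTerm("max_rh", 3),
        ),
    )


def default_region_covariates() -> dict[str, CovariateSpec]:
    return {
        "Northern": northern_covariates(),
        "CentralSouthern": central_southern_covariates(),
        "Eastern": eastern_covariates(),
    }


@dataclass(frozen=True)
class PriorSpec:
    """Independent Normal prior on each regression coefficient.

    The default Normal(0, 100) (variance 100, SD 10) is weakly informative
    on the log-odds scale.
    """

    mean: float = 0.0
    variance: float = 100.0

    def __post_init__(self) -> None:
        _require(self.variance > 0, "prior variance must be positive")
        _require(
            math.isfinite(self.mean) and math.isfinite(self.variance),
            "prior parameters must be finite",
        )


@dataclass(frozen=True)
class MCMCSettings:
    """Random-walk Metropolis schedule.

    Defaults follow the 60,000-iteration / 10,000 burn-in / thin-10 schedule,
    which retains exactly 5000 draws. Proposal scales are adapted toward
    ``target_acceptance`` during burn-in only and frozen afterwards.
    """

    iterations: int = 60_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    initial_scale: float = 0.1
    target_acceptance: float = 0.44

    def __post_init__(self) -> None:
        _require(self.burn_in < self.iterations, "burn-in must be < total iterations")
        _require(self.burn_in >= 0, "burn-in must be nonnegative")
        _require(self.thinning >= 1, "thinning must be >= 1")
        _require(self.initial_scale > 0, "initial proposal scale must be positive")
        _require(0 < self.target_acceptance < 1, "target acceptance in (0,1)")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


# ---------------------------------------------------------------------------
# Whole-pipeline configuration (YAML/JSON)
# ---------------------------------------------------------------------------

def _term_from_dict(d: Mapping) -> CovariateTerm:
    return CovariateTerm(
        variable=d["variable"],
        lag=int(d["lag"]),
        season_crossed=bool(d.get("season_crossed", True)),
    )


def _covariates_from_obj(region: str, obj) -> CovariateSpec:
    if isinstance(obj, str):  # named default, e.g. "northern"
        factory = {
            "northern": northern_covariates,
            "central_southern": central_southern_covariates,
            "eastern": eastern_covariates,
        }.get(obj)
        _require(factory is not None, f"unknown covariate preset {obj!r}")
        return factory(region)
    return CovariateSpec(region=region, terms=tuple(_term_from_dict(t) for t in obj))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run simulate -> fit -> alert end to end."""

    series_csv: str = "series.csv"
    onsets_csv: str = "onsets.csv"
    output_dir: str = "out"
    covariates: Mapping[str, CovariateSpec] = field(
        default_factory=default_region_covariates
    )
    season_map: SeasonMap = field(default_factory=SeasonMap)
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    detrend_variables: tuple[str, ...] = ("min_temp", "max_temp")
    raw_log_stats: bool = False
    dispersion_scale: str = "or"

    def __post_init__(self) -> None:
        _require(
            self.dispersion_scale in ("log", "or"),
            "dispersion_scale must be 'log' or 'or'",
        )
        for v in self.detrend_variables:
            _require(v in VARIABLES, f"unknown detrend variable {v!r}")
        for spec in self.covariates.values():
            spec.validate_against_window(self.window_spec)

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.covariates)

    # -- construction from plain dicts / files ------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("series_csv", "onsets_csv", "output_dir",
                    "raw_log_stats", "dispersion_scale"):
            if key in d:
                kwargs[key] = d[key]
        if "detrend_variables" in d:
            kwargs["detrend_variables"] = tuple(d["detrend_variables"])
        if "covariates" in d:
            kwargs["covariates"] = {
                region: _covariates_from_obj(region, obj)
                for region, obj in d["covariates"].items()
            }
        if "season_map" in d:
            kwargs["season_map"] = SeasonMap(
                {int(m): s for m, s in d["season_map"].items()}
            )
        if "window_spec" in d:
            kwargs["window_spec"] = WindowSpec(
                tuple((int(a), int(b)) for a, b in d["window_spec"])
            )
        if "prior" in d:
            kwargs["prior"] = PriorSpec(**d["prior"])
        if "mcmc" in d:
            kwargs["mcmc"] = MCMCSettings(**d["mcmc"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        _require(isinstance(data, Mapping), f"config file {path} is not a mapping")
        return cls.from_dict(data)
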