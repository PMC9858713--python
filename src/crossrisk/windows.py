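"""Matched case/control exposure windows and the differenced design matrix.

The self-matched design compares each event's exposure near onset (the case
window: days 0, -1, -3) with the same person's exposure exactly one week
earlier (the control window: days -7, -8, -10). This module extracts those
paired exposures, removes the annual sinusoidal component from control-window
temperatures so that pure seasonality does not masquerade as a short-term
contrast, and assembles the per-event case-minus-control difference vectors
that the conditional logistic likelihood operates on.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    SEASONS,
    ConfigurationError,
    CovariateSpec,
    SeasonMap,
    WindowSpec,
)
from .series import EnvironmentalSeries

__all__ = [
    "MissingExposureError",
    "WindowPair",
    "SineFit",
    "MatchedPairDesign",
    "assign_season",
    "extract_window_pairs",
    "fit_seasonal_sine",
    "adjust_control_temperature",
    "build_design_matrix",
    "read_design_csv",
]

logger = logging.getLogger(__name__)

#: Angular frequency of the annual cycle, radians per day.
ANNUAL_OMEGA = 2.0 * math.pi / 365.25

META_COLUMNS = ("event_id", "region", "season", "label")


class MissingExposureError(KeyError):
    """An event's required exposure day is not covered by the series."""


def assign_season(day: date, season_map: SeasonMap) -> str:
    """Season label of a calendar day under the configured month mapping."""
    return season_map.season_of(day)


@dataclass(frozen=True)
class WindowPair:
    """Paired raw exposures for one (case_lag, control_lag) pair."""

    case_lag: int
    control_lag: int
    case_date: date
    control_date: date
    values: Mapping[str, tuple[float, float]]  # variable -> (case, control)


def extract_window_pairs(
    onset_date: date,
    series: EnvironmentalSeries,
    spec: WindowSpec,
) -> list[WindowPair]:
    """Raw case-day and control-day exposures for every lag pair.

    Raises :class:`MissingExposureError` if the series does not cover
    ``onset_date - 13`` through ``onset_date`` (the event is then excluded
    by the caller, never imputed).
    """
    earliest = onset_date - timedelta(days=spec.required_history)
    if not (series.covers(earliest) and series.covers(onset_date)):
        raise MissingExposureError(
            f"series {series.region} does not cover {earliest}..{onset_date}"
        )
    pairs: list[WindowPair] = []
    for case_lag, control_lag in spec.lag_pairs:
        cd = onset_date - timedelta(days=case_lag)
        kd = onset_date - timedelta(days=control_lag)
        values = {}
        for v in series.frame.columns:
            cv, kv = series.value(v, cd), series.value(v, kd)
            if not (np.isfinite(cv) and np.isfinite(kv)):
                raise MissingExposureError(
                    f"missing {v} on {cd} or {kd} for onset {onset_date}"
                )
            values[v] = (cv, kv)
        pairs.append(WindowPair(case_lag, control_lag, cd, kd, values))
    return pairs


@dataclass(frozen=True)
class SineFit:
    """Least-squares annual sinusoid ``a0 + a1 sin(wd) + a2 cos(wd)`` with
    the angular frequency fixed at 2*pi/365.25 per day; ``d`` counts days
    from ``origin``."""

    variable: str
    a0: float
    a1: float
    a2: float
    origin: date
    omega: float = ANNUAL_OMEGA

    def predict(self, day: date) -> float:
        d = (day - self.origin).days
        return self.a0 + self.a1 * math.sin(self.omega * d) + self.a2 * math.cos(self.omega * d)


def fit_seasonal_sine(series: EnvironmentalSeries, variable: str) -> SineFit:
    """OLS fit of the annual sinusoid to one variable of a daily series.

    The sin+cos basis is the linear reparameterisation of amplitude+phase,
    so the fit is closed-form and exact on pure sinusoids. A series shorter
    than a full year leaves the annual frequency poorly identified, so a
    warning is emitted in that case.
    """
    y = series.frame[variable].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError(f"variable {variable!r} has no finite values")
    if len(y) < 365:
        warnings.warn(
            f"seasonal sine fit on {len(y)} days (< 365); annual component "
            "is weakly identified",
            stacklevel=2,
        )
    d = np.arange(len(y), dtype=float)[ok]
    X = np.column_stack([np.ones_like(d), np.sin(ANNUAL_OMEGA * d), np.cos(ANNUAL_OMEGA * d)])
    coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    return SineFit(
        variable=variable,
        a0=float(coef[0]),
        a1=float(coef[1]),
        a2=float(coef[2]),
        origin=series.start_date,
    )


def adjust_control_temperature(
    raw_control_value: float,
    case_date: date,
    control_date: date,
    fit: SineFit,
) -> float:
    """Shift a control-window value by the fitted seasonal difference
    between case and control days.

    Adding ``fitted(case) - fitted(control)`` to the control value removes
    the predictable one-week seasonal drift from the case-minus-control
    contrast: on a purely sinusoidal series the adjusted difference is zero.
    """
    return raw_control_value + (fit.predict(case_date) - fit.predict(control_date))


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class MatchedPairDesign:
    """Per-event case-minus-control difference vectors.

    ``frame`` holds the metadata columns (event_id, region, season, label)
    followed by one column per expanded covariate term; ``terms`` records
    the deterministic column order. ``label`` is 1 for study rows (the event
    occurred on the index day) and 0/1 in pair-mode validation data.
    """

    frame: pd.DataFrame
    terms: tuple[str, ...]
    exclusions: list[tuple[object, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *self.terms) if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"design frame missing columns {missing}")
        X = self.frame[list(self.terms)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ConfigurationError("non-finite design-matrix entries")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.terms)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=float)

    @property
    def n_events(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "MatchedPairDesign":
        return MatchedPairDesign(
            frame=self.frame.loc[mask].reset_index(drop=True),
            terms=self.terms,
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6g")


def read_design_csv(path: str | Path) -> MatchedPairDesign:
    frame = pd.read_csv(path)
    terms = tuple(c for c in frame.columns if c not in META_COLUMNS)
    return MatchedPairDesign(frame=frame, terms=terms)


def event_difference_row(
    onset_date: date,
    series: EnvironmentalSeries,
    cov: CovariateSpec,
    season_map: SeasonMap,
    window_spec: WindowSpec,
    sine_fits: Mapping[str, SineFit] | None = None,
    detrend_variables: Sequence[str] = ("min_temp", "max_temp"),
) -> tuple[str, dict[str, float]]:
    """Season and expanded difference vector for a single onset date.

    The event's season is that of the onset day and applies to all its
    lagged terms. Season-crossed terms contribute to the event's-season
    column only; all other expanded columns are zero.
    """
    season = assign_season(onset_date, season_map)
    pairs = {p.case_lag: p for p in extract_window_pairs(onset_date, series, window_spec)}
    row = dict.fromkeys(cov.column_names, 0.0)
    for term in cov.terms:
        pair = pairs[term.lag]
        case_val, control_val = pair.values[term.variable]
        if sine_fits and term.variable in detrend_variables and term.variable in sine_fits:
            control_val = adjust_control_temperature(
                control_val, pair.case_date, pair.control_date, sine_fits[term.variable]
            )
        diff = case_val - control_val
        if term.season_crossed:
            row[f"{term.variable}_lag{term.lag}_{season}"] = diff
        else:
            row[f"{term.variable}_lag{term.lag}"] = diff
    return season, row


def build_design_matrix(
    onsets: pd.DataFrame,
    series: EnvironmentalSeries,
    cov: CovariateSpec,
    season_map: SeasonMap | None = None,
    window_spec: WindowSpec | None = None,
    sine_fits: Mapping[str, SineFit] | None = None,
    detrend_variables: Sequence[str] = ("min_temp", "max_temp"),
) -> MatchedPairDesign:
    """Assemble the matched-pair design matrix for one region.

    Parameters
    ----------
    onsets
        DataFrame with columns ``subject_id`` and ``onset_date`` (plus an
        optional ``region`` column, filtered to this series' region).
    series
        The region's environmental series.
    cov
        Covariate specification for the region; season-crossed base terms
        expand into four columns each, plain terms into one.
    sine_fits
        Per-variable annual sine fits; when given, control-window values of
        the ``detrend_variables`` are seasonally adjusted before differencing.

    Events missing any required exposure day are excluded and logged, never
    imputed. Every retained row has ``label = 1``.
    """
    season_map = season_map or SeasonMap()
    window_spec = window_spec or WindowSpec()
    cov.validate_against_window(window_spec)
    for term in cov.terms:
        if term.variable not in series.frame.columns:
            raise ConfigurationError(
                f"covariate variable {term.variable!r} absent from series"
            )
    if "region" in onsets.columns:
        onsets = onsets[onsets["region"] == series.region]

    rows: list[dict] = []
    exclusions: list[tuple[object, str]] = []
    for rec in onsets.itertuples(index=False):
        onset = pd.Timestamp(rec.onset_date).date()
        event_id = getattr(rec, "subject_id", None) or getattr(rec, "event_id", None)
        try:
            season, diff = event_difference_row(
                onset, series, cov, season_map, window_spec, sine_fits, detrend_variables
            )
        except MissingExposureError as exc:
            exclusions.append((event_id, str(exc)))
            continue
        rows.append(
            {"event_id": event_id, "region": series.region, "season": season,
             "label": 1, **diff}
        )
    if exclusions:
        logger.info(
            "excluded %d/%d events for missing exposure days in region %s",
            len(exclusions), len(onsets), series.region,
        )
    columns = [*META_COLUMNS, *cov.column_names]
    frame = pd.DataFrame(rows, columns=columns)
    if frame.empty:
        frame = frame.astype({c: float for c in cov.column_names} | {"label": int})
    return MatchedPairDesign(frame=frame, terms=cov.column_names, exclusions=exclusions)
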