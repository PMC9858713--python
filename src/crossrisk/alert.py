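"""Per-event odds-ratio prediction and the six-level disease-risk alert scale.

For an exposure contrast d (case-minus-control differences) and fitted
coefficients beta, the predicted log odds ratio is lnOR = beta . d. Alert
thresholds for a region-season stratum are built from the lnOR values of all
its retained case days: with m = median(lnOR) and s = SD(lnOR),

    c_g = exp{ m + 0.5 * (g - 2) * s },   g = 1..6,

a geometric progression of critical values on the OR scale (common ratio
exp(0.5 s), with c2 = exp(m)). A predicted OR is assigned the smallest level
g with OR < c_g; ORs at or above c6 are capped at level 6, so level g
occupies the interval [c_{g-1}, c_g) with c0 = 0.

Published alert tables sometimes report the stratum dispersion already
exponentiated onto the OR scale; ``AlertThresholds.from_or_stats`` accepts
either reading via ``dispersion_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clogit import PosteriorDraws, _align_beta

__all__ = [
    "N_LEVELS",
    "AlertThresholds",
    "RiskPrediction",
    "predict_lnor",
    "compute_thresholds",
    "classify",
    "level_probabilities",
    "threshold_table_report",
    "predict_events",
]

N_LEVELS = 6


def predict_lnor(beta, d, terms: Sequence[str] | None = None) -> float:
    """Predicted log odds ratio ``beta . d`` for one exposure contrast.

    ``beta`` and ``d`` may both be mappings keyed by term name (aligned via
    ``terms`` or beta's own keys) or plain arrays in matching order.
    """
    if isinstance(beta, Mapping) and terms is None:
        terms = tuple(beta)
    if terms is not None:
        b = _align_beta(beta, terms)
        dv = _align_beta(d, terms)
    else:
        b = np.asarray(beta, dtype=float).ravel()
        dv = np.asarray(d, dtype=float).ravel()
        if b.size != dv.size:
            raise ValueError(f"length mismatch: beta {b.size} vs d {dv.size}")
    return float(b @ dv)


@dataclass(frozen=True)
class AlertThresholds:
    """Six-level alert critical values for one region-season stratum.

    Stored on the log-OR scale (``median_lnor``, ``sd_lnor``); the critical
    values c1..c6 are derived on the OR scale and form a geometric
    progression with ratio exp(0.5 * sd_lnor) anchored at c2 = exp(median).
    """

    region: str
    season: str
    median_lnor: float
    sd_lnor: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.median_lnor) and math.isfinite(self.sd_lnor)):
            raise ValueError("non-finite alert statistics")
        if self.sd_lnor < 0:
            raise ValueError("negative lnOR dispersion")

    @property
    def critical_values(self) -> np.ndarray:
        g = np.arange(1, N_LEVELS + 1)
        return np.exp(self.median_lnor + 0.5 * (g - 2) * self.sd_lnor)

    @property
    def median_or(self) -> float:
        return math.exp(self.median_lnor)

    @classmethod
    def from_or_stats(
        cls,
        region: str,
        season: str,
        median_or: float,
        dispersion: float,
        dispersion_scale: str = "log",
    ) -> "AlertThresholds":
        """Build thresholds from an OR-scale summary row.

        ``dispersion_scale="log"`` treats ``dispersion`` as SD(lnOR)
        directly; ``"or"`` treats it as exp(SD(lnOR)) and takes its log.
        """
        if median_or <= 0:
            raise ValueError("median OR must be positive")
        if dispersion_scale == "log":
            sd = float(dispersion)
        elif dispersion_scale == "or":
            if dispersion <= 0:
                raise ValueError("OR-scale dispersion must be positive")
            sd = math.log(dispersion)
        else:
            raise ValueError("dispersion_scale must be 'log' or 'or'")
        return cls(region=region, season=season,
                   median_lnor=math.log(median_or), sd_lnor=sd)


def compute_thresholds(
    lnor_values: Iterable[float], region: str, season: str
) -> AlertThresholds:
    """Thresholds from the lnOR values of a stratum's retained case days
    (median and sample SD on the log scale; needs at least two values)."""
    vals = np.asarray(list(lnor_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 lnOR values to estimate a spread")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite lnOR values")
    return AlertThresholds(
        region=region,
        season=season,
        median_lnor=float(np.median(vals)),
        sd_lnor=float(np.std(vals, ddof=1)),
    )


def classify(or_value: float, thresholds: AlertThresholds) -> int:
    """Alert level of a predicted OR: smallest g with OR < c_g, capped at 6."""
    if not (or_value > 0) or not math.isfinite(or_value):
        raise ValueError(f"OR must be positive and finite, got {or_value}")
    c = thresholds.critical_values
    level = int(np.searchsorted(c, or_value, side="right")) + 1
    return min(level, N_LEVELS)


def level_probabilities(
    draws: PosteriorDraws, d, thresholds: AlertThresholds
) -> np.ndarray:
    """Posterior probability of each alert level for one exposure contrast.

    Each retained draw gives OR = exp(beta_draw . d); the returned 6-vector
    is the relative frequency of each level over the draws (sums to 1).
    """
    if draws.n_retained == 0:
        raise ValueError("no retained draws")
    dv = _align_beta(d, draws.terms)
    lnors = draws.draws @ dv
    c = thresholds.critical_values
    levels = np.minimum(
        np.searchsorted(c, np.exp(lnors), side="right") + 1, N_LEVELS
    )
    counts = np.bincount(levels, minlength=N_LEVELS + 1)[1:]
    return counts / counts.sum()


@dataclass(frozen=True)
class RiskPrediction:
    """One event's (or forecast day's) predicted risk and alert level."""

    event_id: object
    lnor: float
    odds_ratio: float
    level: int
    level_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.odds_ratio > 0:
            raise ValueError("odds ratio must be positive")
        if not 1 <= self.level <= N_LEVELS:
            raise ValueError("level out of range 1..6")
        if self.level_probs is not None:
            p = np.asarray(self.level_probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("level probabilities must sum to 1")


def predict_events(
    beta,
    design_frame: pd.DataFrame,
    terms: Sequence[str],
    thresholds_by_stratum: Mapping[tuple[str, str], AlertThresholds],
    draws: PosteriorDraws | None = None,
) -> pd.DataFrame:
    """Classify every row of a design/forecast table.

    Returns a DataFrame with ``event_id``, ``lnOR``, ``OR``, ``level`` and,
    when posterior draws are supplied, ``p_level1``..``p_level6``.
    """
    b = _align_beta(beta, terms)
    records = []
    for rec in design_frame.itertuples(index=False):
        d = np.array([getattr(rec, t) for t in terms], dtype=float)
        lnor = float(b @ d)
        thr = thresholds_by_stratum[(rec.region, rec.season)]
        or_val = math.exp(lnor)
        row = {
            "event_id": rec.event_id,
            "region": rec.region,
            "season": rec.season,
            "lnOR": lnor,
            "OR": or_val,
            "level": classify(or_val, thr),
        }
        if draws is not None:
            probs = level_probabilities(draws, d, thr)
            row.update({f"p_level{g}": probs[g - 1] for g in range(1, N_LEVELS + 1)})
        records.append(row)
    return pd.DataFrame.from_records(records)


def threshold_table_report(
    thresholds: Iterable[AlertThresholds], raw_log_stats: bool = False
) -> pd.DataFrame:
    """Per region-season alert table: central value, dispersion and the six
    level boundaries.

    By default both summary columns are OR-scale quantities (median OR and
    exp(SD lnOR)); with ``raw_log_stats=True`` the log-scale median and SD
    are emitted instead. The boundary columns c1..c6 are always OR-scale.
    """
    rows = []
    for thr in thresholds:
        c = thr.critical_values
        row = {
            "region": thr.region,
            "season": thr.season,
            "median_OR" if not raw_log_stats else "median_lnOR":
                thr.median_or if not raw_log_stats else thr.median_lnor,
            "dispersion":
                math.exp(thr.sd_lnor) if not raw_log_stats else thr.sd_lnor,
        }
        row.update({f"c{g}": c[g - 1] for g in range(1, N_LEVELS + 1)})
        rows.append(row)
    return pd.DataFrame.from_records(rows)
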