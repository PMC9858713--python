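"""End-to-end orchestration: simulate -> fit -> alert.

These functions tie the stages together with file-based interchange so a
whole analysis is reproducible from one :class:`~crossrisk.config.PipelineConfig`
(YAML/JSON). Each stage is idempotent given fixed seed and inputs; every
floating-point artifact is written with 6 significant digits so reruns diff
cleanly. Regions are always fitted independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import alert as alert_mod
from .clogit import PosteriorDraws, PosteriorSummary, run_mcmc, summarize
from .config import SEASONS, ConfigurationError, PipelineConfig
from .series import read_series_csv
from .synthetic import generate_fixture_bundle
from .windows import MatchedPairDesign, build_design_matrix, fit_seasonal_sine

__all__ = ["RegionFit", "run_simulate", "run_fit", "run_alert", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RegionFit:
    """In-memory artifacts of one region's fit."""

    region: str
    design: MatchedPairDesign
    draws: PosteriorDraws
    summary: PosteriorSummary


def _outdir(config: PipelineConfig, out_dir) -> Path:
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig, out_dir=None, seed: int = 1) -> dict[str, Path]:
    """Write the synthetic fixture set (series, onsets, pair-mode table,
    config) into the output directory; seed is echoed in the log."""
    out = _outdir(config, out_dir)
    logger.info("simulate: seed=%d out=%s", seed, out)
    return generate_fixture_bundle(out, seed=seed)


def run_fit(config: PipelineConfig, out_dir=None) -> dict[str, RegionFit]:
    """Per region: build the matched design, run the MCMC, summarize.

    Writes ``design_<region>.csv``, ``summary_<region>.csv``,
    ``draws_<region>.csv`` and a JSON sidecar with N, DIC, settings, seed,
    acceptance rates and exclusion counts.
    """
    out = _outdir(config, out_dir)
    series_by_region = read_series_csv(config.series_csv)
    onsets = pd.read_csv(config.onsets_csv, parse_dates=["onset_date"])

    fits: dict[str, RegionFit] = {}
    for region, cov in config.covariates.items():
        if region not in series_by_region:
            raise ConfigurationError(f"no series for region {region!r}")
        series = series_by_region[region]
        sine_fits = {
            v: fit_seasonal_sine(series, v) for v in config.detrend_variables
        }
        design = build_design_matrix(
            onsets, series, cov,
            season_map=config.season_map,
            window_spec=config.window_spec,
            sine_fits=sine_fits,
            detrend_variables=config.detrend_variables,
        )
        if design.n_events == 0:
            raise ConfigurationError(f"empty design for region {region!r}")
        draws = run_mcmc(design, config.prior, config.mcmc)
        summary = summarize(draws, design)
        logger.info(
            "fit %s: N=%d (excluded %d), DIC=%.1f, acceptance %.2f-%.2f",
            region, summary.n_events, len(design.exclusions), summary.dic,
            draws.acceptance.min(), draws.acceptance.max(),
        )
        design.to_csv(out / f"design_{region}.csv")
        summary.to_csv(out / f"summary_{region}.csv")
        draws.to_frame().to_csv(out / f"draws_{region}.csv",
                                index=False, float_format="%.6g")
        sidecar = summary.sidecar()
        sidecar["excluded"] = len(design.exclusions)
        (out / f"fit_{region}.json").write_text(json.dumps(sidecar, indent=2))
        fits[region] = RegionFit(region, design, draws, summary)
    return fits


def run_alert(
    config: PipelineConfig,
    fits: Mapping[str, RegionFit] | None = None,
    out_dir=None,
    forecast_csv=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alert thresholds per region-season and classified predictions.

    Thresholds come from the lnOR values of every retained case day in the
    stratum, predicted with the posterior-mean coefficients. Rows classified
    are the forecast CSV when given (same term columns as the design),
    otherwise the fitted case days themselves. Returns
    ``(thresholds_table, predictions)`` and writes both CSVs.
    """
    out = _outdir(config, out_dir)
    if fits is None:
        fits = _reload_fits(config, out)

    all_thresholds = []
    predictions = []
    for region, fit in fits.items():
        beta = fit.summary.table["mean"].to_numpy()
        terms = fit.draws.terms
        X = fit.design.X
        lnors = X @ beta
        frame = fit.design.frame
        thr_by_stratum = {}
        for season in SEASONS:
            mask = (frame["season"] == season).to_numpy()
            if mask.sum() < 2:
                logger.warning(
                    "region %s season %s has %d case days; no thresholds",
                    region, season, int(mask.sum()),
                )
                continue
            thr = alert_mod.compute_thresholds(lnors[mask], region, season)
            thr_by_stratum[(region, season)] = thr
            all_thresholds.append(thr)

        if forecast_csv is not None:
            rows = pd.read_csv(forecast_csv)
            rows = rows[rows["region"] == region]
        else:
            rows = frame
        rows = rows[rows["season"].isin([s for (_, s) in thr_by_stratum])]
        if len(rows):
            predictions.append(
                alert_mod.predict_events(beta, rows, terms, thr_by_stratum,
                                         draws=fit.draws)
            )

    thr_table = alert_mod.threshold_table_report(
        all_thresholds, raw_log_stats=config.raw_log_stats
    )
    pred_table = (
        pd.concat(predictions, ignore_index=True) if predictions else pd.DataFrame()
    )
    thr_table.to_csv(out / "thresholds.csv", index=False, float_format="%.6g")
    pred_table.to_csv(out / "predictions.csv", index=False, float_format="%.6g")
    logger.info("alert: %d strata, %d rows classified", len(thr_table), len(pred_table))
    return thr_table, pred_table


def _reload_fits(config: PipelineConfig, out: Path) -> dict[str, RegionFit]:
    """Rebuild RegionFit objects from the CSV artifacts of a prior run_fit."""
    from .windows import read_design_csv
    import numpy as np
    from .clogit import summarize as _summarize

    fits = {}
    for region in config.covariates:
        design_path = out / f"design_{region}.csv"
        draws_path = out / f"draws_{region}.csv"
        if not design_path.exists() or not draws_path.exists():
            raise FileNotFoundError(
                f"missing fit artifacts for region {region!r} in {out}; "
                "run run_fit first"
            )
        design = read_design_csv(design_path)
        dframe = pd.read_csv(draws_path)
        draws = PosteriorDraws(
            draws=dframe.to_numpy(dtype=float),
            terms=tuple(dframe.columns),
            acceptance=np.full(len(dframe.columns), float("nan")),
            settings=config.mcmc,
        )
        fits[region] = RegionFit(region, design, draws, _summarize(draws, design))
    return fits


def run_all(config: PipelineConfig, out_dir=None, seed: int = 1):
    """simulate -> fit -> alert in one call, rewiring the config's input
    paths to the freshly simulated fixture files."""
    out = _outdir(config, out_dir)
    paths = run_simulate(config, out, seed=seed)
    config = replace(
        config, series_csv=str(paths["series"]), onsets_csv=str(paths["onsets"])
    )
    fits = run_fit(config, out)
    thresholds, predictions = run_alert(config, fits, out)
    return fits, thresholds, predictions
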