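"""Window extraction, seasonal sine adjustment and design-matrix assembly."""

from __future__ import annotations

import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossrisk import (
    ConfigurationError,
    MissingExposureError,
    SeasonMap,
    WindowSpec,
    adjust_control_temperature,
    assign_season,
    build_design_matrix,
    central_southern_covariates,
    eastern_covariates,
    extract_window_pairs,
    fit_seasonal_sine,
    northern_covariates,
)
from crossrisk.windows import ANNUAL_OMEGA, SineFit

from conftest import constant_series, sinusoid_series


class TestSeasons:
    @pytest.mark.parametrize(
        "day,season",
        [(date(2010, 4, 15), "Spring"), (date(2010, 12, 31), "Winter"),
         (date(2010, 7, 1), "Summer"), (date(2010, 9, 1), "Autumn")],
    )
    def test_default_map(self, day, season):
        assert assign_season(day, SeasonMap()) == season

    def test_exhaustive_leap_year(self):
        """Every calendar day of a leap year maps to exactly one season and
        season totals equal the month lengths of the map."""
        smap = SeasonMap()
        counts = {s: 0 for s in ("Spring", "Summer", "Autumn", "Winter")}
        d = date(2012, 1, 1)
        while d.year == 2012:
            counts[assign_season(d, smap)] += 1
            d += timedelta(days=1)
        assert sum(counts.values()) == 366
        assert counts == {"Spring": 92, "Summer": 92, "Autumn": 91, "Winter": 91}

    def test_partial_map_rejected(self):
        with pytest.raises(ConfigurationError):
            SeasonMap({m: "Spring" for m in range(1, 12)})


class TestWindowExtraction:
    def test_case_and_control_days_one_week_apart(self, env_series):
        pairs = extract_window_pairs(date(2006, 6, 10), env_series, WindowSpec())
        case_days = {p.case_date for p in pairs}
        control_days = {p.control_date for p in pairs}
        assert case_days == {date(2006, 6, 10), date(2006, 6, 9), date(2006, 6, 7)}
        assert control_days == {date(2006, 6, 3), date(2006, 6, 2), date(2006, 5, 31)}
        for p in pairs:
            assert p.case_date - p.control_date == timedelta(days=7)

    def test_boundary_onset_excluded(self):
        series = constant_series(n_days=60)
        early = series.start_date + timedelta(days=12)  # needs day -13
        with pytest.raises(MissingExposureError):
            extract_window_pairs(early, series, WindowSpec())
        # one day later the full history is available
        extract_window_pairs(series.start_date + timedelta(days=13),
                             series, WindowSpec())

    def test_constant_series_case_equals_control(self):
        series = constant_series()
        pairs = extract_window_pairs(series.start_date + timedelta(days=20),
                                     series, WindowSpec())
        for p in pairs:
            for case_val, control_val in p.values.values():
                assert case_val == control_val

    def test_window_spec_invariants(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(((0, 6),))
        with pytest.raises(ConfigurationError):
            WindowSpec(((7, 14),))


class TestSeasonalSine:
    def test_exact_recovery_on_pure_sinusoid(self):
        series = sinusoid_series(mean=20.0, amplitude=5.0, phase=0.0)
        fit = fit_seasonal_sine(series, "min_temp")
        assert fit.a0 == pytest.approx(20.0, abs=1e-9)
        assert fit.a1 == pytest.approx(5.0, abs=1e-9)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)

    def test_constant_input(self):
        series = constant_series(n_days=800, min_temp=20.0)
        fit = fit_seasonal_sine(series, "min_temp")
        assert fit.a0 == pytest.approx(20.0, abs=1e-9)
        assert fit.a1 == pytest.approx(0.0, abs=1e-9)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_3_analytic_se(self):
        # OLS on [1, sin, cos]: X'X ~ diag(n, n/2, n/2), so for iid noise
        # SE(a0)=sigma/sqrt(n) and SE(a1)=SE(a2)=sigma*sqrt(2/n).
        n, sigma = 1461, 1.0
        rng = np.random.default_rng(8)
        base = sinusoid_series(n_days=n, mean=20.0, amplitude=5.0, phase=0.7)
        frame = base.frame.copy()
        frame["min_temp"] = frame["min_temp"] + rng.normal(0, sigma, n)
        frame["max_temp"] = frame["min_temp"] + 6.0
        from crossrisk import EnvironmentalSeries
        series = EnvironmentalSeries(region="R", frame=frame)
        fit = fit_seasonal_sine(series, "min_temp")
        a1_true = 5.0 * math.cos(0.7)
        a2_true = 5.0 * math.sin(0.7)
        assert abs(fit.a0 - 20.0) < 3 * sigma / math.sqrt(n)
        assert abs(fit.a1 - a1_true) < 3 * sigma * math.sqrt(2 / n)
        assert abs(fit.a2 - a2_true) < 3 * sigma * math.sqrt(2 / n)

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="365"):
            fit_seasonal_sine(constant_series(n_days=100), "min_temp")


class TestControlAdjustment:
    def test_pure_sinusoid_adjusted_difference_is_zero(self):
        series = sinusoid_series()
        fit = fit_seasonal_sine(series, "min_temp")
        onset = series.start_date + timedelta(days=500)
        for p in extract_window_pairs(onset, series, WindowSpec()):
            case_val, control_val = p.values["min_temp"]
            adj = adjust_control_temperature(control_val, p.case_date,
                                             p.control_date, fit)
            assert case_val - adj == pytest.approx(0.0, abs=1e-9)

    def test_flat_fit_is_identity(self):
        fit = SineFit(variable="min_temp", a0=20.0, a1=0.0, a2=0.0,
                      origin=date(2010, 1, 1))
        assert adjust_control_temperature(
            13.7, date(2010, 5, 1), date(2010, 4, 24), fit
        ) == 13.7

    def test_closed_form_one_week_apart(self):
        fit = SineFit(variable="min_temp", a0=18.0, a1=4.0, a2=-2.0,
                      origin=date(2010, 1, 1))
        case, control = date(2010, 3, 11), date(2010, 3, 4)
        d1, d2 = 69, 62  # day numbers since origin
        w = ANNUAL_OMEGA
        expected = 4.0 * (math.sin(w * d1) - math.sin(w * d2)) \
            + (-2.0) * (math.cos(w * d1) - math.cos(w * d2))
        got = adjust_control_temperature(10.0, case, control, fit) - 10.0
        assert got == pytest.approx(expected, abs=1e-12)


def onsets_frame(dates, region="Northern"):
    return pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(len(dates))],
         "region": region, "onset_date": pd.to_datetime(dates)}
    )


class TestDesignMatrix:
    def test_column_counts_match_regional_specs(self):
        assert northern_covariates().n_columns == 24
        assert central_southern_covariates().n_columns == 25
        assert eastern_covariates().n_columns == 20

    def test_spring_event_nonzero_only_in_spring_columns(self, env_series):
        design = build_design_matrix(
            onsets_frame([date(2006, 4, 20)]), env_series, northern_covariates()
        )
        assert design.n_events == 1
        row = design.frame.iloc[0]
        assert row["season"] == "Spring"
        spring_cols = [t for t in design.terms if t.endswith("_Spring")]
        other_cols = [t for t in design.terms if not t.endswith("_Spring")]
        assert len(spring_cols) == 6
        assert (row[other_cols] == 0).all()

    def test_constant_series_gives_all_zero_row(self):
        series = constant_series()
        design = build_design_matrix(
            onsets_frame([series.start_date + timedelta(days=30)]),
            series, northern_covariates(),
        )
        assert np.allclose(design.X, 0.0)
        assert design.frame["label"].tolist() == [1]

    def test_boundary_events_counted_as_exclusions(self, env_series):
        start = env_series.start_date
        good = [start + timedelta(days=20 + i) for i in range(97)]
        bad = [start + timedelta(days=k) for k in (0, 5, 12)]
        design = build_design_matrix(
            onsets_frame(good + bad), env_series, northern_covariates()
        )
        assert design.n_events == 97
        assert len(design.exclusions) == 3

    def test_translation_invariance(self, env_series):
        """Adding a constant to a variable leaves its differences unchanged."""
        onsets = onsets_frame(
            [env_series.start_date + timedelta(days=k) for k in (40, 200, 400)]
        )
        base = build_design_matrix(onsets, env_series, northern_covariates())
        from crossrisk import EnvironmentalSeries
        shifted_frame = env_series.frame.copy()
        shifted_frame["min_temp"] += 5.0
        shifted_frame["max_temp"] += 5.0
        shifted = EnvironmentalSeries(region=env_series.region, frame=shifted_frame)
        design = build_design_matrix(onsets, shifted, northern_covariates())
        assert np.allclose(design.X, base.X, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(offset=st.integers(13, 780))
    def test_window_arithmetic_property(self, offset):
        series = constant_series(n_days=800)
        onset = series.start_date + timedelta(days=offset)
        for p in extract_window_pairs(onset, series, WindowSpec()):
            assert p.control_date == p.case_date - timedelta(days=7)
            assert p.case_date == onset - timedelta(days=p.case_lag)

    def test_missing_variable_is_configuration_error(self, env_series):
        from crossrisk import EnvironmentalSeries
        # series lacking ozone triggers a config error for the C-S spec
        frame = env_series.frame.copy()
        frame["ave_o3"] = np.nan
        series = EnvironmentalSeries(region="CentralSouthern", frame=frame)
        onsets = onsets_frame([series.start_date + timedelta(days=40)],
                              region="CentralSouthern")
        design = build_design_matrix(onsets, series,
                                     central_southern_covariates())
        # NaN ozone day -> event excluded, not imputed
        assert design.n_events == 0 and len(design.exclusions) == 1
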