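"""Odds-ratio prediction, alert thresholds and level classification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossrisk import (
    AlertThresholds,
    MCMCSettings,
    PosteriorDraws,
    RiskPrediction,
    classify,
    compute_thresholds,
    level_probabilities,
    predict_lnor,
    threshold_table_report,
)

# Published Northern-Taiwan Spring point estimates: the six coefficients of
# the worked single-region risk model, in design order.
SPRING_COEFS = {
    "min_temp_lag0_Spring": -0.1614,
    "min_temp_lag3_Spring": -0.1398,
    "max_temp_lag0_Spring": 0.0109,
    "max_temp_lag1_Spring": -0.0116,
    "ave_rh_lag0_Spring": 0.0074,
    "max_rh_lag3_Spring": -0.0090,
}

# Published Northern-Taiwan Summer alert statistics (median OR, dispersion).
NORTH_SUMMER = dict(median_or=1.9162, dispersion=3.7221)


def brute_force_level(or_value: float, c: np.ndarray) -> int:
    """Exhaustive scan over the six [c_{g-1}, c_g) intervals, c0 = 0."""
    edges = np.concatenate([[0.0], c])
    for g in range(1, 7):
        if edges[g - 1] <= or_value < edges[g]:
            return g
    return 6  # at or above c6


class TestPredictLnor:
    def test_zero_contrast_gives_unit_or(self):
        assert predict_lnor({"a": 1.2, "b": -0.5}, {"a": 0.0, "b": 0.0}) == 0.0

    def test_published_spring_coefficients_unit_contrasts(self):
        """With every case-minus-control difference set to +1 the six
        published coefficients sum to lnOR = -0.3035."""
        d = dict.fromkeys(SPRING_COEFS, 1.0)
        assert predict_lnor(SPRING_COEFS, d) == pytest.approx(-0.3035, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        b, d = rng.normal(size=4), rng.normal(size=4)
        assert predict_lnor(b, 2 * d) == pytest.approx(2 * predict_lnor(b, d))

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_lnor([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            predict_lnor({"a": 1.0}, {"b": 1.0}, terms=("a",))


class TestThresholds:
    def test_degenerate_spread_collapses_all_levels(self):
        thr = compute_thresholds([0.5, 0.5, 0.5], "R", "Spring")
        assert np.allclose(thr.critical_values, math.exp(0.5))

    def test_c2_is_exp_median(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.3, 0.8, size=101)
        thr = compute_thresholds(vals, "R", "Summer")
        assert thr.critical_values[1] == pytest.approx(
            math.exp(np.median(vals)), rel=1e-12
        )

    def test_closed_form_on_three_values(self):
        vals = [0.0, math.log(2), math.log(4)]
        thr = compute_thresholds(vals, "R", "Autumn")
        m = math.log(2)
        s = np.std(vals, ddof=1)
        expected = [math.exp(m + 0.5 * (g - 2) * s) for g in range(1, 7)]
        np.testing.assert_allclose(thr.critical_values, expected, rtol=1e-12)

    def test_geometric_progression_and_monotonicity(self):
        thr = compute_thresholds([0.1, 0.4, 0.9, -0.2], "R", "Winter")
        c = thr.critical_values
        assert (np.diff(c) > 0).all()
        ratios = c[1:] / c[:-1]
        np.testing.assert_allclose(ratios, math.exp(0.5 * thr.sd_lnor), rtol=1e-12)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            compute_thresholds([0.3], "R", "Spring")

    def test_dispersion_scale_readings(self):
        log_read = AlertThresholds.from_or_stats("N", "Summer",
                                                 dispersion_scale="log",
                                                 **NORTH_SUMMER)
        or_read = AlertThresholds.from_or_stats("N", "Summer",
                                                dispersion_scale="or",
                                                **NORTH_SUMMER)
        assert log_read.sd_lnor == pytest.approx(3.7221)
        assert or_read.sd_lnor == pytest.approx(math.log(3.7221))
        for thr in (log_read, or_read):
            assert thr.critical_values[1] == pytest.approx(1.9162, rel=1e-12)

    def test_scale_equivariance(self):
        """Stretching the lnOR spread by k multiplies every interval ratio
        by exp(0.5 (k-1) SD)."""
        rng = np.random.default_rng(5)
        vals = rng.normal(0.2, 0.5, size=51)
        base = compute_thresholds(vals, "R", "Spring")
        k = 2.5
        stretched_vals = np.median(vals) + k * (vals - np.median(vals))
        stretched = compute_thresholds(stretched_vals, "R", "Spring")
        r0 = base.critical_values[1] / base.critical_values[0]
        r1 = stretched.critical_values[1] / stretched.critical_values[0]
        assert r1 / r0 == pytest.approx(math.exp(0.5 * (k - 1) * base.sd_lnor),
                                        rel=1e-9)


class TestClassify:
    @pytest.mark.parametrize("scale", ["log", "or"])
    def test_worked_example_level3_under_both_readings(self, scale):
        """OR 2.4511 in a Northern-summer stratum lands in level 3 whether
        the tabulated dispersion is read as SD(lnOR) or exp(SD(lnOR))."""
        thr = AlertThresholds.from_or_stats("N", "Summer",
                                            dispersion_scale=scale, **NORTH_SUMMER)
        assert classify(2.4511, thr) == 3

    def test_bottom_interval(self):
        thr = AlertThresholds("R", "Spring", median_lnor=0.5, sd_lnor=0.4)
        assert classify(thr.critical_values[0] * 0.5, thr) == 1

    def test_top_cap(self):
        thr = AlertThresholds("R", "Spring", median_lnor=0.5, sd_lnor=0.4)
        assert classify(thr.critical_values[-1] * 10, thr) == 6

    def test_nonpositive_or_rejected(self):
        thr = AlertThresholds("R", "Spring", median_lnor=0.0, sd_lnor=0.3)
        for bad in (0.0, -1.0, float("nan"), float("inf")):
            with pytest.raises(ValueError):
                classify(bad, thr)

    def test_agrees_with_exhaustive_scan_on_1000_random_ors(self):
        rng = np.random.default_rng(9)
        thr = AlertThresholds("R", "Autumn", median_lnor=0.3, sd_lnor=0.7)
        ors = np.exp(rng.normal(0.3, 2.0, size=1000))
        c = thr.critical_values
        for v in ors:
            assert classify(float(v), thr) == brute_force_level(float(v), c)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        lnor=st.floats(-30, 30),
        median=st.floats(-2, 2),
        sd=st.floats(0.01, 3),
    )
    def test_partition_property(self, lnor, median, sd):
        """Every positive OR maps to exactly one level, nondecreasing in OR."""
        thr = AlertThresholds("R", "Spring", median_lnor=median, sd_lnor=sd)
        or_value = math.exp(lnor)
        g = classify(or_value, thr)
        assert 1 <= g <= 6
        assert classify(or_value * 1.5, thr) >= g


def make_draws(matrix, terms=("a", "b")):
    return PosteriorDraws(
        draws=np.asarray(matrix, dtype=float), terms=terms,
        acceptance=np.full(len(terms), 0.4), settings=MCMCSettings(seed=0),
    )


class TestLevelProbabilities:
    thr = AlertThresholds("R", "Spring", median_lnor=0.2, sd_lnor=0.5)

    def test_single_draw_is_indicator(self):
        draws = make_draws([[0.4, -0.1]])
        p = level_probabilities(draws, [1.0, 1.0], self.thr)
        assert p.sum() == 1.0
        assert (p == 1.0).sum() == 1

    def test_sums_to_one_and_matches_direct_count(self):
        rng = np.random.default_rng(3)
        draws = make_draws(rng.normal(0, 0.8, size=(500, 2)))
        d = np.array([0.7, -1.2])
        p = level_probabilities(draws, d, self.thr)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        counts = np.zeros(6)
        for b in draws.draws:
            g = classify(math.exp(float(b @ d)), self.thr)
            counts[g - 1] += 1
        np.testing.assert_allclose(p, counts / counts.sum(), atol=1e-12)


class TestRiskPrediction:
    def test_probability_vector_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RiskPrediction("e1", lnor=0.1, odds_ratio=math.exp(0.1), level=2,
                           level_probs=np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.0]))

    def test_valid_prediction(self):
        p = RiskPrediction("e1", lnor=0.0, odds_ratio=1.0, level=1)
        assert p.odds_ratio == 1.0


class TestReport:
    def make_thresholds(self):
        return [
            AlertThresholds("N", "Spring", 0.43, 0.84),
            AlertThresholds("N", "Summer", 0.65, 1.31),
            AlertThresholds("N", "Autumn", 0.85, 0.0),
        ]

    def test_degenerate_sd_collapses_ranges(self):
        table = threshold_table_report(self.make_thresholds())
        row = table[table["season"] == "Autumn"].iloc[0]
        cs = row[[f"c{g}" for g in range(1, 7)]].to_numpy(dtype=float)
        assert np.allclose(cs, cs[0])

    def test_boundaries_monotone_nondecreasing(self):
        table = threshold_table_report(self.make_thresholds())
        for _, row in table.iterrows():
            cs = row[[f"c{g}" for g in range(1, 7)]].to_numpy(dtype=float)
            assert (np.diff(cs) >= 0).all()

    def test_or_scale_and_raw_log_columns(self):
        thr = self.make_thresholds()[0]
        or_table = threshold_table_report([thr])
        log_table = threshold_table_report([thr], raw_log_stats=True)
        assert or_table["median_OR"].iloc[0] == pytest.approx(math.exp(0.43))
        assert or_table["dispersion"].iloc[0] == pytest.approx(math.exp(0.84))
        assert log_table["median_lnOR"].iloc[0] == pytest.approx(0.43)
        assert log_table["dispersion"].iloc[0] == pytest.approx(0.84)

    def test_csv_round_trip(self, tmp_path):
        table = threshold_table_report(self.make_thresholds())
        path = tmp_path / "thresholds.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-12)
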