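"""Window statistics, feature grammar and featurization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icpdyn.features import (
    FeatureError,
    FeatureGrammar,
    age_decile,
    begin_feature,
    coef_feature,
    end_feature,
    enumerate_candidate_features,
    featurize,
    ols_slope,
    window_stat,
)
from icpdyn.vitals import VitalsSeries, build_patient

from conftest import constant_patient, make_series


def icp_series(values, times=None):
    times = range(len(values)) if times is None else times
    return make_series("icp", times, values)


class TestWindowStat:
    def test_diff_is_mean_of_signed_consecutive_differences(self):
        s = icp_series([10.0, 12.0, 11.0, 15.0])
        assert window_stat(s, 0, 10, "diff") == pytest.approx(5.0 / 3.0)

    def test_ht20_fraction_strictly_above(self):
        s = icp_series([18.0, 22.0, 25.0, 19.0])
        assert window_stat(s, 0, 10, "ht20") == pytest.approx(0.5)

    def test_population_variance(self):
        s = icp_series([20.0, 30.0])
        assert window_stat(s, 0, 10, "var") == pytest.approx(25.0)

    def test_single_sample_degenerate(self):
        s = icp_series([42.0])
        assert window_stat(s, 0, 10, "avg") == 42.0
        assert math.isnan(window_stat(s, 0, 10, "var"))
        assert math.isnan(window_stat(s, 0, 10, "diff"))

    def test_empty_window_missing(self):
        s = icp_series([1.0, 2.0], times=[100, 101])
        assert math.isnan(window_stat(s, 0, 50, "avg"))

    def test_threshold_stat_signal_pairing(self):
        m = make_series("map", [0], [100.0])
        with pytest.raises(FeatureError):
            window_stat(m, 0, 10, "ht20")
        with pytest.raises(FeatureError):
            window_stat(icp_series([10.0]), 0, 10, "ht120")

    @given(st.lists(st.floats(0, 60), min_size=2, max_size=50))
    @settings(max_examples=80, deadline=None)
    def test_diff_telescoping_identity(self, values):
        """Mean of signed consecutive differences telescopes to (last-first)/(n-1)."""
        s = icp_series(values)
        got = window_stat(s, 0, len(values), "diff")
        assert got == pytest.approx((values[-1] - values[0]) / (len(values) - 1),
                                    abs=1e-9)

    @given(st.lists(st.floats(0, 80), min_size=1, max_size=50))
    @settings(max_examples=80, deadline=None)
    def test_quantile_ordering_and_fraction_bounds(self, values):
        s = icp_series(values)
        b = len(values)
        assert window_stat(s, 0, b, "q10") <= window_stat(s, 0, b, "q90")
        for kind in ("ht20", "lt10"):
            assert 0.0 <= window_stat(s, 0, b, kind) <= 1.0

    @given(st.lists(st.floats(5, 50), min_size=3, max_size=30),
           st.floats(-20, 20))
    @settings(max_examples=60, deadline=None)
    def test_location_shift(self, values, c):
        """Adding c shifts avg/min/max/q90/q10 by c; diff and var are unmoved."""
        a = icp_series(values)
        b = make_series("icp", range(len(values)), np.asarray(values) + c)
        n = len(values)
        for kind in ("avg", "min", "max", "q90", "q10"):
            assert window_stat(b, 0, n, kind) == pytest.approx(
                window_stat(a, 0, n, kind) + c, abs=1e-8)
        for kind in ("diff", "var"):
            assert window_stat(b, 0, n, kind) == pytest.approx(
                window_stat(a, 0, n, kind), abs=1e-7)


class TestAggregations:
    def test_begin_constant(self):
        p = constant_patient(icp_level=15.0, hours=30.0)
        assert begin_feature(p.icp, "avg") == pytest.approx(15.0)

    def test_begin_missing_without_first_day_samples(self):
        s = icp_series([10.0, 11.0], times=[1500, 1600])
        assert math.isnan(begin_feature(s, "avg"))

    def test_begin_diff_linear_ramp(self):
        t = np.arange(1440)
        s = icp_series(10.0 + 10.0 * t / 1439.0, times=t)
        assert begin_feature(s, "diff") == pytest.approx(10.0 / 1439.0)

    def test_end_window_geometry(self):
        p = constant_patient(map_level=85.0, icp_level=15.0, hours=48.0)
        assert end_feature(p.cpp, "avg", 24) == pytest.approx(70.0)

    def test_end_missing_outside_trailing_window(self):
        s = icp_series([9.0, 9.5], times=[0, 100])
        assert math.isnan(end_feature(s, "avg", 24))

    def test_coef_flat_series_zero_slope(self):
        p = constant_patient(hours=40.0)
        assert coef_feature(p.icp, "avg", 32) == pytest.approx(0.0, abs=1e-9)

    def test_coef_exact_linear_trend(self):
        # mean value in window ending at hour k is 0.5*(k - 2) for a ramp
        t = np.arange(32 * 60)
        s = icp_series(0.5 * t / 60.0, times=t)
        assert coef_feature(s, "avg", 32) == pytest.approx(0.5, rel=1e-9)

    def test_coef_matches_polyfit_oracle(self):
        rng = np.random.default_rng(4)
        t = np.arange(24 * 60)
        s = icp_series(rng.uniform(5, 30, t.size), times=t)
        got = coef_feature(s, "avg", 24)
        ends = np.arange(4, 25)
        vals = [s.slice_window((k - 4) * 60, k * 60).mean() for k in ends]
        expected = np.polyfit(ends, vals, 1)[0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_coef_missing_with_fewer_than_two_windows(self):
        s = icp_series([10.0], times=[30])
        assert math.isnan(coef_feature(s, "avg", 24))


class TestAgeDecile:
    @pytest.mark.parametrize("age, expected", [(46, 4), (16, 1), (101, 9),
                                               (5, 1), (99, 9)])
    def test_bins(self, age, expected):
        assert age_decile(age) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(FeatureError):
            age_decile(-1.0)


class TestGrammar:
    def test_default_candidate_count(self):
        names = enumerate_candidate_features()
        assert len(names) == 55 and names[-1] == "agec"
        assert len(set(names)) == 55

    def test_retrained_model_names_present(self):
        names = enumerate_candidate_features()
        selected_in_study = [
            "cpp_diff_coef", "map_diff_coef", "map_diff_begin", "icp_diff_coef",
            "cpp_diff_begin", "icp_q90_coef", "icp_end", "agec", "cpp_end",
            "cpp_var_coef", "icp_diff_end", "icp_coef", "map_var_coef",
            "icp_var_coef",
        ]
        assert all(n in names for n in selected_in_study)

    def test_min_max_grammar_grows_to_73(self):
        g = FeatureGrammar(include_min_max=True)
        assert len(g.feature_names()) == 73

    def test_digest_tracks_grammar(self):
        assert FeatureGrammar().digest() != FeatureGrammar(signed_diff=False).digest()

    def test_parse_round_trip(self):
        g = FeatureGrammar()
        for name in g.feature_names():
            sig, stat, agg = g.parse(name)
            if sig == "agec":
                continue
            rendered = f"{sig}_{agg}" if stat == "avg" else f"{sig}_{stat}_{agg}"
            assert rendered == name


class TestFeaturize:
    def test_fully_sampled_patient_has_no_missing(self):
        p = constant_patient(hours=30.0)
        vec = featurize(p, 24)
        assert not any(math.isnan(v) for v in vec.values())
        assert len(vec) == 55

    def test_missing_trailing_window_propagates(self):
        # MAP absent in [16 h, 24 h) makes every cpp_*_end and map_*_end missing
        times = np.arange(0, 30 * 60)
        icp = make_series("icp", times, np.full(times.size, 12.0))
        keep = times < 16 * 60
        map_ = make_series("map", times[keep], np.full(int(keep.sum()), 80.0))
        p = build_patient("p0", 40.0, 0, icp, map_)
        vec = featurize(p, 24)
        for name, value in vec.items():
            sig, stat, agg = FeatureGrammar().parse(name)
            if sig in ("map", "cpp") and agg == "end":
                assert math.isnan(value), name
        assert not math.isnan(vec["icp_end"])

    def test_pure_function(self):
        p = constant_patient(hours=40.0)
        assert featurize(p, 32) == featurize(p, 32)

    def test_off_schedule_time_rejected(self):
        p = constant_patient(hours=40.0)
        with pytest.raises(FeatureError):
            featurize(p, 30)

    def test_begin_features_stable_across_prediction_times(self):
        p = constant_patient(hours=40.0)
        v24, v32 = featurize(p, 24), featurize(p, 32)
        for name in v24:
            if name.endswith("_begin") or name == "agec":
                assert v24[name] == v32[name]
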