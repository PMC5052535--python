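import numpy as np
import pytest

from tramqc import (
    ConfigurationError,
    ScaleTable,
    TrackIntegrityError,
    TramParams,
    compute_tram,
    compute_tram_table,
    fluctuation_scales,
    smooth_series,
    tram_filter,
    tram_statistic,
)
from conftest import make_track
from _oracles import tram_naive


class TestSmoothSeries:
    def test_reproduces_constants(self):
        y = np.full(20, 7.5)
        np.testing.assert_allclose(smooth_series(y), y, atol=1e-9)

    def test_reproduces_linear_trends(self):
        t = np.arange(25, dtype=float)
        y = 3.0 - 0.4 * t
        np.testing.assert_allclose(smooth_series(y), y, rtol=0, atol=1e-9)

    def test_beats_constant_fit_on_sinusoid(self, rng):
        t = np.arange(25, dtype=float)
        y = np.sin(2 * np.pi * t / 25) + rng.normal(0, 0.2, 25)
        rss_spline = np.sum((y - smooth_series(y, 5)) ** 2)
        rss_const = np.sum((y - y.mean()) ** 2)  # brute-force best constant
        assert rss_spline <= rss_const

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.ones(3))

    def test_knots_reduced_for_short_series(self):
        # T=5 < n_knots+2: fit still runs and reproduces a line
        y = 1.0 + 2.0 * np.arange(5)
        np.testing.assert_allclose(smooth_series(y, 5), y, atol=1e-8)


class TestFluctuationScales:
    @pytest.mark.filterwarnings("ignore:zero spatial fluctuation")
    def test_single_cell_alternating(self, make_trackset):
        ts = make_trackset([make_track("a", T=5, f=[0, 1, 0, 1, 0])])
        scales = fluctuation_scales(ts, TramParams(features=("f",)))
        assert scales.features["f"] == 1.0

    @pytest.mark.filterwarnings("ignore:zero spatial fluctuation")
    def test_pooled_median_over_cells(self, make_trackset):
        # diffs {1,1,1} and {3,3,3}: median of the six pooled diffs is 2
        ts = make_trackset(
            [
                make_track("a", T=4, f=[0, 1, 2, 3]),
                make_track("b", T=4, f=[0, 3, 6, 9]),
            ]
        )
        scales = fluctuation_scales(ts, TramParams(features=("f",)))
        assert scales.features["f"] == 2.0

    @pytest.mark.filterwarnings("ignore:zero spatial fluctuation")
    def test_higher_quantile_gives_larger_scale(self, make_trackset):
        ts = make_trackset(
            [make_track("a", T=8, f=np.cumsum([0, 1, 1, 1, 1, 1, 1, 10.0]))]
        )
        s50 = fluctuation_scales(ts, TramParams(features=("f",))).features["f"]
        s90 = fluctuation_scales(
            ts, TramParams(features=("f",), scale_quantile=0.9)
        ).features["f"]
        assert s90 > s50

    def test_xy_scale_is_euclidean_step_quantile(self, make_trackset):
        # steps of length 5 (3-4-5 triangles)
        ts = make_trackset(
            [make_track("a", T=4, x=[0, 3, 6, 9], y=[0, 4, 8, 12])]
        )
        scales = fluctuation_scales(ts, TramParams(use_euclidean_xy=True))
        assert scales.s_xy == pytest.approx(5.0)

    @pytest.mark.filterwarnings("ignore:zero spatial fluctuation")
    def test_constant_feature_warns(self, make_trackset):
        ts = make_trackset([make_track("a", T=5, f=np.ones(5))])
        with pytest.warns(UserWarning, match="zero fluctuation scale"):
            scales = fluctuation_scales(ts, TramParams(features=("f",)))
        assert scales.features["f"] == 0.0

    def test_absent_feature_raises(self, make_trackset):
        ts = make_trackset([make_track("a", T=5, f=np.arange(5.0))])
        with pytest.raises(KeyError):
            fluctuation_scales(ts, TramParams(features=("g",)))


class TestTramStatistic:
    def test_formula_level_example(self):
        # two features over two time points, deviations [[1,1],[4,0]]
        z = np.array([[1.0, 4.0], [1.0, 0.0]])  # (series, time)
        tau, t = tram_statistic(z, p=0.5)
        assert tau == pytest.approx(1.0)
        assert t == 0  # tie between equal per-time values: smallest index

    def test_simultaneity_beats_concentration(self):
        # equal total deviation 4: spread [[2],[2]] vs concentrated [[4],[0]]
        tau_spread, _ = tram_statistic(np.array([[2.0], [2.0]]), p=0.5)
        tau_conc, _ = tram_statistic(np.array([[4.0], [0.0]]), p=0.5)
        assert tau_spread == pytest.approx(2.0)
        assert tau_conc == pytest.approx(1.0)
        assert tau_spread > tau_conc

    def test_p2_is_rms(self):
        z = np.array([[3.0], [4.0]])
        tau, _ = tram_statistic(z, p=2.0)
        assert tau == pytest.approx(np.sqrt(25 / 2))

    def test_single_series_any_p_is_max(self):
        z = np.array([[0.5, 2.0, 1.0]])
        for p in (0.5, 1.0, 2.0):
            tau, t = tram_statistic(z, p=p)
            assert tau == pytest.approx(2.0) and t == 1


class TestComputeTram:
    def test_zero_for_spline_reproducible_track(self, make_trackset):
        # linear series are reproduced exactly by the cubic spline baseline
        t = np.arange(12, dtype=float)
        tr = make_track("a", T=12, x=2 * t, y=-t, area=100 + 3 * t)
        scales = ScaleTable(features={"area": 2.0}, s_xy=1.0)
        res = compute_tram(tr, scales, TramParams(features=("area",)))
        assert res.tau == pytest.approx(0.0, abs=1e-8)

    def test_matches_naive_oracle_small(self, make_trackset, rng):
        params = TramParams(features=("a", "b"), use_euclidean_xy=True)
        scales = ScaleTable(features={"a": 1.3, "b": 0.7}, s_xy=0.9)
        for i in range(10):
            T = int(rng.integers(10, 30))
            tr = make_track(
                f"c{i}", T=T,
                x=np.cumsum(rng.normal(0, 1, T)),
                y=np.cumsum(rng.normal(0, 1, T)),
                a=rng.normal(0, 2, T), b=rng.normal(5, 1, T),
            )
            res = compute_tram(tr, scales, params)
            tau_ref, _, per_time = tram_naive(tr, scales, params)
            assert res.tau == pytest.approx(tau_ref, rel=1e-9)
            assert per_time[res.argmax_time] == pytest.approx(tau_ref, rel=1e-9)

    def test_affine_rescaling_invariance(self, make_trackset, rng):
        # rescaling a feature rescales its s identically, leaving tau fixed
        tracks = [
            make_track(f"c{i}", T=15, x=np.cumsum(rng.normal(0, 1, 15)),
                       y=np.cumsum(rng.normal(0, 1, 15)),
                       f=rng.normal(10, 2, 15))
            for i in range(8)
        ]
        ts = make_trackset(tracks)
        params = TramParams(features=("f",), use_euclidean_xy=False)
        taus1, _ = compute_tram_table(ts, params)

        scaled = make_trackset(
            [
                make_track(tr.cell_id, T=15, x=tr.x, y=tr.y,
                           f=-3.5 * tr.features["f"] + 11.0)
                for tr in tracks
            ]
        )
        taus2, _ = compute_tram_table(scaled, params)
        np.testing.assert_allclose(taus1["tau"], taus2["tau"], rtol=1e-9)

    def test_window_restricts_scoring(self, make_trackset, rng):
        # a huge late jump is invisible when scoring only the first 10 points
        f = rng.normal(0, 1, 20)
        f2 = f.copy()
        f2[15] += 100.0
        tr = make_track("a", T=20, f=f2)
        scales = ScaleTable(features={"f": 1.0})
        full = compute_tram(tr, scales, TramParams(features=("f",), use_euclidean_xy=False))
        early = compute_tram(
            tr, scales,
            TramParams(features=("f",), use_euclidean_xy=False, window=(0, 10)),
        )
        assert full.argmax_time == 15 and full.tau > 10
        assert early.tau < 10 and early.argmax_time < 10

    def test_missing_scale_is_configuration_error(self, make_trackset):
        tr = make_track("a", T=6, f=np.arange(6.0))
        with pytest.raises(ConfigurationError):
            compute_tram(tr, ScaleTable(features={}), TramParams(features=("f",)))

    def test_zero_scale_feature_dropped(self, make_trackset, rng):
        tr = make_track("a", T=10, f=rng.normal(0, 1, 10), g=np.zeros(10))
        scales = ScaleTable(features={"f": 1.0, "g": 0.0})
        params = TramParams(features=("f", "g"), use_euclidean_xy=False)
        res = compute_tram(tr, scales, params)
        assert "g" not in res.deviations and "f" in res.deviations


class TestTramFilter:
    def _results(self, make_trackset, taus):
        tracks = [make_track(f"c{i}", T=4) for i in range(len(taus))]
        ts = make_trackset(tracks)
        import pandas as pd

        df = pd.DataFrame(
            {"cell_id": [t.cell_id for t in tracks], "tau": taus,
             "argmax_time": 0}
        )
        return ts, df

    def test_infinite_threshold_keeps_all(self, make_trackset):
        ts, df = self._results(make_trackset, [1.0, 2.0, 10.0])
        report = tram_filter(ts, df, np.inf)
        assert report.rejected_ids == []

    def test_threshold_is_strict_greater(self, make_trackset):
        ts, df = self._results(make_trackset, [1.0, 2.0, 10.0])
        report = tram_filter(ts, df, 4.69)
        assert report.rejected_ids == ["c2"]
        assert report.rejected_fraction == pytest.approx(1 / 3)
        report2 = tram_filter(ts, df, 10.0)  # tau == tau* is kept
        assert report2.rejected_ids == []

    def test_missing_result_raises(self, make_trackset):
        ts, df = self._results(make_trackset, [1.0, 2.0, 3.0])
        with pytest.raises(TrackIntegrityError):
            tram_filter(ts, df.iloc[:2], 5.0)

    def test_partition(self, make_trackset):
        ts, df = self._results(make_trackset, [1.0, 5.0, 2.0, 8.0])
        report = tram_filter(ts, df, 3.0)
        assert sorted(report.kept_ids + report.rejected_ids) == sorted(ts.cell_ids())


def test_params_validation():
    with pytest.raises(ConfigurationError):
        TramParams(features=("f",), p=0.0)
    with pytest.raises(ConfigurationError):
        TramParams(features=("f",), n_knots=2)
    with pytest.raises(ConfigurationError):
        TramParams(features=(), use_euclidean_xy=False)
    with pytest.raises(ConfigurationError):
        TramParams(features=("f",), scale_quantile=1.0)
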