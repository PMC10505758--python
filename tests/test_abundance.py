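"""Independent-event filtering, capture rates and the wedge regression."""

import numpy as np
import pandas as pd
import pytest

from wedge_sdm.abundance import (DEFAULT_TAUS, capture_rate,
                                 filter_independent, pinball_loss,
                                 quantile_fit, select_quantile, wedge_profile)
from wedge_sdm.synth import DetectionLog


def _log(times, n_ind=None, station="s1", cell=0, species="cat"):
    n = len(times)
    return pd.DataFrame({
        "station_id": [station] * n, "cell_id": [cell] * n,
        "species": [species] * n, "timestamp_h": list(times),
        "n_individuals": n_ind if n_ind is not None else [1] * n,
    })


def pairline_oracle(x, y, tau):
    """Best pinball loss over all lines through two data points — the LP
    optimum coincides with one of these basic solutions."""
    best = np.inf
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            b1 = (y[j] - y[i]) / (x[j] - x[i])
            b0 = y[i] - b1 * x[i]
            best = min(best, pinball_loss(y - b0 - b1 * x, tau))
    return best


class TestFilterIndependent:
    def test_24h_scan_rule(self):
        events = filter_independent(_log([0.0, 23.0, 25.0]))
        assert list(events["timestamp_h"]) == [0.0, 25.0]

    def test_multi_individual_counts_regardless_of_timing(self):
        events = filter_independent(_log([0.0, 12.0], n_ind=[1, 2]))
        assert len(events) == 2

    def test_multi_individual_resets_clock(self):
        # 25 h is >24 h after 0 h but only 13 h after the counted multi-
        # animal photo at 12 h, so it is not independent
        events = filter_independent(_log([0.0, 12.0, 25.0], n_ind=[1, 2, 1]))
        assert list(events["timestamp_h"]) == [0.0, 12.0]

    def test_single_detection_kept(self):
        assert len(filter_independent(_log([5.0]))) == 1

    def test_streams_are_separate_per_station_and_species(self):
        log = pd.concat([_log([0.0, 1.0], station="s1"),
                         _log([0.5], station="s2"),
                         _log([0.7], station="s1", species="dog")])
        events = filter_independent(log)
        assert len(events) == 3

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError):
            filter_independent(_log([-1.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_random_logs(self, seed):
        rng = np.random.default_rng(seed)
        log = _log(np.sort(rng.uniform(0, 500, size=40)),
                   n_ind=rng.choice([1, 2], size=40, p=[0.8, 0.2]).tolist())
        once = filter_independent(log)
        twice = filter_independent(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCaptureRate:
    def _effort(self, rows):
        return pd.DataFrame(rows, columns=["station_id", "cell_id",
                                           "effort_days"])

    def test_events_per_camera_day(self):
        events = _log([0, 30, 60, 90, 120])
        rates = capture_rate(events, self._effort([("s1", 0, 100.0)]))
        assert rates["rate"].iloc[0] == pytest.approx(0.05)

    def test_zero_events_is_rate_zero_not_missing(self):
        rates = capture_rate(_log([])[:0], self._effort([("s1", 3, 50.0)]))
        assert rates["rate"].iloc[0] == 0.0 and rates["cell_id"].iloc[0] == 3

    def test_stations_in_same_cell_pool(self):
        events = pd.concat([_log([0, 30], station="s1"),
                            _log([5, 40, 80], station="s2")])
        rates = capture_rate(events, self._effort([("s1", 0, 30.0),
                                                   ("s2", 0, 70.0)]))
        assert len(rates) == 1
        assert rates["rate"].iloc[0] == pytest.approx(5 / 100)

    def test_events_without_effort_is_error(self):
        with pytest.raises(ValueError):
            capture_rate(_log([0.0], cell=9), self._effort([("s1", 0, 10.0)]))


class TestQuantileFit:
    def test_perfect_line_has_unit_r1(self):
        x = np.linspace(0, 1, 20)
        for tau in (0.5, 0.9):
            f = quantile_fit(x, x.copy(), tau)
            assert f.slope == pytest.approx(1.0, abs=1e-9)
            assert f.intercept == pytest.approx(0.0, abs=1e-9)
            assert f.r1 == pytest.approx(1.0)

    def test_median_through_collinear_points(self):
        f = quantile_fit(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]),
                         0.5)
        assert (f.slope, f.intercept) == (pytest.approx(1.0),
                                          pytest.approx(0.0))

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.8, 0.95])
    def test_matches_pairline_enumeration_oracle(self, tau):
        rng = np.random.default_rng(int(tau * 100))
        for _ in range(50):
            n = rng.integers(3, 13)
            x = rng.uniform(size=n)
            y = rng.uniform(size=n)
            f = quantile_fit(x, y, tau)
            assert abs(f.loss - pairline_oracle(x, y, tau)) <= 1e-9
            assert f.subgradient_ok()

    def test_matches_statsmodels(self):
        from statsmodels.regression.quantile_regression import QuantReg

        rng = np.random.default_rng(7)
        x = rng.uniform(size=200)
        y = rng.uniform(size=200) * x
        for tau in (0.6, 0.9):
            f = quantile_fit(x, y, tau)
            sm = QuantReg(y, np.column_stack([np.ones(200), x])).fit(q=tau)
            sm_loss = pinball_loss(y - sm.params[0] - sm.params[1] * x, tau)
            assert f.loss <= sm_loss + 1e-6
            assert f.slope == pytest.approx(sm.params[1], abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            quantile_fit(np.ones(10), np.arange(10.0), 0.5)
        with pytest.raises(ValueError):
            quantile_fit(np.arange(2.0), np.arange(2.0), 0.5)
        with pytest.raises(ValueError):
            quantile_fit(np.arange(5.0), np.arange(5.0), 1.0)


class TestWedgeProfile:
    def test_slopes_track_tau_on_wedge_data(self):
        monotone = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = rng.uniform(size=1000)
            y = rng.uniform(size=1000) * s          # ceiling a=0, b=1
            slopes = [f.slope for f in wedge_profile(s, y)]
            monotone += all(b >= a for a, b in zip(slopes, slopes[1:]))
        assert monotone >= 8

    def test_null_data_has_flat_slopes(self):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            x = rng.uniform(size=2000)
            y = rng.uniform(size=2000)
            assert max(abs(f.slope) for f in wedge_profile(x, y)) < 0.1

    def test_duplicating_points_changes_nothing(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(size=50)
        y = rng.uniform(size=50) * x
        for f1, f2 in zip(wedge_profile(x, y, (0.6, 0.9)),
                          wedge_profile(np.tile(x, 2), np.tile(y, 2),
                                        (0.6, 0.9))):
            assert f1.slope == pytest.approx(f2.slope, abs=1e-8)
            assert f1.intercept == pytest.approx(f2.intercept, abs=1e-8)


class TestSelectQuantile:
    def _fit(self, tau, r1, slope, intercept):
        from wedge_sdm.abundance import QuantileFit
        return QuantileFit(tau, slope, intercept, r1, 100, 1.0, 2.0)

    def test_dominating_fit_selected(self):
        fits = [self._fit(0.6, 0.1, 0.5, 0.1), self._fit(0.9, 0.4, 1.0, 0.0)]
        assert select_quantile(fits).selected.tau == 0.9

    def test_r1_tie_broken_by_slope(self):
        fits = [self._fit(0.9, 0.300, 1.0, 0.0),
                self._fit(0.95, 0.301, 2.0, 0.0)]
        assert select_quantile(fits).selected.slope == 2.0

    def test_r1_peak_profile_selects_peak(self):
        r1s = [0.05, 0.10, 0.20, 0.35, 0.50, 0.48, 0.30, 0.20, 0.10, 0.05]
        fits = [self._fit(t, r, 1.0, 0.0) for t, r in zip(DEFAULT_TAUS, r1s)]
        assert select_quantile(fits).selected.tau == 0.90

    def test_no_positive_slope_flagged(self):
        fits = [self._fit(0.6, 0.2, -0.5, 0.1), self._fit(0.9, 0.1, -1.0, 0.0)]
        sel = select_quantile(fits)
        assert not sel.positive_wedge
        assert sel.selected.r1 == 0.2
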