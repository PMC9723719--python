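"""Weekly grid, Morlet wavelets, coherence and phase segmentation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from sarcycle import (
    WeeklySeries, compare_phases, consecutive_distances, minmax_standardize,
    morlet_cwt, segment_phases, snap_to_monday, to_weekly_grid,
    wavelet_coherence,
)
from sarcycle.env_coupling import dyadic_scales, _fourier_factor


class TestMinmax:
    def test_hand_values(self):
        np.testing.assert_allclose(minmax_standardize([2, 4, 6]),
                                   [0.0, 0.5, 1.0])

    def test_unit_interval_series_unchanged(self):
        x = np.array([0.0, 0.25, 0.9, 1.0])
        np.testing.assert_allclose(minmax_standardize(x), x)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.0, 5.0, 3.5])
        np.testing.assert_allclose(minmax_standardize(a * x + b),
                                   minmax_standardize(x), atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            minmax_standardize([3.0, 3.0, 3.0])


class TestSnapToMonday:
    @pytest.mark.parametrize("date,expected", [
        ("2016-06-15", "2016-06-13"),   # Wednesday -> previous Monday
        ("2016-06-17", "2016-06-20"),   # Friday -> next Monday
        ("2016-06-13", "2016-06-13"),   # Monday -> itself
    ])
    def test_calendar_arithmetic(self, date, expected):
        snapped, report = snap_to_monday(
            pd.Series(pd.to_datetime([date]), index=["s"]))
        assert snapped.iloc[0] == pd.Timestamp(expected)
        assert report.empty

    @given(st.integers(0, 3650))
    def test_never_moves_more_than_three_days(self, offset):
        d = pd.Timestamp("2015-01-01") + pd.Timedelta(days=offset)
        snapped, _ = snap_to_monday(pd.Series([d], index=["s"]))
        assert abs((snapped.iloc[0] - d).days) <= 3
        assert snapped.iloc[0].weekday() == 0

    def test_collision_keeps_nearer_sample(self):
        dates = pd.Series(pd.to_datetime(["2016-06-14", "2016-06-15"]),
                          index=["near", "far"])   # Tue (1 day), Wed (2 days)
        snapped, report = snap_to_monday(dates)
        assert list(snapped.index) == ["near"]
        assert report["sample_id"].tolist() == ["far"]


class TestWeeklyGrid:
    def test_midpoint_interpolation(self):
        dates = pd.Series(pd.to_datetime(["2016-06-13", "2016-06-27"]),
                          index=["a", "b"])
        ws = to_weekly_grid(dates, pd.Series([1.0, 3.0], index=["a", "b"]))
        np.testing.assert_allclose(ws.values.iloc[:, 0], [1.0, 2.0, 3.0])
        assert ws.interpolated_mask.tolist() == [False, True, False]

    def test_complete_grid_is_identity(self):
        dates = pd.Series(pd.date_range("2016-06-13", periods=5, freq="7D"),
                          index=list("abcde"))
        vals = pd.Series(np.arange(5.0), index=dates.index)
        ws = to_weekly_grid(dates, vals)
        assert not ws.interpolated_mask.any()
        np.testing.assert_allclose(ws.values.iloc[:, 0], vals.to_numpy())

    def test_grid_spacing_enforced(self):
        bad_dates = pd.DatetimeIndex(["2016-06-13", "2016-06-21"])
        with pytest.raises(ValueError, match="7 days"):
            WeeklySeries(bad_dates, pd.DataFrame({"x": [1.0, 2.0]},
                                                 index=bad_dates),
                         np.array([False, False]))


class TestConsecutiveDistances:
    def test_identical_rows_give_zero(self):
        dates = pd.date_range("2016-06-13", periods=3, freq="7D")
        ws = WeeklySeries(dates, pd.DataFrame({"x": [0.2] * 3,
                                               "y": [0.8] * 3}, index=dates),
                          np.zeros(3, bool))
        assert (consecutive_distances(ws, "bray_curtis") == 0).all()

    def test_unit_step_appears_once(self):
        dates = pd.date_range("2016-06-13", periods=8, freq="7D")
        vals = pd.DataFrame({"x": [0.0] * 6 + [1.0] * 2}, index=dates)
        d = consecutive_distances(WeeklySeries(dates, vals,
                                               np.zeros(8, bool)))
        np.testing.assert_allclose(d.to_numpy(),
                                   [0, 0, 0, 0, 0, 1.0, 0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        dates = pd.date_range("2016-06-13", periods=10, freq="7D")
        vals = pd.DataFrame(rng.random((10, 4)), index=dates)
        ws = WeeklySeries(dates, vals, np.zeros(10, bool))
        d = consecutive_distances(ws, "euclidean").to_numpy()
        for i in range(9):
            assert d[i] == pytest.approx(np.linalg.norm(
                vals.iloc[i + 1] - vals.iloc[i]))


class TestMorletCwt:
    def test_ridge_at_sinusoid_period(self):
        n = 128
        t = np.arange(n)
        y = np.sin(2 * np.pi * t / 16)
        scales = dyadic_scales(n)
        w = morlet_cwt(y, scales)
        periods = _fourier_factor(6.0) * scales
        power = np.abs(w) ** 2
        # inside the cone of influence, the power maximum tracks 16 weeks
        for ti in range(30, 98):
            ridge = periods[np.argmax(power[:, ti])]
            assert 16 / 2 ** (1 / 20) <= ridge <= 16 * 2 ** (1 / 20)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(64)
        scales = dyadic_scales(64)
        np.testing.assert_allclose(morlet_cwt(2 * y, scales),
                                   2 * morlet_cwt(y, scales), atol=1e-10)

    def test_total_power_tracks_variance(self):
        # white noise: mean wavelet power over scales ~ series variance
        rng = np.random.default_rng(2)
        n = 128
        scales = dyadic_scales(n)
        dj = 1 / 20
        ratio = []
        for _ in range(200):
            y = rng.standard_normal(n)
            w = morlet_cwt(y, scales)
            # Torrence & Compo variance reconstruction (Morlet: C_delta 0.776)
            power = (np.abs(w) ** 2 / scales[:, None]).sum()
            est = power * dj / (0.776 * n)
            ratio.append(est / y.var())
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            morlet_cwt(np.ones(5), np.array([1.0]))


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(96)
        m = wavelet_coherence(x, x + 1e-9 * rng.standard_normal(96),
                              n_sim=20, seed=0)
        assert m.coherence.min() > 0.99

    def test_coherence_bounded(self):
        rng = np.random.default_rng(4)
        m = wavelet_coherence(rng.standard_normal(96),
                              rng.standard_normal(96), n_sim=20, seed=0)
        assert (m.coherence >= 0).all() and (m.coherence <= 1).all()

    def test_null_significance_rate_inside_coi(self):
        rng = np.random.default_rng(5)
        fracs = []
        for seed in range(10):
            m = wavelet_coherence(rng.standard_normal(104),
                                  rng.standard_normal(104),
                                  n_sim=100, alpha=0.05, seed=seed)
            fracs.append(m.significant[m.in_coi].mean())
        assert np.mean(fracs) <= 0.10

    def test_shared_driver_gives_in_phase_band(self):
        rng = np.random.default_rng(6)
        t = np.arange(104)
        driver = np.sin(2 * np.pi * t / 16)
        x = driver + 0.3 * rng.standard_normal(104)
        y = driver + 0.3 * rng.standard_normal(104)
        m = wavelet_coherence(x, y, n_sim=100, seed=0)
        band = (np.abs(np.log2(m.periods / 16)) < 0.5)
        cells = m.significant & m.in_coi & band[:, None]
        assert cells.any()
        phases = m.phase_difference[cells]
        assert (np.abs(phases) < np.pi / 4).mean() >= 0.8

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wavelet_coherence(np.ones(64), np.random.default_rng(0)
                              .standard_normal(64), n_sim=5)


class TestSegmentPhases:
    def test_fully_coherent_pair_is_one_coupled_interval(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(104)
        m = wavelet_coherence(x, x + 0.05 * rng.standard_normal(104),
                              n_sim=50, seed=0)
        intervals = segment_phases(m)
        assert len(intervals) == 1
        assert intervals["label"].iloc[0] == "coupled"

    def test_independent_noise_yields_no_coupling(self):
        rng = np.random.default_rng(8)
        any_coupled = []
        for seed in range(10):
            m = wavelet_coherence(rng.standard_normal(104),
                                  rng.standard_normal(104),
                                  n_sim=100, seed=seed)
            coupled = segment_phases(m).attrs["coupled"]
            any_coupled.append(coupled.mean())
        assert np.mean(any_coupled) <= 0.05

    def test_two_regime_changepoint_located(self):
        # second half shares a 16-week driver, first half independent
        rng = np.random.default_rng(9)
        t = np.arange(104)
        driver = (1 + 0.8 * np.sin(2 * np.pi * t / 16)) \
            * np.abs(rng.standard_normal(104))
        x = np.where(t < 52, rng.standard_normal(104), driver)
        y = driver + 0.2 * np.abs(rng.standard_normal(104))
        m = wavelet_coherence(x, y, n_sim=100, seed=1)
        coupled = segment_phases(m).attrs["coupled"].to_numpy()
        # coupling should be concentrated in the driven half
        assert coupled[60:96].mean() > coupled[8:44].mean() + 0.3

    def test_window_longer_than_series_rejected(self):
        rng = np.random.default_rng(10)
        m = wavelet_coherence(rng.standard_normal(32),
                              rng.standard_normal(32), n_sim=10, seed=0)
        with pytest.raises(ValueError, match="window"):
            segment_phases(m, window=100)


class TestComparePhases:
    def _weekly(self, values: dict, n: int) -> WeeklySeries:
        dates = pd.date_range("2016-01-04", periods=n, freq="7D")
        return WeeklySeries(dates, pd.DataFrame(values, index=dates),
                            np.zeros(n, bool))

    def test_identical_variable_not_significant(self):
        n = 20
        ws = self._weekly({"v": np.tile([1.0, 2.0], 10)}, n)
        coupled = pd.Series([True] * 10 + [False] * 10,
                            index=ws.monday_dates)
        out = compare_phases(ws, coupled)
        assert out.loc["v", "p_value"] > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(11)
        n = 40
        base = rng.standard_normal(n)
        base[:20] += 5.0
        ws = self._weekly({"v": base}, n)
        coupled = pd.Series([True] * 20 + [False] * 20,
                            index=ws.monday_dates)
        assert compare_phases(ws, coupled).loc["v", "p_value"] < 0.001

    def test_u_statistic_matches_enumeration(self):
        # exact two-sided p for 4 vs 4 from the permutation distribution
        a = np.array([1.2, 3.4, 0.5, 2.2])
        b = np.array([2.9, 0.1, 4.4, 3.3])
        u_obs, p_scipy = mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact")
        pooled = np.concatenate([a, b])
        us = []
        for subset in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(subset)] = True
            u, _ = mannwhitneyu(pooled[mask], pooled[~mask],
                                alternative="two-sided")
            us.append(u)
        us = np.array(us)
        n1 = n2 = 4
        mid = n1 * n2 / 2
        exact_p = (np.abs(us - mid) >= np.abs(u_obs - mid) - 1e-12).mean()
        assert p_scipy == pytest.approx(exact_p, abs=1e-9)

    def test_single_phase_rejected(self):
        ws = self._weekly({"v": np.arange(10.0)}, 10)
        coupled = pd.Series([True] * 10, index=ws.monday_dates)
        with pytest.raises(ValueError, match="both phases"):
            compare_phases(ws, coupled)
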