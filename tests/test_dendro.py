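"""Tree water deficit extraction and daily swelling/shrinkage cycles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stemwater.dendro import (
    RadiusSeries,
    compute_plwe_at,
    compute_twd,
    daily_extremes,
    drought_cycles,
)


def _series(r, start="2021-07-01", freq="10min", tree_id="t1"):
    t = pd.date_range(start, periods=len(r), freq=freq)
    return RadiusSeries(tree_id=tree_id, species="beech", t=t, r=np.asarray(r, float))


def _oracle_twd(r):
    """O(n^2) prefix-max definition, independent of the implementation."""
    return np.array([max(r[: i + 1]) - r[i] for i in range(len(r))])


class TestComputeTwd:
    def test_monotone_increasing_radius_gives_zero_deficit(self):
        tw = compute_twd(_series(np.linspace(0, 50, 200)))
        assert np.all(tw.twd == 0)

    def test_worked_prefix_max_example(self):
        tw = compute_twd(_series([100.0, 98.0, 99.0, 101.0, 97.0]))
        np.testing.assert_array_equal(tw.twd, [0.0, 2.0, 1.0, 0.0, 4.0])
        assert tw.twd_max == 4.0
        np.testing.assert_allclose(tw.plwe, [0.0, 50.0, 25.0, 0.0, 100.0])
        np.testing.assert_allclose(tw.tws, tw.twd_max - tw.twd)

    @given(st.integers(0, 1000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(0, 5, size=rng.integers(2, 300)).cumsum() + 1000
        tw = compute_twd(_series(r))
        np.testing.assert_allclose(tw.twd, _oracle_twd(r), atol=0)

    def test_idempotent_on_running_max_envelope(self):
        rng = np.random.default_rng(3)
        r = rng.normal(0, 5, 500).cumsum()
        envelope = np.maximum.accumulate(r)
        assert np.all(compute_twd(_series(envelope)).twd == 0)

    def test_plwe_nondecreasing_when_radius_nonincreasing(self):
        rng = np.random.default_rng(4)
        r = 1000 - np.abs(rng.normal(0, 2, 300)).cumsum()
        tw = compute_twd(_series(r))
        assert np.all(np.diff(tw.plwe) >= 0)

    def test_short_gap_interpolated_long_gap_errors(self):
        r = np.linspace(100, 90, 100)
        r[10:14] = np.nan  # 40 min: within the 60-min policy
        tw = compute_twd(_series(r))
        assert np.isfinite(tw.twd).all()
        r[50:60] = np.nan  # 100 min
        with pytest.raises(ValueError, match="gap"):
            compute_twd(_series(r))

    def test_external_twd_max_override_scales_plwe(self):
        tw = compute_twd(_series([100.0, 98.0, 96.0]), twd_max=8.0)
        np.testing.assert_allclose(tw.plwe, [0.0, 25.0, 50.0])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            compute_twd(_series([1.0]))


class TestPlweAt:
    @pytest.mark.parametrize(
        "twd,twd_max,expected", [(0.0, 7.0, 0.0), (4.0, 4.0, 100.0), (2.0, 4.0, 50.0)]
    )
    def test_values(self, twd, twd_max, expected):
        assert compute_plwe_at(twd, twd_max) == expected

    def test_invalid_twd_max(self):
        with pytest.raises(ValueError):
            compute_plwe_at(1.0, 0.0)

    def test_over_100_flagged(self):
        with pytest.warns(UserWarning, match="exceeds 100"):
            compute_plwe_at(5.0, 4.0)


class TestDailyExtremes:
    def test_constant_twd_gives_zero_swelling_and_shrinkage(self):
        t = pd.date_range("2021-07-01", periods=5 * 144, freq="10min")
        tw = compute_twd(_series(np.full(len(t), 100.0)))
        cycles = daily_extremes(tw)
        assert all(c.shrinkage == 0 for c in cycles)
        assert all(c.swelling == 0 for c in cycles if np.isfinite(c.swelling))

    def test_sinusoid_matches_window_minmax_oracle(self, sine_radius):
        t, r = sine_radius
        series = RadiusSeries("t1", "beech", t, r)
        tw = compute_twd(series)
        cycles = daily_extremes(tw, (3, 7), (12, 18))
        # brute-force oracle over the same windows
        df = pd.DataFrame({"twd": tw.twd}, index=t)
        hours = t.hour + t.minute / 60.0
        for c in cycles[1:-1]:
            day = df[t.normalize() == c.date]
            h = hours[t.normalize() == c.date]
            assert c.twd_pd == pytest.approx(day["twd"][(h >= 3) & (h < 7)].min())
            assert c.twd_md == pytest.approx(day["twd"][(h >= 12) & (h < 18)].max())
            assert c.shrinkage == pytest.approx(c.twd_md - c.twd_pd)

    def test_pure_drying_gives_nonpositive_swelling(self):
        t = pd.date_range("2021-07-01", periods=4 * 144, freq="10min")
        tw = compute_twd(_series(1000 - np.linspace(0, 40, len(t))))
        cycles = daily_extremes(tw)
        finite = [c for c in cycles if np.isfinite(c.swelling)]
        assert all(c.swelling <= 0 for c in finite)
        assert all(c.shrinkage > 0 for c in cycles)

    def test_telescoping_identity(self, sine_radius):
        """swelling(d) - shrinkage(d) telescopes to the predawn-to-predawn
        change in TWD, exactly on gap-free data."""
        t, r = sine_radius
        rng = np.random.default_rng(0)
        r = r - np.abs(rng.normal(0, 1, len(r))).cumsum() * 0.01
        tw = compute_twd(RadiusSeries("t1", "beech", t, r))
        cycles = daily_extremes(tw)
        by_date = {c.date: c for c in cycles}
        for c in cycles:
            nxt = by_date.get(c.date + pd.Timedelta(days=1))
            if nxt is None or not np.isfinite(c.swelling):
                continue
            assert c.shrinkage - c.swelling == pytest.approx(
                nxt.twd_pd - c.twd_pd, abs=1e-9
            )

    def test_empty_window_errors(self):
        t = pd.date_range("2021-07-01", periods=3 * 144, freq="10min")
        tw = compute_twd(_series(np.linspace(10, 0, len(t))))
        with pytest.raises(ValueError):
            daily_extremes(tw, (3, 3), (12, 18))


class TestDroughtCycles:
    def _cycles_with_peak(self, peak_day, n_days=30):
        t = pd.date_range("2021-07-01", periods=n_days * 144, freq="10min")
        day = np.arange(len(t)) / 144.0
        hours = t.hour + t.minute / 60.0
        diurnal = -3.0 * np.cos(2 * np.pi * (hours - 13.0) / 24.0)  # midday minimum
        r = np.where(day <= peak_day, day * 10.0, peak_day * 10.0 - (day - peak_day) * 1.0)
        series = RadiusSeries("t1", "beech", t, r + diurnal)
        tw = compute_twd(series)
        return daily_extremes(tw), series

    def test_keeps_only_days_after_radius_maximum(self):
        cycles, series = self._cycles_with_peak(peak_day=10)
        kept = drought_cycles(cycles, series)
        peak_date = series.t[int(np.argmax(series.r))].normalize()
        assert all(c.date > peak_date for c in kept)
        assert len(kept) > 0

    def test_max_swelling_normalizes_to_one(self):
        cycles, series = self._cycles_with_peak(peak_day=10)
        kept = drought_cycles(cycles, series)
        finite = [c.swelling_norm for c in kept if np.isfinite(c.swelling_norm)]
        assert max(finite) == pytest.approx(1.0)
        finite_sh = [c.shrinkage_norm for c in kept if np.isfinite(c.shrinkage_norm)]
        assert max(finite_sh) == pytest.approx(1.0)

    def test_peak_on_final_day_returns_empty_with_warning(self):
        t = pd.date_range("2021-07-01", periods=5 * 144, freq="10min")
        series = RadiusSeries("t1", "beech", t, np.linspace(0, 10, len(t)))
        cycles = daily_extremes(compute_twd(series))
        with pytest.warns(UserWarning, match="final day"):
            assert drought_cycles(cycles, series) == []

    def test_degenerate_normalization_flagged(self):
        t = pd.date_range("2021-07-01", periods=6 * 144, freq="10min")
        day = np.arange(len(t)) / 144.0
        # rises then holds perfectly flat: zero swelling and shrinkage after peak
        r = np.where(day <= 2, day * 5.0, 10.0)
        series = RadiusSeries("t1", "beech", t, r)
        cycles = daily_extremes(compute_twd(series))
        with pytest.warns(UserWarning, match="degenerate"):
            kept = drought_cycles(cycles, series)
        assert kept and all(c.degenerate for c in kept)
        assert all(np.isnan(c.swelling_norm) for c in kept)
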